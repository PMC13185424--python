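"""Age-group salience comparison via two-sample randomization tests.

Participants are split into younger (age classes 1-3, i.e. 18-45 years) and
older (classes 4-6, i.e. 46 and above).  For each taxon, the test statistic
is the difference in group means of the per-participant Smith's-S
contributions c_i; the null distribution is generated by permuting group
labels over participants (the participant, with their whole freelist, is the
exchangeable unit).  The two-sided Monte-Carlo p-value uses the add-one
estimator p = (1 + #{|d*| >= |d|}) / (n_perm + 1), which is strictly
positive and valid; for small samples the permutation distribution can be
enumerated exhaustively instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .harmonize import AnnotatedFreelist
from .salience import AnyFreelist, participant_salience, salience_table
from .types import ParameterError, ParticipantRecord, N_AGE_CLASSES


@dataclass(frozen=True)
class AgeSplit:
    """Partition of the six age classes into a younger and an older group."""

    young_classes: frozenset[int] = frozenset({1, 2, 3})
    labels: tuple[str, str] = ("young", "old")

    def group_of(self, participant: ParticipantRecord) -> int:
        """0 for the younger group (A), 1 for the older group (B)."""
        return 0 if participant.age_class in self.young_classes else 1


def _one_list_per_participant(
    freelists: Sequence[AnyFreelist],
) -> dict[str, AnyFreelist]:
    by_pid: dict[str, AnyFreelist] = {}
    for fl in freelists:
        if fl.participant_id in by_pid:
            raise ParameterError(
                f"participant {fl.participant_id!r} has more than one freelist; "
                f"pass a single question domain at a time"
            )
        by_pid[fl.participant_id] = fl
    return by_pid


def participant_contributions(
    freelists: Sequence[AnyFreelist],
    participants: Sequence[ParticipantRecord],
    taxon: str,
) -> np.ndarray:
    """Vector of c_i in participant order; participants without a freelist
    contribute 0 (they listed nothing)."""
    by_pid = _one_list_per_participant(freelists)
    out = np.zeros(len(participants))
    for i, p in enumerate(participants):
        fl = by_pid.get(p.participant_id)
        if fl is not None:
            out[i] = participant_salience(fl, taxon)
    return out


def group_salience(
    freelists: Sequence[AnyFreelist],
    participants: Sequence[ParticipantRecord],
    split: AgeSplit = AgeSplit(),
    taxa: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Salience tables computed separately within each age group, each group's
    own size serving as the Smith's-S denominator."""
    by_pid = _one_list_per_participant(freelists)
    groups: tuple[list[AnyFreelist], list[AnyFreelist]] = ([], [])
    for p in participants:
        fl = by_pid.get(p.participant_id)
        if fl is not None:
            groups[split.group_of(p)].append(fl)
    if not groups[0] or not groups[1]:
        raise ParameterError("both age groups must contain participants with freelists")
    if taxa is None:
        taxa = sorted({item.label for fl in freelists for item in fl.items})
    return (
        salience_table(groups[0], taxa, group=split.labels[0]),
        salience_table(groups[1], taxa, group=split.labels[1]),
    )


@dataclass(frozen=True)
class RandTestResult:
    taxon: str
    group_labels: tuple[str, str]
    observed_diff: float        # mean c in group B (older) minus group A (younger)
    n_perm: int
    p_value: float
    seed: int | None
    method: str = "montecarlo"  # or "exhaustive"


def _exhaustive_p(c: np.ndarray, n_a: int, observed: float) -> tuple[float, int]:
    n = len(c)
    total = math.comb(n, n_a)
    count = 0
    idx = np.arange(n)
    tol = 1e-12
    for a_idx in combinations(idx, n_a):
        mask = np.zeros(n, bool)
        mask[list(a_idx)] = True
        diff = c[~mask].mean() - c[mask].mean()
        if abs(diff) >= abs(observed) - tol:
            count += 1
    return count / total, total


def salience_randomization_test(
    freelists: Sequence[AnyFreelist],
    participants: Sequence[ParticipantRecord],
    taxon: str,
    split: AgeSplit = AgeSplit(),
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> RandTestResult:
    """Two-sample randomization test for a between-group difference in mean
    per-participant salience contributions.

    With ``exact=True`` the group-label assignments are enumerated
    exhaustively (feasible for small samples) and the p-value is the exact
    proportion of assignments at least as extreme as the observed one.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    labels = np.array([split.group_of(p) for p in participants])
    n_a = int((labels == 0).sum())
    n_b = int((labels == 1).sum())
    if n_a == 0 or n_b == 0:
        raise ParameterError("both groups must be non-empty")

    c = participant_contributions(freelists, participants, taxon)
    observed = c[labels == 1].mean() - c[labels == 0].mean()

    if exact:
        p, total = _exhaustive_p(c, n_a, observed)
        return RandTestResult(
            taxon, split.labels, float(observed), total, p, seed, "exhaustive"
        )

    rng = np.random.default_rng(seed)
    n = len(c)
    # permute labels by drawing random group-A index sets, vectorized
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_a = np.take(c, order[:, :n_a]).mean(axis=1)
    total_mean = c.mean()
    # group means are linked through the grand total: n_a*mean_a + n_b*mean_b = n*mean
    perm_b = (n * total_mean - n_a * perm_a) / n_b
    perm_diff = perm_b - perm_a
    count = int(np.sum(np.abs(perm_diff) >= abs(observed) - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return RandTestResult(taxon, split.labels, float(observed), n_perm, p, seed)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def salience_randomization_tests(
    freelists: Sequence[AnyFreelist],
    participants: Sequence[ParticipantRecord],
    taxa: Iterable[str],
    split: AgeSplit = AgeSplit(),
    n_perm: int = 10_000,
    seed: int | None = None,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Run the randomization test for each taxon; one independent substream
    of the seeded generator per taxon.

    ``p_adjust`` optionally applies a multiple-testing correction
    ("holm" or "bonferroni") in an extra column; raw p-values are always
    reported.
    """
    taxa = list(taxa)
    seeds = (
        np.random.SeedSequence(seed).spawn(len(taxa)) if seed is not None else [None] * len(taxa)
    )
    rows = []
    for taxon, ss in zip(taxa, seeds):
        sub_seed = None if ss is None else int(ss.generate_state(1)[0] % (2**31))
        res = salience_randomization_test(
            freelists, participants, taxon, split, n_perm, sub_seed
        )
        rows.append(
            {
                "taxon": taxon,
                "observed_diff": res.observed_diff,
                "n_perm": res.n_perm,
                "p_value": res.p_value,
                "stars": significance_stars(res.p_value),
            }
        )
    df = pd.DataFrame(rows)
    if p_adjust is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bonferroni": "bonferroni"}.get(p_adjust)
        if method is None:
            raise ParameterError(f"unknown p_adjust {p_adjust!r}")
        df["p_adjusted"] = multipletests(df["p_value"], method=method)[1]
    return df.sort_values("observed_diff", kind="stable").reset_index(drop=True)


def indicator_frequency_by_age(
    freelists: Sequence[AnyFreelist],
    participants: Sequence[ParticipantRecord],
    indicator_taxa: Iterable[str],
) -> pd.DataFrame:
    """Per (indicator taxon, age class): listers, class size, relative frequency.

    Age classes without any participants are omitted with a warning.
    """
    by_pid = _one_list_per_participant(freelists)
    class_members: dict[int, list[str]] = {k: [] for k in range(1, N_AGE_CLASSES + 1)}
    for p in participants:
        class_members[p.age_class].append(p.participant_id)
    empty = [k for k, members in class_members.items() if not members]
    if empty:
        warnings.warn(f"age classes without participants omitted: {empty}", stacklevel=2)

    rows = []
    for taxon in indicator_taxa:
        listers = {
            pid
            for pid, fl in by_pid.items()
            if any(item.label == taxon for item in fl.items)
        }
        for k, members in class_members.items():
            if not members:
                continue
            n_in_class = len(members)
            n_listers = sum(1 for pid in members if pid in listers)
            rows.append(
                {
                    "taxon": taxon,
                    "age_class": k,
                    "n_listers": n_listers,
                    "n_in_class": n_in_class,
                    "rel_freq": n_listers / n_in_class,
                }
            )
    return pd.DataFrame(
        rows, columns=["taxon", "age_class", "n_listers", "n_in_class", "rel_freq"]
    )
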