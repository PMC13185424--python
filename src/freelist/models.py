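"""Negative-binomial list-length regression with fixed-df smooth terms.

List lengths are overdispersed counts, modelled with a log link and NB2
variance mu + alpha*mu^2 (alpha = 1/theta estimated by maximum likelihood).
Demographic predictors (age, education, income as ordinal class codes,
gender as a factor) enter through one of four effect types:

    I    linear:                length ~ x
    II   smooth:                length ~ s(x)
    III  linear with gender:    length ~ x * gender
    IV   smooth by gender:      length ~ gender + s(x):female + s(x):male

Smooths are unpenalized fixed-df terms (default df = 2, the analogue of a
3-knot regression spline with fixed basis dimension), built from a
QR-orthogonalized polynomial basis centered against the intercept.  Effect
types are chosen per predictor by AIC on univariate fits; the joint model is
then pruned by backward elimination using likelihood-ratio chi-square tests
until every remaining term is significant at the 5% level, never dropping a
main effect while one of its interactions remains.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import FitError, Gender, ParameterError

__all__ = [
    "spline_basis",
    "Term",
    "EffectType",
    "EffectSpec",
    "ModelFit",
    "fit_nb",
    "select_effect_type",
    "backward_select",
    "model_frame",
    "fit_binomial_glmm",
    "GlmmFit",
]


def spline_basis(x: np.ndarray | Sequence[float], df: int) -> np.ndarray:
    """Fixed-df smooth basis: df orthonormal polynomial columns in x.

    Columns are orthogonal to the constant (centered), mutually orthonormal,
    and deterministic given (x, df); df = 1 spans the same space as a plain
    linear term.  Requires more distinct x values than df.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ParameterError(f"smooth df must be >= 1, got {df}")
    if np.unique(x).size <= df:
        raise ParameterError(
            f"smooth basis of df={df} needs at least {df + 1} distinct values, "
            f"got {np.unique(x).size}"
        )
    xc = x - x.mean()
    powers = np.vander(xc / max(np.abs(xc).max(), 1e-12), df + 1, increasing=True)
    q, r = np.linalg.qr(powers)
    # fix the QR sign ambiguity so the basis is reproducible
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:] * np.sqrt(len(x))


class EffectType(enum.Enum):
    LINEAR = "I"
    SMOOTH = "II"
    LINEAR_BY_GENDER = "III"
    SMOOTH_BY_GENDER = "IV"


#: preference order used to break AIC ties (simpler effect wins)
_TYPE_PREFERENCE = [
    EffectType.LINEAR,
    EffectType.LINEAR_BY_GENDER,
    EffectType.SMOOTH,
    EffectType.SMOOTH_BY_GENDER,
]


@dataclass(frozen=True)
class Term:
    """One named, droppable block of design-matrix columns."""

    name: str
    kind: str                      # linear | smooth | gender | interaction | smooth_by
    predictor: str | None = None
    df: int = 1
    level: str | None = None       # gender level for smooth_by terms
    requires: tuple[str, ...] = () # marginality: terms that must stay while this does

    def columns(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        if self.kind == "linear":
            return data[self.predictor].to_numpy(float)[:, None], [self.name]
        if self.kind == "smooth":
            basis = spline_basis(data[self.predictor].to_numpy(float), self.df)
            return basis, [f"{self.name}.{j + 1}" for j in range(self.df)]
        if self.kind == "gender":
            male = _male_indicator(data)
            return male[:, None], ["gender[male]"]
        if self.kind == "interaction":
            male = _male_indicator(data)
            x = data[self.predictor].to_numpy(float)
            return (x * male)[:, None], [self.name]
        if self.kind == "smooth_by":
            male = _male_indicator(data)
            mask = male if self.level == "male" else 1.0 - male
            basis = spline_basis(data[self.predictor].to_numpy(float), self.df)
            return basis * mask[:, None], [
                f"{self.name}.{j + 1}" for j in range(self.df)
            ]
        raise ParameterError(f"unknown term kind {self.kind!r}")

    @property
    def n_columns(self) -> int:
        return self.df if self.kind in ("smooth", "smooth_by") else 1

    @property
    def uses(self) -> tuple[str, ...]:
        cols = () if self.predictor is None else (self.predictor,)
        if self.kind in ("gender", "interaction", "smooth_by"):
            cols = cols + ("gender",)
        return cols


def _male_indicator(data: pd.DataFrame) -> np.ndarray:
    g = data["gender"]
    return np.asarray(
        [1.0 if (v.value if isinstance(v, Gender) else str(v)) == "male" else 0.0 for v in g]
    )


@dataclass(frozen=True)
class EffectSpec:
    """A predictor together with its selected effect type."""

    predictor: str
    effect_type: EffectType
    df: int = 2  # smooth basis dimension (k - 1 with a 3-knot fixed basis)

    def terms(self) -> list[Term]:
        p, df = self.predictor, self.df
        if self.effect_type is EffectType.LINEAR:
            return [Term(p, "linear", p)]
        if self.effect_type is EffectType.SMOOTH:
            return [Term(f"s({p})", "smooth", p, df=df)]
        if self.effect_type is EffectType.LINEAR_BY_GENDER:
            return [
                Term("gender", "gender"),
                Term(p, "linear", p),
                Term(f"{p}:gender", "interaction", p, requires=(p, "gender")),
            ]
        return [
            Term("gender", "gender"),
            Term(f"s({p}):female", "smooth_by", p, df=df, level="female", requires=("gender",)),
            Term(f"s({p}):male", "smooth_by", p, df=df, level="male", requires=("gender",)),
        ]


def merge_terms(specs: Sequence[EffectSpec], include_gender: bool = False) -> list[Term]:
    """Combine per-predictor effect specs into one term list, deduplicating
    the gender main effect."""
    terms: list[Term] = []
    names: set[str] = set()
    if include_gender:
        terms.append(Term("gender", "gender"))
        names.add("gender")
    for spec in specs:
        for term in spec.terms():
            if term.name not in names:
                names.add(term.name)
                terms.append(term)
    return terms


def build_design(
    terms: Sequence[Term], data: pd.DataFrame
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Design matrix with intercept, column names, and per-term column slices."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    slices: dict[str, slice] = {}
    pos = 1
    for term in terms:
        cols, colnames = term.columns(data)
        blocks.append(cols)
        names.extend(colnames)
        slices[term.name] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    return np.hstack(blocks), names, slices


def model_frame(
    data: pd.DataFrame, response: str, terms: Sequence[Term]
) -> pd.DataFrame:
    """Casewise-complete rows for the variables this model actually uses."""
    used = {response}
    for term in terms:
        used.update(term.uses)
    return data.dropna(subset=sorted(used)).reset_index(drop=True)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 deviance; reduces to the Poisson deviance as alpha -> 0."""
    y = np.asarray(y, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if alpha < 1e-10:
        return float(2 * np.sum(term1 - (y - mu)))
    term2 = (y + 1 / alpha) * np.log((1 + alpha * y) / (1 + alpha * mu))
    return float(2 * np.sum(term1 - term2))


@dataclass
class ModelFit:
    """A fitted negative-binomial regression and its reporting table."""

    response: str
    terms: list[Term]
    params: pd.Series
    bse: pd.Series
    alpha: float                     # NB2 dispersion (variance mu + alpha mu^2)
    alpha_estimated: bool
    llf: float
    aic: float
    deviance: float
    null_deviance: float
    deviance_explained: float        # percentage
    n: int
    converged: bool
    term_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def summary_frame(self) -> pd.DataFrame:
        """Term-level report: df, chi-square, p, plus fit-level columns."""
        out = self.term_table.copy()
        out["deviance_explained"] = self.deviance_explained
        out["aic"] = self.aic
        out["n"] = self.n
        return out


def _fit_nb_raw(
    y: np.ndarray, X: np.ndarray, alpha: float | None
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Return (params, bse, alpha, llf, converged) for one design matrix."""
    import statsmodels.api as sm

    if alpha is not None:
        if alpha <= 0:
            # vanishing overdispersion: plain Poisson GLM
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            return res.params, res.bse, 0.0, float(res.llf), True
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        return res.params, res.bse, alpha, float(res.llf), True

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poisson = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        start = np.append(poisson.params, 0.1)
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        res = None
        for method in ("bfgs", "newton", "nm"):
            try:
                cand = model.fit(
                    start_params=start, method=method, maxiter=500, disp=0
                )
            except Exception:
                continue
            if cand.mle_retvals.get("converged", False):
                res = cand
                break
            if res is None:
                res = cand
    if res is None:
        raise FitError("negative-binomial fit failed for every optimizer")
    params = np.asarray(res.params[:-1])
    bse = np.asarray(res.bse[:-1])
    est_alpha = float(res.params[-1])
    if est_alpha < 0:
        est_alpha = 0.0
    return params, bse, est_alpha, float(res.llf), bool(
        res.mle_retvals.get("converged", True)
    )


def fit_nb(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[Term],
    alpha: float | None = None,
    term_tests: bool = True,
) -> ModelFit:
    """Maximum-likelihood NB2 regression of a count response on a term list.

    Rows with missing values in any used variable are dropped casewise.
    ``alpha=None`` (default) estimates the dispersion jointly; a fixed alpha
    fits a plain NB GLM at that dispersion (alpha=0 is Poisson).  Per-term
    chi-square tests are likelihood-ratio tests against the model without
    that term, with the dispersion re-estimated in each fit.  AIC counts the
    regression coefficients plus one dispersion parameter when estimated.
    Deviance explained is 100 * (1 - residual deviance / null deviance),
    both deviances evaluated at this model's dispersion.
    """
    frame = model_frame(data, response, terms)
    y = frame[response].to_numpy()
    if len(y) == 0:
        raise ParameterError("no complete cases for this model")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ParameterError("response must be non-negative integer counts")
    y = np.round(y).astype(int)

    X, colnames, slices = build_design(terms, frame)
    params, bse, est_alpha, llf, converged = _fit_nb_raw(y, X, alpha)
    if not converged:
        raise FitError(
            f"NB fit for {response!r} did not converge (terms: "
            f"{[t.name for t in terms]})"
        )

    mu = np.exp(X @ params)
    deviance = _nb_deviance(y, mu, est_alpha)
    null_deviance = _nb_deviance(y, np.full_like(mu, y.mean()), est_alpha)
    dev_expl = (
        100.0 * (1 - deviance / null_deviance) if null_deviance > 0 else 0.0
    )
    n_params = X.shape[1] + (1 if alpha is None else 0)
    aic = -2 * llf + 2 * n_params

    fit = ModelFit(
        response=response,
        terms=list(terms),
        params=pd.Series(params, index=colnames),
        bse=pd.Series(bse, index=colnames),
        alpha=est_alpha,
        alpha_estimated=alpha is None,
        llf=llf,
        aic=aic,
        deviance=deviance,
        null_deviance=null_deviance,
        deviance_explained=float(np.clip(dev_expl, 0.0, 100.0)),
        n=len(y),
        converged=converged,
    )
    if term_tests:
        fit.term_table = _term_chi2_table(frame, y, terms, alpha, llf)
    return fit


def _term_chi2_table(
    frame: pd.DataFrame,
    y: np.ndarray,
    terms: Sequence[Term],
    alpha: float | None,
    llf_full: float,
) -> pd.DataFrame:
    """Likelihood-ratio chi-square for each term (drop the term, refit)."""
    rows = []
    for term in terms:
        reduced = [t for t in terms if t.name != term.name]
        X_red, _, _ = build_design(reduced, frame)
        _, _, _, llf_red, _ = _fit_nb_raw(y, X_red, alpha)
        chi2 = max(0.0, 2 * (llf_full - llf_red))
        df = term.n_columns
        rows.append(
            {
                "term": term.name,
                "df": df,
                "chi2": chi2,
                "p": float(stats.chi2.sf(chi2, df)),
            }
        )
    return pd.DataFrame(rows, columns=["term", "df", "chi2", "p"])


def select_effect_type(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    include_gender: bool = True,
    df: int = 2,
) -> EffectSpec:
    """Pick the univariate effect type (I-IV) with the lowest AIC.

    Without a gender column only types I and II compete.  Ties go to the
    simpler effect type.
    """
    candidates = (
        _TYPE_PREFERENCE
        if include_gender and "gender" in data.columns
        else [EffectType.LINEAR, EffectType.SMOOTH]
    )
    best: tuple[float, int, EffectSpec] | None = None
    for pref, etype in enumerate(sorted(candidates, key=_TYPE_PREFERENCE.index)):
        spec = EffectSpec(predictor, etype, df)
        fit = fit_nb(data, response, spec.terms(), term_tests=False)
        key = (fit.aic, pref)
        if best is None or key < (best[0], best[1]):
            best = (fit.aic, pref, spec)
    assert best is not None
    return best[2]


def backward_select(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[Term],
    alpha_level: float = 0.05,
) -> ModelFit:
    """Backward elimination by likelihood-ratio chi-square.

    Repeatedly drops the term with the largest p > alpha_level — never a
    term that another remaining term requires (marginality) — and refits,
    until every droppable term is significant.
    """
    current = list(terms)
    while True:
        fit = fit_nb(data, response, current)
        required = {name for t in current for name in t.requires}
        droppable = fit.term_table[~fit.term_table["term"].isin(required)]
        worst = droppable.loc[droppable["p"] > alpha_level]
        if worst.empty or not current:
            return fit
        drop_name = worst.loc[worst["p"].idxmax(), "term"]
        current = [t for t in current if t.name != drop_name]
        if not current:
            return fit_nb(data, response, current)


def model_table(fit: ModelFit, model_name: str) -> pd.DataFrame:
    """One model's rows for a summary ledger (term, df, chi2, p, dev.expl., n)."""
    out = fit.term_table.copy()
    if out.empty:  # nothing survived selection: record the intercept-only fit
        out = pd.DataFrame(
            [{"term": "(intercept only)", "df": 0, "chi2": np.nan, "p": np.nan}]
        )
    out.insert(0, "model", model_name)
    out["dev_expl_pct"] = round(fit.deviance_explained, 2)
    out["n"] = fit.n
    return out


# re-export: the binomial mixed model lives in its own module
from .glmm import GlmmFit, fit_binomial_glmm  # noqa: E402,F401
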