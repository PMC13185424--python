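"""Figure helpers: salience scatter and diverging group-difference bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def salience_scatter(
    table: pd.DataFrame, path: str | Path, title: str = "", annotate_top: int = 15
) -> None:
    """Mean rank vs relative frequency for domain taxa, point size = Smith's S."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(
        table["rel_freq"],
        table["mean_rank"],
        s=20 + 400 * table["smiths_s"],
        alpha=0.6,
        edgecolor="k",
        linewidth=0.5,
    )
    for _, row in table.nlargest(annotate_top, "smiths_s").iterrows():
        ax.annotate(
            row["taxon"], (row["rel_freq"], row["mean_rank"]), fontsize=7,
            xytext=(3, 3), textcoords="offset points",
        )
    ax.invert_yaxis()  # low mean rank (early mention) at the top
    ax.set_xlabel("relative frequency")
    ax.set_ylabel("mean rank (early mentions up)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def salience_diff_bars(
    tests: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Diverging horizontal bars of old-minus-young salience with stars."""
    df = tests.sort_values("observed_diff")
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(df))))
    colors = ["tab:blue" if d < 0 else "tab:orange" for d in df["observed_diff"]]
    ax.barh(df["taxon"], df["observed_diff"], color=colors)
    for y, (_, row) in enumerate(df.iterrows()):
        if row["stars"]:
            ax.annotate(
                row["stars"],
                (row["observed_diff"], y),
                ha="left" if row["observed_diff"] >= 0 else "right",
                va="center",
                fontsize=8,
            )
    ax.axvline(0, color="k", linewidth=0.8)
    ax.set_xlabel("salience difference (older − younger)")
    ax.set_title(title)
    ax.tick_params(axis="y", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def age_frequency_lines(
    table: pd.DataFrame,
    path: str | Path,
    fitted: pd.DataFrame | None = None,
    title: str = "",
) -> None:
    """Thin per-taxon frequency lines over age classes plus the fitted curve."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for taxon, sub in table.groupby("taxon"):
        ax.plot(sub["age_class"], sub["rel_freq"], color="grey", alpha=0.5, lw=0.8)
    if fitted is not None:
        ax.plot(fitted["age_class"], fitted["fitted_freq"], color="tab:red", lw=2.5)
    ax.set_xlabel("age class")
    ax.set_ylabel("relative frequency of listers")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
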