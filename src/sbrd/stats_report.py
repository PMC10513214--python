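"""Statistical comparisons and summary figures for region-level diffusion.

Normality is checked with Shapiro-Wilk; group comparisons use the
Mann-Whitney U rank test (two-sided when no direction is hypothesized,
one-sided for pole comparisons); paired old-vs-new pole differences use the
one-sided Wilcoxon signed-rank test. Significance stars follow the usual
convention: * p < 0.05, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionComparison",
    "significance_stars",
    "test_normality",
    "compare_groups",
    "paired_residual_test",
    "summarize_ratios",
]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class RegionComparison:
    test: str
    sidedness: str
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "sidedness": self.sidedness,
            "statistic": self.statistic,
            "p": self.p_value,
            "stars": self.stars,
        }


def test_normality(sample: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk; returns (statistic, p, is_normal at alpha)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality test requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample is degenerate for the normality test")
    stat, p = stats.shapiro(x)
    return float(stat), float(p), bool(p >= alpha)


def compare_groups(a: Sequence[float], b: Sequence[float], sided: str = "two") -> RegionComparison:
    """Mann-Whitney U. ``sided``: "two", or "greater"/"less" for a > b / a < b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    stat, p = stats.mannwhitneyu(a, b, alternative=alt)
    return RegionComparison("mann-whitney-u", alt, float(stat), float(p))


def paired_residual_test(new_pole_D: Sequence[float], old_pole_D: Sequence[float]) -> RegionComparison:
    """One-sided Wilcoxon signed-rank on the per-cell residuals new - old,
    testing whether the median residual is greater than zero."""
    new = np.asarray(new_pole_D, dtype=float)
    old = np.asarray(old_pole_D, dtype=float)
    if new.size != old.size:
        raise ValueError("paired samples must have equal length")
    diff = new - old
    if np.all(diff == 0):
        return RegionComparison("wilcoxon-signed-rank", "greater", 0.0, 1.0)
    stat, p = stats.wilcoxon(diff, alternative="greater")
    return RegionComparison("wilcoxon-signed-rank", "greater", float(stat), float(p))


def summarize_ratios(
    regions: pd.DataFrame, out_dir=None, kde: bool = True
) -> pd.DataFrame:
    """Per-method mean and SD of the pole/center diffusion ratio.

    ``regions`` is the region summary table with columns D_app_center,
    D_app_poles, D_cc_center, D_cc_poles (one row per cell). Optionally
    writes kernel-density figures (Scott's rule) and the SbRD-vs-SMdM ratio
    scatter with the identity line to ``out_dir``.
    """
    rows = []
    ratios = {}
    for method, c_col, p_col in (
        ("SMdM", "D_app_center", "D_app_poles"),
        ("SbRD", "D_cc_center", "D_cc_poles"),
    ):
        if c_col not in regions or p_col not in regions:
            continue
        ratio = (regions[p_col] / regions[c_col]).to_numpy()
        ratio = ratio[np.isfinite(ratio)]
        ratios[method] = ratio
        rows.append(
            {
                "method": method,
                "n_cells": int(ratio.size),
                "ratio_mean": float(np.mean(ratio)) if ratio.size else np.nan,
                "ratio_sd": float(np.std(ratio, ddof=1)) if ratio.size > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        _ratio_figures(ratios, table, out_dir, kde=kde)
    return table


def _ratio_figures(ratios: dict, table: pd.DataFrame, out_dir, kde: bool) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kde:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for method, ratio in ratios.items():
            if ratio.size > 1 and np.ptp(ratio) > 0:
                grid = np.linspace(ratio.min() - 0.1, ratio.max() + 0.1, 256)
                dens = stats.gaussian_kde(ratio)(grid)  # Scott's rule bandwidth
                ax.plot(grid, dens, label=method)
        ax.set_xlabel(r"$D_{pole} / D_{center}$")
        ax.set_ylabel("density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "ratio_kde.png", dpi=150)
        plt.close(fig)
    if "SMdM" in ratios and "SbRD" in ratios and len(ratios["SMdM"]) == len(ratios["SbRD"]):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(ratios["SMdM"], ratios["SbRD"], s=12)
        lims = [0, max(1.2, ratios["SMdM"].max(), ratios["SbRD"].max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("SMdM ratio")
        ax.set_ylabel("SbRD ratio")
        fig.tight_layout()
        fig.savefig(out / "ratio_scatter.png", dpi=150)
        plt.close(fig)
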