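"""Method-agreement statistics for paired volume series.

Covers the standard method-comparison toolkit: ICC(2,1) (two-way random
effects, absolute agreement, single measurement) with its F-based 95% CI and
the poor/moderate/good/excellent categories; Bland–Altman bias and 95%
limits of agreement; Spearman correlation with a nonparametric pairs
bootstrap CI; and a normality-gated paired difference test (Shapiro–Wilk
routing to the paired t-test or the Wilcoxon signed-rank test).

Difference orientation is always ``method - reference``, so a positive bias
means the method overestimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "PairedSeries",
    "BlandAltman",
    "AgreementSummary",
    "icc_agreement",
    "icc_category",
    "bland_altman",
    "spearman_bootstrap",
    "paired_difference_test",
    "summarize_agreement",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class PairedSeries:
    """Per-exam paired measurements (method A, method B), aligned by exam id."""

    a: np.ndarray
    b: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=np.float64))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=np.float64))
        if self.a.ndim != 1 or self.a.shape != self.b.shape:
            raise ValueError("paired series must be 1D and equal-length")
        if self.ids and len(self.ids) != self.a.size:
            raise ValueError("ids must align with the value pairs")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("paired series must not contain missing values")

    def __len__(self) -> int:
        return self.a.size


def _as_pairs(pairs) -> PairedSeries:
    if isinstance(pairs, PairedSeries):
        return pairs
    a, b = pairs
    return PairedSeries(np.asarray(a), np.asarray(b))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    sd: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class AgreementSummary:
    icc: float
    icc_ci: tuple[float, float]
    icc_class: str
    bias: float
    loa: tuple[float, float]
    spearman_rho: float
    spearman_ci: tuple[float, float]
    test_name: str
    p_value: float


def icc_agreement(pairs) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with its F-based 95% confidence interval.

    Two-way random effects, absolute agreement, single measurement — the
    standard choice when comparing single readings from two methods.
    """
    s = _as_pairs(pairs)
    if len(s) < 3:
        raise ValueError("ICC needs at least 3 pairs")
    values = np.concatenate([s.a, s.b])
    if np.ptp(values) == 0 or (np.ptp(s.a) == 0 and np.ptp(s.b) == 0):
        raise ValueError("degenerate (constant) series: ICC undefined")
    if np.array_equal(s.a, s.b):
        return 1.0, (1.0, 1.0)  # zero residual variance; F-based CI degenerates
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(len(s)), 2),
            "rater": ["A"] * len(s) + ["B"] * len(s),
            "rating": values,
        }
    )
    res = pg.intraclass_corr(df, targets="target", raters="rater", ratings="rating")
    # two-way random, absolute agreement, single rater: "ICC2" or "ICC(A,1)"
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return float(row["ICC"]), (lo, hi)


def icc_category(icc: float) -> str:
    """Reliability category: poor < 0.50 <= moderate <= 0.75 < good <= 0.90 < excellent."""
    if not -1.0 <= icc <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {icc}")
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def bland_altman(pairs) -> BlandAltman:
    """Bias (mean of A - B) and 95% limits of agreement (bias ± 1.96 · SD, sample SD)."""
    s = _as_pairs(pairs)
    if len(s) < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    d = s.a - s.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd=sd,
        means=(s.a + s.b) / 2.0,
        diffs=d,
    )


def spearman_bootstrap(
    pairs, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Spearman rho (average ranks for ties) with a seeded percentile
    bootstrap 95% CI over resampled exam pairs."""
    s = _as_pairs(pairs)
    if len(s) < 3:
        raise ValueError("Spearman needs at least 3 pairs")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if np.ptp(s.a) == 0 or np.ptp(s.b) == 0:
        raise ValueError("constant series: correlation undefined")
    rho = float(stats.spearmanr(s.a, s.b).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(s)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = stats.spearmanr(s.a[idx], s.b[idx]).statistic
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return rho, (float(lo), float(hi))


def paired_difference_test(pairs, normality_alpha: float = 0.05) -> tuple[str, float]:
    """Normality-gated two-sided paired test on A - B.

    Shapiro–Wilk on the differences decides the route: not rejected at
    ``normality_alpha`` → paired t-test, rejected → Wilcoxon signed-rank
    (zeros dropped, average ranks).  All-zero differences → ("degenerate", 1.0).
    """
    s = _as_pairs(pairs)
    if len(s) < 3:
        raise ValueError("paired test needs at least 3 pairs")
    d = s.a - s.b
    if np.all(d == 0):
        return "degenerate", 1.0
    if np.ptp(d) == 0:
        # constant nonzero shift: Shapiro undefined, t-test degenerate
        res = stats.wilcoxon(d, zero_method="wilcox")
        return "wilcoxon", float(res.pvalue)
    normal = stats.shapiro(d).pvalue > normality_alpha
    if normal:
        res = stats.ttest_rel(s.a, s.b)
        return "t-test", float(res.pvalue)
    res = stats.wilcoxon(d, zero_method="wilcox")
    return "wilcoxon", float(res.pvalue)


def summarize_agreement(pairs, n_boot: int = 2000, seed: int = 0) -> AgreementSummary:
    """All paired-method statistics for one (method, reference) series."""
    s = _as_pairs(pairs)
    icc, ci = icc_agreement(s)
    ba = bland_altman(s)
    rho, rho_ci = spearman_bootstrap(s, n_boot=n_boot, seed=seed)
    name, p = paired_difference_test(s)
    return AgreementSummary(
        icc=icc,
        icc_ci=ci,
        # sample ICC(2,1) can numerically undershoot -1 on tiny series
        icc_class=icc_category(float(np.clip(icc, -1.0, 1.0))),
        bias=ba.bias,
        loa=(ba.loa_lower, ba.loa_upper),
        spearman_rho=rho,
        spearman_ci=rho_ci,
        test_name=name,
        p_value=p,
    )


def bland_altman_plot(pairs, ax=None, label_a: str = "A", label_b: str = "B"):
    """Bland–Altman scatter with solid bias line and dashed limits of agreement."""
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.7)
    ax.axhline(ba.bias, color="k", lw=1.5)
    for y in (ba.loa_lower, ba.loa_upper):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel(f"mean of {label_a} and {label_b} (mL)")
    ax.set_ylabel(f"{label_a} − {label_b} (mL)")
    return ax
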