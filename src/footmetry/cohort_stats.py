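"""Cohort-level statistics for paired method comparison.

The analysis shape: per-method descriptive tables (mean, SD per code),
normality-gated paired comparisons (Lilliefors-corrected Kolmogorov–
Smirnov gate, then paired t or Wilcoxon signed-rank), Pearson correlations
between methods and between measurements, difference boxplot summaries
with a clinically motivated threshold count, and the a-priori sample-size
computation.  All significance at two-sided alpha = 0.05 by default, no
multiple-testing correction — the raw per-code convention of the clinical
method-comparison literature this package serves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .measurements import CODES, MeasurementSet

ALPHA = 0.05


@dataclass
class CohortTable:
    """Measurements of one method across a cohort: rows = feet, columns =
    the 32 catalog codes."""

    method: str
    data: pd.DataFrame  # index foot_id, columns CODES

    def __post_init__(self):
        missing = [c for c in CODES if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing codes {missing}")
        self.data = self.data[list(CODES)].astype(float)

    @classmethod
    def from_measurement_sets(cls, sets: list[MeasurementSet],
                              method: str | None = None) -> "CohortTable":
        if not sets:
            raise ValueError("empty cohort")
        rows = {s.foot_id: s.values for s in sets}
        return cls(method=method or sets[0].method,
                   data=pd.DataFrame.from_dict(rows, orient="index"))

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class ComparisonRow:
    """One code's paired method comparison."""

    code: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    normality_p_a: float
    normality_p_b: float
    test_name: str
    p_value: float
    r: float
    r2: float
    corr_p: float
    alpha: float = ALPHA
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power design: two-sided alpha, power 1-beta, detectable
    mean difference delta and common within-group SD sigma (same units)."""

    alpha: float = 0.05
    power: float = 0.80
    delta: float = 1.0
    sigma: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.delta <= 0 or self.sigma < 0:
            raise ValueError("delta must be > 0 and sigma >= 0")


# ---------------------------------------------------------------------------

def _is_constant(x: np.ndarray) -> bool:
    """Numerically constant sample (range zero up to float round-off)."""
    x = np.asarray(x, dtype=float)
    return bool(np.ptp(x) <= 1e-10 * (np.abs(x).max() + 1.0))


def summarize(table: CohortTable) -> pd.DataFrame:
    """Per-code sample mean and SD (n-1 denominator); missing values are
    excluded pairwise with the used count reported."""
    if table.n < 2:
        raise ValueError("need at least 2 feet to summarise")
    df = table.data
    return pd.DataFrame({
        "mean": df.mean(skipna=True),
        "sd": df.std(ddof=1, skipna=True),
        "n_used": df.notna().sum(),
    })


def normality_test(values, corrected: bool = True) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's own mean and
    SD.  Because the parameters are estimated from the data the plain KS
    p-value is anti-conservative; the default applies the Lilliefors
    correction.  Returns (statistic, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("normality test needs n >= 4")
    if np.std(x, ddof=1) == 0:
        return float("inf"), 0.0
    if corrected:
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(min(max(p, 0.0), 1.0))


def paired_compare(a, b, alpha: float = ALPHA, code: str = "",
                   unpaired: bool = False) -> ComparisonRow:
    """Paired method comparison for one measurement.

    If both samples pass the (Lilliefors-corrected) normality gate at 0.05
    the paired Student t test is used, otherwise the Wilcoxon signed-rank
    test on the paired differences.  ``unpaired=True`` switches the
    non-normal branch to the unpaired Mann–Whitney U (provided for
    completeness; the paired design is the default).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 4:
        raise ValueError("paired comparison needs n >= 4")
    warns: list[str] = []
    diffs = x - y

    _, p_a = normality_test(x)
    _, p_b = normality_test(y)

    r, r2, corr_p = pearson(x, y)

    if np.allclose(diffs, 0.0):
        test_name, p = "degenerate", 1.0
    elif p_a >= 0.05 and p_b >= 0.05:
        test_name = "paired-t"
        p = float(stats.ttest_rel(x, y).pvalue)
    elif unpaired:
        test_name = "mann-whitney"
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    else:
        test_name = "wilcoxon-signed-rank"
        p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)

    return ComparisonRow(
        code=code,
        mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)),
        mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)),
        mean_diff=float(diffs.mean()),
        normality_p_a=p_a, normality_p_b=p_b,
        test_name=test_name, p_value=p,
        r=r, r2=r2, corr_p=corr_p,
        alpha=alpha, warnings=warns,
    )


def pearson(x, y) -> tuple[float, float, float]:
    """Product-moment correlation: (r, r^2, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 4:
        raise ValueError("correlation needs n >= 4")
    if _is_constant(x) or _is_constant(y):
        raise ValueError("zero-variance sample")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def compare_tables(a: CohortTable, b: CohortTable,
                   alpha: float = ALPHA) -> list[ComparisonRow]:
    """Paired comparison of every code between two method tables sharing
    the same feet."""
    if list(a.data.index) != list(b.data.index):
        common = a.data.index.intersection(b.data.index)
        bad = set(a.data.index).symmetric_difference(b.data.index)
        if bad:
            raise ValueError(f"unpairable foot ids: {sorted(bad)}")
        a = CohortTable(a.method, a.data.loc[common])
        b = CohortTable(b.method, b.data.loc[common])
    rows = []
    for code in CODES:
        xa, xb = a.data[code].to_numpy(), b.data[code].to_numpy()
        ok = np.isfinite(xa) & np.isfinite(xb)
        rows.append(paired_compare(xa[ok], xb[ok], alpha=alpha, code=code))
    return rows


def correlation_matrix(table: CohortTable, alpha: float = ALPHA
                       ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """32x32 Pearson r matrix between measurements over the cohort.

    Returns (r, significant, flagged): the symmetric r matrix with unit
    diagonal, a boolean mask of p < alpha off-diagonal entries, and the
    list of constant columns (their rows/cols are NaN and flagged)."""
    if table.n < 4:
        raise ValueError("correlation matrix needs n >= 4")
    df = table.data
    flagged = [c for c in CODES
               if _is_constant(df[c].to_numpy()) or not np.isfinite(df[c]).all()]
    k = len(CODES)
    r = np.full((k, k), np.nan)
    pm = np.full((k, k), np.nan)
    for i, ci in enumerate(CODES):
        r[i, i] = 1.0
        pm[i, i] = 0.0
        for j in range(i + 1, k):
            cj = CODES[j]
            if ci in flagged or cj in flagged:
                continue
            rij, _, pij = pearson(df[ci], df[cj])
            r[i, j] = r[j, i] = rij
            pm[i, j] = pm[j, i] = pij
    rdf = pd.DataFrame(r, index=CODES, columns=CODES)
    sig = pd.DataFrame((pm < alpha) & np.isfinite(pm), index=CODES, columns=CODES)
    np.fill_diagonal(sig.values, False)
    return rdf, sig, flagged


def required_sample_size(spec: PowerSpec, design: str = "two-group") -> int:
    """A-priori sample size for detecting a mean difference.

    ``two-group`` (default): the normal-approximation formula for two
    independent groups, n = ceil(2 (z_{1-a/2} + z_{1-b})^2 (sigma/delta)^2)
    per group.  ``paired``: one-sample formula on the differences with the
    Guenther small-sample adjustment, n = ceil((z_{1-a/2} + z_{1-b})^2
    (sigma/delta)^2 + z_{1-a/2}^2 / 2).  Floors at 1.
    """
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    ratio = (spec.sigma / spec.delta) ** 2
    if design == "two-group":
        n = 2.0 * (za + zb) ** 2 * ratio
    elif design == "paired":
        n = (za + zb) ** 2 * ratio + za ** 2 / 2.0
    else:
        raise ValueError("design must be 'two-group' or 'paired'")
    return max(1, math.ceil(n - 1e-9))


def boxplot_stats(values: np.ndarray) -> dict:
    """Tukey five-number boxplot summary: quartiles, 1.5*IQR whiskers
    clipped to the data, and the outliers beyond them."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
        "outliers": sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)]),
    }


def difference_summary(a: CohortTable, b: CohortTable,
                       threshold: float = 3.5
                       ) -> tuple[pd.DataFrame, int, list[str]]:
    """Per-code boxplot summary of the paired per-foot differences and the
    count of codes whose |mean_a - mean_b| exceeds ``threshold``.

    Returns (boxstats DataFrame, count, exceeding codes)."""
    if list(a.data.index) != list(b.data.index):
        raise ValueError("difference summary needs identically paired tables")
    rows = {}
    exceeding = []
    for code in CODES:
        d = (a.data[code] - b.data[code]).to_numpy()
        d = d[np.isfinite(d)]
        rows[code] = boxplot_stats(d)
        ma = np.nanmean(a.data[code].to_numpy())
        mb = np.nanmean(b.data[code].to_numpy())
        rows[code]["mean_diff"] = float(ma - mb)
        if abs(ma - mb) > threshold:
            exceeding.append(code)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "code"
    return df, len(exceeding), exceeding
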