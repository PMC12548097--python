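"""Cohort statistics: Spearman correlations, intergrader ICC, paired t.

The study design correlates foveal morphometry metrics across participants
with Spearman rank correlation (raw p values, no multiplicity correction),
quantifies intergrader agreement of ONL thickness with the two-way
random-effects absolute-agreement single-rater ICC (ICC(2,1)), and tests
for a systematic grader difference with a paired t test.

Implementation notes
--------------------
* Spearman r is the Pearson correlation of mid-ranks (average ranks on
  ties); p comes from the t approximation ``t = r * sqrt((n-2)/(1-r^2))``
  with ``n - 2`` df, and the 95% CI from the Fisher z transform with the
  Fieller-adjusted standard error ``1.03 / sqrt(n - 3)``.
* Missing values are removed pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METRIC_COLUMNS = (
    "pcd",
    "cdc_density",
    "areal_density",
    "max_onl_um",
    "central_onl_um",
    "pit_diameter_mm",
    "pit_volume_mm3",
    "faz_area_mm2",
)

#: metric pairs examined in the study design: ONL thickness vs. the three
#: cone-density metrics, pit geometry vs. density, FAZ vs. pit geometry
DEFAULT_PAIRS = [
    ("max_onl_um", "pcd"),
    ("max_onl_um", "cdc_density"),
    ("max_onl_um", "areal_density"),
    ("central_onl_um", "pcd"),
    ("central_onl_um", "cdc_density"),
    ("central_onl_um", "areal_density"),
    ("pit_diameter_mm", "pcd"),
    ("pit_diameter_mm", "cdc_density"),
    ("pit_diameter_mm", "areal_density"),
    ("pit_volume_mm3", "pcd"),
    ("pit_volume_mm3", "cdc_density"),
    ("pit_volume_mm3", "areal_density"),
    ("faz_area_mm2", "pit_diameter_mm"),
    ("faz_area_mm2", "pit_volume_mm3"),
]


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class AgreementResult:
    icc: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_value: float


def _pairwise(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p and Fisher-z CI."""
    x, y = _pairwise(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 paired observations, got {n}")
    rx = stats.rankdata(x)  # mid-ranks on ties
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant input: rank variance is zero")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        p = 0.0
        lo, hi = (r, 1.0) if r > 0 else (-1.0, r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        z = np.arctanh(r)
        se = 1.03 / np.sqrt(n - 3)
        lo = float(np.tanh(z - 1.959963984540054 * se))
        hi = float(np.tanh(z + 1.959963984540054 * se))
    return CorrelationResult(r=r, p_value=p, ci_low=lo, ci_high=hi, n=n)


def icc_two_grader(
    grader1, grader2, model: str = "two_way_random_absolute_single"
) -> tuple[float, float, float]:
    """ICC for two raters from the two-way ANOVA decomposition.

    ``model`` selects ICC(2,1) (``two_way_random_absolute_single``,
    default — penalizes a systematic grader offset) or the consistency
    variant ICC(3,1) (``two_way_mixed_consistency_single``).  Returns
    ``(icc, ci_low, ci_high)`` with the standard F-based 95% interval.
    """
    x, y = _pairwise(grader1, grader2)
    n = len(x)
    if n < 5:
        raise ValueError(f"need n >= 5 paired measurements, got {n}")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    alpha = 0.05
    if model == "two_way_random_absolute_single":
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if icc >= 1.0 - 1e-12:  # perfect agreement: F interval degenerates
            return 1.0, 1.0, 1.0
        # McGraw & Wong F-based interval for ICC(A,1)
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (
            fl * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (fu * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fu * msr
        )
    elif model == "two_way_mixed_consistency_single":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f = msr / mse
        fl = f / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return float(icc), float(lo), float(hi)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t test; returns ``(t, df, two-sided p)``."""
    x, y = _pairwise(x, y)
    n = len(x)
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        warnings.warn("zero-variance nonzero differences: p degenerates to 0",
                      stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, n - 1, p


def grader_agreement(
    grader1, grader2, model: str = "two_way_random_absolute_single"
) -> AgreementResult:
    """ICC plus paired t test between two graders' measurements."""
    icc, lo, hi = icc_two_grader(grader1, grader2, model)
    t, df, p = paired_t(grader1, grader2)
    return AgreementResult(icc=icc, ci_low=lo, ci_high=hi, t_stat=t, df=df, p_value=p)


def cohort_summary(table: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Per-metric min / max / median / IQR (linear-interpolation quantiles)."""
    metrics = list(metrics) if metrics is not None else [
        c for c in METRIC_COLUMNS if c in table.columns
    ]
    rows = []
    for col in metrics:
        v = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(v)
        if not ok.any():
            warnings.warn(f"metric {col!r} has no values; omitted", stacklevel=2)
            continue
        vv = v[ok]
        q1, med, q3 = np.quantile(vv, [0.25, 0.5, 0.75])  # linear interpolation
        rows.append(
            {
                "metric": col,
                "n": int(ok.sum()),
                "missing": int((~ok).sum()),
                "min": float(vv.min()),
                "max": float(vv.max()),
                "median": float(med),
                "iqr": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Spearman correlation per requested column pair (pairwise deletion).

    No multiplicity correction is applied by default (raw p values, as in
    the study design); ``holm=True`` adds a Holm-adjusted column.
    """
    pairs = pairs if pairs is not None else DEFAULT_PAIRS
    rows = []
    for a, b in pairs:
        for c in (a, b):
            if c not in table.columns:
                raise KeyError(f"column {c!r} not in cohort table")
        res = spearman(table[a], table[b])
        rows.append(
            {
                "metric_a": a,
                "metric_b": b,
                "r": res.r,
                "p_value": res.p_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n": res.n,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        p = out["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    else:
        warnings.warn(
            "multiple comparisons: raw p values reported without correction",
            stacklevel=2,
        )
    return out
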