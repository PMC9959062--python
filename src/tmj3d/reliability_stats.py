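"""Inter-observer reliability statistics.

Implements the agreement toolkit used to validate the assessment:

* ICC(1,1) — one-way random-effects, single-measure intraclass correlation,
  from the one-way ANOVA mean squares, with the exact F-quantile 95%
  confidence interval (Searle).  Negative estimates are reported as
  computed, not truncated.
* MAD (SD) — mean absolute difference between paired observer measurements
  and the sample SD of those absolute differences.
* Bland-Altman bias and 95% limits of agreement (bias ± 1.96 sd of the
  signed differences).
* Cicchetti interpretation bands (poor < 0.40 ≤ fair < 0.60 ≤ good
  < 0.75 ≤ excellent); the assessment counts as reliable when the category
  is good or excellent (ICC > 0.60).
* The Fisher-z one-sample correlation sample-size formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CICCHETTI_BANDS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"), (np.inf, "excellent"))


@dataclass
class RatingsTable:
    """n subjects x k raters measurements of a single metric."""

    values: np.ndarray
    metric: str = ""
    unit: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2D subjects x raters array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain missing / non-finite cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass
class ReliabilityReport:
    """Agreement summary for one metric x structure x region cell."""

    metric: str
    icc: float
    ci_low: float
    ci_high: float
    mad: float
    sd: float
    bias: float
    loa_low: float
    loa_high: float
    category: str
    reliable: bool

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("ICC estimate outside its confidence interval")


def icc_oneway_single(table: RatingsTable, alpha: float = 0.05):
    """ICC(1,1) with its exact F confidence interval.

    From the one-way ANOVA decomposition with subjects as the random factor:
    ``ICC = (MSB - MSW) / (MSB + (k-1) MSW)`` where MSB / MSW are the
    between- and within-subject mean squares on ``n-1`` and ``n(k-1)``
    degrees of freedom.
    """
    x = table.values
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("degenerate ratings: zero total variance")
    subj_means = x.mean(axis=1)
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((x - subj_means[:, None]) ** 2)
    dfb, dfw = n - 1, n * (k - 1)
    msb = ssb / dfb
    msw = ssw / dfw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0:
        return 1.0, 1.0, 1.0
    F = msb / msw
    f_hi = stats.f.ppf(1 - alpha / 2, dfb, dfw)
    f_lo = stats.f.ppf(1 - alpha / 2, dfw, dfb)
    fl = F / f_hi
    fu = F * f_lo
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return float(icc), float(ci_low), float(ci_high)


def mad_sd(x, y):
    """Mean absolute difference and sample SD of the absolute differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observer vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = np.abs(x - y)
    return float(d.mean()), float(d.std(ddof=1))


def bland_altman(x, y):
    """Bias, 95% limits of agreement, and the per-pair plotting data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observer vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (x + y) / 2.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, means, d


def cicchetti_category(icc: float) -> tuple[str, bool]:
    """Cicchetti interpretation band and the reliability verdict (> 0.60)."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    for bound, name in CICCHETTI_BANDS:
        if icc < bound:
            return name, name in ("good", "excellent")
    return "excellent", True


def sample_size_one_correlation(rho_alt: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Subjects needed for a one-sample correlation test (H0: rho = 0).

    Fisher-z formula: ``n = ceil(((z_{1-a/2} + z_{power}) / atanh(rho))^2 + 3)``,
    floored at 4.  With rho = 0.6, two-sided alpha 0.05 and power 0.8 this
    gives n = 20.
    """
    if not (0.0 < rho_alt < 1.0):
        raise ValueError("rho_alt must be in (0, 1)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = math.ceil(((z_a + z_b) / math.atanh(rho_alt)) ** 2 + 3)
    return max(int(n), 4)


# ---------------------------------------------------------------------------
# Two-observer reliability study over morphometric reports
# ---------------------------------------------------------------------------


# the metrics reported in the clinical agreement tables: volumetric change
# and mean surface distance of the condylar structures, RMS distance of the
# fossa, and the change in minimum joint-space distance
TABLE_METRICS = ("volumetric_change", "mean_abs_distance", "rms_distance", "change")


def reliability_study(reports_obs1, reports_obs2, metrics=TABLE_METRICS) -> pd.DataFrame:
    """Assemble per-cell agreement tables from two observers' reports.

    ``reports_obs*`` are equal-length lists of
    :class:`~tmj3d.morphometrics.MorphometricReport` (one per subject/joint,
    matched by position).  For every metric x structure x region cell the
    subjects' paired values form a :class:`RatingsTable`; cells with
    missing values in any subject are dropped with a logged count.
    ``metrics`` defaults to the clinical-table metric set; pass ``None`` to
    tabulate every metric in the reports (including diagnostics such as the
    per-region peak distance).
    """
    if len(reports_obs1) != len(reports_obs2):
        raise ValueError("observer report lists must be matched in length")
    if len(reports_obs1) < 2:
        raise ValueError("ICC needs at least 2 subjects")
    df1 = _stack(reports_obs1, "obs1")
    df2 = _stack(reports_obs2, "obs2")
    if metrics is not None:
        df1 = df1[df1.metric.isin(metrics)].reset_index(drop=True)
        df2 = df2[df2.metric.isin(metrics)].reset_index(drop=True)
    k1 = set(map(tuple, df1[["subject", "side", "structure", "region", "metric"]].values))
    k2 = set(map(tuple, df2[["subject", "side", "structure", "region", "metric"]].values))
    if k1 != k2:
        diff = sorted(k1.symmetric_difference(k2))[:10]
        raise ValueError(f"unmatched observer keys, e.g. {diff}")
    merged = df1.merge(
        df2, on=["subject", "side", "structure", "region", "metric", "unit"]
    )
    out_rows = []
    for (structure, region, metric, unit), grp in merged.groupby(
        ["structure", "region", "metric", "unit"], sort=True
    ):
        x = grp["value_obs1"].to_numpy()
        y = grp["value_obs2"].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < len(x):
            import logging

            logging.getLogger("tmj3d").info(
                "reliability_study: dropped %d incomplete pairs for %s/%s/%s",
                int(len(x) - ok.sum()), structure, region, metric,
            )
        x, y = x[ok], y[ok]
        if len(x) < 2:
            continue
        try:
            icc, lo, hi = icc_oneway_single(RatingsTable(np.column_stack([x, y]), metric))
        except ValueError:
            icc, lo, hi = float("nan"), float("nan"), float("nan")
        mad, sd = mad_sd(x, y)
        if len(x) >= 3:
            bias, loa_lo, loa_hi, _, _ = bland_altman(x, y)
        else:
            bias = loa_lo = loa_hi = float("nan")
        cat, ok_rel = (
            cicchetti_category(icc) if np.isfinite(icc) else ("undefined", False)
        )
        out_rows.append(
            {
                "structure": structure,
                "region": region,
                "metric": metric,
                "unit": unit,
                "n": len(x),
                "icc": icc,
                "ci_low": lo,
                "ci_high": hi,
                "mad": mad,
                "sd": sd,
                "bias": bias,
                "loa_low": loa_lo,
                "loa_high": loa_hi,
                "category": cat,
                "reliable": ok_rel,
            }
        )
    return pd.DataFrame(out_rows)


def _stack(reports, tag) -> pd.DataFrame:
    frames = []
    for i, rep in enumerate(reports):
        df = rep.to_frame().copy()
        df["subject"] = i
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    return df.rename(columns={"value": f"value_{tag}"})


def bland_altman_plot(x, y, title: str, path) -> None:
    """Render a Bland-Altman plot with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bias, lo, hi, means, diffs = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    ax.axhline(bias, color="k", lw=1, label=f"bias {bias:.3g}")
    ax.axhline(lo, color="r", ls="--", lw=1, label=f"LoA {lo:.3g}, {hi:.3g}")
    ax.axhline(hi, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of observers")
    ax.set_ylabel("difference (obs1 - obs2)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
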