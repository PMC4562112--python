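"""Paired-design inference and examiner-reliability estimation.

Implements the statistical layer of a dual-angle reader study: paired
t-tests comparing metrics between the 0 deg and 30 deg exposure conditions,
intraclass correlation coefficients for inter- and intra-examiner
reliability, and a study summary table (per-metric means, SDs, p-values and
percent changes across the two angles).

ICC forms
---------
* inter-examiner: two-way random-effects, absolute-agreement, single
  measures — ICC(2,1) in Shrout–Fleiss notation, ICC(A,1) in McGraw–Wong.
  Matches a blinded multi-reader design where examiners are a random sample
  of possible readers.
* intra-examiner: one-way random-effects single measures across repeated
  blinded reads within one examiner, ICC(1,1), pooled over examiners by a
  target-count-weighted mean.

Confidence intervals are the F-based 95 % intervals of Shrout & Fleiss /
McGraw & Wong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "ICCResult",
    "InsufficientDataError",
    "paired_t_test",
    "icc_inter",
    "icc_intra",
    "percent_change",
    "StudySummary",
    "summarize_study",
    "ReliabilityStudy",
    "StudyResults",
]

METRICS = ("length", "rbl", "rel_rbl")


class InsufficientDataError(ValueError):
    """Fewer observations than the estimator requires."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    n: int
    flag: Optional[str] = None


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_targets: int
    n_raters: int
    flag: Optional[str] = None


def paired_t_test(
    values_0: Sequence[float], values_30: Sequence[float]
) -> TTestResult:
    """Two-sided paired-samples t-test on per-site differences.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = values_30 - values_0`` and
    ``df = n - 1``.  Zero-variance differences are reported explicitly
    instead of scipy's nan: identical pairs give ``t=0, p=1``; a constant
    nonzero shift gives ``p=0`` with a flag.
    """
    v0 = np.asarray(values_0, dtype=float)
    v1 = np.asarray(values_30, dtype=float)
    if v0.shape != v1.shape:
        raise ValueError("paired samples must have equal length")
    n = v0.size
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs n >= 2, got n={n}")
    d = v1 - v0
    if np.ptp(d) == 0.0:
        mean = float(d[0])
        if mean == 0.0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, n=n, flag="zero_variance")
        t = np.inf if mean > 0 else -np.inf
        return TTestResult(t=float(t), df=n - 1, p=0.0, n=n, flag="zero_variance")
    res = sps.ttest_rel(v1, v0)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue), n=n)


def _two_way_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of a complete two-way n x k layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_inter(matrix: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """Inter-examiner ICC(2,1) from a complete (targets x raters) matrix.

    Two-way random effects, absolute agreement, single measures, with the
    Shrout–Fleiss F-based confidence interval.  Targets (rows) are sites;
    raters (columns) are examiners.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (targets x raters) matrix")
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(
            f"ICC(2,1) needs >=2 targets and >=2 raters, got {n}x{k}"
        )
    msr, msc, mse = _two_way_mean_squares(x)
    if msr == 0.0 and mse == 0.0 and msc == 0.0:
        return ICCResult(np.nan, np.nan, np.nan, n, k, flag="no_variance")
    if mse == 0.0 and msc == 0.0:
        # perfect agreement on varying targets
        return ICCResult(1.0, 1.0, 1.0, n, k)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom
    flag = None
    if icc <= 0.0:
        flag = "no_between_target_variance"
    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1.0 - confidence
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return ICCResult(float(icc), 1.0, 1.0, n, k, flag=flag)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    low = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    high = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(float(icc), float(low), float(high), n, k, flag=flag)


def _icc_oneway(x: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """One-way random-effects single-measure ICC(1,1) for an n x k layout."""
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(
            f"ICC(1,1) needs >=2 targets and >=2 measurements, got {n}x{k}"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    msb = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msw = float(((x - row_means[:, None]) ** 2).sum()) / (n * (k - 1))
    if msb == 0.0 and msw == 0.0:
        return ICCResult(np.nan, np.nan, np.nan, n, k, flag="no_variance")
    if msw == 0.0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    flag = "no_between_target_variance" if icc <= 0.0 else None
    alpha = 1.0 - confidence
    f_obs = msb / msw
    f_l = f_obs / sps.f.ppf(1.0 - alpha / 2.0, n - 1, n * (k - 1))
    f_u = f_obs * sps.f.ppf(1.0 - alpha / 2.0, n * (k - 1), n - 1)
    low = (f_l - 1.0) / (f_l + k - 1.0)
    high = (f_u - 1.0) / (f_u + k - 1.0)
    return ICCResult(float(icc), float(low), float(high), n, k, flag=flag)


def icc_intra(
    cube: np.ndarray, confidence: float = 0.95
) -> Tuple[Dict[int, ICCResult], ICCResult]:
    """Intra-examiner reliability from a (targets x examiners x repeats) cube.

    Returns per-examiner one-way single-measure ICCs across repeated reads,
    plus a pooled value: the target-count-weighted mean of the per-examiner
    estimates (CI bounds pooled the same way, an approximation).
    """
    x = np.asarray(cube, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3-D (targets x examiners x repeats) array")
    n, n_exam, n_rep = x.shape
    if n_rep < 2:
        raise InsufficientDataError("intra-examiner ICC needs >=2 repeats")
    per: Dict[int, ICCResult] = {}
    for j in range(n_exam):
        xj = x[:, j, :]
        ok = ~np.isnan(xj).any(axis=1)
        per[j] = _icc_oneway(xj[ok], confidence=confidence)
    weights = np.array([per[j].n_targets for j in per], dtype=float)
    vals = np.array([per[j].icc for j in per])
    lows = np.array([per[j].ci_low for j in per])
    highs = np.array([per[j].ci_high for j in per])
    w = weights / weights.sum()
    pooled = ICCResult(
        icc=float(np.nansum(w * vals)),
        ci_low=float(np.nansum(w * lows)),
        ci_high=float(np.nansum(w * highs)),
        n_targets=int(weights.sum()),
        n_raters=n_rep,
        flag="pooled",
    )
    return per, pooled


def percent_change(mean_0: float, mean_30: float, ndigits: int = 1) -> float:
    """Relative change ``100 * (mean_30 - mean_0) / mean_0`` in percent,
    rounded to ``ndigits`` decimals (one decimal by default, the convention
    of the study tables)."""
    if mean_0 == 0:
        raise ZeroDivisionError("baseline mean must be nonzero")
    return round(100.0 * (mean_30 - mean_0) / mean_0, ndigits)


# ---------------------------------------------------------------------------
# study-level summary


@dataclass(frozen=True)
class StudySummary:
    """Per-metric x angle means/SDs plus paired-test results — the
    dual-angle comparison table of the study."""

    table: pd.DataFrame  # index: metric; columns: mean_0, sd_0, mean_30, ...
    angles: Tuple[float, float]
    n_dropped: int = 0

    def round_trip_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def __str__(self) -> str:
        a0, a1 = self.angles
        lines = [
            f"Dual-angle study summary (alpha = {a0:g} deg vs {a1:g} deg)",
            f"{'metric':<10}{'mean0':>8}{'SD0':>7}{'mean30':>8}{'SD30':>7}"
            f"{'n':>5}{'p':>9}{'change%':>9}",
        ]
        for metric, row in self.table.iterrows():
            p = row["p_value"]
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(
                f"{metric:<10}{row['mean_0']:>8.1f}{row['sd_0']:>7.1f}"
                f"{row['mean_30']:>8.1f}{row['sd_30']:>7.1f}"
                f"{int(row['n']):>5}{p_str:>9}{row['percent_change']:>9.1f}"
            )
        return "\n".join(lines)


def _site_means(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-site mean over examiners and repeats, wide over angle."""
    sub = df[df["metric"] == metric]
    g = sub.groupby(["site", "angle"])["value"].mean().unstack("angle")
    return g


def summarize_study(readings: pd.DataFrame) -> StudySummary:
    """Build the per-metric dual-angle summary from long-format readings.

    ``readings`` columns: site, examiner, repeat, angle, metric, value.
    Exactly two angle conditions are expected.  For each metric the site
    value at an angle is the mean over all examiner x repeat reads; means,
    SDs (over sites), the paired t-test between angles and the percent
    change of the means are reported.  Sites missing either angle are
    dropped and counted.
    """
    if readings.empty:
        raise ValueError("no readings provided")
    angles = sorted(readings["angle"].unique())
    if len(angles) != 2:
        raise ValueError(f"expected exactly 2 angle conditions, got {angles}")
    a0, a1 = angles
    rows = []
    n_dropped = 0
    for metric in [m for m in METRICS if m in set(readings["metric"])]:
        wide = _site_means(readings, metric)
        complete = wide.dropna()
        n_dropped += len(wide) - len(complete)
        v0 = complete[a0].to_numpy()
        v1 = complete[a1].to_numpy()
        if v0.size < 2:
            res = TTestResult(np.nan, v0.size - 1, np.nan, v0.size,
                              flag="insufficient_data")
        else:
            res = paired_t_test(v0, v1)
        rows.append(
            {
                "metric": metric,
                "mean_0": v0.mean() if v0.size else np.nan,
                "sd_0": v0.std(ddof=1) if v0.size > 1 else np.nan,
                "mean_30": v1.mean() if v1.size else np.nan,
                "sd_30": v1.std(ddof=1) if v1.size > 1 else np.nan,
                "n": v0.size,
                "t": res.t,
                "p_value": res.p,
                "percent_change": percent_change(v0.mean(), v1.mean(), ndigits=6)
                if v0.size else np.nan,
                "flag": res.flag,
            }
        )
    table = pd.DataFrame(rows).set_index("metric")
    return StudySummary(table=table, angles=(float(a0), float(a1)),
                        n_dropped=n_dropped)


class ReliabilityStudy:
    """Dual-angle multi-reader study model.

    Built from a long-format readings DataFrame (columns site, examiner,
    repeat, angle, metric, value); ``fit()`` estimates the per-metric
    summary statistics, paired tests and inter-/intra-examiner ICCs and
    returns a :class:`StudyResults`.
    """

    def __init__(self, readings: pd.DataFrame):
        missing = [c for c in
                   ("site", "examiner", "repeat", "angle", "metric", "value")
                   if c not in readings.columns]
        if missing:
            raise ValueError(f"readings missing columns {missing}")
        self.readings = readings.copy()

    @classmethod
    def from_csv(cls, path) -> "ReliabilityStudy":
        from .io import read_readings_csv

        return cls(read_readings_csv(path))

    def _inter_matrix(self, metric: str) -> np.ndarray:
        """(site x angle) targets x examiner matrix of repeat-mean reads."""
        sub = self.readings[self.readings["metric"] == metric]
        g = (
            sub.groupby(["site", "angle", "examiner"])["value"]
            .mean()
            .unstack("examiner")
        )
        return g.to_numpy()

    def _intra_cube(self, metric: str) -> np.ndarray:
        sub = self.readings[self.readings["metric"] == metric]
        g = sub.set_index(["site", "angle", "examiner", "repeat"])["value"]
        wide = g.unstack(["examiner", "repeat"]).sort_index(axis=1)
        examiners = wide.columns.get_level_values(0).unique()
        repeats = wide.columns.get_level_values(1).unique()
        cube = np.full((len(wide), len(examiners), len(repeats)), np.nan)
        for je, e in enumerate(examiners):
            for jr, r in enumerate(repeats):
                cube[:, je, jr] = wide[(e, r)].to_numpy()
        return cube

    def fit(self, confidence: float = 0.95) -> "StudyResults":
        summary = summarize_study(self.readings)
        inter: Dict[str, ICCResult] = {}
        intra: Dict[str, ICCResult] = {}
        intra_per: Dict[str, Dict[int, ICCResult]] = {}
        n_examiners = self.readings["examiner"].nunique()
        n_repeats = self.readings["repeat"].nunique()
        for metric in summary.table.index:
            if n_examiners >= 2:
                inter[metric] = icc_inter(self._inter_matrix(metric),
                                          confidence=confidence)
            if n_repeats >= 2:
                per, pooled = icc_intra(self._intra_cube(metric),
                                        confidence=confidence)
                intra[metric] = pooled
                intra_per[metric] = per
        return StudyResults(
            summary=summary, icc_inter=inter, icc_intra=intra,
            icc_intra_per_examiner=intra_per,
        )


@dataclass(frozen=True)
class StudyResults:
    """Estimates from a fitted :class:`ReliabilityStudy`."""

    summary: StudySummary
    icc_inter: Dict[str, ICCResult] = field(default_factory=dict)
    icc_intra: Dict[str, ICCResult] = field(default_factory=dict)
    icc_intra_per_examiner: Dict[str, Dict[int, ICCResult]] = field(
        default_factory=dict
    )

    def icc_frame(self) -> pd.DataFrame:
        rows = []
        for kind, d in (("inter", self.icc_inter), ("intra", self.icc_intra)):
            for metric, r in d.items():
                rows.append(
                    {
                        "metric": metric, "kind": kind, "icc": r.icc,
                        "ci_low": r.ci_low, "ci_high": r.ci_high,
                        "n_targets": r.n_targets, "flag": r.flag,
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return self.summary.table.copy()

    def summary_text(self) -> str:
        lines = [str(self.summary), "", "Examiner reliability (ICC, 95% CI)"]
        for _, row in self.icc_frame().iterrows():
            if np.isnan(row["icc"]):
                lines.append(
                    f"  {row['metric']:<10}{row['kind']:<7} undefined"
                    f" ({row['flag']})"
                )
            else:
                lines.append(
                    f"  {row['metric']:<10}{row['kind']:<7}"
                    f"{row['icc']:.2f} ({row['ci_low']:.2f}-{row['ci_high']:.2f})"
                )
        return "\n".join(lines)
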