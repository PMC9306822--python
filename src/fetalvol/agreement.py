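"""Reproducibility statistics for paired volume measurements.

Implements the complete intra-/interobserver agreement protocol for repeated
organ-volume measurements:

* equality-plot data (measurement pairs against the identity line);
* two-way absolute-agreement single-measurement ICC — ICC(A,1) in the
  McGraw & Wong taxonomy — from ANOVA mean squares, with the F-based 95% CI
  (a one-way form is available for sensitivity);
* within-subject coefficient of variation by the root-mean-square method
  (alternative: SD of differences / grand mean / sqrt(2));
* Bland–Altman percentage differences, ``d_i = 100 (a_i - b_i) / pair mean``,
  with limits of agreement ``mean(d) ± 1.96 × sample SD(d)``;
* a two-sided paired t-test on the percentage differences;
* a-priori verdict flags: excellent agreement requires ICC > 0.90, CV < 10%,
  |mean difference| < 10%, and both limits of agreement within 10 percentage
  points of the mean difference.

Designs: *intra* pairs one observer's first and second measurements per
subject; *inter* pairs the two observers' per-subject means of their two
repeats.  Subjects with any required value missing are excluded (and
counted) — complete-case analysis per organ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

DEFAULT_THRESHOLDS = {"icc": 0.90, "cv_pct": 10.0, "mean_diff_pct": 10.0, "loa_pct": 10.0}


@dataclass
class PairedSeries:
    """Complete-case paired measurements (mm³) for one organ and design."""

    subject_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    design: str  # "intra:<observer>" or "inter"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1D arrays of equal length")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class BlandAltman:
    mean_diff_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    sd_diff_pct: float
    pair_means: np.ndarray = field(repr=False, default=None)
    diffs_pct: np.ndarray = field(repr=False, default=None)


@dataclass
class AgreementReport:
    design: str
    organ: str | None
    n: int
    n_excluded: int
    icc: float
    icc_ci: tuple[float, float]
    icc_form: str
    cv_pct: float
    cv_method: str
    mean_diff_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    t_stat: float | None
    p_value: float | None
    verdict: dict

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["icc_ci_low"], d["icc_ci_high"] = d.pop("icc_ci")
        for key in ("icc_ok", "cv_ok", "meandiff_ok", "loa_ok"):
            d[key] = self.verdict[key]
        d.pop("verdict")
        return d


def build_pairs(
    records: pd.DataFrame,
    design: str,
    organ: str,
    observer: str | None = None,
    observers: tuple[str, str] | None = None,
) -> PairedSeries:
    """Assemble the paired series for one organ.

    ``design="intra"`` pairs repeat 1 vs repeat 2 for ``observer``;
    ``design="inter"`` pairs the mean of the two repeats of each observer
    (both repeats of both observers required).
    """
    sub = records[records["organ"] == organ]
    if sub.empty:
        raise ValueError(f"organ {organ!r} absent from the measurement table")
    if design == "intra":
        if observer is None:
            raise ValueError("intra design requires an observer id")
        sub = sub[sub["observer_id"] == observer]
        wide = sub.pivot_table(
            index="subject_id", columns="repeat_index", values="volume_mm3", dropna=False
        )
        total = wide.shape[0]
        wide = wide.dropna()
        return PairedSeries(
            subject_ids=list(wide.index),
            a=wide[1].to_numpy(),
            b=wide[2].to_numpy(),
            design=f"intra:{observer}",
            n_excluded=total - wide.shape[0],
        )
    if design == "inter":
        obs = observers or tuple(pd.unique(sub["observer_id"]))[:2]
        if len(obs) < 2:
            raise ValueError("inter design requires two observers")
        wide = sub.pivot_table(
            index="subject_id",
            columns=["observer_id", "repeat_index"],
            values="volume_mm3",
            dropna=False,
        )
        total = wide.shape[0]
        cols = [(o, r) for o in obs for r in (1, 2)]
        wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols)).dropna()
        a = wide[[(obs[0], 1), (obs[0], 2)]].mean(axis=1).to_numpy()
        b = wide[[(obs[1], 1), (obs[1], 2)]].mean(axis=1).to_numpy()
        return PairedSeries(
            subject_ids=list(wide.index),
            a=a,
            b=b,
            design="inter",
            n_excluded=total - wide.shape[0],
        )
    raise ValueError(f"unknown design {design!r}")


def percent_differences(pairs: PairedSeries) -> np.ndarray:
    """Per-subject percentage difference, 100·(a−b)/pair mean."""
    m = (pairs.a + pairs.b) / 2.0
    if np.any(m <= 0):
        raise DegenerateDataError("pair means must be > 0 for percentage differences")
    return 100.0 * (pairs.a - pairs.b) / m


def bland_altman(pairs: PairedSeries) -> BlandAltman:
    """Mean percentage difference with 95% limits of agreement (±1.96 SD)."""
    if pairs.n < 3:
        raise DegenerateDataError("need n >= 3 pairs for limits of agreement")
    d = percent_differences(pairs)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff_pct=mean,
        loa_lower_pct=mean - 1.96 * sd,
        loa_upper_pct=mean + 1.96 * sd,
        sd_diff_pct=sd,
        pair_means=(pairs.a + pairs.b) / 2.0,
        diffs_pct=d,
    )


def _mean_squares(table: np.ndarray):
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((table - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, sst


def icc_estimate(
    pairs: PairedSeries, form: str = "two_way", alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC with a 95% confidence interval.

    ``form="two_way"`` is the two-way absolute-agreement single-measurement
    coefficient ICC(A,1) with the McGraw–Wong F-based interval;
    ``form="one_way"`` is the one-way random single-measurement ICC(1).
    The estimator may be slightly negative.
    """
    if pairs.n < 3:
        raise DegenerateDataError("need n >= 3 pairs for an ICC")
    table = np.column_stack([pairs.a, pairs.b])
    n, k = table.shape
    msr, msc, mse, sst = _mean_squares(table)
    if sst <= 0:
        raise DegenerateDataError("zero total variance: ICC undefined")

    if form == "one_way":
        msw = (sst - msr * (n - 1)) / (n * (k - 1))
        icc = (msr - msw) / (msr + (k - 1) * msw)
        fobs = msr / msw if msw > 0 else np.inf
        fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), float(max(lo, -1.0)), float(min(hi, 1.0))
    if form != "two_way":
        raise ValueError(f"unknown ICC form {form!r}")

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # McGraw & Wong F-based interval for ICC(A,1)
    if mse > 0 and abs(1 - icc) > 1e-12:
        a_ = k * icc / (n * (1 - icc))
        b_ = 1 + k * icc * (n - 1) / (n * (1 - icc))
        num = (a_ * msc + b_ * mse) ** 2
        den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else k - 1
    else:
        v = k - 1  # limiting df as the error mean square vanishes
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), float(max(lo, -1.0)), float(min(hi, 1.0))


def cv_estimate(pairs: PairedSeries, method: str = "rms") -> float:
    """Within-subject coefficient of variation in percent.

    ``rms`` (default): ``100 · sqrt(mean_i((d_i²/2) / m_i²))`` with raw-unit
    differences d_i and pair means m_i.  ``sd_diff``: SD of raw differences /
    (grand mean · sqrt(2)), in percent.
    """
    if pairs.n < 3:
        raise DegenerateDataError("need n >= 3 pairs for a CV")
    m = (pairs.a + pairs.b) / 2.0
    if np.any(m <= 0):
        raise DegenerateDataError("pair means must be > 0 for a CV")
    d = pairs.a - pairs.b
    if method == "rms":
        return float(100.0 * math.sqrt(np.mean((d**2 / 2.0) / m**2)))
    if method == "sd_diff":
        return float(100.0 * d.std(ddof=1) / math.sqrt(2.0) / m.mean())
    raise ValueError(f"unknown CV method {method!r}")


def paired_t(pairs: PairedSeries) -> tuple[float, float]:
    """Two-sided paired t-test on the percentage differences.

    t = mean(d) / (SD(d)/sqrt(n)) with n−1 degrees of freedom.  Raises
    :class:`DegenerateDataError` when the differences have zero SD.
    """
    if pairs.n < 3:
        raise DegenerateDataError("need n >= 3 pairs for a paired t-test")
    d = percent_differences(pairs)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-SD differences: t undefined")
    t = float(d.mean() / (sd / math.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), d.size - 1))
    return t, p


def verdict(
    icc: float,
    cv_pct: float,
    mean_diff_pct: float,
    loa_lower_pct: float,
    loa_upper_pct: float,
    thresholds: dict | None = None,
) -> dict:
    """A-priori excellent-agreement flags.

    ``loa_ok`` requires both limits of agreement to deviate less than the
    threshold (10 percentage points) from the mean difference, i.e. 95% of
    differences within the ±10% measurement-error band around the mean.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    return {
        "icc_ok": bool(icc > th["icc"]),
        "cv_ok": bool(cv_pct < th["cv_pct"]),
        "meandiff_ok": bool(abs(mean_diff_pct) < th["mean_diff_pct"]),
        "loa_ok": bool(
            abs(loa_lower_pct - mean_diff_pct) < th["loa_pct"]
            and abs(loa_upper_pct - mean_diff_pct) < th["loa_pct"]
        ),
    }


def equality_plot_data(pairs: PairedSeries) -> pd.DataFrame:
    """Scatter data (a, b) per subject; the identity line is the reference."""
    return pd.DataFrame(
        {"subject_id": pairs.subject_ids, "a": pairs.a, "b": pairs.b}
    )


def analyze_pairs(
    pairs: PairedSeries,
    organ: str | None = None,
    icc_form: str = "two_way",
    cv_method: str = "rms",
    thresholds: dict | None = None,
) -> AgreementReport:
    """Full agreement report (ICC, CV, Bland–Altman, t-test, verdict)."""
    icc, lo, hi = icc_estimate(pairs, form=icc_form)
    cv = cv_estimate(pairs, method=cv_method)
    ba = bland_altman(pairs)
    try:
        t, p = paired_t(pairs)
    except DegenerateDataError:
        t, p = None, None  # conservative: p not computable
    return AgreementReport(
        design=pairs.design,
        organ=organ,
        n=pairs.n,
        n_excluded=pairs.n_excluded,
        icc=icc,
        icc_ci=(lo, hi),
        icc_form=icc_form,
        cv_pct=cv,
        cv_method=cv_method,
        mean_diff_pct=ba.mean_diff_pct,
        loa_lower_pct=ba.loa_lower_pct,
        loa_upper_pct=ba.loa_upper_pct,
        t_stat=t,
        p_value=p,
        verdict=verdict(icc, cv, ba.mean_diff_pct, ba.loa_lower_pct, ba.loa_upper_pct, thresholds),
    )


def agreement_table(
    records: pd.DataFrame,
    observers: tuple[str, str] | None = None,
    icc_form: str = "two_way",
    cv_method: str = "rms",
) -> pd.DataFrame:
    """Intra- (per observer) and interobserver reports for every organ."""
    obs = observers or tuple(pd.unique(records["observer_id"]))[:2]
    rows = []
    for organ in pd.unique(records["organ"]):
        for o in obs:
            pairs = build_pairs(records, "intra", organ, observer=o)
            if pairs.n >= 3:
                rows.append(analyze_pairs(pairs, organ, icc_form, cv_method).to_dict())
        pairs = build_pairs(records, "inter", organ, observers=obs)
        if pairs.n >= 3:
            rows.append(analyze_pairs(pairs, organ, icc_form, cv_method).to_dict())
    return pd.DataFrame(rows)
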