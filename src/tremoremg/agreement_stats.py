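"""Method-comparison and reliability statistics for paired measurements.

Implements the agreement toolbox used to validate one tremor-measurement
system against another (e.g. a wearable recorder against a clinical EMG
machine) and to assess test–retest reliability: Bland–Altman bias and 95%
limits of agreement, ICC(2,1) (two-way random effects, absolute
agreement, single measurement), the paired t-test, Pearson correlation,
RMSE / maximum absolute error, and a two-sided variance-ratio F test.

Phase differences are treated as ordinary linear quantities on [0°, 180°]
throughout, matching how such device-comparison studies apply
Bland–Altman and t statistics to phase; :func:`circular_agreement_bias`
offers a circular alternative for data near the axial wrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateDataError, InsufficientDataError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "bland_altman",
    "icc_agreement",
    "paired_t",
    "pearson",
    "error_summary",
    "variance_f_test",
    "agreement_report",
    "circular_agreement_bias",
]


@dataclass
class PairedMeasurements:
    """Paired values of one quantity from two systems (or two sessions).

    ``system_a`` is the reference, ``system_b`` the device under test;
    differences are a − b.
    """

    system_a: np.ndarray
    system_b: np.ndarray
    quantity: str = "value"
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.system_a = np.asarray(self.system_a, dtype=float)
        self.system_b = np.asarray(self.system_b, dtype=float)
        if self.system_a.ndim != 1 or self.system_b.ndim != 1:
            raise DataError("paired measurements must be 1-D sequences")
        if len(self.system_a) != len(self.system_b):
            raise DataError("paired measurements must have equal length")
        if len(self.system_a) < 2:
            raise InsufficientDataError("need at least 2 pairs")
        if not (
            np.all(np.isfinite(self.system_a)) and np.all(np.isfinite(self.system_b))
        ):
            raise DataError("paired measurements must be finite")
        if self.labels is not None and len(self.labels) != len(self.system_a):
            raise DataError("labels length must match the number of pairs")

    @property
    def n(self) -> int:
        return len(self.system_a)

    @property
    def diffs(self) -> np.ndarray:
        return self.system_a - self.system_b


def bland_altman(p: PairedMeasurements) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bias and 95% limits of agreement of the paired differences.

    Returns ``(bias, (loa_low, loa_high), diffs)`` with
    ``loa = bias ± 1.96·sd(d)`` and sd using the n−1 denominator.
    """
    d = p.diffs
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd), d


def _two_way_anova(X: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, error) of an n×k two-way table."""
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ssr = k * float(np.sum((row_m - grand) ** 2))
    ssc = n * float(np.sum((col_m - grand) ** 2))
    sse = float(np.sum((X - grand) ** 2)) - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_agreement(
    p: PairedMeasurements, form: str = "agreement", alpha: float = 0.05
) -> tuple[float, float, float]:
    """Single-measurement two-way random-effects ICC with its 95% CI.

    ``form="agreement"`` gives ICC(2,1) (absolute agreement — sensitive to
    a systematic offset between the systems); ``form="consistency"`` gives
    ICC(3,1).  Point estimates come from the two-way ANOVA decomposition
    of the n×2 table; the confidence interval is the standard
    F-distribution interval (Shrout–Fleiss / McGraw–Wong).
    """
    if p.n < 3:
        raise InsufficientDataError("ICC needs at least 3 pairs")
    values = np.concatenate([p.system_a, p.system_b])
    if np.ptp(values) == 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")

    X = np.column_stack([p.system_a, p.system_b])
    n, k = X.shape
    msr, msc, mse = _two_way_anova(X)

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            return float(icc), float(icc), float(icc)
        f_obs = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), float(lo), float(hi)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom
    if mse == 0 and msc == mse:
        return float(icc), float(icc), float(icc)
    # Satterthwaite df for the CI of ICC(2,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else math.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else math.inf
    if math.isinf(a) or math.isinf(b):
        return float(icc), float(icc), float(icc)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), float(lo), float(hi)


def paired_t(p: PairedMeasurements) -> tuple[float, float]:
    """Classical paired t-test on the differences (two-sided).

    Degenerate cases: identical samples give ``(0, 1)`` by convention; a
    constant non-zero difference gives ``(±inf, 0)`` as the limit.
    """
    d = p.diffs
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t, pv = stats.ttest_rel(p.system_a, p.system_b)
    return float(t), float(pv)


def pearson(p: PairedMeasurements) -> tuple[float, float]:
    """Pearson correlation of the paired values with its two-sided p."""
    if p.n < 3:
        raise InsufficientDataError("Pearson correlation needs at least 3 pairs")
    if np.std(p.system_a) == 0 or np.std(p.system_b) == 0:
        raise DegenerateDataError("correlation undefined: zero variance")
    r = stats.pearsonr(p.system_a, p.system_b)
    return float(r.statistic), float(r.pvalue)


def error_summary(p: PairedMeasurements) -> tuple[float, float]:
    """Root-mean-square error and MAXIMUM absolute error of the pairs.

    Note: in device-comparison reports "MAE" often denotes the maximum —
    not mean — absolute paired difference; that convention is used here.
    """
    d = p.diffs
    rmse = float(np.sqrt(np.mean(d**2)))
    return rmse, float(np.max(np.abs(d)))


def variance_f_test(x, y) -> tuple[float, float]:
    """Two-sided F test comparing the variances of two samples.

    ``F = var(x)/var(y)`` with n−1 denominators;
    ``p = 2·min(P(F ≤ f), P(F ≥ f))`` capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("F test needs at least 2 values per sample")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0 or vy == 0:
        raise DegenerateDataError("F test undefined: zero variance")
    f = vx / vy
    dist = stats.f(len(x) - 1, len(y) - 1)
    pv = 2.0 * min(dist.cdf(f), dist.sf(f))
    return f, float(min(pv, 1.0))


def circular_agreement_bias(p: PairedMeasurements) -> float:
    """Circular mean of the paired angular differences, in degrees.

    Alternative to the linear Bland–Altman bias for phase data whose
    differences may straddle the wrap; provided for sensitivity checks,
    not used in the standard report.
    """
    d = np.deg2rad(p.diffs)
    return float(np.degrees(np.angle(np.mean(np.exp(1j * d)))))


@dataclass
class AgreementReport:
    """All paired-comparison statistics for one quantity."""

    quantity: str
    n: int
    bias: float
    loa: tuple[float, float]
    paired_t_stat: float
    paired_t_p: float
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci: tuple[float, float]
    rmse: float
    max_abs_err: float
    f_ratio: float
    f_p: float
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "n": self.n,
            "bias": self.bias,
            "loa_low": self.loa[0],
            "loa_high": self.loa[1],
            "paired_t_stat": self.paired_t_stat,
            "paired_t_p": self.paired_t_p,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "icc": self.icc,
            "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1],
            "rmse": self.rmse,
            "max_abs_err": self.max_abs_err,
            "f_ratio": self.f_ratio,
            "f_p": self.f_p,
            "meta": self.meta,
        }


def agreement_report(p: PairedMeasurements) -> AgreementReport:
    """Compute the full agreement report for one paired quantity.

    The F test compares the dispersion of the two systems' values (a vs
    b); everything else operates on the paired differences a − b.
    """
    bias, loa, _ = bland_altman(p)
    t, t_p = paired_t(p)
    r, r_p = pearson(p)
    icc, lo, hi = icc_agreement(p)
    rmse, mae = error_summary(p)
    f, f_p = variance_f_test(p.system_a, p.system_b)
    return AgreementReport(
        quantity=p.quantity,
        n=p.n,
        bias=bias,
        loa=loa,
        paired_t_stat=t,
        paired_t_p=t_p,
        pearson_r=r,
        pearson_p=r_p,
        icc=icc,
        icc_ci=(lo, hi),
        rmse=rmse,
        max_abs_err=mae,
        f_ratio=f,
        f_p=f_p,
        meta={"difference": "system_a - system_b"},
    )
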