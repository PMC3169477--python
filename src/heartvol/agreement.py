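"""Method- and observer-agreement statistics.

Implements the standard method-comparison toolkit: Bland-Altman bias and
95% limits of agreement, Pearson correlation (r, r^2), the paired t test,
mean absolute / relative observer differences, signed percent bias
against a ground truth, and a coefficient of variation.

Sign convention: differences are method - reference (d = y - x), so a
negative bias means the method underestimates the reference.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "correlation",
    "paired_t",
    "observer_differences",
    "percent_bias_vs_truth",
    "compare_series",
]


@dataclass
class AgreementReport:
    """Agreement summary between a method series and a reference series.

    bias, sd_diff and the limits of agreement share the input units;
    mean_rel_diff and cv are percentages. ``flags`` records degenerate
    situations (zero-variance differences, undefined relative forms).
    """

    n: int
    bias: float = float("nan")
    sd_diff: float = float("nan")
    loa_low: float = float("nan")
    loa_high: float = float("nan")
    r: float = float("nan")
    r2: float = float("nan")
    t_stat: float = float("nan")
    p_value: float = float("nan")
    mean_abs_diff: float = float("nan")
    mean_rel_diff: float = float("nan")
    cv: float = float("nan")
    loa_multiplier: float = 1.96
    flags: tuple[str, ...] = ()
    means: tuple[float, ...] = ()
    diffs: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        d = self.to_dict()
        d["flags"] = list(d["flags"])
        d["means"] = list(d["means"])
        d["diffs"] = list(d["diffs"])
        return json.dumps(d, sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        d = dict(d)
        for k in ("flags", "means", "diffs"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "AgreementReport":
        return cls.from_dict(json.loads(s))


def _pair(x: Sequence[float], y: Sequence[float], min_n: int = 2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D series of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    return x, y


def bland_altman(x: Sequence[float], y: Sequence[float],
                 loa_multiplier: float = 1.96,
                 exact_t: bool = False) -> AgreementReport:
    """Bland-Altman bias and limits of agreement for d = y - x.

    bias is mean(d); sd_diff the sample SD (n-1 denominator); the limits
    of agreement are bias +/- 1.96*sd_diff by convention (``exact_t``
    swaps in the two-sided t quantile for small n). The per-pair
    (mean, difference) points are kept on the report for plotting.
    """
    x, y = _pair(x, y)
    d = y - x
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mult = float(stats.t.ppf(0.975, n - 1)) if exact_t else loa_multiplier
    flags: list[str] = []
    if sd == 0.0:
        flags.append("zero-variance differences; limits of agreement collapse to the bias")
    return AgreementReport(
        n=n, bias=bias, sd_diff=sd,
        loa_low=bias - mult * sd, loa_high=bias + mult * sd,
        loa_multiplier=mult, flags=tuple(flags),
        means=tuple((x + y) / 2.0), diffs=tuple(d),
    )


def correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r and r^2."""
    x, y = _pair(x, y, min_n=3)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation is undefined for a zero-variance series")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t test on d = y - x with n-1 degrees of freedom.

    Degenerate zero-variance differences are handled explicitly: all-zero
    differences give (t=0, p=1) by convention; a constant nonzero
    difference gives an infinite t with p = 0.
    """
    x, y = _pair(x, y)
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            warnings.warn("identical series; paired t reported as (0, 1) by convention",
                          stacklevel=2)
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences; t is infinite", stacklevel=2)
        return math.copysign(math.inf, float(d.mean())), 0.0
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)


def observer_differences(a: Sequence[float],
                         b: Sequence[float]) -> tuple[float, float]:
    """Mean absolute and mean relative (percent) inter-observer difference.

    The relative form divides each |a_i - b_i| by the initial measurement
    a_i; any a_i = 0 makes it undefined (NaN) while the absolute form is
    still returned.
    """
    a, b = _pair(a, b, min_n=1)
    absd = np.abs(a - b)
    mean_abs = float(absd.mean())
    if np.any(a == 0.0):
        warnings.warn("initial measurement contains zeros; relative difference "
                      "undefined", stacklevel=2)
        return mean_abs, float("nan")
    return mean_abs, float(100.0 * (absd / np.abs(a)).mean())


def percent_bias_vs_truth(measured: Sequence[float],
                          truth: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Signed per-heart percent bias against ground truth, plus mean +/- SD.

    Returns (per-heart percent series, mean, sample SD); negative values
    mean the method underestimates the truth.
    """
    measured, truth = _pair(measured, truth, min_n=1)
    if np.any(truth <= 0.0):
        raise ValueError("truth values must be strictly positive")
    pct = 100.0 * (measured - truth) / truth
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else float("nan")
    return pct, float(pct.mean()), sd


def compare_series(x: Sequence[float], y: Sequence[float],
                   loa_multiplier: float = 1.96,
                   exact_t: bool = False) -> AgreementReport:
    """Full agreement report of method y against reference x.

    Combines Bland-Altman, Pearson correlation, the paired t test, the
    observer-difference summaries and a coefficient of variation defined
    as 100 * SD(d) / mean(x) (the reference series sets the scale).
    """
    report = bland_altman(x, y, loa_multiplier=loa_multiplier, exact_t=exact_t)
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    flags = list(report.flags)
    if len(x_a) >= 3 and x_a.std() > 0 and y_a.std() > 0:
        report.r, report.r2 = correlation(x_a, y_a)
    else:
        flags.append("correlation undefined (n < 3 or zero variance)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report.t_stat, report.p_value = paired_t(x_a, y_a)
        report.mean_abs_diff, report.mean_rel_diff = observer_differences(x_a, y_a)
    if x_a.mean() != 0.0:
        report.cv = float(100.0 * report.sd_diff / x_a.mean())
    else:
        flags.append("CV undefined (reference mean is zero)")
    report.flags = tuple(flags)
    return report
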