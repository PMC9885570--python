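"""Degree-distribution statistics: reverse-cumulative curves, discrete
power-law fits and two-sample distribution comparison.

Heavy-tailed ("scale-free") layer-degree distributions are the fingerprint of
hub structure in both the drug-target and drug-sensitive layers.  The fit is
the standard discrete maximum-likelihood estimator: for a tail k >= xmin,

    p(k) = k^(-alpha) / zeta(alpha, xmin),

with zeta the Hurwitz zeta function; xmin="auto" scans candidate cutoffs and
keeps the one whose fitted model minimizes the Kolmogorov-Smirnov distance to
the empirical tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats


@dataclass(frozen=True)
class ReverseCumulative:
    """Empirical CCDF on the distinct observed degrees: ccdf(k) = P(K >= k)."""

    support: np.ndarray  # ascending distinct positive integers
    ccdf: np.ndarray  # values in (0, 1], non-increasing

    def as_table(self) -> list[tuple[int, float]]:
        return list(zip(self.support.tolist(), self.ccdf.tolist()))


@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law tail fit.

    alpha: ML exponent (> 1); xmin: tail cutoff; n_tail: observations >= xmin;
    ks_distance: sup-norm gap between empirical and fitted tail CCDF.
    """

    alpha: float
    xmin: int
    n_tail: int
    ks_distance: float


def _check_degrees(degrees: Sequence[int], what: str = "degrees") -> np.ndarray:
    arr = np.asarray(degrees)
    if arr.size == 0:
        raise ValueError(f"{what} must be non-empty")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{what} must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 1).any():
        raise ValueError(f"{what} must be positive (>= 1)")
    return arr


def reverse_cumulative(degrees: Sequence[int]) -> ReverseCumulative:
    """Reverse-cumulative distribution: ccdf(k) = #{d >= k} / n over observed k."""
    arr = _check_degrees(degrees)
    support, counts = np.unique(arr, return_counts=True)
    # count of values >= k, via suffix sums of the per-value counts
    tail_counts = counts[::-1].cumsum()[::-1]
    return ReverseCumulative(support=support, ccdf=tail_counts / arr.size)


def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def _mle_alpha(tail: np.ndarray, xmin: int) -> float:
    """Maximize the discrete power-law log-likelihood in alpha."""
    mean_log = float(np.log(tail).mean())

    def nll(alpha: float) -> float:
        return np.log(_zeta(alpha, xmin)) + alpha * mean_log

    res = optimize.minimize_scalar(nll, bounds=(1.000001, 25.0), method="bounded")
    return float(res.x)


def _model_ccdf(support: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    """P(K >= k | K >= xmin) = zeta(alpha, k) / zeta(alpha, xmin)."""
    return special.zeta(alpha, support) / _zeta(alpha, xmin)


def _ks_tail(tail: np.ndarray, alpha: float, xmin: int) -> float:
    support, counts = np.unique(tail, return_counts=True)
    emp_ccdf = counts[::-1].cumsum()[::-1] / tail.size
    model = _model_ccdf(support, alpha, xmin)
    # sup-norm gap between empirical and model tail CCDF on observed support
    return float(np.max(np.abs(emp_ccdf - model)))


def fit_power_law(degrees: Sequence[int], xmin: int | str = "auto") -> PowerLawFit:
    """Discrete ML power-law fit of the degree tail.

    With ``xmin="auto"`` every distinct observed value leaving a tail of
    >= 2 distinct values is tried and the KS-minimizing cutoff kept (the
    field-standard Clauset-style selection).  A degenerate tail (all values
    equal) is an error, not a fit.
    """
    arr = _check_degrees(degrees)

    if xmin == "auto":
        candidates = np.unique(arr)
        best: PowerLawFit | None = None
        for xm in candidates:
            tail = arr[arr >= xm]
            if np.unique(tail).size < 2:
                continue
            alpha = _mle_alpha(tail, int(xm))
            ks = _ks_tail(tail, alpha, int(xm))
            if best is None or ks < best.ks_distance:
                best = PowerLawFit(alpha=alpha, xmin=int(xm), n_tail=tail.size, ks_distance=ks)
        if best is None:
            raise ValueError("degenerate degree data: no tail with >= 2 distinct values")
        return best

    xmin = int(xmin)
    if xmin < 1:
        raise ValueError("xmin must be a positive integer")
    tail = arr[arr >= xmin]
    if np.unique(tail).size < 2:
        raise ValueError("degenerate tail: need >= 2 distinct values at or above xmin")
    alpha = _mle_alpha(tail, xmin)
    return PowerLawFit(
        alpha=alpha, xmin=xmin, n_tail=tail.size, ks_distance=_ks_tail(tail, alpha, xmin)
    )


def compare_distributions(
    a: Sequence[int], b: Sequence[int]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of two degree samples.

    Returns (statistic, p-value).  A small statistic supports treating one
    sample as representative of the other (the dual-set vs full-set check).
    """
    arr_a = _check_degrees(a, "first sample")
    arr_b = _check_degrees(b, "second sample")
    res = stats.ks_2samp(arr_a, arr_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def plot_ccdf(curves: dict[str, ReverseCumulative], path: str, title: str = "") -> None:
    """Log-log CCDF plot for one or more labelled degree samples."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.loglog(curve.support, curve.ccdf, marker="o", ls="none", ms=4, label=label)
    ax.set_xlabel("degree k")
    ax.set_ylabel("P(K >= k)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
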