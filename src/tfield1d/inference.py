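"""Critical thresholds and suprathreshold intervals for t continua.

Four domain-wide thresholds are computed, all two-tailed:

uncorrected
    The 0-D critical value ``F_t^{-1}(1 - alpha/2; df)``.
bonferroni
    The 0-D critical value at per-node level ``alpha / Q``.
rft
    The value ``u`` at which the expected Euler characteristic of the
    suprathreshold set of a smooth null t-field equals ``alpha / 2`` per
    tail, with resel count ``(Q - 1) / fwhm``.
fdr
    The Benjamini-Hochberg step-up threshold on two-tailed node-wise
    p-values: the t value of the highest p satisfying ``p(i) <= i alpha / Q``,
    or undefined (``None``) when no node satisfies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .tfields import TField

__all__ = [
    "ThresholdSet",
    "p_from_t",
    "threshold_uncorrected",
    "threshold_bonferroni",
    "threshold_rft",
    "threshold_fdr",
    "compute_thresholds",
    "significant_intervals",
    "intervals_to_percent",
]

_EC_CONST = np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi)


@dataclass(frozen=True)
class ThresholdSet:
    """The four critical t thresholds at level ``alpha`` (two-tailed).

    ``fdr`` is ``None`` when no node's p-value satisfies the BH inequality
    (no discovery).
    """

    alpha: float
    df: int
    Q: int
    fwhm: float
    uncorrected: float
    bonferroni: float
    rft: float
    fdr: float | None

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "df": self.df,
            "Q": self.Q,
            "fwhm": self.fwhm,
            "thresholds": {
                "uncorrected": self.uncorrected,
                "bonferroni": self.bonferroni,
                "rft": self.rft,
                "fdr": self.fdr,
            },
        }


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")


def p_from_t(tfield: TField) -> np.ndarray:
    """Two-tailed node-wise p-values: ``p = 2 (1 - F_t(|t|; df))``."""
    return 2.0 * stats.t.sf(np.abs(tfield.t), tfield.df)


def threshold_uncorrected(alpha: float, df: int) -> float:
    """Two-tailed 0-D critical value at level alpha."""
    _check_alpha(alpha)
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def threshold_bonferroni(alpha: float, df: int, Q: int) -> float:
    """Two-tailed critical value at per-node level ``alpha / Q``."""
    _check_alpha(alpha)
    if int(Q) != Q or Q < 1:
        raise ValueError(f"Q must be an integer >= 1, got {Q!r}")
    return float(stats.t.ppf(1.0 - alpha / (2.0 * Q), df))


def expected_ec(u, df: int, resels: float):
    """Expected Euler characteristic of the excursion set above ``u``.

    ``P(T > u) + resels * sqrt(4 ln 2) / (2 pi) * (1 + u^2 / df)^(-(df-1)/2)``
    — the standard high-threshold approximation to the one-tailed
    suprathreshold probability of a smooth 1-D t-field.
    """
    u = np.asarray(u, dtype=float)
    return stats.t.sf(u, df) + resels * _EC_CONST * (1.0 + u ** 2 / df) ** (
        -(df - 1) / 2.0
    )


def threshold_rft(alpha: float, df: int, Q: int, fwhm: float) -> float:
    """Two-tailed RFT critical value: solve ``E[EC](u) = alpha / 2``.

    Solved by bracketed root-finding to absolute tolerance 1e-6.  Strictly
    decreasing in ``fwhm`` and in ``df``; approaches the uncorrected value
    as ``fwhm -> inf`` (one-resel limit).
    """
    _check_alpha(alpha)
    if not fwhm > 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm!r}")
    if int(Q) != Q or Q < 2:
        raise ValueError(f"Q must be an integer >= 2, got {Q!r}")
    resels = (Q - 1) / float(fwhm)
    target = alpha / 2.0

    def f(u: float) -> float:
        return float(expected_ec(u, df, resels)) - target

    hi = 10.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError(
                f"no RFT root below {hi}: alpha={alpha}, df={df}, Q={Q}, fwhm={fwhm}"
            )
    return float(brentq(f, 0.0, hi, xtol=1e-6))


def rft_thresholds_batch(
    alpha: float, df: int, Q: int, fwhm: np.ndarray, tol: float = 1e-6
) -> np.ndarray:
    """Vectorized RFT thresholds for an array of fwhm values (bisection).

    Same root as :func:`threshold_rft` to within ``tol``; used by the Monte
    Carlo harness where one threshold per iteration is needed.
    """
    _check_alpha(alpha)
    fwhm = np.asarray(fwhm, dtype=float)
    if np.any(fwhm <= 0):
        raise ValueError("fwhm values must be > 0")
    resels = (Q - 1) / fwhm
    target = alpha / 2.0
    lo = np.zeros_like(fwhm)
    hi = np.full_like(fwhm, 10.0)
    while True:
        bad = expected_ec(hi, df, resels) > target
        if not np.any(bad):
            break
        hi[bad] *= 2.0
        if np.any(hi > 1e6):
            raise RuntimeError("no RFT root below 1e6")
    # ~60 bisection steps reach well below tol for any bracket width here
    for _ in range(int(np.ceil(np.log2(np.max(hi) / tol))) + 2):
        mid = 0.5 * (lo + hi)
        above = expected_ec(mid, df, resels) > target
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def bh_critical_p(p: np.ndarray, alpha: float) -> float | None:
    """Benjamini-Hochberg critical p: highest ``p(i) <= i alpha / Q``.

    Returns ``None`` when no ordered p-value satisfies the inequality.
    """
    _check_alpha(alpha)
    p = np.sort(np.asarray(p, dtype=float))
    Q = p.size
    i = np.arange(1, Q + 1)
    ok = p <= i * alpha / Q
    if not np.any(ok):
        return None
    return float(p[np.flatnonzero(ok)[-1]])


def threshold_fdr(tfield: TField, alpha: float) -> float | None:
    """FDR (BH) critical t threshold, or ``None`` when nothing is significant.

    Nodes with two-tailed p <= the BH critical p are the discoveries; the
    returned t value is ``F_t^{-1}(1 - p*/2; df)`` so that ``|t| >= threshold``
    marks exactly those nodes (up to floating-point round-off).
    """
    p_star = bh_critical_p(p_from_t(tfield), alpha)
    if p_star is None:
        return None
    return float(stats.t.ppf(1.0 - p_star / 2.0, tfield.df))


def compute_thresholds(tfield: TField, alpha: float = 0.05) -> ThresholdSet:
    """All four thresholds for a t-field at level alpha."""
    return ThresholdSet(
        alpha=alpha,
        df=tfield.df,
        Q=tfield.Q,
        fwhm=tfield.fwhm,
        uncorrected=threshold_uncorrected(alpha, tfield.df),
        bonferroni=threshold_bonferroni(alpha, tfield.df, tfield.Q),
        rft=threshold_rft(alpha, tfield.df, tfield.Q, tfield.fwhm),
        fdr=threshold_fdr(tfield, alpha),
    )


def significant_intervals(tfield: TField, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of consecutive nodes with ``|t| > threshold``.

    Returns disjoint, sorted, half-open ``(start, end)`` node intervals.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold!r}")
    above = np.abs(tfield.t) > threshold
    if not np.any(above):
        return []
    padded = np.concatenate([[False], above, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def intervals_to_percent(
    intervals: list[tuple[int, int]], Q: int
) -> list[tuple[float, float]]:
    """Map half-open node intervals to closed percent-of-domain intervals.

    Node ``x`` maps to ``100 x / (Q - 1)``; the displayed end is the last
    node in the run.
    """
    scale = 100.0 / (Q - 1)
    return [(start * scale, (end - 1) * scale) for start, end in intervals]
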