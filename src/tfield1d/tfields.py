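"""Node-wise t-statistic continua and the residuals behind them."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fieldgen import ContinuumSample, scale_covariate
from .smoothness import estimate_fwhm

__all__ = ["TField", "ZeroVarianceError", "one_sample_t", "paired_t", "regression_t"]


class ZeroVarianceError(ValueError):
    """Raised when a node has zero residual variance (t would be infinite)."""


@dataclass(frozen=True)
class TField:
    """A t-statistic continuum with its degrees of freedom and smoothness.

    Attributes
    ----------
    t : (Q,) array of finite t statistics
    df : degrees of freedom (>= 1)
    fwhm : estimated residual smoothness in node units (> 0)
    residuals : (J, Q) array of model residuals
    """

    t: np.ndarray
    df: int
    fwhm: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("t contains non-finite entries")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if not self.fwhm > 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        object.__setattr__(self, "t", t)

    @property
    def Q(self) -> int:
        return self.t.size


def _as_matrix(sample) -> np.ndarray:
    if isinstance(sample, ContinuumSample):
        return sample.values
    return ContinuumSample(np.asarray(sample, dtype=float)).values


def one_sample_t(sample) -> TField:
    """Node-wise one-sample t against zero: ``t = mean / (sd / sqrt(J))``, df = J-1."""
    x = _as_matrix(sample)
    J = x.shape[0]
    mean = x.mean(axis=0)
    residuals = x - mean
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        nodes = np.flatnonzero(sd == 0)
        raise ZeroVarianceError(f"zero variance at node(s) {nodes.tolist()}")
    t = mean / (sd / np.sqrt(J))
    return TField(t, J - 1, estimate_fwhm(residuals), residuals)


def paired_t(sample_a, sample_b) -> TField:
    """Node-wise paired t on differences ``A - B``; df = J-1.

    Exactly equivalent to ``one_sample_t(A - B)``.
    """
    a, b = _as_matrix(sample_a), _as_matrix(sample_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return one_sample_t(a - b)


def regression_t(sample, covariate) -> TField:
    """Node-wise t of the slope in simple linear regression on the covariate.

    df = J-2; residuals are the per-node fit residuals.  The covariate need
    only be non-constant; centering/scaling does not change t.
    """
    x = _as_matrix(sample)
    J = x.shape[0]
    if J < 3:
        raise ValueError(f"regression needs J >= 3, got J={J}")
    c = np.asarray(covariate, dtype=float)
    if c.shape != (J,):
        raise ValueError(f"covariate must have length J={J}, got shape {c.shape}")
    c = scale_covariate(c)  # raises on constant covariate
    sxx = np.sum(c ** 2)
    slope = (c @ x) / sxx
    fit = x.mean(axis=0) + np.outer(c, slope)
    residuals = x - fit
    sse = np.sum(residuals ** 2, axis=0)
    if np.any(sse == 0):
        nodes = np.flatnonzero(sse == 0)
        raise ZeroVarianceError(
            f"perfect fit (zero residual variance) at node(s) {nodes.tolist()}"
        )
    se = np.sqrt(sse / (J - 2) / sxx)
    return TField(slope / se, J - 2, estimate_fwhm(residuals), residuals)


# ---------------------------------------------------------------------------
# batch helpers used by the Monte Carlo harness (same math, stacked inputs)

def _one_sample_t_batch(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """t fields and residuals for a ``(n, J, Q)`` stack; returns (t, residuals, df)."""
    J = x.shape[1]
    mean = x.mean(axis=1)
    residuals = x - mean[:, None, :]
    sd = x.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(J))
    return t, residuals, J - 1


def _regression_t_batch(
    x: np.ndarray, covariate: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Slope t fields for a ``(n, J, Q)`` stack against one length-J covariate."""
    J = x.shape[1]
    c = scale_covariate(covariate)
    sxx = np.sum(c ** 2)
    slope = np.einsum("j,njq->nq", c, x) / sxx
    fit = x.mean(axis=1)[:, None, :] + c[None, :, None] * slope[:, None, :]
    residuals = x - fit
    sse = np.sum(residuals ** 2, axis=1)
    se = np.sqrt(sse / (J - 2) / sxx)
    return slope / se, residuals, J - 2
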