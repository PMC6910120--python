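"""Smooth 1-D Gaussian noise, Gaussian pulse signals, and synthetic datasets.

The noise model is white Gaussian noise convolved with a Gaussian kernel
parameterized by its full-width-at-half-maximum (FWHM, in node units).  The
kernel is scaled so that every node has exactly unit population variance,
which makes a pulse amplitude directly interpretable as a signal-to-noise
ratio.  White noise is generated on a padded domain and truncated after
convolution so that boundary nodes have the same (non-wrapped) covariance
structure as interior nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "MIN_FWHM",
    "NoiseSpec",
    "SignalSpec",
    "ContinuumSample",
    "SyntheticDataset",
    "generate_noise",
    "gaussian_pulse",
    "synthesize_dataset",
    "fwhm_to_sd",
]

#: Requested smoothness below this is clamped: the generator degenerates to
#: white noise and the smoothness estimator is undefined below ~1 node.
MIN_FWHM = 0.5

_FWHM_PER_SD = np.sqrt(8.0 * np.log(2.0))

DESIGNS = ("one-sample", "paired", "regression")


def fwhm_to_sd(fwhm: float) -> float:
    """Convert a Gaussian kernel FWHM to its standard deviation."""
    return float(fwhm) / _FWHM_PER_SD


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of a smooth Gaussian noise sample.

    Attributes
    ----------
    J : int
        Number of observations (rows), ``>= 2``.
    Q : int
        Number of continuum nodes (columns), ``>= 2``.
    fwhm : float
        Smoothness of the noise in node units, ``> 0``.  Values below
        :data:`MIN_FWHM` are clamped at generation time.
    seed : int or None
        Seed for reproducible generation; identical spec + seed gives
        bit-identical output.
    """

    J: int
    Q: int
    fwhm: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.J) != self.J or self.J < 2:
            raise ValueError(f"J must be an integer >= 2, got {self.J!r}")
        if int(self.Q) != self.Q or self.Q < 2:
            raise ValueError(f"Q must be an integer >= 2, got {self.Q!r}")
        if not np.isfinite(self.fwhm) or self.fwhm <= 0:
            raise ValueError(f"fwhm must be finite and > 0, got {self.fwhm!r}")


@dataclass(frozen=True)
class SignalSpec:
    """A Gaussian pulse: ``amp * exp(-(x - q)^2 / (2 sigma^2))``.

    ``sigma = 0`` denotes the no-signal (flat zero) case.  Because generated
    noise has unit variance, ``amp`` equals the signal-to-noise ratio.
    ``q`` may lie outside ``[0, Q-1]``; only the pulse tail then enters the
    domain.
    """

    q: float
    sigma: float
    amp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.q):
            raise ValueError(f"q must be finite, got {self.q!r}")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")
        if not np.isfinite(self.amp):
            raise ValueError(f"amp must be finite, got {self.amp!r}")

    @classmethod
    def null(cls) -> "SignalSpec":
        return cls(q=0.0, sigma=0.0, amp=0.0)


@dataclass(frozen=True)
class ContinuumSample:
    """A J x Q matrix of registered 1-D observations (one row per trial)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (J x Q), got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def J(self) -> int:
        return self.values.shape[0]

    @property
    def Q(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SyntheticDataset:
    """Output of :func:`synthesize_dataset`.

    ``samples`` holds one sample (one-sample, regression) or two (paired);
    ``covariate`` is the raw covariate vector for regression designs;
    ``signal_profile`` is the injected pulse evaluated at every node.
    """

    design: str
    samples: tuple[ContinuumSample, ...]
    signal_profile: np.ndarray
    covariate: np.ndarray | None = None


def _kernel(fwhm: float) -> np.ndarray:
    """Discrete Gaussian kernel scaled to unit power (sum of squares == 1).

    Unit power makes the convolution of unit-variance white noise have unit
    variance at every node.
    """
    sd = fwhm_to_sd(fwhm)
    radius = max(1, int(np.ceil(4.0 * sd)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x ** 2) / (2.0 * sd ** 2))
    return k / np.sqrt(np.sum(k ** 2))


def pad_width(fwhm: float) -> int:
    """One-sided white-noise padding needed for edge-correct smoothing."""
    return (_kernel(max(float(fwhm), MIN_FWHM)).size - 1) // 2


def _smooth(white: np.ndarray, fwhm: float) -> np.ndarray:
    """Convolve rows of padded white noise with the unit-power kernel.

    ``white`` must have ``Q + 2 * pad_width(fwhm)`` columns; the 'valid'
    convolution returns exactly ``Q`` columns free of boundary wrap-around.
    """
    k = _kernel(fwhm)
    return fftconvolve(white, k[None, :], mode="valid", axes=1)


def generate_noise(spec: NoiseSpec) -> ContinuumSample:
    """Generate J rows of smooth, unit-variance Gaussian noise.

    Each node is marginally N(0, 1); the inter-node correlation at lag
    ``d`` is ``exp(-2 ln 2 * d^2 / fwhm^2)`` (Gaussian-kernel-smoothed
    white noise).
    """
    fwhm = max(float(spec.fwhm), MIN_FWHM)
    rng = np.random.default_rng(spec.seed)
    pad = pad_width(fwhm)
    white = rng.standard_normal((spec.J, spec.Q + 2 * pad))
    return ContinuumSample(_smooth(white, fwhm))


def gaussian_pulse(signal: SignalSpec, Q: int) -> np.ndarray:
    """Evaluate the pulse ``amp * exp(-(x - q)^2 / (2 sigma^2))`` at nodes 0..Q-1.

    ``sigma = 0`` or ``amp = 0`` yields the all-zero continuum.
    """
    if int(Q) != Q or Q < 2:
        raise ValueError(f"Q must be an integer >= 2, got {Q!r}")
    x = np.arange(Q, dtype=float)
    if signal.sigma == 0.0 or signal.amp == 0.0:
        return np.zeros(Q)
    return signal.amp * np.exp(-((x - signal.q) ** 2) / (2.0 * signal.sigma ** 2))


def scale_covariate(covariate: np.ndarray) -> np.ndarray:
    """Center a covariate and scale it to unit standard deviation."""
    c = np.asarray(covariate, dtype=float)
    c = c - c.mean()
    sd = c.std(ddof=0)
    if sd == 0:
        raise ValueError("covariate is constant")
    return c / sd


def synthesize_dataset(
    noise: NoiseSpec,
    signal: SignalSpec,
    design: str = "one-sample",
    covariate: np.ndarray | None = None,
) -> SyntheticDataset:
    """Build a complete synthetic dataset for one of the three designs.

    paired
        Two samples; the second equals the first offset by the pulse plus an
        independent noise realization, so the paired differences are
        ``pulse + unit-variance smooth noise`` and ``amp`` is the
        signal-to-noise ratio of the analyzed differences.
    one-sample
        One noise sample offset by the pulse.
    regression
        One noise sample in which observation ``j`` receives the pulse scaled
        by its centered, unit-SD-scaled covariate value, so ``amp`` is the
        systematic effect in noise-SD units per standard deviation of the
        covariate.  ``covariate`` defaults to ``0..J-1`` (evenly spaced).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
    pulse = gaussian_pulse(signal, noise.Q)
    if design == "paired":
        ss = np.random.SeedSequence(noise.seed)
        seed_a, seed_b = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
        a = generate_noise(NoiseSpec(noise.J, noise.Q, noise.fwhm, seed_a))
        d = generate_noise(NoiseSpec(noise.J, noise.Q, noise.fwhm, seed_b))
        b = ContinuumSample(a.values + pulse + d.values)
        return SyntheticDataset(design, (a, b), pulse)
    base = generate_noise(noise)
    if design == "one-sample":
        if covariate is not None:
            raise ValueError("covariate is only valid for the regression design")
        return SyntheticDataset(design, (ContinuumSample(base.values + pulse),), pulse)
    # regression
    if covariate is None:
        covariate = np.arange(noise.J, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (noise.J,):
        raise ValueError(
            f"covariate must have length J={noise.J}, got shape {covariate.shape}"
        )
    scaled = scale_covariate(covariate)
    values = base.values + np.outer(scaled, pulse)
    return SyntheticDataset(design, (ContinuumSample(values),), pulse, covariate)
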