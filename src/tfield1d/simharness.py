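"""Monte Carlo engine for threshold convergence/divergence experiments.

Each grid cell runs ``iterations`` independent simulated datasets through the
full pipeline (noise -> t-field -> smoothness -> thresholds) and records mean
thresholds and empirical error rates.  Per-iteration seeds are derived
deterministically from the root seed, the cell's *noise* parameters (J, fwhm)
and the iteration index, so that cells differing only in signal parameters
share noise realizations.  This makes results independent of execution order
and makes RFT thresholds — which depend only on noise — exactly identical
across signal cells at fixed (J, Q, fwhm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import fieldgen
from .fieldgen import ContinuumSample, NoiseSpec, SignalSpec, SyntheticDataset
from .inference import compute_thresholds, rft_thresholds_batch, significant_intervals
from .smoothness import estimate_fwhm_batch
from .tfields import TField, _one_sample_t_batch, _regression_t_batch, paired_t, regression_t

__all__ = [
    "SimulationGrid",
    "run_no_signal",
    "run_with_signal",
    "estimate_error_rates",
    "replicate_table2",
    "TABLE2_DATASET_A",
    "TABLE2_DATASET_B",
]

METHODS = ("uncorrected", "bonferroni", "rft", "fdr")

#: Replication parameters for the two simulated datasets
#: (design, J, fwhm, pulse center q, pulse breadth sigma, amplitude).
TABLE2_DATASET_A = dict(design="paired", J=10, fwhm=20.37, q=101.0, sigma=3.0, amp=2.3)
TABLE2_DATASET_B = dict(design="regression", J=7, fwhm=7.94, q=17.0, sigma=19.0, amp=1.2)


@dataclass(frozen=True)
class SimulationGrid:
    """Parameter grid for a Monte Carlo run.

    Defaults follow the published experiment bounds: J in 5..50, fwhm in
    10..30 (% of domain), sigma in 0..20, amp in 0..4, Q = 101, 10,000
    iterations per cell.
    """

    J_values: tuple = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
    fwhm_values: tuple = (10.0, 15.0, 20.0, 25.0, 30.0)
    sigma_values: tuple = (0.0,)
    amp_values: tuple = (0.0,)
    q: float = 50.0
    Q: int = 101
    iterations: int = 10_000
    seed: int = 0
    design: str = "one-sample"
    alpha: float = 0.05
    null_cutoff: float = 0.01  # a node is 'null' when |pulse| < null_cutoff * amp

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for name in ("J_values", "fwhm_values", "sigma_values", "amp_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.design not in fieldgen.DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def iteration_seed(root: int, J: int, fwhm: float, iteration: int) -> int:
    """Deterministic per-iteration seed from the root seed and noise cell."""
    ss = np.random.SeedSequence([root, J, int(round(fwhm * 1e6)), iteration])
    return int(ss.generate_state(1)[0])


def _white_rows(design: str, J: int, seed: int, width: int) -> np.ndarray:
    """Padded white-noise rows exactly matching fieldgen's seeded generation.

    For the paired design only the difference-noise stream (the second seed
    spawned by ``synthesize_dataset``) is generated: the paired differences
    are ``pulse + that noise``, so the first sample never enters the t-field.
    """
    if design == "paired":
        child = np.random.SeedSequence(seed).spawn(2)[1]
        seed = int(child.generate_state(1)[0])
    return np.random.default_rng(seed).standard_normal((J, width))


def _simulate_cell(
    *,
    J: int,
    Q: int,
    fwhm: float,
    signal: SignalSpec,
    design: str,
    iterations: int,
    seed: int,
    alpha: float,
    null_cutoff: float,
    covariate: np.ndarray | None = None,
) -> dict:
    """Run all iterations of one grid cell, vectorized in chunks."""
    fwhm_gen = max(float(fwhm), fieldgen.MIN_FWHM)
    pad = fieldgen.pad_width(fwhm_gen)
    width = Q + 2 * pad
    pulse = fieldgen.gaussian_pulse(signal, Q)
    if design == "regression":
        if covariate is None:
            covariate = np.arange(J, dtype=float)
        scaled_cov = fieldgen.scale_covariate(covariate)

    rows_per_iter = J
    chunk = max(1, int(4e6) // (rows_per_iter * width))

    rft_thr = np.empty(iterations)
    fdr_thr = np.full(iterations, np.nan)
    max_abs_t = np.empty(iterations)
    n_disc = np.zeros(iterations, dtype=int)
    n_false = np.zeros(iterations, dtype=int)

    null_nodes = (
        np.ones(Q, dtype=bool)
        if signal.amp == 0.0 or signal.sigma == 0.0
        else np.abs(pulse) < null_cutoff * abs(signal.amp)
    )

    for start in range(0, iterations, chunk):
        stop = min(start + chunk, iterations)
        m = stop - start
        white = np.empty((m * rows_per_iter, width))
        for k, i in enumerate(range(start, stop)):
            s = iteration_seed(seed, J, fwhm, i)
            white[k * rows_per_iter : (k + 1) * rows_per_iter] = _white_rows(
                design, J, s, width
            )
        noise = fieldgen._smooth(white, fwhm_gen).reshape(m, rows_per_iter, Q)

        if design in ("paired", "one-sample"):
            # paired differences reduce to pulse + one noise realization
            t, residuals, df = _one_sample_t_batch(noise + pulse)
        else:
            data = noise + scaled_cov[None, :, None] * pulse[None, None, :]
            t, residuals, df = _regression_t_batch(data, covariate)

        fwhm_hat = estimate_fwhm_batch(residuals)
        rft_thr[start:stop] = rft_thresholds_batch(alpha, df, Q, fwhm_hat)
        max_abs_t[start:stop] = np.max(np.abs(t), axis=1)

        p = 2.0 * stats.t.sf(np.abs(t), df)
        p_sorted = np.sort(p, axis=1)
        bh_line = np.arange(1, Q + 1) * alpha / Q
        ok = p_sorted <= bh_line
        any_ok = np.any(ok, axis=1)
        # index of the largest satisfying i per row
        last_idx = Q - 1 - np.argmax(ok[:, ::-1], axis=1)
        p_star = p_sorted[np.arange(m), last_idx]
        fdr_thr[start:stop][any_ok] = stats.t.ppf(1.0 - p_star[any_ok] / 2.0, df)

        disc = p <= p_star[:, None]
        disc[~any_ok] = False
        n_disc[start:stop] = disc.sum(axis=1)
        n_false[start:stop] = (disc & null_nodes).sum(axis=1)

    unc = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    bonf = float(stats.t.ppf(1.0 - alpha / (2.0 * Q), df))
    has_disc = n_disc > 0
    fdp = np.zeros(iterations)
    fdp[has_disc] = n_false[has_disc] / n_disc[has_disc]

    def _rate(x: np.ndarray) -> tuple[float, float]:
        r = float(np.mean(x))
        return r, float(np.sqrt(r * (1.0 - r) / iterations))

    fwer = {
        "uncorrected": _rate(max_abs_t > unc),
        "bonferroni": _rate(max_abs_t > bonf),
        "rft": _rate(max_abs_t > rft_thr),
        "fdr": _rate(has_disc),
    }
    finite_fdr = fdr_thr[np.isfinite(fdr_thr)]
    out = {
        "J": J,
        "fwhm": fwhm,
        "sigma": signal.sigma,
        "amp": signal.amp,
        "q": signal.q,
        "Q": Q,
        "design": design,
        "iterations": iterations,
        "df": df,
        "mean_uncorrected": unc,
        "mean_bonferroni": bonf,
        "mean_rft": float(np.mean(rft_thr)),
        "se_rft": float(np.std(rft_thr, ddof=1) / np.sqrt(iterations))
        if iterations > 1
        else 0.0,
        "mean_fdr": float(np.mean(finite_fdr)) if finite_fdr.size else np.nan,
        "se_fdr": float(np.std(finite_fdr, ddof=1) / np.sqrt(finite_fdr.size))
        if finite_fdr.size > 1
        else np.nan,
        "prop_fdr_undefined": float(np.mean(~np.isfinite(fdr_thr))),
        "mean_fdp": float(np.mean(fdp)),
        "mean_fdp_conditional": float(np.mean(fdp[has_disc])) if has_disc.any() else np.nan,
        "se_fdp_conditional": float(
            np.std(fdp[has_disc], ddof=1) / np.sqrt(has_disc.sum())
        )
        if has_disc.sum() > 1
        else np.nan,
    }
    for method, (r, se) in fwer.items():
        out[f"fwer_{method}"] = r
        out[f"se_fwer_{method}"] = se
    return out


def run_no_signal(grid: SimulationGrid) -> pd.DataFrame:
    """Mean RFT/FDR thresholds and empirical FWERs over the (J, fwhm) grid."""
    records = [
        _simulate_cell(
            J=J,
            Q=grid.Q,
            fwhm=fwhm,
            signal=SignalSpec.null(),
            design=grid.design,
            iterations=grid.iterations,
            seed=grid.seed,
            alpha=grid.alpha,
            null_cutoff=grid.null_cutoff,
        )
        for J in grid.J_values
        for fwhm in grid.fwhm_values
    ]
    return pd.DataFrame.from_records(records)


def run_with_signal(grid: SimulationGrid) -> pd.DataFrame:
    """Mean FDR thresholds, undefined proportions and empirical FDR over the
    full (J, fwhm, sigma, amp) grid."""
    if all(s == 0 for s in grid.sigma_values) and all(a == 0 for a in grid.amp_values):
        raise ValueError("with-signal run needs at least one positive sigma or amp")
    records = [
        _simulate_cell(
            J=J,
            Q=grid.Q,
            fwhm=fwhm,
            signal=SignalSpec(q=grid.q, sigma=sigma, amp=amp),
            design=grid.design,
            iterations=grid.iterations,
            seed=grid.seed,
            alpha=grid.alpha,
            null_cutoff=grid.null_cutoff,
        )
        for J in grid.J_values
        for fwhm in grid.fwhm_values
        for sigma in grid.sigma_values
        for amp in grid.amp_values
    ]
    return pd.DataFrame.from_records(records)


def estimate_error_rates(grid: SimulationGrid, method: str) -> pd.DataFrame:
    """Empirical FWER (no-signal cells) or FDR (signal cells) for one method.

    Rates come with binomial standard errors; the underlying simulations are
    the same deterministic streams as the threshold runs.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    has_signal = any(s > 0 for s in grid.sigma_values) and any(
        a > 0 for a in grid.amp_values
    )
    table = run_with_signal(grid) if has_signal else run_no_signal(grid)
    cols = ["J", "fwhm", "sigma", "amp", "Q", "design", "iterations"]
    out = table[cols].copy()
    out["method"] = method
    out["fwer"] = table[f"fwer_{method}"]
    out["se_fwer"] = table[f"se_fwer_{method}"]
    if has_signal and method == "fdr":
        out["empirical_fdr"] = table["mean_fdp_conditional"]
        out["se_empirical_fdr"] = table["se_fdp_conditional"]
    return out


def _replicate_one(params: dict, seed: int, alpha: float, amp_override=None) -> dict:
    amp = params["amp"] if amp_override is None else amp_override
    signal = SignalSpec(q=params["q"], sigma=params["sigma"], amp=amp)
    noise = NoiseSpec(params["J"], 101, params["fwhm"], seed=seed)
    ds = fieldgen.synthesize_dataset(noise, signal, params["design"])
    if params["design"] == "paired":
        tf = paired_t(ds.samples[1], ds.samples[0])
    else:
        tf = regression_t(ds.samples[0], ds.covariate)
    thresholds = compute_thresholds(tf, alpha)
    intervals = {
        m: significant_intervals(tf, thr)
        for m, thr in (
            ("uncorrected", thresholds.uncorrected),
            ("bonferroni", thresholds.bonferroni),
            ("rft", thresholds.rft),
            ("fdr", thresholds.fdr),
        )
        if thr is not None
    }
    return {"dataset": ds, "tfield": tf, "thresholds": thresholds, "intervals": intervals}


def replicate_table2(
    seed: int = 0,
    n_replicates: int = 1,
    alpha: float = 0.05,
    amp_override: float | None = None,
) -> list[dict]:
    """Simulate and analyze the two replication datasets.

    Dataset A: paired design, J=10, boundary pulse (q=101, sigma=3, amp=2.3),
    noise fwhm 20.37.  Dataset B: regression design, J=7, broad pulse (q=17,
    sigma=19, amp=1.2), noise fwhm 7.94.  Returns one bundle per dataset per
    replicate with keys ``dataset``, ``tfield``, ``thresholds``, ``intervals``.
    """
    bundles = []
    for r in range(n_replicates):
        for name, params in (("A", TABLE2_DATASET_A), ("B", TABLE2_DATASET_B)):
            s = int(
                np.random.SeedSequence([seed, r, 0 if name == "A" else 1]).generate_state(1)[0]
            )
            bundle = _replicate_one(params, s, alpha, amp_override)
            bundle["name"] = name
            bundle["replicate"] = r
            bundles.append(bundle)
    return bundles
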