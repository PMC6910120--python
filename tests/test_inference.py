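import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from tfield1d.fieldgen import NoiseSpec, SignalSpec, gaussian_pulse, generate_noise
from tfield1d.inference import (
    bh_critical_p,
    compute_thresholds,
    intervals_to_percent,
    p_from_t,
    rft_thresholds_batch,
    significant_intervals,
    threshold_bonferroni,
    threshold_fdr,
    threshold_rft,
    threshold_uncorrected,
)
from tfield1d.tfields import TField, one_sample_t


def _tfield(t, df=9, fwhm=20.0):
    t = np.asarray(t, dtype=float)
    return TField(t, df, fwhm, np.zeros((2, t.size)))


def _quantile_oracle(p_upper, df):
    """Independent t quantile: integrate the density and root-find."""

    def tail(u):
        val, _ = quad(lambda x: stats.t.pdf(x, df), u, np.inf)
        return val - p_upper

    return brentq(tail, 0.0, 200.0, xtol=1e-10)


class TestPFromT:
    def test_zero_t_gives_p_one(self):
        tf = _tfield([0.0, 1.0, -1.0])
        assert p_from_t(tf)[0] == pytest.approx(1.0)

    def test_hand_value(self):
        # frozen: 2 * (1 - F_t(2 sqrt(3); 2)) = 0.07417990...
        tf = _tfield([2.0 * np.sqrt(3.0)], df=2)
        assert p_from_t(tf)[0] == pytest.approx(0.0741799, abs=1e-6)

    @given(t=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_sign_symmetry(self, t):
        pa = p_from_t(_tfield([t], df=5))[0]
        pb = p_from_t(_tfield([-t], df=5))[0]
        assert pa == pb
        assert 0.0 < pa <= 1.0


class TestUncorrected:
    def test_textbook_value(self):
        assert threshold_uncorrected(0.05, 9) == pytest.approx(2.2622, abs=1e-4)

    def test_alpha_near_one_limit(self):
        assert threshold_uncorrected(0.999, 9) == pytest.approx(0.0, abs=0.01)

    def test_equals_bonferroni_with_single_node(self):
        assert threshold_uncorrected(0.05, 7) == threshold_bonferroni(0.05, 7, 1)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            threshold_uncorrected(alpha, 9)


class TestBonferroni:
    def test_against_independent_quantile_oracle(self):
        # frozen from the integration + root-finding oracle below
        oracle = _quantile_oracle(0.05 / 202, 9)
        assert oracle == pytest.approx(5.29818, abs=1e-4)
        assert threshold_bonferroni(0.05, 9, 101) == pytest.approx(oracle, abs=1e-8)

    def test_strictly_increasing_in_Q(self):
        vals = [threshold_bonferroni(0.05, 9, Q) for Q in (1, 2, 5, 20, 101, 500)]
        assert np.all(np.diff(vals) > 0)


class TestRFT:
    def test_one_resel_limit_approaches_uncorrected(self):
        # threshold decreases toward the 0-D value as smoothness grows;
        # at fwhm = 100 Q the gap is ~0.01, and it keeps shrinking
        unc = threshold_uncorrected(0.05, 9)
        gaps = [
            threshold_rft(0.05, 9, 101, f * 101) - unc for f in (10, 100, 1000)
        ]
        assert np.all(np.diff(gaps) < 0)
        assert gaps[0] > 0
        assert gaps[1] < 0.011
        assert gaps[2] < 0.01

    def test_strictly_decreasing_in_fwhm_and_df(self):
        by_fwhm = [threshold_rft(0.05, 9, 101, f) for f in (5, 10, 20, 40)]
        assert np.all(np.diff(by_fwhm) < 0)
        by_df = [threshold_rft(0.05, df, 101, 20.0) for df in (4, 9, 19, 49)]
        assert np.all(np.diff(by_df) < 0)

    def test_matches_simulation_quantile(self):
        # empirical 95th percentile of max |t| over null fields
        mx = []
        for k in range(2000):
            x = generate_noise(NoiseSpec(10, 101, 20.0, seed=50_000 + k)).values
            mx.append(np.max(np.abs(one_sample_t(x).t)))
        emp = np.quantile(mx, 0.95)
        thr = threshold_rft(0.05, 9, 101, 20.0)
        assert thr == pytest.approx(emp, abs=0.15)

    def test_batch_matches_scalar(self):
        fwhms = np.array([5.0, 12.3, 20.0, 77.7])
        batch = rft_thresholds_batch(0.05, 9, 101, fwhms)
        scalar = [threshold_rft(0.05, 9, 101, f) for f in fwhms]
        np.testing.assert_allclose(batch, scalar, atol=5e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            threshold_rft(0.05, 9, 101, 0.0)
        with pytest.raises(ValueError):
            threshold_rft(1.5, 9, 101, 20.0)


def _bh_bruteforce(p, alpha):
    """Exhaustive check of all Q inequalities (independent oracle)."""
    ps = np.sort(p)
    Q = ps.size
    best = None
    for i in range(1, Q + 1):
        if ps[i - 1] <= i * alpha / Q:
            best = ps[i - 1]
    return best


class TestFDR:
    def test_hand_enumerated_example(self):
        # p = (.01,.02,.04,.06) vs (.0125,.025,.0375,.05): largest i = 2
        p = np.array([0.010, 0.020, 0.040, 0.060])
        assert bh_critical_p(p, 0.05) == pytest.approx(0.020)

    def test_no_discovery_returns_none(self):
        p = np.full(10, 0.9)
        assert bh_critical_p(p, 0.05) is None
        tf = _tfield(np.full(10, 0.01))
        assert threshold_fdr(tf, 0.05) is None

    def test_full_discovery(self):
        Q = 8
        p = np.linspace(0.0001, 0.0005, Q)  # all below alpha/Q
        assert bh_critical_p(p, 0.05) == pytest.approx(p.max())

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            Q = rng.integers(2, 40)
            p = rng.uniform(size=Q) ** rng.uniform(0.5, 3.0)
            got = bh_critical_p(p, 0.05)
            want = _bh_bruteforce(p, 0.05)
            assert (got is None and want is None) or got == pytest.approx(want)

    def test_threshold_t_matches_critical_p(self):
        rng = np.random.default_rng(3)
        t = rng.standard_normal(101) * 3
        tf = _tfield(t, df=9)
        thr = threshold_fdr(tf, 0.05)
        if thr is not None:
            p = p_from_t(tf)
            p_star = bh_critical_p(p, 0.05)
            # discoveries by p match |t| >= threshold (up to round-off)
            np.testing.assert_array_equal(p <= p_star, np.abs(t) >= thr - 1e-9)

    def test_ties_share_one_decision(self):
        p = np.array([0.01, 0.01, 0.01, 0.9])
        assert bh_critical_p(p, 0.05) == pytest.approx(0.01)


class TestSignificantIntervals:
    def test_no_exceedance_empty(self):
        assert significant_intervals(_tfield(np.zeros(10)), 1.0) == []

    def test_single_boundary_run(self):
        t = np.zeros(101)
        t[95:101] = 5.0
        ivs = significant_intervals(_tfield(t), 3.0)
        assert ivs == [(95, 101)]
        assert intervals_to_percent(ivs, 101) == [(95.0, 100.0)]

    def test_multiple_runs_sorted_disjoint(self):
        t = np.zeros(50)
        t[2:5] = 4.0
        t[10:12] = -4.0  # negative excursions count via |t|
        t[40] = 6.0
        ivs = significant_intervals(_tfield(t), 3.0)
        assert ivs == [(2, 5), (10, 12), (40, 41)]

    def test_overwhelming_snr_pulse_yields_one_interval(self):
        noise = NoiseSpec(20, 101, 20.0, seed=8)
        pulse = gaussian_pulse(SignalSpec(q=50, sigma=3, amp=4.0), 101)
        tf = one_sample_t(generate_noise(noise).values + pulse)
        ts = compute_thresholds(tf, 0.05)
        ivs = significant_intervals(tf, ts.rft)
        assert len(ivs) == 1
        start, end = ivs[0]
        assert start <= 50 < end

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            significant_intervals(_tfield(np.zeros(5)), np.inf)


class TestThresholdSet:
    def test_ordering_invariants_null_field(self):
        # uncorrected <= rft and rft <= bonferroni in the smooth regime
        for seed in range(10):
            x = generate_noise(NoiseSpec(10, 101, 20.0, seed=seed)).values
            ts = compute_thresholds(one_sample_t(x), 0.05)
            assert ts.uncorrected < ts.rft
            assert ts.rft < ts.bonferroni

    def test_monotone_in_alpha(self, small_noise):
        tf = one_sample_t(small_noise)
        lo = compute_thresholds(tf, 0.5)
        hi = compute_thresholds(tf, 0.05)
        assert lo.uncorrected < hi.uncorrected
        assert lo.bonferroni < hi.bonferroni
        assert lo.rft < hi.rft

    def test_as_dict_round_trip(self, small_noise):
        import json

        ts = compute_thresholds(one_sample_t(small_noise), 0.05)
        d = ts.as_dict()
        json.dumps(d)  # serializable
        assert set(d["thresholds"]) == {"uncorrected", "bonferroni", "rft", "fdr"}
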