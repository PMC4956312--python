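"""Insulin-on-board, transfer entropy and policy initialisation."""

import warnings

import numpy as np
import pytest

from apctl import (
    ActiveInsulinTrace,
    GlucoseTrace,
    PumpRecord,
    TEConfig,
    ThetaInitWeights,
    active_insulin,
    initialize_theta,
    insulin_on_board,
    standard_regimen,
    simulate_open_loop,
    te_window_stability,
    transfer_entropy,
    generate_cohort,
    CohortSpec,
)
from conftest import MEAL_PROTOCOL, make_trace


class TestInsulinOnBoard:
    def test_full_at_injection(self):
        assert insulin_on_board([(100.0, 5.0)], 100.0) == pytest.approx(5.0)

    def test_zero_after_duration(self):
        cfg = TEConfig(iob_duration=4.0)
        assert insulin_on_board([(0.0, 5.0)], 240.0, cfg) == 0.0

    def test_linear_half_life(self):
        cfg = TEConfig(iob_curve="linear", iob_duration=4.0)
        assert insulin_on_board([(0.0, 5.0)], 120.0, cfg) == pytest.approx(2.5)

    def test_biexponential_monotone_and_bounded(self):
        cfg = TEConfig(iob_curve="biexponential", iob_duration=4.0)
        ts = np.linspace(0, 240, 100)
        vals = [insulin_on_board([(0.0, 1.0)], t, cfg) for t in ts]
        assert vals[0] == pytest.approx(1.0)
        assert vals[-1] == 0.0
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_superposition_of_boluses(self):
        cfg = TEConfig(iob_curve="linear")
        events = [(0.0, 4.0), (60.0, 2.0)]
        expected = 4.0 * (1 - 120 / 240) + 2.0 * (1 - 60 / 240)
        assert insulin_on_board(events, 120.0, cfg) == pytest.approx(expected)


class TestActiveInsulin:
    def test_constant_basal_gives_constant_ia(self):
        pump = PumpRecord(np.full(288, 1.0), (), 5.0)
        glu = make_trace(np.full(288, 100.0))
        ia = active_insulin(pump, glu)
        assert np.ptp(ia.values) < 1e-9
        # 1 U/h through a 4-h linear decay holds ~2 U on board
        assert ia.values[0] == pytest.approx(2.0, rel=0.03)

    def test_bolus_never_decreases_ia(self):
        glu = make_trace(np.full(288, 100.0))
        base = active_insulin(PumpRecord(np.full(288, 1.0), (), 5.0), glu)
        with_bolus = active_insulin(
            PumpRecord(np.full(288, 1.0), ((300.0, 5.0),), 5.0), glu
        )
        assert np.all(with_bolus.values >= base.values - 1e-12)

    def test_worked_series_instantaneous_mode(self):
        # 3 samples, linear curve: IOB of a 6 U bolus at t=0 plus rate*dt
        cfg = TEConfig(basal_mode="instantaneous", iob_curve="linear")
        pump = PumpRecord(np.array([1.2, 1.2, 1.2]), ((0.0, 6.0),), 5.0)
        glu = make_trace([100.0, 100.0, 100.0])
        ia = active_insulin(pump, glu, cfg)
        basal_term = 1.2 * 5 / 60
        expected = [
            6.0 + basal_term,
            6.0 * (1 - 5 / 240) + basal_term,
            6.0 * (1 - 10 / 240) + basal_term,
        ]
        np.testing.assert_allclose(ia.values, expected)

    def test_grid_mismatch_rejected(self):
        pump = PumpRecord(np.full(100, 1.0), (), 5.0)
        glu = make_trace(np.full(288, 100.0))
        with pytest.raises(ValueError):
            active_insulin(pump, glu)


class TestTransferEntropy:
    def test_constant_insulin_gives_exactly_zero(self):
        rng = np.random.default_rng(0)
        glu = make_trace(rng.uniform(60, 250, 1152))
        ia = ActiveInsulinTrace(np.full(1152, 2.3))
        assert transfer_entropy(glu, ia) == 0.0

    def test_degenerate_glucose_warns_and_returns_zero(self):
        glu = make_trace(np.full(600, 105.0))
        ia = ActiveInsulinTrace(np.arange(600) % 7 + 0.5)
        with pytest.warns(UserWarning, match="degenerate"):
            assert transfer_entropy(glu, ia) == 0.0

    def test_deterministic_coupling_is_one_bit(self):
        """G_t a binary function of IA_{t-d}: exact plug-in gives 1 bit."""
        rng = np.random.default_rng(1)
        n = 10_000
        ia = rng.integers(0, 2, n) * 1.0 + 0.5
        g = np.empty(n)
        g[:4] = 105.0
        g[4:] = np.where(ia[:-4] > 1, 115.0, 105.0)
        te = transfer_entropy(make_trace(g), ActiveInsulinTrace(ia))
        # brute-force oracle on the exact joint: H(G_t)=1, H(G_t|G_-1,IA)=0
        assert te == pytest.approx(1.0, abs=0.02)

    def test_independent_series_below_surrogate_band(self):
        rng = np.random.default_rng(2)
        n = 1152
        g = np.clip(100 + np.cumsum(rng.normal(0, 3, n)), 40, 300)
        ia = np.abs(np.cumsum(rng.normal(0, 0.3, n))) + 1
        te_obs = transfer_entropy(make_trace(g), ActiveInsulinTrace(ia))
        sur = [
            transfer_entropy(
                make_trace(g), ActiveInsulinTrace(rng.permutation(ia))
            )
            for _ in range(200)
        ]
        assert te_obs < np.percentile(sur, 95)

    def test_bin_shift_invariance(self):
        """Shifting glucose by a whole bin and insulin within a bin is neutral."""
        rng = np.random.default_rng(3)
        g = rng.uniform(61, 249, 1152)
        # keep each insulin value away from its bin edges so a small offset
        # cannot cross them (bins anchored at 0, width 1)
        ia = np.floor(rng.uniform(0, 8, 1152)) + 0.4
        te = transfer_entropy(make_trace(g), ActiveInsulinTrace(ia))
        te_shift_g = transfer_entropy(
            make_trace(g + 10.0), ActiveInsulinTrace(ia)
        )
        te_shift_i = transfer_entropy(
            make_trace(g), ActiveInsulinTrace(ia + 0.2)
        )
        assert te_shift_g == pytest.approx(te, abs=1e-12)
        assert te_shift_i == pytest.approx(te, abs=1e-12)

    def test_nonnegative_after_clipping(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            r = np.random.default_rng(seed)
            glu = make_trace(r.uniform(60, 250, 400))
            ia = ActiveInsulinTrace(r.uniform(0, 6, 400))
            assert transfer_entropy(glu, ia) >= 0.0


class TestInitializeTheta:
    @pytest.mark.parametrize(
        "te, expected",
        [(0.5, [0.2, -0.4]), (1.0, [0.1, -0.2])],
    )
    def test_inverse_proportionality(self, te, expected):
        np.testing.assert_allclose(initialize_theta(te).theta, expected)

    def test_halving_te_doubles_theta(self):
        a = initialize_theta(0.4).theta
        b = initialize_theta(0.2).theta
        np.testing.assert_allclose(b, 2 * a)

    def test_sign_structure(self):
        theta = initialize_theta(0.3).theta
        assert theta[0] > 0  # hyperglycaemia raises insulin
        assert theta[1] < 0  # hypoglycaemia lowers insulin

    def test_floor_falls_back_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            theta = initialize_theta(1e-5)
        np.testing.assert_allclose(theta.theta, 0.0)

    def test_custom_weights(self):
        w = ThetaInitWeights(w_h=0.3, w_l=-0.6)
        np.testing.assert_allclose(initialize_theta(0.5, w).theta, [0.6, -1.2])


class TestWindowStability:
    def _cohort_series(self, n, days, seed):
        cohort = generate_cohort(CohortSpec(n_subjects=n, rng_seed=seed))
        cfg = TEConfig()
        glus, ias = [], []
        for i, p in enumerate(cohort):
            rng = np.random.default_rng(seed * 100 + i)
            glu, pump, _ = simulate_open_loop(
                p, standard_regimen(p), MEAL_PROTOCOL, days, 0.5, rng
            )
            glus.append(glu)
            ias.append(active_insulin(pump, glu, cfg))
        return glus, ias, cfg

    def test_correlation_increases_with_window_length(self):
        glus, ias, cfg = self._cohort_series(8, 5, seed=21)
        df = te_window_stability(glus, ias, cfg, [1, 2, 4, 5])
        corr = dict(zip(zip(df.days_a, df.days_b), df.correlation))
        assert corr[(4, 5)] > corr[(1, 2)]
        assert corr[(4, 5)] > 0.9

    def test_too_small_cohort_rejected(self):
        glus, ias, cfg = self._cohort_series(2, 2, seed=5)
        with pytest.raises(ValueError):
            te_window_stability(glus, ias, cfg, [1, 2])

    def test_anticorrelated_vectors_give_minus_one(self):
        # direction sanity on the correlation computation itself
        a = np.array([0.1, 0.2, 0.3, 0.4])
        b = 1.0 - a
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(-1.0)
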