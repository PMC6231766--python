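"""Train quantal analysis: PPR, cumulative-EPSC and exponential estimators."""

import numpy as np
import pytest

import presyn as ps


def _det_train(n0, p, r, n_stim=30, ipi=10.0):
    pool = ps.ReleasePoolParams(N0_nA=n0, p=p, r_pA_per_ms=r)
    return ps.simulate_train_deterministic(pool, ps.StimProtocol(n_stim, ipi))


class TestPairedPulseRatio:
    def test_arithmetic(self):
        train = ps.EPSCTrain(ipi_ms=5.0, amplitudes_nA=[6.85, 4.93])
        assert ps.paired_pulse_ratio(train) == pytest.approx(0.72, abs=0.005)

    def test_identical_pulses(self):
        assert ps.paired_pulse_ratio(ps.EPSCTrain(10.0, [3.0, 3.0])) == 1.0

    def test_closed_form_for_depletion_model(self):
        # PPR = 1 - p + r*ipi/N0 for the depletion-replenishment recursion.
        train = _det_train(16.3, 0.44, 62.2)
        expected = 1.0 - 0.44 + 0.622 / 16.3
        assert ps.paired_pulse_ratio(train) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.598, abs=5e-4)

    def test_zero_first_pulse_is_an_error(self):
        with pytest.raises(ValueError):
            ps.paired_pulse_ratio(ps.EPSCTrain(10.0, [0.0, 1.0]))


class TestCumulativeEPSC:
    def test_running_sum(self):
        train = ps.EPSCTrain(10.0, [5.0, 2.5, 1.25])
        np.testing.assert_allclose(ps.cumulative_epsc(train), [5.0, 7.5, 8.75])

    def test_all_zero_train(self):
        train = ps.EPSCTrain(10.0, [0.0, 0.0, 0.0])
        assert np.all(ps.cumulative_epsc(train) == 0.0)

    def test_depletion_only_geometric_sum(self):
        n0, p, n = 12.0, 0.35, 25
        train = _det_train(n0, p, 0.0, n_stim=n)
        c_n = ps.cumulative_epsc(train)[-1]
        assert c_n == pytest.approx(n0 * (1.0 - (1.0 - p) ** n), rel=1e-12)


class TestCumulativeEstimator:
    def test_depletion_only_recovers_pool(self):
        est = ps.estimate_quantal_train(_det_train(10.0, 0.5, 0.0))
        assert est.rrp_nA == pytest.approx(10.0, abs=1e-3)
        assert est.slope_pA_per_ms == pytest.approx(0.0, abs=1e-3)
        assert est.pr1 == pytest.approx(0.5, abs=1e-3)
        assert est.ok

    def test_replenished_train_closed_form(self, control_pool, protocol_100hz):
        # Intercept -> N0 - r*ipi/p, slope -> r once steady state is reached.
        train = ps.simulate_train_deterministic(control_pool, protocol_100hz)
        est = ps.estimate_quantal_train(train)
        assert est.rrp_nA == pytest.approx(16.3 - 0.622 / 0.44, abs=5e-3)
        assert est.slope_pA_per_ms == pytest.approx(62.2, abs=5e-3)

    def test_oracle_equivalence_at_steady_state(self):
        """With the fit window placed after the depletion transient has died,
        the regression returns slope = r and intercept = N0 - r*ipi/p to
        numerical precision."""
        ipi, n0 = 10.0, 16.0
        for p in (0.2, 0.5, 0.8):
            for r in (0.0, 0.02 * n0 * p * 100.0):  # r*ipi <= 0.1*N0*p (r in pA/ms)
                train = _det_train(n0, p, r, n_stim=400, ipi=ipi)
                est = ps.estimate_quantal_train(train, window=(200, 230))
                assert abs(est.slope_pA_per_ms - r) < 1e-9
                assert abs(est.rrp_nA - (n0 - r * ipi / 1000.0 / p)) < 1e-6 * n0

    def test_methods_window_variant(self, control_pool, protocol_100hz):
        train = ps.simulate_train_deterministic(control_pool, protocol_100hz)
        est = ps.estimate_quantal_train(train, window=(15, 30))
        assert est.fit_window == (15, 30)
        assert est.rrp_nA == pytest.approx(16.3 - 0.622 / 0.44, abs=5e-2)

    def test_negative_intercept_is_flagged_not_silent(self):
        growing = ps.EPSCTrain(10.0, np.linspace(0.1, 40.0, 30) ** 2 / 100.0)
        est = ps.estimate_quantal_train(growing)
        assert "nonpositive_rrp" in est.flags and not est.ok

    def test_window_outside_train_rejected(self):
        with pytest.raises(ValueError):
            ps.estimate_quantal_train(_det_train(10.0, 0.5, 0.0, n_stim=20))


class TestExponentialEstimator:
    def test_exact_geometric_decay(self):
        est = ps.estimate_pr_exponential(_det_train(10.0, 0.3, 0.0))
        assert est.tau_stim == pytest.approx(-1.0 / np.log(0.7), abs=1e-3)
        assert est.pr == pytest.approx(0.3, abs=1e-6)
        assert est.fc == 1.0
        assert est.rrp_nA == pytest.approx(10.0, abs=1e-5)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_recovers_release_probability_exactly(self, p):
        est = ps.estimate_pr_exponential(_det_train(8.0, p, 0.0))
        assert abs(est.pr - p) < 1e-6

    def test_replenished_train_still_exact(self, control_pool, protocol_100hz):
        # With constant replenishment the decay stays geometric with rate 1-p.
        train = ps.simulate_train_deterministic(control_pool, protocol_100hz)
        est = ps.estimate_pr_exponential(train)
        assert est.pr == pytest.approx(0.44, abs=1e-6)
        assert est.rrp_nA == pytest.approx(16.3, abs=1e-4)

    def test_facilitation_correction(self):
        """A first pulse 20% below the fitted curve yields Fc = 1.25 and
        divides the uncorrected Pr accordingly."""
        base = _det_train(10.0, 0.3, 0.0)
        amps = base.amplitudes_nA.copy()
        amps[0] *= 0.8
        est = ps.estimate_pr_exponential(ps.EPSCTrain(base.ipi_ms, amps))
        assert est.fc == pytest.approx(1.25, abs=1e-6)
        assert est.pr == pytest.approx(0.3 / 1.25, abs=1e-6)

    def test_short_train_rejected(self):
        with pytest.raises(ValueError):
            ps.estimate_pr_exponential(ps.EPSCTrain(10.0, [1.0] * 5))


class TestNormalizationAndRatios:
    def test_normalize_geometric(self):
        train = ps.EPSCTrain(10.0, [4.0, 2.0, 1.0])
        np.testing.assert_allclose(ps.normalize_train(train), [1.0, 0.5, 0.25])

    def test_normalized_depletion_train_is_geometric(self):
        p = 0.4
        train = _det_train(9.0, p, 0.0, n_stim=15)
        expected = (1.0 - p) ** np.arange(15)
        np.testing.assert_allclose(ps.normalize_train(train), expected, rtol=1e-12)

    def test_constant_train_normalizes_to_ones(self):
        assert np.all(ps.normalize_train(ps.EPSCTrain(10.0, [2.0] * 4)) == 1.0)

    def test_treatment_ratio_elementwise(self):
        c = np.array([2.0, 1.0, 0.5])
        assert np.all(ps.treatment_ratio(c, c) == 1.0)
        np.testing.assert_allclose(ps.treatment_ratio(1.4 * c, c), 1.4)

    def test_treatment_ratio_steady_state(self):
        """Steady-state ratio of two deterministic trains equals the ratio of
        their replenishment rates."""
        t_treated = _det_train(16.3, 0.29, 96.9, n_stim=200)
        t_control = _det_train(16.3, 0.44, 62.2, n_stim=200)
        ratio = ps.treatment_ratio(t_treated.amplitudes_nA, t_control.amplitudes_nA)
        assert ratio[-1] == pytest.approx(96.9 / 62.2, abs=1e-6)
        assert 96.9 / 62.2 == pytest.approx(1.558, abs=5e-4)

    def test_treatment_ratio_length_mismatch(self):
        with pytest.raises(ValueError):
            ps.treatment_ratio([1.0, 2.0], [1.0])

    def test_fold_change_rounding(self):
        raw, rounded = ps.replenishment_fold_change(102.8, 62.2)
        assert rounded == 1.65 and raw == pytest.approx(102.8 / 62.2)
        assert ps.replenishment_fold_change(154.1, 96.9)[1] == 1.59
        assert ps.replenishment_fold_change(5.0, 5.0)[0] == 1.0
        with pytest.raises(ValueError):
            ps.replenishment_fold_change(1.0, 0.0)


class TestGroupSummary:
    def test_mean_sem(self):
        s = ps.group_summary([0.4, 0.5, 0.6])
        assert s["mean"] == pytest.approx(0.5)
        assert s["sem"] == pytest.approx(0.1 / np.sqrt(3))
        assert ps.group_summary([])["n"] == 0


class TestStochasticRecovery:
    def test_mean_estimates_near_oracle(self, control_pool, protocol_100hz):
        """Mean cumulative-method estimates over stochastic trains stay within
        10% of their deterministic-oracle values."""
        oracle = ps.estimate_quantal_train(
            ps.simulate_train_deterministic(control_pool, protocol_100hz)
        )
        ests = [
            ps.estimate_quantal_train(
                ps.simulate_train_stochastic(control_pool, protocol_100hz, seed=s)
            )
            for s in range(100)
        ]
        assert np.mean([e.rrp_nA for e in ests]) == pytest.approx(oracle.rrp_nA, rel=0.1)
        assert np.mean([e.pr1 for e in ests]) == pytest.approx(oracle.pr1, rel=0.1)
        assert np.mean([e.slope_pA_per_ms for e in ests]) == pytest.approx(
            oracle.slope_pA_per_ms, rel=0.1
        )

    def test_rrp_frequency_invariance(self, control_pool):
        """The deterministic RRP estimates at 100 and 200 Hz differ exactly by
        the predicted r*ipi/p offset term."""
        est100 = ps.estimate_quantal_train(
            ps.simulate_train_deterministic(control_pool, ps.StimProtocol(400, 10.0)),
            window=(200, 230),
        )
        est200 = ps.estimate_quantal_train(
            ps.simulate_train_deterministic(control_pool, ps.StimProtocol(400, 5.0)),
            window=(200, 230),
        )
        predicted_offset = 62.2 * (10.0 - 5.0) / 1000.0 / 0.44
        assert est200.rrp_nA - est100.rrp_nA == pytest.approx(predicted_offset, abs=1e-6)
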