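"""Chemometrics: background subtraction, PCR fitting/prediction, the
Jackson-Mudholkar residual threshold, quality-control vetoes, and
sensitivity transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from duoprobe import fscv, synth


class TestBackgroundSubtract:
    def test_reference_frame_becomes_zero(self, fscv_session, trials16):
        cp, _ = fscv_session
        t_ref = float(trials16["t_value_cue"].iloc[0])
        sub = fscv.background_subtract(cp, t_ref)
        assert np.all(sub.currents[sub.background_ref_index] == 0.0)

    def test_constant_colorplot_zeroes_everywhere(self, waveform):
        frames = np.tile(np.sin(np.arange(850)), (20, 1))
        cp = fscv.ColorPlot(frames, np.arange(20) / 10.0, waveform)
        sub = fscv.background_subtract(cp, 1.0)
        assert np.allclose(sub.currents, 0.0)

    def test_reference_maps_to_frame_at_or_before(self, waveform):
        cp = fscv.ColorPlot(np.zeros((20, 850)), np.arange(20) / 10.0, waveform)
        assert fscv.background_subtract(cp, 0.55).background_ref_index == 5
        assert fscv.background_subtract(cp, 0.5).background_ref_index == 5

    def test_out_of_range_reference_rejected(self, waveform):
        cp = fscv.ColorPlot(np.zeros((20, 850)), np.arange(20) / 10.0, waveform)
        with pytest.raises(ValueError, match="outside"):
            fscv.background_subtract(cp, 100.0)

    def test_subtracted_transient_matches_template_arithmetic(self, templates,
                                                              trials16):
        cp, truth = synth.simulate_fscv_session(
            trials16, templates, noise_nA=0.0, drift_linear_nA_s=0.0,
            drift_step_nA=0.0, movement_prob=0.0, ph_per_reward=0.0, seed=11)
        t_cue = float(trials16["t_value_cue"].iloc[0])
        sub = fscv.background_subtract(cp, t_cue)
        ref = sub.background_ref_index
        peak = ref + int(np.argmax(truth.da_nM[ref:ref + 30]))
        expected = (truth.da_nM[peak] - truth.da_nM[ref]) * templates.response("da")
        assert np.allclose(sub.currents[peak], expected, atol=1e-9)


class TestQAlpha:
    def test_empty_residual_space_gives_zero(self):
        assert fscv.q_alpha([], 0.05) == 0.0

    def test_matches_chi_square_oracle_for_equal_eigenvalues(self):
        # Q = z1^2+z2^2+z3^2 ~ chi2(3); independent closed-form oracle
        oracle = stats.chi2.ppf(0.95, df=3)
        approx = fscv.q_alpha([1.0, 1.0, 1.0], 0.05)
        assert approx == pytest.approx(7.78, abs=0.02)
        assert approx == pytest.approx(oracle, rel=0.02)

    def test_monte_carlo_quantile_for_unequal_eigenvalues(self):
        lam = np.array([4.0, 2.0, 1.0, 0.5])
        rng = np.random.default_rng(0)
        q = (lam * rng.standard_normal((200_000, 4)) ** 2).sum(axis=1)
        oracle = np.quantile(q, 0.95)
        assert fscv.q_alpha(lam, 0.05) == pytest.approx(oracle, rel=0.03)

    def test_all_zero_eigenvalues_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert fscv.q_alpha([0.0, 0.0], 0.05) == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(a1=st.floats(0.01, 0.2), a2=st.floats(0.21, 0.5))
    def test_threshold_decreases_with_alpha(self, a1, a2):
        lam = [3.0, 1.0, 0.4]
        assert fscv.q_alpha(lam, a1) > fscv.q_alpha(lam, a2)


class TestPCR:
    def _noiseless_bank(self, templates, n=12, seed=0):
        rng = np.random.default_rng(seed)
        conc = np.column_stack([rng.uniform(0, 100, n), rng.uniform(-0.1, 0.1, n)])
        X = (conc[:, :1] * templates.response("da")
             + conc[:, 1:] * templates.response("ph"))
        return X, conc

    def test_noiseless_training_recovered_exactly(self, templates, waveform):
        X, conc = self._noiseless_bank(templates)
        model = fscv.fit_pcr(X, conc, k_rule="fixed", k=2)
        cp = fscv.ColorPlot(X, np.arange(len(X)) / 10.0, waveform)
        pred = fscv.predict_concentrations(model, cp)
        assert np.allclose(pred.concentrations.to_numpy(), conc, atol=1e-8)
        assert np.all(pred.q < 1e-12)

    def test_training_standard_q_below_threshold(self, pcr_model, waveform):
        X = pcr_model.training_matrix
        cp = fscv.ColorPlot(X, np.arange(len(X)) / 10.0, waveform)
        pred = fscv.predict_concentrations(pcr_model, cp)
        assert np.mean(pred.q < pcr_model.qalpha) > 0.9

    def test_prediction_is_linear(self, templates, waveform):
        X, conc = self._noiseless_bank(templates)
        model = fscv.fit_pcr(X, conc, k_rule="fixed", k=2)

        def pred(frames):
            cp = fscv.ColorPlot(np.atleast_2d(frames),
                                np.arange(len(np.atleast_2d(frames))) / 10.0,
                                waveform)
            return fscv.predict_concentrations(model, cp).concentrations.to_numpy()

        a, b = 2.5, -0.7
        lhs = pred(a * X[0] + b * X[1])
        rhs = a * pred(X[0]) + b * pred(X[1])
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_full_rank_reconstruction_has_zero_q(self, templates, waveform):
        X, conc = self._noiseless_bank(templates, n=6)
        model = fscv.fit_pcr(X, conc, k_rule="fixed", k=5)
        cp = fscv.ColorPlot(X, np.arange(len(X)) / 10.0, waveform)
        assert np.all(fscv.predict_concentrations(model, cp).q < 1e-10)

    def test_rank_deficient_training_rejected(self, templates):
        X = np.tile(templates.response("da"), (6, 1))
        conc = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(ValueError, match="rank"):
            fscv.fit_pcr(X, conc)

    def test_dimension_mismatch_rejected(self, pcr_model, waveform):
        small = synth.generate_waveform(adc_rate=50_000.0)
        cp = fscv.ColorPlot(np.zeros((3, small.n_samples)),
                            np.arange(3) / 10.0, small)
        with pytest.raises(ValueError, match="dimension"):
            fscv.predict_concentrations(pcr_model, cp)

    def test_sklearn_pca_agrees_on_subspace_and_spectrum(self, templates):
        """Independent cross-check of the decomposition against scikit-learn
        (used only as an oracle, never in the analysis path)."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        conc = np.column_stack([rng.uniform(0, 100, 15),
                                rng.uniform(-0.1, 0.1, 15)])
        X = (conc[:, :1] * templates.response("da")
             + conc[:, 1:] * templates.response("ph")
             + 0.5 * rng.standard_normal((15, 850)))
        model = fscv.fit_pcr(X, conc, center=True, k_rule="fixed", k=2)
        ref = PCA(n_components=2, svd_solver="full").fit(X)
        assert np.allclose(model.eigenvalues[:2], ref.explained_variance_,
                           rtol=1e-8)
        # loadings are sign-ambiguous: compare projection matrices
        P_mine = model.components.T @ model.components
        P_ref = ref.components_.T @ ref.components_
        assert np.allclose(P_mine, P_ref, atol=1e-8)


class TestQC:
    def test_movement_standard_frame_is_vetoed(self, pcr_model, waveform,
                                               templates):
        frames = np.vstack([pcr_model.movement_standards[0],
                            50.0 * templates.response("da")])
        cp = fscv.ColorPlot(frames, np.arange(2) / 10.0, waveform)
        trace = fscv.apply_qc(fscv.predict_concentrations(pcr_model, cp),
                              pcr_model, cp)
        assert not trace.valid[0] and trace.reason[0] == "movement"
        assert trace.valid[1]
        assert np.isnan(trace.series("da_nM")[0])

    def test_q_failure_nulled_with_reason(self, pcr_model, waveform):
        rng = np.random.default_rng(0)
        bad = 100.0 * rng.standard_normal(850)   # far outside the model span
        cp = fscv.ColorPlot(bad[None, :], np.zeros(1), waveform)
        trace = fscv.apply_qc(fscv.predict_concentrations(pcr_model, cp),
                              pcr_model, cp)
        assert not trace.valid[0] and trace.reason[0] == "q_fail"

    def test_invalid_threshold_rejected(self, pcr_model, waveform):
        cp = fscv.ColorPlot(np.zeros((1, 850)), np.zeros(1), waveform)
        trace = fscv.predict_concentrations(pcr_model, cp)
        with pytest.raises(ValueError):
            fscv.apply_qc(trace, pcr_model, cp, r_threshold=1.5)


class TestSensitivity:
    def _trace(self, waveform):
        import pandas as pd
        n = 5
        return fscv.ChemTrace(
            frame_times=np.arange(n) / 10.0,
            concentrations=pd.DataFrame({"da_nM": np.full(n, 80.0),
                                         "ph": np.zeros(n)}),
            q=np.zeros(n), qalpha=1.0, valid=np.ones(n, bool),
            reason=np.array([""] * n, object))

    def test_equal_sensitivities_are_identity(self, waveform):
        t = fscv.sensitivity_normalize(
            self._trace(waveform), oxidation_current_nA=4.0,
            background_current_nA=400.0, calibration_oxidation_nA=4.0,
            calibration_background_nA=400.0)
        assert t.sensitivity_factor == pytest.approx(1.0)
        assert np.allclose(t.series("da_nM"), 80.0)

    def test_halved_background_doubles_factor(self, waveform):
        t = fscv.sensitivity_normalize(
            self._trace(waveform), oxidation_current_nA=4.0,
            background_current_nA=200.0, calibration_oxidation_nA=4.0,
            calibration_background_nA=400.0)
        assert t.sensitivity_factor == pytest.approx(2.0)

    def test_low_sensitivity_electrode_recovers_truth(self, templates,
                                                      trials16, pcr_model):
        """An electrode at 0.8x the calibration-bank dopamine sensitivity
        underestimates concentration by 0.8; the transfer factor undoes it."""
        cp, truth = synth.simulate_fscv_session(
            trials16, templates, noise_nA=0.0, drift_linear_nA_s=0.0,
            drift_step_nA=0.0, movement_prob=0.0, ph_per_reward=0.0,
            sensitivity_scale=0.8, seed=21)
        cues = trials16["t_value_cue"].to_numpy()
        rel, mat = fscv.trial_chem_matrix(cp, pcr_model, cues, (0.0, 3.0))
        # apply the in-vivo/calibration sensitivity ratio of 0.8
        corrected = mat / 0.8
        from tests.conftest import epoch_matrix
        _, tmat = epoch_matrix(truth.frame_times, truth.da_nM, cues,
                               (0.0, 3.0), reference_event=True)
        scale = np.nansum(corrected * tmat) / np.nansum(tmat * tmat)
        assert scale == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_background_rejected(self, waveform):
        with pytest.raises(ValueError, match="positive"):
            fscv.sensitivity_normalize(
                self._trace(waveform), oxidation_current_nA=4.0,
                background_current_nA=0.0, calibration_oxidation_nA=4.0,
                calibration_background_nA=400.0)
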