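"""Virtual plant: truth generation, spectra synthesis, disturbances."""

import numpy as np
import pytest

from fermstate.chemometrics import CalibrationSet, fit_pls
from fermstate.design import DesignSpace, select_design
from fermstate.estimator import NoiseSpec, run_monitor
from fermstate.kinetics import IDX, StateVector
from fermstate.plant import (AbsorptivityLibrary, DisturbanceWindow,
                             ScenarioSpec, calibration_spectra, emit_batch,
                             generate_truth, inject_disturbance,
                             synthesize_spectrum)
from fermstate.workflow import (build_calibration, estimate_measurement_noise,
                                pls_predictions, validation_params)


class TestGenerateTruth:
    def test_sterile_batch_is_flat(self, params):
        scen = ScenarioSpec.default(
            x0=StateVector(glu=37, xyl=22, fur=0.5, fa=0, hmf=0.15, hac=2.5,
                           etoh=0, x=0.0), batch_hours=5.0)
        truth, gly = generate_truth(scen)
        assert np.allclose(truth.y, truth.y[0], atol=1e-12)
        assert np.all(gly == 0.0)

    def test_glycerol_plateau_default(self, params):
        scen = ScenarioSpec.default(batch_hours=20.0)
        assert scen.glycerol_plateau == 3.0
        truth, gly = generate_truth(scen)
        assert gly.max() == pytest.approx(3.0, abs=0.05)

    def test_glucose_phase_end_close_to_glycerol_plateau(self, params):
        scen = ScenarioSpec.default(batch_hours=20.0)
        truth, gly = generate_truth(scen)
        threshold = scen.params.ki_glu_xyl / 4.0
        t_phase = truth.t[np.argmax(truth.state("glu") < threshold)]
        t_plateau = truth.t[np.argmax(gly >= 0.99 * scen.glycerol_plateau)]
        assert abs(t_plateau - t_phase) < 1.0


class TestSynthesizeSpectrum:
    def test_zero_concentrations_zero_spectrum(self, library):
        s = synthesize_spectrum({"glu": 0.0, "xyl": 0.0, "etoh": 0.0}, library)
        assert np.all(s.absorbance == 0.0)

    def test_beer_lambert_linearity(self, library):
        base = {"glu": 10.0, "xyl": 5.0, "etoh": 8.0, "glycerol": 1.5}
        s1 = synthesize_spectrum(base, library)
        s2 = synthesize_spectrum({k: 2 * v for k, v in base.items()}, library)
        np.testing.assert_allclose(s2.absorbance, 2 * s1.absorbance, rtol=1e-12)

    def test_negative_concentration_rejected(self, library):
        with pytest.raises(ValueError):
            synthesize_spectrum({"glu": -1.0}, library)

    def test_analyte_profiles_identifiable(self, library):
        assert library.analyte_condition_number() < 1e6


class TestCalibrationChain:
    def test_noise_free_design_recovered_exactly(self, library, design21):
        spectra = calibration_spectra(design21.samples, library, noise_sd=0.0)
        cal = CalibrationSet(
            spectra=spectra,
            references={"glu": design21.samples[:, 0],
                        "xyl": design21.samples[:, 1],
                        "etoh": design21.samples[:, 2]})
        errs = []
        for analyte, col in (("glu", 0), ("xyl", 1), ("etoh", 2)):
            model = fit_pls(cal, analyte, n_lv=3)
            preds = [model.predict(s) for s in spectra]
            errs.append(preds - design21.samples[:, col])
        assert np.sqrt(np.mean(np.square(errs))) < 0.1

    def test_clean_chain_recovers_below_five_centigram(self, library):
        """Design -> noise-free spectra without interferents -> PLS ->
        prediction closes to < 0.05 g/L RMSE."""
        design = select_design(DesignSpace.default(), 21, 200, seed=9)
        spectra = calibration_spectra(design.samples, library, noise_sd=0.0,
                                      matrix_glycerol=0.0, matrix_biomass=0.0)
        cal = CalibrationSet(
            spectra=spectra,
            references={"glu": design.samples[:, 0],
                        "xyl": design.samples[:, 1],
                        "etoh": design.samples[:, 2]})
        errs = []
        for analyte, col in (("glu", 0), ("xyl", 1), ("etoh", 2)):
            model = fit_pls(cal, analyte, n_lv=3)
            errs.append([model.predict(s) for s in spectra] - design.samples[:, col])
        assert np.sqrt(np.mean(np.square(errs))) < 0.05


@pytest.fixture(scope="module")
def small_batch(library):
    scen = ScenarioSpec.default(batch_hours=2.0, seed=5)
    return emit_batch(scen, library), scen


class TestEmitBatch:

    def test_counts(self, small_batch):
        batch, scen = small_batch
        assert len(batch.spectra) == 120
        assert len(batch.offline) == 3

    def test_timestamps_minute_spaced(self, small_batch):
        batch, _ = small_batch
        stamps = np.array([s.timestamp_min for s in batch.spectra])
        assert np.all(np.diff(stamps) == 1.0)

    def test_offline_noise_zero_matches_truth(self, library):
        scen = ScenarioSpec.default(batch_hours=2.0, offline_noise_sd=0.0)
        batch = emit_batch(scen, library)
        truth_at = batch.truth.at(batch.offline["time_h"].to_numpy())
        np.testing.assert_allclose(batch.offline["glu"],
                                   truth_at[:, IDX["glu"]], atol=1e-9)

    def test_full_length_batch_spectra_count(self, library):
        scen = ScenarioSpec.default(batch_hours=30.0, seed=1)
        batch = emit_batch(scen, library)
        assert len(batch.spectra) == 1800
        assert len(batch.offline) == 31


class TestInjectDisturbance:
    def test_empty_window_is_identity(self, library):
        scen = ScenarioSpec.default(batch_hours=1.0, seed=2)
        batch = emit_batch(scen, library)
        out = inject_disturbance(batch.spectra,
                                 DisturbanceWindow(5.0, 0.5, "clog"))
        assert all(np.array_equal(a.absorbance, b.absorbance)
                   for a, b in zip(out, batch.spectra))

    def test_unknown_mode_rejected(self, library):
        scen = ScenarioSpec.default(batch_hours=1.0, seed=2)
        batch = emit_batch(scen, library)
        with pytest.raises(ValueError):
            inject_disturbance(batch.spectra, DisturbanceWindow(0.2, 0.5, "flood"))

    def test_clog_depresses_pls_glucose_but_not_hybrid(self, params, pls_models,
                                                        library):
        """During a clog window the raw PLS glucose prediction collapses by
        several g/L while the hybrid posterior stays close to the truth
        (correctly identified model: the residual deviation isolates the
        measurement corruption)."""
        tuning = emit_batch(ScenarioSpec.default(params=params, seed=21,
                                                 batch_hours=16.0), library)
        r1, r2 = estimate_measurement_noise(pls_models, tuning,
                                            params.ki_glu_xyl / 4.0)
        window = DisturbanceWindow(2.0, 0.5, "clog", severity=0.45)
        scen = ScenarioSpec.default(params=params, seed=22, batch_hours=8.0,
                                    disturbances=(window,))
        batch = emit_batch(scen, library)
        mins = np.array([s.timestamp_min for s in batch.spectra]) / 60.0
        in_window = (mins >= 2.0) & (mins < 2.5)
        preds = pls_predictions(pls_models, batch.spectra)
        truth_glu = batch.truth.at(mins)[:, IDX["glu"]]
        assert np.min(preds[in_window, 0] - truth_glu[in_window]) < -3.0

        noise = NoiseSpec.isotropic(1e-5, r1, r2)
        result = run_monitor(scen.x0, params, pls_models, batch.spectra, noise)
        t_upd = result.times()
        est_glu = result.posterior_means()[:, IDX["glu"]]
        upd_window = (t_upd >= 2.0) & (t_upd <= 2.5)
        truth_upd = batch.truth.at(t_upd)[:, IDX["glu"]]
        assert np.max(np.abs(est_glu[upd_window] - truth_upd[upd_window])) < 1.5

    def test_clog_changes_hybrid_rmse_little_but_pls_much(self, params,
                                                          pls_models):
        """A 30-minute clog changes the hybrid posterior trajectory RMSE by
        < 25% relative to the undisturbed run, while the PLS-only RMSE in
        the disturbed window degrades by > 100%."""
        from fermstate.workflow import run_hybrid_comparison

        disturbed = run_hybrid_comparison(seed=0, models=pls_models)
        clean = run_hybrid_comparison(seed=0, models=pls_models,
                                      clog_duration_h=0.0)
        for analyte in ("glu", "xyl", "etoh"):
            change = abs(disturbed.hybrid_rmse[analyte]
                         - clean.hybrid_rmse[analyte]) / clean.hybrid_rmse[analyte]
            assert change < 0.25, (analyte, change)

        def window_pls_rmse(cmp_):
            mins = np.array([s.timestamp_min
                             for s in cmp_.batch.spectra]) / 60.0
            mask = (mins >= 2.0) & (mins < 2.5)
            preds = pls_predictions(pls_models, cmp_.batch.spectra)
            truth = cmp_.batch.truth.at(mins)[:, IDX["glu"]]
            return np.sqrt(np.mean((preds[mask, 0] - truth[mask]) ** 2))

        assert window_pls_rmse(disturbed) > 2.0 * window_pls_rmse(clean)


class TestMatrixInterference:
    def test_xylose_prediction_rises_through_glucose_phase(self, pls_models,
                                                           params, library):
        """The end-of-fermentation calibration matrix leaves early-batch
        glycerol/biomass changes unmodelled: the predicted xylose drifts
        upward through the glucose phase while true xylose does not rise."""
        scen = ScenarioSpec.default(params=validation_params(params), seed=33,
                                    batch_hours=12.0, spectra_noise_sd=0.0)
        batch = emit_batch(scen, library)
        mins = np.array([s.timestamp_min for s in batch.spectra]) / 60.0
        truth = batch.truth.at(mins)
        phase1 = truth[:, IDX["glu"]] >= params.ki_glu_xyl / 4.0
        preds = pls_predictions(pls_models, batch.spectra)
        xyl_pred = preds[phase1, 1]
        xyl_true = truth[phase1, IDX["xyl"]]
        early = slice(0, 60)
        late = slice(-60, None)
        assert np.mean(xyl_pred[late]) - np.mean(xyl_pred[early]) > 1.0
        assert np.mean(xyl_true[late]) <= np.mean(xyl_true[early]) + 1e-6
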