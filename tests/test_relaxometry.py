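"""Spectral fitting: initial fit, composition, joint TE/TI fits, CRLB, rules."""

import math

import numpy as np
import pytest

from marrowmrs.preprocess import preprocess_series
from marrowmrs.relaxometry import (
    FitResult,
    apply_reporting_rules,
    compute_crlb,
    derive_parameters,
    estimate_composition,
    estimate_spectral_noise,
    fit_initial,
    fit_multi_te,
    fit_multi_ti,
)
from marrowmrs.spectral import (
    AcquisitionContext,
    FattyAcidComposition,
    RelaxationState,
    Resonance,
    ResonanceModel,
    compute_pdff,
    default_marrow_model,
)
from marrowmrs.synthetic import (
    add_complex_noise,
    fid_to_spectrum,
    generate_study,
    sigma_for_snr,
    synthesize_fid,
    tissue_preset,
)


def noiseless_spectra(preset, kind):
    te, ti = generate_study(preset, snr=None, seed=0)
    series = te if kind == "TE" else ti
    fids, _, _ = preprocess_series(series)
    return series, fid_to_spectrum(fids, series.acq.dwell)


@pytest.fixture(scope="module")
def healthy_te():
    return noiseless_spectra("healthy_L5", "TE")


@pytest.fixture(scope="module")
def healthy_ti():
    return noiseless_spectra("healthy_L5", "TI")


@pytest.fixture(scope="module")
def healthy_initial(healthy_te, model):
    series, spectra = healthy_te
    acq = AcquisitionContext(tr=3500.0)
    return fit_initial(spectra[0], model, acq)


class TestFitInitial:
    def test_noiseless_amplitudes_recovered(self, healthy_initial, healthy_state):
        # fitted amplitudes are TE=20-weighted
        for name, t2g in (("water", "water"), ("methylene", "methylene")):
            truth = healthy_state.a0[name] * math.exp(-20.0 / healthy_state.t2[t2g])
            assert healthy_initial.amplitudes[name] == pytest.approx(truth, rel=5e-3)

    def test_water_only_spectrum_fat_below_censor_level(self, model, acq):
        state = RelaxationState(
            t1={g: 800.0 for g in model.groups("t1")},
            t2={g: 40.0 for g in model.groups("t2")},
            lw={g: 45.0 for g in model.groups("lw")},
            a0={r.name: (100.0 if r.name == "water" else 0.0) for r in model.resonances},
        )
        spec = fid_to_spectrum(synthesize_fid(state, model, acq), acq.dwell)
        fit = fit_initial(spec, model, acq)
        for name, a in fit.amplitudes.items():
            if name != "water":
                assert a < 0.01 * fit.amplitudes["water"]

    def test_misset_frequency_converges(self, model, acq, healthy_state):
        sigma = sigma_for_snr(healthy_state, model, acq, 50.0)
        fid = add_complex_noise(synthesize_fid(healthy_state, model, acq), sigma, seed=4)
        spec = fid_to_spectrum(fid, acq.dwell)
        fit = fit_initial(spec, model, acq, init={"f_water": 10.0, "f_methyl": 10.0})
        assert abs(fit.params["f_water"]) < 0.5
        assert abs(fit.params["f_methyl"]) < 0.5


class TestEstimateComposition:
    def test_single_noiseless_subject_exact(self, healthy_initial):
        comp = estimate_composition([healthy_initial])
        assert comp.ndb == pytest.approx(2.7, abs=1e-3)
        assert comp.nmidb == pytest.approx(0.7, abs=1e-3)

    def test_cohort_recovery_at_snr50(self, model):
        acq = AcquisitionContext(tr=3500.0)
        state = tissue_preset("healthy_L5")
        sigma = sigma_for_snr(state, model, acq, 50.0)
        clean = synthesize_fid(state, model, acq)
        fits = []
        for seed in range(5):
            spec = fid_to_spectrum(add_complex_noise(clean, sigma, seed=seed), acq.dwell)
            fits.append(fit_initial(spec, model, acq))
        comp = estimate_composition(fits)
        assert comp.ndb == pytest.approx(2.7, rel=0.05)
        assert comp.nmidb == pytest.approx(0.7, rel=0.05)

    def test_saturated_fat_forces_nmidb_zero(self, model, acq):
        comp0 = FattyAcidComposition(17.5, 0.0, 0.0)
        state = tissue_preset("healthy_L5", comp0)
        spec = fid_to_spectrum(synthesize_fid(state, model, acq), acq.dwell)
        fit = fit_initial(spec, model, acq)
        comp = estimate_composition([fit])
        assert comp.nmidb == pytest.approx(0.0, abs=1e-3)

    def test_fallback_when_unresolvable(self):
        with pytest.warns(UserWarning, match="fallback"):
            comp = estimate_composition(
                [FitResult("single", {}, {}, None, 0.0, True, 0)],
                fallback=FattyAcidComposition(17.5, 3.0, 1.0),
            )
        assert comp.ndb == 3.0


class TestFitMultiTe:
    def test_noiseless_t2_recovery(self, healthy_te, healthy_initial, model):
        series, spectra = healthy_te
        acq = AcquisitionContext(tr=3500.0)
        comp = estimate_composition([healthy_initial])
        fit = fit_multi_te(
            spectra, series.contrasts, model, acq, composition=comp, init=healthy_initial
        )
        assert fit.params["t2_water"] == pytest.approx(27.0, rel=0.01)
        assert fit.params["t2_methylene"] == pytest.approx(68.0, rel=0.01)
        assert fit.params["t2_composite"] == pytest.approx(41.0, rel=0.01)
        assert compute_pdff(fit.amplitudes, "water") == pytest.approx(0.30, abs=0.005)

    def test_te_subset_matches_full_fit(self, healthy_te, healthy_initial, model):
        series, spectra = healthy_te
        acq = AcquisitionContext(tr=3500.0)
        comp = estimate_composition([healthy_initial])
        full = fit_multi_te(spectra, series.contrasts, model, acq, comp, "all", healthy_initial)
        sub = fit_multi_te(spectra, series.contrasts, model, acq, comp, "20-50", healthy_initial)
        pdff_full = compute_pdff(full.amplitudes, "water")
        pdff_sub = compute_pdff(sub.amplitudes, "water")
        assert abs(pdff_full - pdff_sub) * 100.0 < 0.1  # percentage points

    def test_scale_equivariance(self, healthy_te, healthy_initial, model):
        series, spectra = healthy_te
        acq = AcquisitionContext(tr=3500.0)
        comp = estimate_composition([healthy_initial])
        a = fit_multi_te(spectra, series.contrasts, model, acq, comp, "all", healthy_initial)
        b = fit_multi_te(10.0 * spectra, series.contrasts, model, acq, comp, "all", healthy_initial)
        assert b.params["amp_water"] / a.params["amp_water"] == pytest.approx(10.0, rel=1e-3)
        assert b.params["t2_water"] == pytest.approx(a.params["t2_water"], rel=1e-3)

    def test_small_subset_rejected(self, healthy_te, model):
        series, spectra = healthy_te
        with pytest.raises(ValueError):
            fit_multi_te(spectra[:2], series.contrasts[:2], model, te_subset="all")


@pytest.fixture(scope="module")
def ti_fit(healthy_ti, model):
    series, spectra = healthy_ti
    init = fit_initial(spectra[-1], model, AcquisitionContext(te=20.0, tr=5000.0))
    comp = estimate_composition([init])
    fit = fit_multi_ti(spectra, series.contrasts, model, series.acq, comp, init)
    return series, fit


class TestFitMultiTi:
    def test_noiseless_t1_and_beta_recovery(self, ti_fit, healthy_state):
        _, fit = ti_fit
        assert fit.params["t1_water"] == pytest.approx(1368.0, rel=0.01)
        assert fit.params["t1_methylene"] == pytest.approx(369.0, rel=0.01)
        assert fit.params["beta"] == pytest.approx(0.93, abs=0.02)

    def test_polarities_match_analytic_sign(self, ti_fit, healthy_state, model):
        series, fit = ti_fit
        for ti_ms, sign in zip(series.contrasts, fit.sign_schedule.signs):
            a = AcquisitionContext(te=20.0, ti=float(ti_ms), tr=5000.0)
            spec = fid_to_spectrum(synthesize_fid(healthy_state, model, a), a.dwell)
            k = np.argmax(np.abs(spec.real))
            assert sign == np.sign(spec.real[k])

    def test_accepted_candidate_has_lower_cost(self, ti_fit):
        _, fit = ti_fit
        for sign, costs in zip(fit.sign_schedule.signs[1:-1], fit.sign_schedule.candidate_costs[1:-1]):
            cost_up, cost_down = costs
            accepted = cost_up if sign > 0 else cost_down
            rejected = cost_down if sign > 0 else cost_up
            assert accepted <= rejected

    def test_too_few_inversion_times_rejected(self, healthy_ti, model):
        series, spectra = healthy_ti
        with pytest.raises(ValueError):
            fit_multi_ti(spectra[:3], series.contrasts[:3], model)


@pytest.fixture(scope="module")
def lorentzian_fit():
    res = (Resonance("water", 4.7, 1.0, "water", "water", "water", "free"),)
    model = ResonanceModel(res, water_index=0)
    acq = AcquisitionContext()
    state = RelaxationState(
        t1={"water": 1000.0}, t2={"water": 50.0}, lw={"water": 20.0},
        a0={"water": 100.0},
    )
    fid = add_complex_noise(
        synthesize_fid(state, model, acq),
        sigma_for_snr(state, model, acq, 50.0),
        seed=0,
    )
    spec = fid_to_spectrum(fid, acq.dwell)
    fit = fit_initial(spec, model, acq)
    sigma_f = estimate_spectral_noise(spec, fit._problem)
    return fit, sigma_f


class TestCrlbAndRules:
    def test_crlb_linear_in_sigma(self, lorentzian_fit):
        fit, sigma_f = lorentzian_fit
        c1 = dict(compute_crlb(fit, sigma_f))
        c2 = compute_crlb(fit, 2.0 * sigma_f)
        for k in c1:
            if np.isfinite(c1[k]):
                assert c2[k] == pytest.approx(2.0 * c1[k], rel=1e-6)

    def test_unidentifiable_parameter_gets_infinite_bound(self, model, acq):
        # saturated-fat composition zeroes the olefinic peak: its T1 group
        # carries no information
        comp0 = FattyAcidComposition(17.5, 0.0, 0.0)
        state = tissue_preset("healthy_L5", comp0)
        te, ti = generate_study("healthy_L5", snr=None, seed=0, composition=comp0)
        fids, _, _ = preprocess_series(ti)
        spectra = fid_to_spectrum(fids, ti.acq.dwell)
        init = fit_initial(spectra[-1], model, AcquisitionContext(te=20.0, tr=5000.0),
                           composition=comp0, fit_composition=False)
        fit = fit_multi_ti(spectra, ti.contrasts, model, ti.acq, comp0, init)
        crlb = compute_crlb(fit, 1e-4)
        assert not np.isfinite(crlb["t1_olefin"])
        apply_reporting_rules(fit)
        assert fit.censored["t1_olefin"] == "unidentifiable"

    def test_censoring_thresholds(self):
        fit = FitResult(
            mode="te",
            params={"t2_water": 27.0, "t2_methylene": 68.0, "t2_composite": 41.0},
            amplitudes={"water": 100.0, "methylene": 50.0},
            composition=None,
            cost=0.0, success=True, nfev=1,
            crlb_rel={"t2_water": 0.26, "t2_methylene": 0.24, "t2_composite": 0.10},
        )
        apply_reporting_rules(fit)
        assert "t2_water" in fit.censored and fit.censored["t2_water"].startswith("crlb")
        assert "t2_methylene" not in fit.censored
        assert np.isnan(fit.reported("t2_water"))
        assert fit.reported("t2_methylene") == 68.0

    def test_low_amplitude_censoring(self, healthy_te, healthy_initial, model):
        series, spectra = healthy_te
        acq = AcquisitionContext(tr=3500.0)
        comp = estimate_composition([healthy_initial])
        fit = fit_multi_te(spectra, series.contrasts, model, acq, comp, "all", healthy_initial)
        # fake a tiny composite-group amplitude: both member peaks below 1%
        ref = max(fit.amplitudes["water"], fit.amplitudes["methylene"])
        fit.amplitudes["alpha_olefinic"] = 0.005 * ref
        fit.amplitudes["alpha_carboxyl"] = 0.005 * ref
        fit.crlb_rel = {k: 0.01 for k in fit.params}
        apply_reporting_rules(fit)
        assert fit.censored["t2_composite"].startswith("amp")


class TestDeriveParameters:
    def test_healthy_end_to_end_table(self, healthy_te, healthy_ti, healthy_initial, model):
        series_te, spectra_te = healthy_te
        series_ti, spectra_ti = healthy_ti
        acq = AcquisitionContext(tr=3500.0)
        comp = estimate_composition([healthy_initial])
        fit_te = fit_multi_te(spectra_te, series_te.contrasts, model, acq, comp, "all", healthy_initial)
        init_ti = fit_initial(spectra_ti[-1], model, AcquisitionContext(te=20.0, tr=5000.0))
        fit_ti = fit_multi_ti(spectra_ti, series_ti.contrasts, model, series_ti.acq, comp, init_ti)
        table, pdff = derive_parameters(fit_te, fit_ti)
        assert pdff * 100.0 == pytest.approx(30.0, abs=0.5)
        water = table.set_index("resonance").loc["water"]
        assert water.r2star_hz == pytest.approx(142.0, abs=1.0)
        assert water.t1_ms == pytest.approx(1368.0, rel=0.01)
        methylene = table.set_index("resonance").loc["methylene"]
        assert methylene.r2star_hz == pytest.approx(124.0, abs=1.0)
        # R2* reported only for water and methylene
        others = table[~table.resonance.isin(["water", "methylene"])]
        assert others.r2star_hz.isna().all()

    def test_fat_free_voxel(self, model, acq):
        state = RelaxationState(
            t1={g: 800.0 for g in model.groups("t1")},
            t2={g: 40.0 for g in model.groups("t2")},
            lw={g: 45.0 for g in model.groups("lw")},
            a0={r.name: (100.0 if r.name == "water" else 0.0) for r in model.resonances},
        )
        tes = np.array([20.0, 30.0, 40.0, 60.0, 80.0])
        spectra = np.stack([
            fid_to_spectrum(
                synthesize_fid(state, model, AcquisitionContext(te=t, tr=3500.0)),
                acq.dwell,
            )
            for t in tes
        ])
        fit = fit_multi_te(spectra, tes, model, AcquisitionContext(tr=3500.0))
        table, pdff = derive_parameters(fit)
        assert pdff * 100.0 == pytest.approx(0.0, abs=0.5)
        fat_rows = table[table.resonance != "water"]
        assert fat_rows.t2_ms.isna().all()
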