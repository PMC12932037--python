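"""Lineshapes, signal equations and the resonance model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from marrowmrs.spectral import (
    AcquisitionContext,
    FattyAcidComposition,
    RelaxationState,
    Resonance,
    ResonanceModel,
    compute_pdff,
    default_marrow_model,
    gaussian,
    hamilton_amplitudes,
    linewidth_to_r2star,
    lorentzian,
    pseudo_voigt,
    r2star_to_linewidth,
    ste_signal,
    ste_weight,
    sti_weight,
    ti_null,
)


class TestPseudoVoigt:
    def test_pure_lorentzian_peak_height(self, wide_axis):
        lw = 30.0
        prof = pseudo_voigt(0.0, lw, 1.0, wide_axis)
        assert prof.max() == pytest.approx(2.0 / (math.pi * lw), rel=1e-6)
        assert wide_axis[np.argmax(prof)] == pytest.approx(0.0, abs=0.1)

    def test_pure_gaussian_fwhm(self):
        lw = 40.0
        axis = np.linspace(-200, 200, 400_001)
        prof = pseudo_voigt(10.0, lw, 0.0, axis)
        half = prof.max() / 2.0
        above = axis[prof >= half]
        assert above.max() - above.min() == pytest.approx(lw, rel=1e-3)

    @pytest.mark.parametrize("lsf", [0.0, 0.2, 0.5, 0.8, 1.0])
    def test_unit_area(self, lsf, wide_axis):
        prof = pseudo_voigt(0.0, 25.0, lsf, wide_axis)
        area = np.trapezoid(prof, wide_axis)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_both_components_share_fwhm(self):
        # the mixed profile's width parameter is LW for any shape fraction
        lw = 50.0
        axis = np.linspace(-500, 500, 200_001)
        for lsf in (0.2, 0.5):
            prof = pseudo_voigt(0.0, lw, lsf, axis)
            half = prof.max() / 2.0
            above = axis[prof >= half]
            assert above.max() - above.min() == pytest.approx(lw, rel=0.02)

    def test_nonpositive_linewidth_rejected(self):
        axis = np.linspace(-10, 10, 100)
        with pytest.raises(ValueError):
            pseudo_voigt(0.0, 0.0, 0.5, axis)
        with pytest.raises(ValueError):
            lorentzian(axis, 0.0, -1.0)
        with pytest.raises(ValueError):
            gaussian(axis, 0.0, -1.0)

    def test_invalid_shape_fraction_rejected(self):
        with pytest.raises(ValueError):
            pseudo_voigt(0.0, 10.0, 1.5, np.linspace(-10, 10, 11))


class TestSignalEquations:
    def test_te_to_zero_recovers_a0(self):
        assert ste_weight(12.0, 68.0, 1e-9) == pytest.approx(12.0, rel=1e-9)

    def test_echo_ratio_methylene(self):
        # e^(-20/68) for the fat reference T2 of healthy vertebral marrow
        ratio = ste_weight(1.0, 68.0, 40.0) / ste_weight(1.0, 68.0, 20.0)
        assert ratio == pytest.approx(math.exp(-20.0 / 68.0), rel=1e-12)
        assert ratio == pytest.approx(0.7452, abs=5e-4)

    def test_echo_ratio_water(self):
        ratio = ste_weight(1.0, 27.0, 40.0) / ste_weight(1.0, 27.0, 20.0)
        assert ratio == pytest.approx(math.exp(-20.0 / 27.0), rel=1e-12)
        assert ratio == pytest.approx(0.4767, abs=5e-4)

    def test_ir_beta_zero_is_ti_independent(self):
        t1, tr = 800.0, 5000.0
        vals = [sti_weight(1.0, t1, 0.0, ti, tr) for ti in (10.0, 500.0, 4000.0)]
        assert np.allclose(vals, 1.0 + math.exp(-tr / t1))

    def test_null_point_healthy_water(self):
        # TI_null = T1 ln(2 beta / (1 + e^(-TR/T1)))
        null = ti_null(1368.0, 0.93, 5000.0)
        assert null == pytest.approx(814.0, abs=1.0)
        assert sti_weight(1.0, 1368.0, 0.93, null, 5000.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_null_point_long_tr_limit(self):
        assert ti_null(500.0, 1.0, 1e7) == pytest.approx(500.0 * math.log(2.0), rel=1e-6)

    def test_ir_signal_signed(self):
        assert sti_weight(1.0, 1368.0, 0.93, 15.0, 5000.0) < 0
        assert sti_weight(1.0, 1368.0, 0.93, 4000.0, 5000.0) > 0

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            sti_weight(1.0, 1000.0, 1.2, 100.0, 5000.0)

    def test_missing_t2_group_is_configuration_error(self, model, acq):
        state = RelaxationState(
            t1={g: 500.0 for g in model.groups("t1")},
            t2={"water": 27.0},  # fat T2 groups missing
            lw={g: 45.0 for g in model.groups("lw")},
            a0={r.name: 1.0 for r in model.resonances},
        )
        with pytest.raises(KeyError):
            ste_signal(state, model, 20.0, np.linspace(-600, 200, 100), acq)

    def test_area_conservation_at_te_zero(self, model, healthy_state, wide_axis):
        spec = ste_signal(healthy_state, model, 1e-9, wide_axis, AcquisitionContext())
        total = np.trapezoid(spec, wide_axis)
        assert total == pytest.approx(sum(healthy_state.a0.values()), rel=2e-3)


class TestHamiltonAmplitudes:
    def test_no_double_bonds_zeroes_olefinic_and_diacyl(self, model):
        amps = hamilton_amplitudes(FattyAcidComposition(17.5, 0.0, 0.0), model)
        assert amps["olefinic"] == 0.0
        assert amps["diacyl"] == 0.0
        assert amps["alpha_olefinic"] == 0.0

    def test_nmidb_equals_ndb_boundary(self, model):
        amps = hamilton_amplitudes(FattyAcidComposition(17.5, 2.0, 2.0), model)
        assert amps["alpha_olefinic"] == 0.0  # 4*(ndb - nmidb)

    def test_linearity_in_ndb(self, model):
        base = hamilton_amplitudes(FattyAcidComposition(17.5, 1.0, 0.5), model)
        doubled = hamilton_amplitudes(FattyAcidComposition(17.5, 2.0, 0.5), model)
        # composition-independent peaks unchanged
        for name in ("methyl", "beta_carboxyl", "alpha_carboxyl", "glycerol_a"):
            assert doubled[name] == base[name]
        # ndb-linear peaks move by their ndb coefficient
        assert doubled["olefinic"] - base["olefinic"] == pytest.approx(2.0)
        assert doubled["methylene"] - base["methylene"] == pytest.approx(-8.0)
        assert doubled["alpha_olefinic"] - base["alpha_olefinic"] == pytest.approx(4.0)

    def test_invalid_composition_names_offending_peak(self, model):
        with pytest.raises(ValueError, match="methylene"):
            hamilton_amplitudes(FattyAcidComposition(5.0, 4.0, 0.0), model)

    def test_composition_invariants(self):
        with pytest.raises(ValueError):
            FattyAcidComposition(CL=3.0)
        with pytest.raises(ValueError):
            FattyAcidComposition(17.5, 1.0, 2.0)  # nmidb > ndb


class TestPdffAndR2star:
    def test_trivial_fractions(self):
        assert compute_pdff({"water": 70.0, "fat": 0.0}, "water") == 0.0
        assert compute_pdff({"water": 50.0, "fat": 50.0}, "water") == 0.5
        assert compute_pdff([10.0, 15.0, 5.0, 70.0], 3) == pytest.approx(0.30)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError):
            compute_pdff({"water": 0.0, "fat": 0.0}, "water")

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, scale):
        amps = {"water": 70.0, "a": 20.0, "b": 10.0}
        scaled = {k: v * scale for k, v in amps.items()}
        assert compute_pdff(scaled, "water") == pytest.approx(
            compute_pdff(amps, "water"), rel=1e-12
        )

    def test_r2star_mapping(self):
        assert linewidth_to_r2star(0.0) == 0.0
        assert linewidth_to_r2star(100.0 / math.pi) == pytest.approx(100.0)
        # healthy-marrow water linewidth maps to the reported 142 Hz
        assert linewidth_to_r2star(45.20) == pytest.approx(142.0, abs=0.1)
        with pytest.raises(ValueError):
            linewidth_to_r2star(-1.0)

    @given(lw=st.floats(min_value=0.0, max_value=500.0))
    def test_r2star_exactly_invertible(self, lw):
        assert r2star_to_linewidth(linewidth_to_r2star(lw)) == pytest.approx(
            lw, abs=1e-9
        )


class TestResonanceModel:
    def test_exactly_one_water(self, model):
        with pytest.raises(ValueError):
            ResonanceModel(model.resonances, water_index=0)  # methyl is not free

    def test_lsf_bounds(self):
        with pytest.raises(ValueError):
            Resonance("x", 1.0, 1.2, "a", "b", "c", "9")

    def test_groups_cover_all_resonances(self, model):
        assert set(model.groups("t1")) == {
            "methyl", "methylene", "composite", "diacyl", "olefin", "water",
        }
        assert set(model.groups("t2")) == {"methylene", "composite", "water"}
        assert set(model.groups("lw")) == {"water", "methylene", "other_fat"}

    def test_composite_peaks_share_relaxation(self, model):
        a = model.resonances[model.index("alpha_olefinic")]
        b = model.resonances[model.index("alpha_carboxyl")]
        assert a.t2_group == b.t2_group == "composite"
        assert a.t1_group == b.t1_group == "composite"

    def test_json_roundtrip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ResonanceModel.from_json(path)
        assert back == model

    def test_state_validation(self):
        with pytest.raises(ValueError):
            RelaxationState(t1={"w": -1.0}, t2={}, lw={}, a0={})
        with pytest.raises(ValueError):
            RelaxationState(t1={}, t2={}, lw={}, a0={"w": -1.0})
        with pytest.raises(ValueError):
            RelaxationState(t1={}, t2={}, lw={}, a0={}, beta=1.5)

    def test_acquisition_invariants(self):
        with pytest.raises(ValueError):
            AcquisitionContext(te=4000.0, tr=3500.0)
        acq = AcquisitionContext()
        assert acq.ppm_to_hz(4.7) == 0.0
        assert acq.ppm_to_hz(1.3) == pytest.approx(-3.4 * 127.73)
        assert acq.hz_to_ppm(acq.ppm_to_hz(2.0)) == pytest.approx(2.0)
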