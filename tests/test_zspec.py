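import numpy as np
import pytest
from helpers import linear_mtr_stack, shifted_measurement
from hypothesis import given
from hypothesis import strategies as st

from glucocest.bloch import simulate_zspectrum
from glucocest.pools import glucose_invivo_system
from glucocest.zspec import (
    B0EstimationError,
    B0Map,
    ZSpectrum,
    asymmetry_curve,
    b0_correct,
    estimate_b0_shift,
    mtr_asym_at,
    mtr_asym_map,
    normalize,
)

LARMOR = 298.039


def lorentzian_spectrum(offsets, shift=0.0, depth=0.7, width=120.0, larmor=LARMOR):
    off = np.asarray(offsets, dtype=float)
    z = 1.0 - depth / (1.0 + ((off - shift) / width) ** 2)
    return ZSpectrum(off, z, larmor)


GRID = np.arange(-900.0, 901.0, 30.0)


class TestNormalize:
    def test_equal_signals_give_unit_spectrum(self):
        spec = normalize(np.full(5, 100.0), 100.0, np.arange(5.0))
        assert np.all(spec.z == 1.0)

    def test_direct_ratio(self):
        spec = normalize(np.array([80.0, 70.0]), 100.0, np.array([-10.0, 10.0]))
        assert spec.z.tolist() == [0.8, 0.7]

    def test_permuted_offsets_sorted_with_pairing_preserved(self):
        rng = np.random.default_rng(0)
        off = np.arange(-300.0, 301.0, 30.0)
        raw = rng.uniform(50, 90, off.size)
        perm = rng.permutation(off.size)
        spec = normalize(raw[perm], 100.0, off[perm])
        assert np.all(spec.offsets_hz == off)
        assert np.allclose(spec.z, raw / 100.0)

    @pytest.mark.parametrize("bad_s0", [0.0, -1.0, np.nan])
    def test_nonpositive_reference_rejected(self, bad_s0):
        with pytest.raises(ValueError, match="S0"):
            normalize(np.ones(3), bad_s0, np.arange(3.0))

    def test_superunity_values_flagged(self):
        with pytest.warns(UserWarning, match="1.05"):
            normalize(np.array([120.0, 80.0]), 100.0, np.array([-10.0, 10.0]))


class TestMtrAsym:
    def test_stated_formula(self):
        """z(-0.9 ppm)=0.8, z(+0.9 ppm)=0.7 must give exactly 0.1."""
        stack = linear_mtr_stack(0.1, GRID, (1, 1), LARMOR, level=0.75)
        spec = ZSpectrum(GRID, stack[0, 0], LARMOR)
        assert mtr_asym_at(spec) == pytest.approx(0.1, abs=1e-12)
        d = 0.9 * LARMOR
        cs = spec._spline()
        assert cs(-d) == pytest.approx(0.8, abs=0.01)

    def test_symmetric_spectrum_gives_zero(self):
        spec = lorentzian_spectrum(GRID)
        assert mtr_asym_at(spec) == pytest.approx(0.0, abs=1e-12)

    def test_interpolation_matches_dense_grid_oracle(self, invivo_sch):
        """Spline evaluation at +/-0.9 ppm on the 30 Hz grid agrees with a
        1 Hz-resolution simulation of the same system."""
        from dataclasses import replace

        system = glucose_invivo_system(100.0)
        coarse = simulate_zspectrum(system, invivo_sch)
        d_hz = 0.9 * invivo_sch.larmor_hz_per_ppm
        dense_off = (-float(np.ceil(d_hz)) - 1.0, -d_hz, d_hz, float(np.ceil(d_hz)) + 1.0)
        dense = simulate_zspectrum(system, replace(invivo_sch, offsets_hz=dense_off))
        oracle = dense.z[1] - dense.z[2]
        assert abs(mtr_asym_at(coarse) - oracle) < 1e-3

    def test_antisymmetric_under_mirroring(self):
        rng = np.random.default_rng(3)
        z = np.clip(0.5 + 0.3 * rng.standard_normal(GRID.size), 0, 1)
        spec = ZSpectrum(GRID, z, LARMOR)
        mirrored = ZSpectrum(GRID, z[::-1], LARMOR)
        assert mtr_asym_at(mirrored) == pytest.approx(-mtr_asym_at(spec), abs=1e-12)

    def test_out_of_support_delta_rejected(self):
        spec = lorentzian_spectrum(np.arange(-150.0, 151.0, 30.0))
        with pytest.raises(ValueError, match="support"):
            mtr_asym_at(spec, 0.9)


class TestAsymmetryCurve:
    def test_matches_pointwise_evaluation(self, glucose25_spectrum):
        curve = asymmetry_curve(glucose25_spectrum)
        for off, val in zip(curve.offsets_hz[::10], curve.mtr_asym[::10]):
            ppm = off / glucose25_spectrum.larmor_hz_per_ppm
            assert val == pytest.approx(mtr_asym_at(glucose25_spectrum, ppm), abs=1e-12)

    def test_concentration_shifts_peak_upfield(self, invivo_sch, phantom_sch):
        from glucocest.pools import glucose_phantom_system

        a25 = asymmetry_curve(simulate_zspectrum(glucose_phantom_system(25.0), phantom_sch))
        a100 = asymmetry_curve(simulate_zspectrum(glucose_phantom_system(100.0), phantom_sch))
        assert a100.argmax_ppm >= a25.argmax_ppm


class TestB0Estimation:
    @pytest.mark.parametrize("true_shift", [0.0, 30.0, -90.0])
    def test_recovers_injected_lorentzian_shift(self, true_shift):
        spec = lorentzian_spectrum(GRID, shift=true_shift)
        assert estimate_b0_shift(spec) == pytest.approx(true_shift, abs=2.0)

    def test_too_few_points_rejected(self):
        spec = lorentzian_spectrum(np.arange(-900.0, 901.0, 300.0))
        with pytest.raises(B0EstimationError, match="7"):
            estimate_b0_shift(spec)

    def test_boundary_minimum_rejected(self):
        off = np.arange(-300.0, 301.0, 30.0)
        spec = ZSpectrum(off, 1.0 - 0.001 * off / 300.0, LARMOR)  # monotone ramp
        with pytest.raises(B0EstimationError, match="minimum"):
            estimate_b0_shift(spec)


class TestB0Correction:
    def test_zero_shift_is_identity(self, glucose25_spectrum):
        out = b0_correct(glucose25_spectrum, 0.0)
        assert np.max(np.abs(out.z - glucose25_spectrum.z)) < 1e-12

    @pytest.mark.parametrize("shift", [-75.0, 45.0])
    def test_round_trip_on_smooth_spectrum(self, glucose25_spectrum, shift):
        once = b0_correct(glucose25_spectrum, shift)
        back = b0_correct(once, -shift)
        sel = back.valid
        assert np.max(np.abs(back.z[sel] - glucose25_spectrum.z[sel])) < 1e-3

    def test_recovers_mtr_asym_of_shifted_glucose_spectrum(self, invivo_sch):
        """Estimating and removing a +60 Hz injected shift restores the
        0.9 ppm asymmetry of the unshifted forward simulation."""
        system = glucose_invivo_system(100.0)
        truth = mtr_asym_at(simulate_zspectrum(system, invivo_sch))
        meas = shifted_measurement(system, invivo_sch, 60.0)
        est = estimate_b0_shift(meas)
        assert est == pytest.approx(60.0, abs=2.0)
        assert mtr_asym_at(b0_correct(meas, est)) == pytest.approx(truth, abs=0.005)

    def test_excessive_shift_rejected(self, glucose25_spectrum):
        with pytest.raises(ValueError, match="support"):
            b0_correct(glucose25_spectrum, 5000.0)


class TestMtrAsymMap:
    def test_uniform_image_equals_scalar_pipeline(self):
        stack = linear_mtr_stack(0.07, GRID, (6, 5), LARMOR)
        values, mask = mtr_asym_map(stack, np.ones((6, 5)), GRID, larmor=LARMOR)
        scalar = mtr_asym_at(ZSpectrum(GRID, stack[0, 0], LARMOR))
        assert mask.all()
        assert np.max(np.abs(values - scalar)) < 1e-14

    def test_nonpositive_s0_masked_not_nan_propagated(self):
        stack = linear_mtr_stack(0.07, GRID, (4, 4), LARMOR)
        s0 = np.ones((4, 4))
        s0[1, 2] = 0.0
        s0[3, 0] = -2.0
        values, mask = mtr_asym_map(stack, s0, GRID, larmor=LARMOR)
        assert not mask[1, 2] and not mask[3, 0]
        assert np.isnan(values[1, 2])
        assert np.isfinite(values[mask]).all()

    def test_smooth_b0_field_recovered_within_tolerance(self, invivo_sch):
        """A +/-60 Hz linear B0 field, corrected with the known map, leaves
        the MTRasym map within 0.005 of the zero-field map."""
        system = glucose_invivo_system(150.0)
        clean = simulate_zspectrum(system, invivo_sch)
        ny, nx = 3, 7
        shifts = np.linspace(-60, 60, nx)[None, :].repeat(ny, axis=0)
        stack = np.empty((ny, nx, clean.offsets_hz.size))
        for j, s in enumerate(np.linspace(-60, 60, nx)):
            stack[:, j, :] = shifted_measurement(system, invivo_sch, s).z
        ref, _ = mtr_asym_map(
            np.broadcast_to(clean.z, stack.shape).copy(),
            np.ones((ny, nx)), clean.offsets_hz, larmor=invivo_sch.larmor_hz_per_ppm,
        )
        corrected, mask = mtr_asym_map(
            stack, np.ones((ny, nx)), clean.offsets_hz,
            b0=B0Map(shifts), larmor=invivo_sch.larmor_hz_per_ppm,
        )
        assert mask.all()
        assert np.max(np.abs(corrected - ref)) < 0.005

    def test_shape_mismatch_rejected(self):
        stack = linear_mtr_stack(0.05, GRID, (4, 4), LARMOR)
        with pytest.raises(ValueError, match="shape"):
            mtr_asym_map(stack, np.ones((3, 4)), GRID, larmor=LARMOR)


@given(level=st.floats(0.3, 0.9), value=st.floats(-0.2, 0.2))
def test_linear_spectrum_mtr_asym_exact(level, value):
    """Property: linear Z-spectra carry their construction value exactly."""
    stack = linear_mtr_stack(value, GRID, (1, 1), LARMOR, level=level)
    spec = ZSpectrum(GRID, stack[0, 0], LARMOR)
    assert mtr_asym_at(spec) == pytest.approx(value, abs=1e-10)
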