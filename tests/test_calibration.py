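import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import froidose as fd
from froidose.calibration import (
    FILTER_EFFECTIVE_THICKNESSES_MM,
    TABLE_TRANSMISSIONS,
    TransmissionMeasurement,
    average_effective_thickness,
    calibration_factor,
    fit_effective_density,
    fit_effective_thickness,
)
from froidose.instruments import carm_spectrum, ct_spectrum
from froidose.spectra import FilterStack, kerma_weighted_transmission


def _gd_slab(mats, t_mm):
    return FilterStack(((mats["gadolinium_oxysulfide"], t_mm),))


class TestThicknessFit:
    def test_unit_transmission_gives_zero_thickness(self, mats, spec90):
        assert fit_effective_thickness(1.0, mats["gadolinium_oxysulfide"], spec90) == 0.0

    def test_round_trip_recovers_known_slab(self, mats, spec90):
        gd = mats["gadolinium_oxysulfide"]
        target = kerma_weighted_transmission(spec90, _gd_slab(mats, 0.306))
        assert fit_effective_thickness(target, gd, spec90) == pytest.approx(
            0.306, abs=1e-4
        )

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        t=st.floats(0.05, 0.5),
        kvp=st.sampled_from([80.0, 90.0, 100.0]),
    )
    def test_round_trip_property_sweep(self, t, kvp):
        mats = fd.predefined()
        gd = mats["gadolinium_oxysulfide"]
        spec = carm_spectrum(kvp)
        target = kerma_weighted_transmission(spec, _gd_slab(mats, t))
        assert fit_effective_thickness(target, gd, spec) == pytest.approx(t, abs=1e-4)

    def test_invalid_targets_rejected(self, mats, spec90):
        gd = mats["gadolinium_oxysulfide"]
        with pytest.raises(ValueError):
            fit_effective_thickness(0.0, gd, spec90)
        with pytest.raises(ValueError):
            fit_effective_thickness(1.5, gd, spec90)


class TestThicknessAveraging:
    def test_published_per_voltage_values_pool_to_published_averages(self):
        s = average_effective_thickness(FILTER_EFFECTIVE_THICKNESSES_MM)
        assert round(s.per_layer_mean_mm, 3) == 0.102
        assert round(s.per_layer_two_sigma_mm, 3) == 0.006
        assert round(s.rows[2][0], 3) == 0.204
        assert round(s.rows[4][0], 3) == 0.408

    def test_constant_input_has_zero_spread(self):
        data = [(n, kvp, 0.1 * n) for n in (1, 2, 3) for kvp in (80, 90)]
        s = average_effective_thickness(data)
        assert s.per_layer_mean_mm == pytest.approx(0.1)
        assert s.per_layer_two_sigma_mm == pytest.approx(0.0, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_effective_thickness([])


class TestDensityFit:
    def test_synthetic_round_trip_recovers_known_density(self, mats):
        rho_true, t_mm = 0.5, 30.0
        meas = []
        for kvp in TABLE_TRANSMISSIONS:
            spec = ct_spectrum(kvp)
            slab = FilterStack(
                ((fd.Material("carbon", (("C", 1.0),), rho_true), t_mm),)
            )
            meas.append(
                TransmissionMeasurement(
                    kvp, kerma_weighted_transmission(spec, slab), spec
                )
            )
        fit = fit_effective_density(meas, mats["carbon"], t_mm)
        for kvp, rho in fit.per_kvp_density.items():
            assert rho == pytest.approx(rho_true, abs=1e-4)

    def test_areal_density_is_the_invariant(self, mats):
        spec = ct_spectrum(90.0)
        meas = [TransmissionMeasurement(90.0, 0.695, spec)]
        full = fit_effective_density(meas, mats["carbon"], 30.0)
        half = fit_effective_density(meas, mats["carbon"], 15.0)
        assert half.per_kvp_density[90.0] == pytest.approx(
            2.0 * full.per_kvp_density[90.0], rel=1e-6
        )
        assert half.mean_areal_density == pytest.approx(
            full.mean_areal_density, rel=1e-6
        )

    def test_degenerate_measurements_rejected(self, mats):
        spec = ct_spectrum(90.0)
        with pytest.raises(ValueError):
            fit_effective_density([], mats["carbon"], 30.0)
        with pytest.raises(ValueError):
            TransmissionMeasurement(90.0, 1.2, spec)


class TestCalibrationFactor:
    def test_identity_and_linearity(self):
        cf = calibration_factor(1.0, 1.0, 90.0)
        assert cf.cf == 1.0
        assert calibration_factor(2.0, 1.0, 90.0).cf == 2.0
        assert calibration_factor(1.0, 2.0, 90.0).cf == 0.5

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            calibration_factor(0.0, 1.0, 90.0)
        with pytest.raises(ValueError):
            calibration_factor(1.0, -1.0, 90.0)

    def test_closed_loop_reproduces_measured_air_kerma(self):
        # Eq. 2 applied to the calibration geometry itself gives back the
        # measured free-in-air dose exactly
        proto = fd.ScanProtocol(kvp=90.0, projections=10)
        d_sim = fd.air_kerma_at_isocenter(proto)
        measured_per_mas = 3.2e-3  # Gy/mAs, arbitrary
        cf = calibration_factor(measured_per_mas, d_sim, 90.0)
        absolute = d_sim * cf.cf * proto.mas_per_frame
        assert absolute == pytest.approx(
            measured_per_mas * proto.mas_per_frame, rel=1e-12
        )
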