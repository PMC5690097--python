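import numpy as np
import pytest

import froidose as fd
from froidose.dosimetry import (
    REMAINDER_ORGANS,
    TISSUE_WEIGHTS,
    OrganDoseReport,
    absolute_voxel_dose,
    dose_reduction,
    effective_dose,
    organ_dose,
    phantom_dose_report,
    theoretical_reduction,
)
from froidose.phantom import IsocenterPlacement, VoxelPhantom
from froidose.transport import DoseGrid


def _grid(dose, engine="primary_kerma", **prov):
    return DoseGrid(np.asarray(dose, dtype=float), {"engine": engine, **prov})


def _two_voxel_phantom(mats, densities):
    labels = np.array([[[1, 1]]], dtype=np.int16)
    return VoxelPhantom(
        labels, (10.0, 10.0, 10.0), (0, 0, 0),
        {1: ("brain", mats["brain"])}, {1: mats["brain"].density},
        density_array=np.array([[list(densities)]], dtype=float),
    )


class TestOrganDose:
    def test_two_voxel_mass_weighted_oracle(self, mats):
        # doses 1 and 3 mGy with masses 1 g and 3 g -> (1*1 + 3*3)/4 = 2.5 mGy
        ph = _two_voxel_phantom(mats, (1.0, 3.0))  # volumes equal: mass ratio 1:3
        grid = _grid([[[1.0e-3, 3.0e-3]]])
        rep = organ_dose(grid, ph, "brain")
        assert rep.h_t == pytest.approx(2.5e-3)
        assert rep.w_r == 1.0

    def test_uniform_dose_independent_of_density_distribution(self, mats):
        ph = _two_voxel_phantom(mats, (0.5, 7.7))
        rep = organ_dose(_grid([[[2.0e-4, 2.0e-4]]]), ph, "brain")
        assert rep.h_t == pytest.approx(2.0e-4)

    def test_equal_densities_reduce_to_plain_mean(self, mats):
        ph = _two_voxel_phantom(mats, (1.04, 1.04))
        rep = organ_dose(_grid([[[1.0, 3.0]]]), ph, "brain")
        assert rep.h_t == pytest.approx(2.0)

    def test_missing_organ_rejected(self, mats, head5):
        with pytest.raises(KeyError):
            organ_dose(_grid(np.zeros(head5.shape)), head5, "liver")


class TestAbsoluteDose:
    def test_unit_scaling_is_identity(self):
        cf = fd.calibration_factor(1.0, 1.0, 90.0)
        proto = fd.ScanProtocol(kvp=90.0, tube_current_ma=1000.0,
                                exposure_time_ms=1.0)
        grid = _grid([[[1.0, 2.0]]])
        out = absolute_voxel_dose(grid, cf, proto)
        np.testing.assert_allclose(out.dose, grid.dose)

    def test_linear_in_tube_current(self):
        cf = fd.calibration_factor(2.0, 1.0, 90.0)
        base = fd.ScanProtocol(kvp=90.0)
        double = fd.ScanProtocol(kvp=90.0, tube_current_ma=500.0)
        g = _grid([[[1.0]]])
        assert absolute_voxel_dose(g, cf, double).dose[0, 0, 0] == pytest.approx(
            2.0 * absolute_voxel_dose(g, cf, base).dose[0, 0, 0]
        )

    def test_kvp_mismatch_rejected(self):
        cf = fd.calibration_factor(1.0, 1.0, 90.0)
        with pytest.raises(ValueError):
            absolute_voxel_dose(_grid([[[1.0]]]), cf, fd.ScanProtocol(kvp=100.0))

    def test_calibration_geometry_closed_loop(self):
        # applying the absolute scaling to the air-kerma simulation itself
        # reproduces the measured free-in-air dose per frame exactly
        proto = fd.ScanProtocol(kvp=90.0, projections=6)
        d_sim = fd.air_kerma_at_isocenter(proto)
        measured = 2.7e-3  # Gy/mAs
        cf = fd.calibration_factor(measured, d_sim, 90.0)
        grid = _grid([[[d_sim]]])
        out = absolute_voxel_dose(grid, cf, proto)
        assert out.dose[0, 0, 0] == pytest.approx(
            measured * proto.mas_per_frame, rel=1e-12
        )


def _rep(organ, h, mass=100.0):
    return OrganDoseReport(organ, h, 1.0, 10, mass, "test")


class TestEffectiveDose:
    def test_single_term(self):
        out = effective_dose([_rep("brain", 100.0)])
        assert out.effective == pytest.approx(1.0)  # w_T = 0.01
        assert "salivary_glands" in out.absent

    def test_null_case(self):
        out = effective_dose([_rep("brain", 0.0), _rep("skin", 0.0)])
        assert out.effective == 0.0

    def test_full_weight_set_is_normalized(self):
        # every ICRP tissue at dose D (remainder via one remainder organ)
        d = 7.5
        reports = [
            _rep(t, d) for t in TISSUE_WEIGHTS if t != "remainder"
        ] + [_rep(REMAINDER_ORGANS[0], d)]
        out = effective_dose(reports)
        assert not out.absent
        assert out.effective == pytest.approx(d, rel=1e-12)

    def test_remainder_is_arithmetic_mean(self):
        reports = [_rep("muscle", 1.0), _rep("spleen", 3.0)]
        out = effective_dose(reports)
        assert out.terms["remainder"][1] == pytest.approx(2.0)
        assert out.effective == pytest.approx(0.12 * 2.0)

    def test_salivary_glands_combined_mass_weighted(self):
        out = effective_dose([
            _rep("salivary_gland_left", 1.0, mass=10.0),
            _rep("salivary_gland_right", 3.0, mass=30.0),
        ])
        assert out.terms["salivary_glands"][1] == pytest.approx(2.5)

    def test_eye_lens_never_contributes(self):
        with_lens = effective_dose([_rep("brain", 5.0), _rep("eye_lens_left", 999.0)])
        without = effective_dose([_rep("brain", 5.0)])
        assert with_lens.effective == without.effective
        assert "eye_lens_left" in with_lens.excluded

    def test_duplicates_and_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            effective_dose([_rep("brain", 1.0), _rep("brain", 2.0)])
        with pytest.raises(KeyError):
            effective_dose([_rep("gizzard", 1.0)])


class TestReduction:
    def test_identity_and_proportional_cases(self, head5):
        grid = _grid(np.where(head5.labels > 0, 4.0e-19, 0.0))
        rep = phantom_dose_report(grid, head5)
        red = dose_reduction(rep, rep)
        assert all(abs(v) < 1e-12 for v in red.values())
        half = phantom_dose_report(grid.scaled(0.5), head5)
        red = dose_reduction(half, rep)
        assert all(v == pytest.approx(0.5) for v in red.values())

    def test_zero_baseline_rejected(self, head5):
        z = phantom_dose_report(_grid(np.zeros(head5.shape)), head5)
        with pytest.raises(ValueError):
            dose_reduction(z, z)

    def test_theoretical_reduction_limits(self):
        assert theoretical_reduction(1.0, 0.2) == 0.0
        assert theoretical_reduction(0.5, 1.0) == 0.0
        assert theoretical_reduction(0.0, 0.2) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            theoretical_reduction(1.2, 0.2)
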