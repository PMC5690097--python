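import numpy as np
import pytest

import froidose as fd
from froidose.phantom import IsocenterPlacement
from froidose.spectra import monoenergetic

ORIGIN_ISO = IsocenterPlacement(0.0, 0.0, 0.0)


class TestSiddon:
    def test_axis_aligned_ray_crosses_every_voxel_once(self, water_cube):
        n, s = 16, 6.0
        tr = fd.siddon_trace(water_cube, (-200.0, 0.1, 0.2), (200.0, 0.1, 0.2))
        assert len(tr) == n
        for _, length in tr:
            assert length == pytest.approx(s, rel=1e-9)

    def test_lengths_sum_to_chord_for_random_rays(self, water_cube):
        rng = np.random.default_rng(11)
        half = 48.0
        for _ in range(300):
            p0 = rng.uniform(-300, 300, 3)
            p1 = rng.uniform(-40, 40, 3)
            tr = fd.siddon_trace(water_cube, p0, p1)
            total = sum(length for _, length in tr)
            # chord of the segment inside the cube
            d = p1 - p0
            tmin, tmax = 0.0, 1.0
            for a in range(3):
                if abs(d[a]) > 1e-12:
                    t1, t2 = (-half - p0[a]) / d[a], (half - p0[a]) / d[a]
                    tmin = max(tmin, min(t1, t2))
                    tmax = min(tmax, max(t1, t2))
                elif not (-half <= p0[a] <= half):
                    tmax = tmin
            chord = max(tmax - tmin, 0.0) * np.linalg.norm(d)
            assert total == pytest.approx(chord, rel=1e-9, abs=1e-9)

    def test_miss_and_degenerate_segment(self, water_cube):
        assert fd.siddon_trace(water_cube, (1000, 1000, 0), (1000, -1000, 0)) == []
        with pytest.raises(ValueError):
            fd.siddon_trace(water_cube, (1, 2, 3), (1, 2, 3))


class TestPrimaryKerma:
    def test_water_slab_beer_lambert_inverse_square_oracle(self, water_cube, mats):
        # single projection, monoenergetic beam, isocenter on a voxel-center
        # row: the engine must reproduce D0 * exp(-mu depth) * (r0/r)^2
        proto = fd.ScanProtocol(
            kvp=100.0, projections=1, start_angle_deg=0.0
        )
        iso = IsocenterPlacement(0.0, -3.0, -3.0)  # a voxel-center row
        e = 60.0
        spec = monoenergetic(e)
        grid = fd.primary_kerma_dose(water_cube, proto, iso, spectrum=spec)
        water = mats["water"]
        mu = water.mu(e)
        muen = water.mu(e, "energy_absorption")
        xs = water_cube.voxel_centers_axis(0)
        j = k = 7  # the row y = z = -3 mm
        src_x = 700.0  # source at angle 0: iso + 700 mm along +x
        for i, x in enumerate(xs):
            depth_cm = (48.0 - x) / 10.0
            r_cm = (src_x - x) / 10.0
            expected = (
                e * muen * np.exp(-mu * depth_cm)
                / (4.0 * np.pi * r_cm**2) * 1.602176634e-13
            )
            assert grid.dose[i, j, k] == pytest.approx(expected, rel=1e-6)

    def test_dose_decreases_with_depth_in_homogeneous_medium(self, water_cube):
        proto = fd.ScanProtocol(kvp=100.0, projections=1, start_angle_deg=0.0)
        grid = fd.primary_kerma_dose(
            water_cube, proto, IsocenterPlacement(0, -3, -3),
            spectrum=monoenergetic(60.0),
        )
        row = grid.dose[::-1, 7, 7]  # entry side first
        assert np.all(np.diff(row) < 0)

    def test_closed_filter_scales_central_row_by_slab_transmission(
        self, water_cube, mats
    ):
        proto = fd.ScanProtocol(kvp=100.0, projections=1, start_angle_deg=0.0)
        iso = IsocenterPlacement(0.0, -3.0, -3.0)
        e, th = 60.0, 0.3
        spec = monoenergetic(e)
        base = fd.primary_kerma_dose(water_cube, proto, iso, spectrum=spec)
        # tiny aperture displaced out of the FOV: every ray is filtered
        roi = fd.ROIFilterSpec.gadolinium(
            th, 0.001, aperture_center_cm=(90.0, 0.0)
        )
        filt = fd.primary_kerma_dose(
            water_cube, proto, iso, roi_filter=roi, spectrum=spec
        )
        gd = mats["gadolinium_oxysulfide"]
        t_normal = np.exp(-gd.mu(e) * gd.density * th / 10.0)
        # exact on the central row (normal incidence)
        ratio = filt.dose[:, 7, 7] / base.dose[:, 7, 7]
        np.testing.assert_allclose(ratio, t_normal, rtol=1e-9)
        # never less attenuation anywhere (oblique rays see longer paths)
        m = base.dose > 0
        assert np.all(filt.dose[m] <= base.dose[m] * (t_normal + 1e-12))

    def test_any_filter_never_increases_any_voxel_dose(self, head5):
        proto = fd.ScanProtocol(kvp=90.0, projections=8)
        iso = IsocenterPlacement(265.0, 90.0, 1580.0)
        base = fd.primary_kerma_dose(head5, proto, iso)
        roi = fd.ROIFilterSpec.gadolinium(0.204, 0.2)
        filt = fd.primary_kerma_dose(head5, proto, iso, roi_filter=roi)
        assert np.all(filt.dose <= base.dose + 1e-30)

    def test_linear_in_spectrum_scale(self, water_cube):
        proto = fd.ScanProtocol(kvp=100.0, projections=2, start_angle_deg=0.0)
        iso = IsocenterPlacement(0, -3, -3)
        g1 = fd.primary_kerma_dose(water_cube, proto, iso, spectrum=monoenergetic(60))
        g2 = fd.primary_kerma_dose(
            water_cube, proto, iso, spectrum=monoenergetic(60, weight=5.0)
        )
        np.testing.assert_allclose(g2.dose, g1.dose, rtol=1e-12)

    def test_isocenter_outside_phantom_rejected(self, water_cube):
        with pytest.raises(ValueError):
            fd.primary_kerma_dose(
                water_cube, fd.ScanProtocol(), IsocenterPlacement(500, 0, 0)
            )


class TestAirKerma:
    def test_additivity_over_frames(self):
        a1 = fd.air_kerma_at_isocenter(fd.ScanProtocol(projections=10))
        a2 = fd.air_kerma_at_isocenter(fd.ScanProtocol(projections=20))
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)

    def test_monoenergetic_point_source_closed_form(self, mats):
        e = 60.0
        proto = fd.ScanProtocol(projections=1)
        got = fd.air_kerma_at_isocenter(proto, spectrum=monoenergetic(e))
        muen = mats["air"].mu(e, "energy_absorption")
        r_cm = proto.source_isocenter_cm
        expected = e * muen / (4.0 * np.pi * r_cm**2) * 1.602176634e-13
        assert got == pytest.approx(expected, rel=1e-12)

    def test_centered_aperture_leaves_isocenter_unfiltered(self):
        proto = fd.ScanProtocol(projections=4)
        roi = fd.ROIFilterSpec.gadolinium(0.4, 0.2)
        assert fd.air_kerma_at_isocenter(proto, roi_filter=roi) == pytest.approx(
            fd.air_kerma_at_isocenter(proto), rel=1e-12
        )
        off = fd.ROIFilterSpec.gadolinium(0.4, 0.01, aperture_center_cm=(8.0, 0.0))
        assert fd.air_kerma_at_isocenter(proto, roi_filter=off) < \
            fd.air_kerma_at_isocenter(proto)


class TestMonteCarlo:
    proto = fd.ScanProtocol(kvp=100.0, projections=4, start_angle_deg=0.0)

    def test_same_seed_reproduces_bit_for_bit(self, water_cube):
        kw = dict(spectrum=monoenergetic(60.0), histories=20000, seed=5)
        a = fd.mc_photon_dose(water_cube, self.proto, ORIGIN_ISO, **kw)
        b = fd.mc_photon_dose(water_cube, self.proto, ORIGIN_ISO, **kw)
        assert np.array_equal(a.dose, b.dose)
        c = fd.mc_photon_dose(
            water_cube, self.proto, ORIGIN_ISO,
            spectrum=monoenergetic(60.0), histories=20000, seed=6,
        )
        assert not np.array_equal(a.dose, c.dose)

    def test_energy_conservation_bound(self, water_cube):
        g = fd.mc_photon_dose(
            water_cube, self.proto, ORIGIN_ISO, histories=50000, seed=2
        )
        p = g.provenance
        assert p["deposited_kev_per_history"] <= p["emitted_kev_per_history"]

    def test_uncertainty_scales_as_inverse_root_histories(self, water_cube):
        def organ_rel_sem(histories):
            g = fd.mc_photon_dose(
                water_cube, self.proto, ORIGIN_ISO,
                spectrum=monoenergetic(60.0),
                histories=histories, seed=9, n_batches=30,
            )
            mask = water_cube.labels == 1
            bm = g.batches[:, mask].mean(axis=1)
            return bm.std(ddof=1) / np.sqrt(len(bm)) / bm.mean()

        ratio = organ_rel_sem(40000) / organ_rel_sem(160000)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_invalid_inputs_rejected(self, water_cube):
        with pytest.raises(ValueError):
            fd.mc_photon_dose(water_cube, self.proto, ORIGIN_ISO, histories=0)
        with pytest.raises(ValueError):
            fd.mc_photon_dose(
                water_cube, self.proto, ORIGIN_ISO, histories=10, seed=-1
            )
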