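"""Backprojection, azimuth assignment, FSC and amplitude operations."""

import numpy as np
import pytest

from vertexrec.phantom import DensityMap, PhantomSpec, turret_reference
from vertexrec.projection import project
from vertexrec.reconstruct import (FSCCurve, amplitude_ops, backproject,
                                   backproject_halves, fsc, resolution_at,
                                   sharpening_factor)
from vertexrec.simulate import random_orientations
from vertexrec.symmetry import Orientation


@pytest.fixture(scope="module")
def blob_map():
    box = 32
    c = box // 2
    ax = np.arange(box) - c
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((box,) * 3)
    for (cx, cy, cz), s, a in [((4, 2, -3), 3.0, 1.0), ((-5, 1, 4), 2.5, 0.8),
                               ((0, -6, 0), 2.0, 1.2), ((3, 5, 3), 2.2, 0.9)]:
        vol += a * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
                            / (2 * s * s)))
    return DensityMap(vol, 1.35)


class TestBackprojection:
    def test_self_consistency_from_uniform_projections(self, blob_map):
        """2,000 clean uniform projections reconstruct the object."""
        rng = np.random.default_rng(0)
        orients = random_orientations(2000, rng)
        imgs = np.array([project(blob_map, o) for o in orients])
        rec = backproject(imgs, orients, None, 1.35, "C1")
        sel = blob_map.data > 0.05 * blob_map.data.max()
        assert np.corrcoef(rec.data[sel], blob_map.data[sel])[0, 1] > 0.95

    def test_shift_handling(self, blob_map):
        rng = np.random.default_rng(1)
        orients = random_orientations(300, rng, shift_sigma=1.5)
        imgs = np.array([project(blob_map, o) for o in orients])
        rec = backproject(imgs, orients, None, 1.35, "C1")
        sel = blob_map.data > 0.05 * blob_map.data.max()
        assert np.corrcoef(rec.data[sel], blob_map.data[sel])[0, 1] > 0.95

    def test_c6_idempotent_on_c6_object(self):
        """Requesting C6 on a C6-symmetric object changes nothing."""
        spec = PhantomSpec()
        ref = turret_reference(spec, 32)
        rng = np.random.default_rng(2)
        orients = random_orientations(400, rng)
        imgs = np.array([project(ref, o) for o in orients])
        rec1 = backproject(imgs, orients, None, 1.35, "C1")
        rec6 = backproject(imgs, orients, None, 1.35, "C6")
        sel = ref.data > 0.05 * ref.data.max()
        assert np.corrcoef(rec1.data[sel], rec6.data[sel])[0, 1] > 0.99

    def test_equivalent_triplet_choice_does_not_change_c5_map(
            self, clean_stack, vertices):
        """Re-extracting with different stabilizer triplets and C5
        reconstruction yields the same vertex map."""
        from vertexrec.extract import (SelectionParams, drop_out_of_bounds,
                                       extract_subparticles)
        params = SelectionParams(subparticle_box=32, vertex_radius=42.0)
        maps = []
        for seed in (10, 77):
            subs = drop_out_of_bounds(
                extract_subparticles(clean_stack, vertices, params,
                                     seed=seed))
            orients = [subs.orientation(i) for i in range(len(subs.table))]
            maps.append(backproject(subs.images, orients, None, 1.35, "C5"))
        a, b = maps
        sel = np.abs(a.data) > 0.1 * np.abs(a.data).max()
        assert np.corrcoef(a.data[sel], b.data[sel])[0, 1] > 0.999

    def test_identical_poses_warn(self, blob_map):
        o = Orientation(10.0, 40.0, 0.0)
        imgs = np.array([project(blob_map, o)] * 3)
        with pytest.warns(UserWarning, match="anisotropic"):
            backproject(imgs, [o, o, o], None, 1.35, "C1")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="2 images"):
            backproject(np.zeros((1, 8, 8)), [Orientation()], None, 1.35)

    def test_halves_never_share_parents(self, blob_map):
        rng = np.random.default_rng(3)
        orients = random_orientations(40, rng)
        imgs = np.array([project(blob_map, o) for o in orients])
        ids = np.arange(40)
        full, h1, h2 = backproject_halves(imgs, orients, None, 1.35, ids)
        even = [o for i, o in enumerate(orients) if i % 2 == 0]
        ref1 = backproject(imgs[ids % 2 == 0], even, None, 1.35)
        np.testing.assert_allclose(h1.data, ref1.data, atol=1e-10)
        assert not np.allclose(h1.data, h2.data)


class TestAzimuthAssignment:
    def test_reference_convention_periodicity(self):
        """Shifting the reference azimuth by 60 degrees leaves the
        assignment problem unchanged (C6 periodicity)."""
        spec = PhantomSpec()
        a = turret_reference(spec, 32, azimuth=0.0)
        b = turret_reference(spec, 32, azimuth=60.0)
        np.testing.assert_allclose(a.data, b.data,
                                   atol=1e-4 * a.data.max())

    def test_blank_image_flagged(self):
        from vertexrec.reconstruct import assign_azimuth_fullframe
        spec = PhantomSpec()
        ref = turret_reference(spec, 32)
        az, cc = assign_azimuth_fullframe(np.zeros((96, 96)), np.eye(3),
                                          (48, 48), ref, None)
        assert np.isnan(az) and np.isnan(cc)

    def test_recovers_known_azimuth_on_clean_side_view(self):
        from vertexrec.reconstruct import assign_azimuth_fullframe
        spec = PhantomSpec()
        truth = 23.0
        ref = turret_reference(spec, 32)
        content = turret_reference(spec, 32, azimuth=truth)
        # near-side view; an exact side view of the planar achiral arm ring
        # cannot distinguish azimuth +phi from -phi
        o = Orientation(12.0, 70.0, -25.0)
        img = project(content, o)
        buf = np.zeros((96, 96))
        buf[32:64, 32:64] = img
        az, cc = assign_azimuth_fullframe(buf, o.matrix(), (48, 48), ref,
                                          None, step=1.0)
        assert az == pytest.approx(truth, abs=1.0)
        assert cc > 0.95


class TestFSC:
    def test_identical_maps_give_unity(self, blob_map):
        curve = fsc(blob_map, blob_map)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-10)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(5)
        a = DensityMap(rng.normal(size=(96,) * 3), 1.35)
        b = DensityMap(rng.normal(size=(96,) * 3), 1.35)
        curve = fsc(a, b)
        assert np.abs(curve.values[1:]).mean() < 0.05

    def test_constructed_curve_interpolation(self):
        """A curve crossing 0.143 between the shells at 1/10 and 1/9 per
        Angstrom reports a resolution between 9 and 10 A, at the
        hand-computed interpolation point."""
        freqs = np.array([0.0, 0.05, 0.1, 1.0 / 9.0])
        vals = np.array([1.0, 0.8, 0.5, 0.0])
        curve = FSCCurve(frequencies=freqs, values=vals)
        res = resolution_at(curve, 0.143)
        assert 9.0 < res < 10.0
        # crossing at 0.1 + (0.357/0.5) * (1/9 - 1/10)
        fc = 0.1 + (0.5 - 0.143) / 0.5 * (1.0 / 9.0 - 0.1)
        assert res == pytest.approx(1.0 / fc, abs=1e-9)

    def test_curve_never_crossing_reports_nyquist(self):
        freqs = np.linspace(0.0, 0.37, 10)[1:]
        curve = FSCCurve(frequencies=freqs, values=np.full(9, 0.9))
        assert resolution_at(curve) == pytest.approx(1.0 / freqs[-1])

    def test_mismatched_grids_rejected(self, blob_map):
        other = DensityMap(np.zeros((16, 16, 16)), 1.35)
        with pytest.raises(ValueError, match="identical grids"):
            fsc(blob_map, other)

    def test_tsv_export(self, blob_map, tmp_path):
        import pandas as pd
        curve = fsc(blob_map, blob_map)
        path = tmp_path / "fsc.tsv"
        curve.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["frequency_invA", "fsc"]
        assert len(df) == len(curve.frequencies)


class TestAmplitudeOps:
    def test_zero_bfactor_no_lowpass_is_identity(self, blob_map):
        out = amplitude_ops(blob_map, bfactor=0.0)
        np.testing.assert_allclose(out.data, blob_map.data, atol=1e-10)

    def test_sharpening_closed_form(self):
        """B = -600 A^2 boosts the amplitude at 1/9.1 1/A by
        exp(600 / (4 * 9.1^2)) ~ 6.12."""
        factor = sharpening_factor(-600.0, 9.1)
        assert factor == pytest.approx(np.exp(600.0 / (4.0 * 9.1 ** 2)))
        assert factor == pytest.approx(6.12, abs=0.01)

    def test_sharpening_scales_shell_amplitudes(self, blob_map):
        sharp = amplitude_ops(blob_map, bfactor=-200.0)
        F0 = np.fft.fftn(blob_map.data)
        F1 = np.fft.fftn(sharp.data)
        f = np.fft.fftfreq(blob_map.box, d=1.35)
        s = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2
                    + f[None, None, :] ** 2)
        sel = (s > 0.10) & (s < 0.11)
        ratio = np.abs(F1[sel]) / np.abs(F0[sel])
        expected = np.exp(200.0 * (s[sel] ** 2) / 4.0)
        np.testing.assert_allclose(ratio, expected, rtol=1e-6)

    def test_lowpass_removes_high_frequency_power(self, blob_map):
        cutoff = 9.1
        out = amplitude_ops(blob_map, lowpass=cutoff)
        F = np.fft.fftn(out.data)
        f = np.fft.fftfreq(blob_map.box, d=1.35)
        s = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2
                    + f[None, None, :] ** 2)
        beyond = (np.abs(F[s >= 1.0 / cutoff]) ** 2).sum()
        total = (np.abs(F) ** 2).sum()
        assert beyond < 0.01 * total

    def test_lowpass_beyond_nyquist_rejected(self, blob_map):
        with pytest.raises(ValueError, match="Nyquist"):
            amplitude_ops(blob_map, lowpass=2.0)

    def test_nonfinite_bfactor_rejected(self, blob_map):
        with pytest.raises(ValueError):
            amplitude_ops(blob_map, bfactor=np.inf)
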