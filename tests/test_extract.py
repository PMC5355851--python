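"""Subparticle extraction: projected coordinates, poses, selection filter."""

import numpy as np
import pandas as pd
import pytest

from vertexrec.extract import (SelectionParams, drop_out_of_bounds,
                               extract_subparticles, side_view_filter,
                               subparticle_records, vertex_projection_coords)
from vertexrec.projection import project
from vertexrec.simulate import random_orientations
from vertexrec.symmetry import Orientation


@pytest.fixture(scope="module")
def params():
    return SelectionParams(subparticle_box=32, vertex_radius=42.0)


def _records_for(orients, vertices, params, box=96, seed=3, truth=None):
    table = pd.DataFrame(
        [{"vrxParticleId": i, "rlnAngleRot": o.rot, "rlnAngleTilt": o.tilt,
          "rlnAnglePsi": o.psi, "rlnOriginX": o.dx, "rlnOriginY": o.dy}
         for i, o in enumerate(orients)])
    return subparticle_records(table, vertices, params, 1.35, box, seed,
                               truth_azimuths=truth)


class TestVertexProjectionCoords:
    def test_identity_pose_geometry(self, vertices):
        coords, side_dev = vertex_projection_coords(Orientation(), vertices,
                                                    42.0, 1.35)
        # antipodal axes project to mirrored coordinates with equal deviation
        for k in range(12):
            kk = int(np.argmin(np.abs(vertices.axes + vertices.axes[k])
                               .max(axis=1)))
            np.testing.assert_allclose(coords[kk], -coords[k], atol=1e-9)
            assert side_dev[kk] == pytest.approx(side_dev[k], abs=1e-9)
        # the closer an axis is to the viewing axis, the larger its
        # deviation from a side view and the nearer its projected position
        order = np.argsort(np.abs(vertices.axes[:, 2]))
        dist = np.hypot(coords[:, 0], coords[:, 1])
        assert (np.diff(side_dev[order]) >= -1e-9).all()
        assert (np.diff(dist[order]) <= 1e-9).all()

    def test_in_plane_rotation_rotates_coords_only(self, vertices):
        o0 = Orientation(20.0, 60.0, 0.0)
        o1 = Orientation(20.0, 60.0, 35.0)
        c0, d0 = vertex_projection_coords(o0, vertices, 42.0, 1.35)
        c1, d1 = vertex_projection_coords(o1, vertices, 42.0, 1.35)
        np.testing.assert_allclose(d0, d1, atol=1e-9)
        th = np.radians(35.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(c1, c0 @ rot.T, atol=1e-9)

    def test_coords_match_matrix_oracle(self, vertices):
        rng = np.random.default_rng(17)
        for o in random_orientations(100, rng, shift_sigma=1.0):
            coords, side_dev = vertex_projection_coords(o, vertices,
                                                        42.0, 1.35)
            R = o.matrix()
            for k in range(12):
                u = R @ vertices.axes[k]
                exp = u[:2] * (42.0 / 1.35) + [o.dx, o.dy]
                np.testing.assert_allclose(coords[k], exp, atol=1e-6)
                exp_dev = abs(90.0 - np.degrees(np.arccos(
                    np.clip(u[2], -1, 1))))
                assert side_dev[k] == pytest.approx(exp_dev, abs=1e-6)


class TestRecords:
    def test_twelve_records_per_particle(self, vertices, params):
        rng = np.random.default_rng(5)
        recs = _records_for(random_orientations(7, rng), vertices, params)
        assert len(recs) == 7 * 12
        assert (recs.groupby("vrxParticleId").size() == 12).all()

    def test_pose_consistency_invariant(self, vertices, params):
        rng = np.random.default_rng(5)
        orients = random_orientations(5, rng)
        recs = _records_for(orients, vertices, params)
        for _, row in recs.iterrows():
            sub = Orientation(row.rlnAngleRot, row.rlnAngleTilt,
                              row.rlnAnglePsi)
            R = orients[int(row.vrxParticleId)].matrix()
            np.testing.assert_allclose(
                sub.matrix() @ [0, 0, 1],
                R @ vertices.axes[int(row.vrxVertex)], atol=1e-7)

    def test_truth_azimuth_accounts_for_triplet(self, vertices, params):
        truth = np.arange(12, dtype=float)
        rng = np.random.default_rng(5)
        recs = _records_for(random_orientations(4, rng), vertices, params,
                            truth=truth)
        expected = (truth[recs.vrxVertex.to_numpy()]
                    - 72.0 * recs.vrxTriplet.to_numpy()) % 60.0
        np.testing.assert_allclose(recs.vrxTrueAzimuth, expected, atol=1e-12)

    def test_seeded_triplet_choice_reproducible(self, vertices, params):
        rng = np.random.default_rng(5)
        orients = random_orientations(5, rng)
        a = _records_for(orients, vertices, params, seed=9)
        b = _records_for(orients, vertices, params, seed=9)
        assert a.equals(b)


class TestExtraction:
    def test_crop_matches_projection_oracle(self, clean_stack, vertices,
                                            phantom, params):
        """Noise-free crops correlate with the full-phantom projection
        rendered over the crop window."""
        subs = extract_subparticles(clean_stack, vertices, params, seed=4)
        subs = side_view_filter(drop_out_of_bounds(subs), 40.0)
        b = params.subparticle_box
        b2 = b // 2
        checked = 0
        for i in range(0, len(subs.table), 7):
            row = subs.table.iloc[i]
            full = project(phantom.full_map,
                           clean_stack.orientation(int(row.vrxParticleId)))
            cx, cy = int(row.rlnCoordinateX), int(row.rlnCoordinateY)
            window = full[cy - b2:cy - b2 + b, cx - b2:cx - b2 + b]
            cc = np.corrcoef(subs.images[i].ravel(), window.ravel())[0, 1]
            assert cc > 0.99
            checked += 1
        assert checked >= 5

    def test_count_conservation(self, clean_stack, vertices, params):
        subs = extract_subparticles(clean_stack, vertices, params, seed=4)
        n = len(clean_stack)
        assert len(subs.table) == 12 * n
        kept = side_view_filter(subs, 40.0)
        removed = side_view_filter(subs, 90.0)
        oob = subs.table.vrxOutOfBounds.sum()
        in_dev = (subs.table.vrxSideDev <= 40.0).sum()
        assert len(kept.table) == in_dev
        assert len(removed.table) == 12 * n
        assert oob + len(drop_out_of_bounds(subs).table) == 12 * n

    def test_out_of_bounds_records_have_blank_images(self, clean_stack,
                                                     vertices):
        # a large box forces out-of-bounds crops near the particle edge
        big = SelectionParams(subparticle_box=64, vertex_radius=42.0)
        subs = extract_subparticles(clean_stack, vertices, big, seed=4)
        oob = subs.table.vrxOutOfBounds.to_numpy().astype(bool)
        assert oob.any()
        assert np.all(subs.images[oob] == 0)


class TestSideViewFilter:
    def test_threshold_semantics_inclusive(self, vertices, params):
        rng = np.random.default_rng(2)
        recs = _records_for(random_orientations(50, rng), vertices, params)
        from vertexrec.simulate import ParticleStack
        stack = ParticleStack(images=np.zeros((len(recs), 4, 4),
                                              dtype=np.float32),
                              table=recs, pixel_size=1.35)
        kept = side_view_filter(stack, 40.0)
        assert (kept.table.vrxSideDev <= 40.0).all()
        assert len(kept.table) == (recs.vrxSideDev <= 40.0).sum()

    def test_90_degrees_is_identity_filter(self, vertices, params):
        rng = np.random.default_rng(2)
        recs = _records_for(random_orientations(20, rng), vertices, params)
        from vertexrec.simulate import ParticleStack
        stack = ParticleStack(images=np.zeros((len(recs), 4, 4),
                                              dtype=np.float32),
                              table=recs, pixel_size=1.35)
        assert len(side_view_filter(stack, 90.0).table) == len(recs)

    def test_order_preserved(self, vertices, params):
        rng = np.random.default_rng(2)
        recs = _records_for(random_orientations(20, rng), vertices, params)
        from vertexrec.simulate import ParticleStack
        stack = ParticleStack(images=np.zeros((len(recs), 4, 4),
                                              dtype=np.float32),
                              table=recs, pixel_size=1.35)
        kept = side_view_filter(stack, 40.0)
        dev = kept.table.vrxSideDev.to_numpy()
        orig = recs.vrxSideDev.to_numpy()
        assert list(dev) == [d for d in orig if d <= 40.0]

    def test_uniform_orientations_retain_sine_fraction(self, vertices,
                                                       params):
        """For uniform poses the vertex axes are uniform on the sphere, so
        the fraction within 40 degrees of the image plane is sin(40)."""
        rng = np.random.default_rng(31)
        recs = _records_for(random_orientations(2000, rng), vertices, params)
        frac = (recs.vrxSideDev <= 40.0).mean()
        assert frac == pytest.approx(np.sin(np.radians(40.0)), abs=0.01)

    def test_invalid_selection_params(self):
        with pytest.raises(ValueError):
            SelectionParams(max_side_dev=0.0)
        with pytest.raises(ValueError):
            SelectionParams(max_side_dev=95.0)
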