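"""Rigid superposition, hinge decomposition and interface-angle changes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vertexrec.conformation import (AtomicModel, DomainDefinition,
                                    hinge_transform, hinged_copy,
                                    interface_angle_change, paired_coords,
                                    superpose, synthetic_two_domain_chain)


def _apply(coords: dict, R: np.ndarray, t: np.ndarray) -> dict:
    return {i: R @ v + t for i, v in coords.items()}


def _random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


@pytest.fixture(scope="module")
def chain():
    return synthetic_two_domain_chain(seed=3)


class TestSuperpose:
    def test_identical_sets(self, chain):
        X = np.array(list(chain.values()))
        tr = superpose(X, X)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)

    def test_recovers_constructed_transform(self, chain):
        X = np.array(list(chain.values()))
        R = Rotation.from_euler("z", 30.0, degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 12.0])
        tr = superpose(X, X @ R.T + t)
        assert tr.angle == pytest.approx(30.0, abs=1e-9)
        assert tr.rmsd < 1e-6

    def test_rmsd_invariant_under_global_motion(self, chain):
        rng = np.random.default_rng(4)
        X = np.array(list(chain.values()))
        Y = X + rng.normal(scale=1.0, size=X.shape)
        base = superpose(X, Y).rmsd
        R, t = _random_rigid(rng)
        moved = superpose(X @ R.T + t, Y @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-8)

    def test_optimality_against_random_perturbations(self, chain):
        rng = np.random.default_rng(9)
        X = np.array(list(chain.values()))
        Y = X + rng.normal(scale=1.5, size=X.shape)
        tr = superpose(X, Y)

        def rmsd_of(R, t):
            return np.sqrt(((X @ R.T + t - Y) ** 2).sum(axis=1).mean())

        best = rmsd_of(tr.rotation, tr.translation)
        for _ in range(1000):
            dR = Rotation.from_rotvec(
                rng.normal(scale=0.05, size=3)).as_matrix()
            dt = rng.normal(scale=0.3, size=3)
            assert best <= rmsd_of(dR @ tr.rotation,
                                   tr.translation + dt) + 1e-12

    def test_reflection_case_yields_proper_rotation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        Y = X * np.array([1.0, 1.0, -1.0])       # mirrored target
        tr = superpose(X, Y)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_pairing_by_residue_intersection(self, chain):
        partial = {i: v for i, v in chain.items() if i % 2 == 0}
        X, Y = paired_coords(chain, partial)
        assert len(X) == len(partial)
        with pytest.raises(ValueError, match="3 paired"):
            paired_coords(chain, {1: chain[1], 2: chain[2]})


class TestHinge:
    def test_identical_chains_report_zero(self, chain):
        rep = hinge_transform(chain, chain)
        assert rep.angle == pytest.approx(0.0, abs=1e-9)
        assert rep.displacement == pytest.approx(0.0, abs=1e-9)

    def test_constructed_71_degree_hinge(self, chain):
        """A peripheral domain rotated 71 degrees about the linker pivot is
        recovered exactly, with the constructed centroid displacement."""
        opened = hinged_copy(chain, 71.0, axis=(1.0, 0.3, 0.0))
        rep = hinge_transform(chain, opened)
        assert rep.angle == pytest.approx(71.0, abs=1e-6)
        dom = DomainDefinition()
        pd_idx = [i for i in chain
                  if dom.pd_range[0] <= i <= dom.pd_range[1]]
        c0 = np.mean([chain[i] for i in pd_idx], axis=0)
        c1 = np.mean([opened[i] for i in pd_idx], axis=0)
        assert rep.displacement == pytest.approx(np.linalg.norm(c1 - c0),
                                                 abs=1e-6)

    def test_hinge_angle_is_symmetric(self, chain):
        opened = hinged_copy(chain, 47.0)
        a = hinge_transform(chain, opened).angle
        b = hinge_transform(opened, chain).angle
        assert a == pytest.approx(b, abs=1e-6)

    def test_global_motion_of_either_chain_ignored(self, chain):
        rng = np.random.default_rng(12)
        opened = hinged_copy(chain, 71.0)
        base = hinge_transform(chain, opened)
        R, t = _random_rigid(rng)
        moved = hinge_transform(chain, _apply(opened, R, t))
        assert moved.angle == pytest.approx(base.angle, abs=1e-6)
        assert moved.displacement == pytest.approx(base.displacement,
                                                   abs=1e-6)

    def test_missing_domain_residues_rejected(self, chain):
        cd_only = {i: v for i, v in chain.items() if i >= 94}
        with pytest.raises(ValueError, match="PD"):
            hinge_transform(cd_only, cd_only)

    def test_domain_ranges_validated(self):
        with pytest.raises(ValueError, match="ordered"):
            DomainDefinition(pd_range=(1, 95), linker_range=(84, 93))


class TestInterfaceAngle:
    def test_identical_states_report_zero(self, chain):
        other = _apply(chain, *_random_rigid(np.random.default_rng(2)))
        ang = interface_angle_change(chain, other, chain, other)
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_constructed_57_degree_change(self, chain):
        """Re-hinging chain B by 57 degrees between states is measured as a
        57-degree interface-angle change."""
        rng = np.random.default_rng(6)
        chain_b1 = _apply(chain, *_random_rigid(rng))
        R57 = Rotation.from_rotvec(
            np.radians(57.0) * np.array([0.0, 1.0, 0.0])).as_matrix()
        chain_b2 = {i: R57 @ v for i, v in chain_b1.items()}
        ang = interface_angle_change(chain, chain_b1, chain, chain_b2)
        assert ang == pytest.approx(57.0, abs=1e-6)

    def test_frame_independence(self, chain):
        rng = np.random.default_rng(8)
        b1 = _apply(chain, *_random_rigid(rng))
        b2 = _apply(hinged_copy(chain, 30.0), *_random_rigid(rng))
        base = interface_angle_change(chain, b1, chain, b2)
        Ra, ta = _random_rigid(rng)
        Rb, tb = _random_rigid(rng)
        moved = interface_angle_change(
            _apply(chain, Ra, ta), _apply(b1, Ra, ta),
            _apply(chain, Rb, tb), _apply(b2, Rb, tb))
        assert moved == pytest.approx(base, abs=1e-6)


class TestAtomicModelIO:
    def _write_pdb(self, path, chains):
        lines = []
        serial = 1
        for cname, coords in chains.items():
            for resnum in sorted(coords):
                x, y, z = coords[resnum]
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA {cname}{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
                serial += 1
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")

    def test_pdb_roundtrip_and_hinge(self, chain, tmp_path):
        """Synthetic two-chain model written as PDB: coordinates survive the
        round trip and the hinge measurement matches the in-memory value."""
        opened = hinged_copy(chain, 71.0)
        path = tmp_path / "synthetic_hinge.pdb"
        self._write_pdb(path, {"A": chain, "B": opened})
        model = AtomicModel.read(path)
        assert set(model.chain_names()) == {"A", "B"}
        ca = model.ca_coords("A")
        assert len(ca) == len(chain)
        np.testing.assert_allclose(ca[10], chain[10], atol=1e-3)
        rep = hinge_transform(model.ca_coords("A"), model.ca_coords("B"))
        assert rep.angle == pytest.approx(71.0, abs=0.05)

    def test_residue_range_selection(self, chain, tmp_path):
        path = tmp_path / "one.pdb"
        self._write_pdb(path, {"A": chain})
        model = AtomicModel.read(path)
        sel = model.ca_coords("A", residue_range=(94, 149))
        assert min(sel) >= 94 and max(sel) <= 149

    def test_missing_chain_named_in_error(self, chain, tmp_path):
        path = tmp_path / "one.pdb"
        self._write_pdb(path, {"A": chain})
        with pytest.raises(KeyError, match="'Z'"):
            AtomicModel.read(path).ca_coords("Z")
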