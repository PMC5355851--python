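"""Point-group algebra and pose conventions for icosahedral subparticle work.

Conventions
-----------
* Orientations are intrinsic ZYZ Euler triplets ``(rot, tilt, psi)`` in degrees
  with in-plane origin shifts ``(dx, dy)`` in pixels.  The associated rotation
  matrix ``R = Rz(psi) @ Ry(tilt) @ Rz(rot)`` transforms reference-map
  coordinates into the particle-image frame, the dominant single-particle
  metadata convention; a particle image is the projection of the rotated map
  along the image z axis.
* The icosahedral group ``I`` is built in the "222" setting: two-fold axes on
  the coordinate axes, five-fold axes derived from the icosahedron with
  vertices at the cyclic permutations of ``(0, ±1, ±phi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: Angle between neighbouring five-fold axes of an icosahedron, arccos(1/sqrt 5).
VERTEX_ANGLE_DEG = float(np.degrees(np.arccos(1.0 / np.sqrt(5.0))))


# ---------------------------------------------------------------------------
# rotation-matrix helpers

def is_rotation(matrix: np.ndarray, tol: float = 1e-10) -> bool:
    """True if ``matrix`` is a proper rotation (orthonormal, det +1) within tol."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return False
    return (np.abs(m @ m.T - np.eye(3)).max() < tol
            and abs(np.linalg.det(m) - 1.0) < tol)


def axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about ``axis`` (need not be unit)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def rotation_angle_deg(matrix: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, in [0, 180] degrees."""
    return float(np.degrees(np.linalg.norm(Rotation.from_matrix(matrix).as_rotvec())))


# ---------------------------------------------------------------------------
# orientations

def _wrap180(a: float) -> float:
    """Wrap an angle to [-180, 180)."""
    a = (a + 180.0) % 360.0 - 180.0
    return float(a)


@dataclass(frozen=True)
class Orientation:
    """A per-image pose: ZYZ Euler triplet (degrees) plus origin shifts (pixels)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot", _wrap180(self.rot))
        object.__setattr__(self, "psi", _wrap180(self.psi))
        tilt = float(self.tilt)
        if not (0.0 <= tilt <= 180.0):
            raise ValueError(f"tilt must lie in [0, 180] degrees, got {tilt}")
        object.__setattr__(self, "tilt", tilt)

    def matrix(self) -> np.ndarray:
        """Rotation matrix Rz(psi) @ Ry(tilt) @ Rz(rot) (map frame -> image frame)."""
        return Rotation.from_euler(
            "ZYZ", [self.psi, self.tilt, self.rot], degrees=True).as_matrix()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, dx: float = 0.0, dy: float = 0.0,
                    ) -> "Orientation":
        """Inverse of :meth:`matrix`.

        At gimbal-degenerate tilts (0 or 180) the triplet is canonicalized with
        ``rot = 0`` and psi absorbing the full in-plane angle.
        """
        if not is_rotation(matrix, tol=1e-8):
            raise ValueError("matrix is not a proper rotation")
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # scipy warns at gimbal lock
                psi, tilt, rot = Rotation.from_matrix(matrix).as_euler(
                    "ZYZ", degrees=True)
        return cls(rot=float(rot), tilt=float(tilt), psi=float(psi), dx=dx, dy=dy)

    def compose(self, other: "Orientation | np.ndarray") -> "Orientation":
        """Pose whose matrix is ``self.matrix() @ other_matrix``.

        Shifts of ``self`` are kept: composing on the right acts purely in the
        reference frame and does not move the particle in the image.
        """
        m = other.matrix() if isinstance(other, Orientation) else np.asarray(other)
        return Orientation.from_matrix(self.matrix() @ m, dx=self.dx, dy=self.dy)

    def inverse(self) -> "Orientation":
        """Pose with the transposed matrix and zero shifts."""
        return Orientation.from_matrix(self.matrix().T)

    def with_shifts(self, dx: float, dy: float) -> "Orientation":
        return replace(self, dx=dx, dy=dy)


# ---------------------------------------------------------------------------
# point groups

@dataclass(frozen=True)
class SymmetryGroup:
    """A finite rotation point group: symbol plus explicit operator stack."""

    symbol: str
    ops: np.ndarray  # (n, 3, 3)

    @property
    def order(self) -> int:
        return len(self.ops)

    def is_closed(self, tol: float = 1e-8) -> bool:
        """Every pairwise product is again in the set (group closure)."""
        for a in self.ops:
            for b in self.ops:
                prod = a @ b
                if min(np.abs(self.ops - prod).max(axis=(1, 2))) > tol:
                    return False
        return True


def _closure(generators: list[np.ndarray], max_order: int = 120) -> np.ndarray:
    """Close a generator set under composition (matrices deduped to 1e-6)."""
    ops: list[np.ndarray] = [np.eye(3)]

    def _known(m: np.ndarray) -> bool:
        return any(np.abs(o - m).max() < 1e-6 for o in ops)

    frontier = [g for g in generators if not _known(g)]
    ops.extend(frontier)
    while frontier:
        new: list[np.ndarray] = []
        for g in frontier:
            for o in list(ops):
                for prod in (g @ o, o @ g):
                    if not _known(prod):
                        ops.append(prod)
                        new.append(prod)
                        if len(ops) > max_order:
                            raise RuntimeError("group closure did not terminate")
        frontier = new
    # orthonormalize accumulated round-off
    out = np.array([Rotation.from_matrix(o).as_matrix() for o in ops])
    return out


def icosahedral_vertices() -> np.ndarray:
    """The 12 unit five-fold axes of the icosahedron in the 222 setting."""
    v = []
    for a in (1.0, -1.0):
        for b in (GOLDEN, -GOLDEN):
            v.extend([(0.0, a, b), (a, b, 0.0), (b, 0.0, a)])
    v = np.array(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def build_point_group(symbol: str) -> SymmetryGroup:
    """Build the rotation group ``I`` (order 60) or ``Cn`` (rotations about z).

    The icosahedral group is generated in the 222 setting (two-fold axes on the
    coordinate axes) from a two-fold about z and a five-fold about the vertex
    axis (0, 1, phi).
    """
    if symbol == "I":
        gens = [axis_angle_matrix([0, 0, 1], 180.0),
                axis_angle_matrix([1, 0, 0], 180.0),
                axis_angle_matrix([0.0, 1.0, GOLDEN], 72.0)]
        ops = _closure(gens)
        if len(ops) != 60:  # pragma: no cover - construction invariant
            raise RuntimeError(f"icosahedral closure gave {len(ops)} ops, not 60")
        return SymmetryGroup(symbol="I", ops=ops)
    if symbol.startswith("C") and symbol[1:].isdigit():
        n = int(symbol[1:])
        if n < 1:
            raise ValueError(f"cyclic order must be >= 1, got {symbol!r}")
        ops = np.array([axis_angle_matrix([0, 0, 1], 360.0 * k / n)
                        for k in range(n)])
        return SymmetryGroup(symbol=symbol, ops=ops)
    raise ValueError(
        f"unknown point-group symbol {symbol!r}: expected 'I' or 'Cn' (n >= 1)")


# ---------------------------------------------------------------------------
# vertex geometry

@dataclass(frozen=True)
class VertexSet:
    """The 12 five-fold vertex axes of an icosahedral particle."""

    axes: np.ndarray  # (12, 3) unit vectors
    stabilizer_order: int = 5

    def __len__(self) -> int:
        return len(self.axes)

    def frame(self, k: int) -> np.ndarray:
        """Rotation mapping the reference +z axis onto vertex axis ``k``.

        The minimal (geodesic) rotation is used; for the antipodal axis -z a
        180-degree flip about x is returned.  This matrix defines the
        subparticle reference frame of vertex ``k``.
        """
        return _z_to_axis(self.axes[k])

    def stabilizer(self, k: int) -> np.ndarray:
        """The 5 rotations about vertex axis ``k`` (the C5 site stabilizer)."""
        return np.array([axis_angle_matrix(self.axes[k], 72.0 * j)
                         for j in range(5)])


def _z_to_axis(axis: np.ndarray) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return axis_angle_matrix([1, 0, 0], 180.0)
    rotvec = np.cross(z, axis)
    rotvec = rotvec / np.linalg.norm(rotvec) * np.arccos(np.clip(c, -1, 1))
    return Rotation.from_rotvec(rotvec).as_matrix()


def vertex_axes(group: SymmetryGroup) -> VertexSet:
    """Five-fold vertex axes as the orbit of one vertex under the group."""
    if group.symbol != "I":
        raise ValueError("vertex axes are defined for the icosahedral group only")
    seed = np.array([0.0, 1.0, GOLDEN])
    seed = seed / np.linalg.norm(seed)
    orbit = group.ops @ seed
    axes: list[np.ndarray] = []
    for v in orbit:
        if not any(np.abs(v - a).max() < 1e-8 for a in axes):
            axes.append(v)
    axes_arr = np.array(sorted(axes, key=lambda a: (-a[2], a[1], a[0])))
    if len(axes_arr) != 12:  # pragma: no cover - construction invariant
        raise RuntimeError(f"expected 12 vertex axes, found {len(axes_arr)}")
    return VertexSet(axes=axes_arr)


# ---------------------------------------------------------------------------
# symmetry-equivalent poses

def equivalent_orientations(o: Orientation, vertex_index: int,
                            vertices: VertexSet) -> list[Orientation]:
    """The 5 particle poses equivalent under the C5 stabilizer of one vertex.

    All returned poses send the vertex axis to the same laboratory direction;
    they differ only by which of the five symmetric views of the rest of the
    particle is used.
    """
    if not 0 <= vertex_index < len(vertices):
        raise ValueError(f"vertex index {vertex_index} out of range 0-11")
    base = o.matrix()
    return [Orientation.from_matrix(base @ s, dx=o.dx, dy=o.dy)
            for s in vertices.stabilizer(vertex_index)]


def pick_random_equivalent(o: Orientation, vertex_index: int,
                           vertices: VertexSet,
                           rng: np.random.Generator) -> tuple[Orientation, int]:
    """Uniformly choose one of the 5 equivalent poses; returns (pose, index)."""
    j = int(rng.integers(5))
    s = vertices.stabilizer(vertex_index)[j]
    return Orientation.from_matrix(o.matrix() @ s, dx=o.dx, dy=o.dy), j
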