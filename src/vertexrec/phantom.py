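"""Ground-truth phantoms: double-shelled icosahedral particles with
symmetry-mismatched C6 vertex turrets.

The phantom emulates a double-shelled dsRNA-virus nucleocapsid: a smooth inner
protein shell, an outer shell with openings at the 12 five-fold vertices
(where no trimers sit), optional concentric "RNA" layers underneath, and a
six-fold turret of Gaussian arms at every vertex.  Each turret carries an
independent azimuthal offset in [0, 60) degrees about its own five-fold axis —
the symmetry mismatch that icosahedral averaging cannot resolve and that
localized reconstruction is designed to recover.

All components are additive, so for every vertex k the full map decomposes
exactly into ``hexamer_map(k) + all_but_one_map(k)`` voxelwise, which makes
signal-subtraction tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .symmetry import VertexSet, build_point_group, vertex_axes


@dataclass(frozen=True)
class DensityMap:
    """A cubic voxel grid with physical voxel size.

    Data is indexed ``[z, y, x]`` (MRC section order); the rotation center is
    the ``box // 2`` voxel in every dimension.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or len(set(d.shape)) != 1:
            raise ValueError(f"density grid must be cubic, got shape {d.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def box(self) -> int:
        return self.data.shape[0]

    @property
    def center(self) -> int:
        return self.box // 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and densities of the synthetic double-shelled particle.

    Distances are in Angstrom.  Defaults describe a desk-scale particle in a
    96-voxel box at 1.35 A/pixel; the true-scale particle (512 box) uses the
    same code with scaled radii.
    """

    box: int = 96
    voxel_size: float = 1.35
    inner_radius: float = 22.0
    inner_thickness: float = 4.0
    outer_radius: float = 30.0
    outer_thickness: float = 4.0
    rna_layer_count: int = 1
    rna_spacing: float = 30.0          # ~3 nm between concentric layers
    rna_thickness: float = 4.0
    vertex_hole_half_angle: float = 24.0   # outer-shell opening at five-folds
    vertex_hole_edge: float = 6.0          # angular cosine edge, degrees
    turret_height: float = 42.0        # turret center distance from origin
    turret_arm_radius: float = 11.0    # ring radius of the 6 arms
    turret_blob_sigma: float = 2.0     # Gaussian arm width
    shell_density: float = 1.0
    rna_density: float = 0.6
    turret_density: float = 1.6
    azimuths: tuple[float, ...] = field(default_factory=lambda: (0.0,) * 12)

    def __post_init__(self) -> None:
        if not (self.inner_radius < self.outer_radius < self.turret_height):
            raise ValueError("radii must satisfy inner < outer < turret height")
        if len(self.azimuths) != 12:
            raise ValueError("exactly 12 per-vertex azimuth offsets are required")
        if any(not (0.0 <= a < 60.0) for a in self.azimuths):
            raise ValueError("azimuth offsets must lie in [0, 60) degrees")
        extent = (np.hypot(self.turret_height, self.turret_arm_radius)
                  + 3.0 * self.turret_blob_sigma)
        if extent > self.box / 2 * self.voxel_size:
            raise ValueError(
                f"turret (extent {extent:.1f} A) overlaps the box boundary "
                f"({self.box / 2 * self.voxel_size:.1f} A half-width)")

    def with_azimuths(self, azimuths) -> "PhantomSpec":
        from dataclasses import replace
        return replace(self, azimuths=tuple(float(a) for a in azimuths))

    def random_azimuths(self, rng: np.random.Generator) -> "PhantomSpec":
        return self.with_azimuths(rng.uniform(0.0, 60.0, size=12))


def _radius_grid(box: int, voxel_size: float) -> tuple[np.ndarray, ...]:
    c = box // 2
    ax = (np.arange(box) - c) * voxel_size
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    return x, y, z, r


def _soft_shell(r: np.ndarray, radius: float, thickness: float,
                edge: float = 2.0) -> np.ndarray:
    """Radial shell of given mean radius/thickness with cosine edges (A)."""
    half = thickness / 2.0
    d = np.abs(r - radius)
    out = np.zeros_like(r)
    out[d <= half] = 1.0
    ramp = (d > half) & (d < half + edge)
    out[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - half) / edge))
    return out


class Phantom:
    """A built phantom with exact additive per-vertex turret companions."""

    def __init__(self, spec: PhantomSpec, vertices: VertexSet | None = None):
        self.spec = spec
        self.vertices = vertices or vertex_axes(build_point_group("I"))
        self._shells = self._build_shells()
        self._turrets = [self._build_turret(k) for k in range(12)]
        full = self._shells.copy()
        for t in self._turrets:
            full += t
        self.full_map = DensityMap(full, spec.voxel_size)

    # -- components -------------------------------------------------------
    def _build_shells(self) -> np.ndarray:
        s = self.spec
        x, y, z, r = _radius_grid(s.box, s.voxel_size)
        grid = s.shell_density * _soft_shell(r, s.inner_radius, s.inner_thickness)
        outer = s.shell_density * _soft_shell(r, s.outer_radius, s.outer_thickness)
        # openings at the five-fold vertices (no trimers under the turrets)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.stack([x, y, z], axis=-1) / r[..., None]
        unit = np.nan_to_num(unit)
        cosang = np.clip(np.abs(unit @ self.vertices.axes.T).max(axis=-1), -1, 1)
        ang = np.degrees(np.arccos(cosang))
        hole = np.ones_like(r)
        a0, w = s.vertex_hole_half_angle, s.vertex_hole_edge
        hole[ang <= a0] = 0.0
        ramp = (ang > a0) & (ang < a0 + w)
        hole[ramp] = 0.5 * (1.0 - np.cos(np.pi * (ang[ramp] - a0) / w))
        grid += outer * hole
        for i in range(s.rna_layer_count):
            radius = s.inner_radius - 8.0 - i * s.rna_spacing
            if radius <= s.rna_thickness:
                raise ValueError(
                    f"RNA layer {i} radius {radius:.1f} A does not fit the box")
            grid += s.rna_density * _soft_shell(r, radius, s.rna_thickness)
        return grid

    def _build_turret(self, k: int) -> np.ndarray:
        """Six Gaussian arms about vertex axis k at the vertex azimuth offset.

        Arm centers are expressed in the canonical vertex frame (the minimal
        rotation mapping +z to the vertex axis), so the recorded azimuth is
        directly the apparent turret azimuth in the subparticle frame.
        """
        s = self.spec
        frame = self.vertices.frame(k)
        grid = np.zeros((s.box, s.box, s.box))
        c = s.box // 2
        for m in range(6):
            phi = np.radians(s.azimuths[k] + 60.0 * m)
            local = np.array([s.turret_arm_radius * np.cos(phi),
                              s.turret_arm_radius * np.sin(phi),
                              s.turret_height])
            center = frame @ local
            _add_gaussian(grid, c, s.voxel_size, center,
                          s.turret_blob_sigma, s.turret_density)
        return grid

    # -- companions -------------------------------------------------------
    def hexamer_map(self, k: int) -> DensityMap:
        """Density of vertex-k turret alone (additive companion)."""
        return DensityMap(self._turrets[k].copy(), self.spec.voxel_size)

    def all_but_one_map(self, k: int) -> DensityMap:
        """Full phantom minus vertex-k turret, exactly (voxelwise)."""
        return DensityMap(self.full_map.data - self._turrets[k],
                          self.spec.voxel_size)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom and its per-vertex companion decompositions."""
    return Phantom(spec)


def turret_reference(spec: PhantomSpec, box: int, azimuth: float = 0.0,
                     ) -> DensityMap:
    """Canonical turret map: C6 arms about +z, ring centered on the box center.

    This is the reference used for azimuth assignment and as ground truth for
    localized reconstructions; a subparticle crop is centered on the turret
    center, so the reference ring sits at the box center rather than at the
    turret's radial position in the particle.
    """
    s = spec
    grid = np.zeros((box, box, box))
    c = box // 2
    for m in range(6):
        phi = np.radians(azimuth + 60.0 * m)
        center = np.array([s.turret_arm_radius * np.cos(phi),
                           s.turret_arm_radius * np.sin(phi), 0.0])
        _add_gaussian(grid, c, s.voxel_size, center,
                      s.turret_blob_sigma, s.turret_density)
    return DensityMap(grid, s.voxel_size)


def turret_reference_mask(spec: PhantomSpec, box: int,
                          margin_sigma: float = 3.0) -> np.ndarray:
    """Boolean arm-region mask of the canonical (azimuth 0) turret reference."""
    c = box // 2
    ax = (np.arange(box) - c) * spec.voxel_size
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([x, y, z], axis=-1)
    radius = margin_sigma * spec.turret_blob_sigma
    mask = np.zeros(x.shape, dtype=bool)
    for m in range(6):
        phi = np.radians(60.0 * m)
        cen = np.array([spec.turret_arm_radius * np.cos(phi),
                        spec.turret_arm_radius * np.sin(phi), 0.0])
        mask |= ((pts - cen) ** 2).sum(axis=-1) <= radius * radius
    return mask


def _add_gaussian(grid: np.ndarray, center_voxel: int, voxel_size: float,
                  pos_ang: np.ndarray, sigma_ang: float, amp: float) -> None:
    """Accumulate a 3D Gaussian into ``grid`` (only within a 4-sigma subbox)."""
    box = grid.shape[0]
    pos_vox = pos_ang / voxel_size + center_voxel    # (x, y, z) voxel coords
    sigma_vox = sigma_ang / voxel_size
    r = int(np.ceil(4.0 * sigma_vox))
    lo = np.maximum(np.floor(pos_vox).astype(int) - r, 0)
    hi = np.minimum(np.floor(pos_vox).astype(int) + r + 2, box)
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    zs = np.arange(lo[2], hi[2])
    dz2 = (zs - pos_vox[2])[:, None, None] ** 2
    dy2 = (ys - pos_vox[1])[None, :, None] ** 2
    dx2 = (xs - pos_vox[0])[None, None, :] ** 2
    grid[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += amp * np.exp(
        -(dx2 + dy2 + dz2) / (2.0 * sigma_vox ** 2))


def turret_mask(spec: PhantomSpec, vertices: VertexSet, k: int,
                margin_sigma: float = 3.0) -> np.ndarray:
    """Boolean mask of the vertex-k turret region in the full-particle grid."""
    s = spec
    x, y, z, _ = _radius_grid(s.box, s.voxel_size)
    pts = np.stack([x, y, z], axis=-1)
    frame = vertices.frame(k)
    radius = margin_sigma * s.turret_blob_sigma
    mask = np.zeros(x.shape, dtype=bool)
    for m in range(6):
        phi = np.radians(s.azimuths[k] + 60.0 * m)
        local = np.array([s.turret_arm_radius * np.cos(phi),
                          s.turret_arm_radius * np.sin(phi),
                          s.turret_height])
        center = frame @ local
        d2 = ((pts - center) ** 2).sum(axis=-1)
        mask |= d2 <= radius * radius
    return mask
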