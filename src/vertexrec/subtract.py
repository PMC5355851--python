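"""Partial signal subtraction: remove "all-but-one" density from particle
images, isolating the signal of a single vertex turret.

The subtraction reference for vertex k is the full map multiplied by the
complement of a soft mask around the kept turret; the kept map is the full
map times the mask, so reference + kept = full voxelwise.  The mask is a
cylindrical cap along the vertex axis (the turret sits above the outer shell,
so a cap cleanly separates it from shells and RNA) with raised-cosine edges.

The CTF-modulated projection of the reference is subtracted from the particle
image, either with unit amplitude (calibrated simulations) or with a
per-image least-squares amplitude fit over a background annulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctf import CTFParams, apply_ctf
from .phantom import DensityMap
from .projection import project
from .symmetry import Orientation, VertexSet


@dataclass(frozen=True)
class MaskParams:
    """Soft cylindrical-cap mask around a kept vertex turret (Angstrom)."""

    axial_min: float = 35.0       # cap starts above the outer shell
    radial: float = 21.0          # cylinder radius around the vertex axis
    edge_voxels: float = 3.0      # raised-cosine edge width, in voxels


@dataclass(frozen=True)
class SubtractionReference:
    """All-but-one reference map plus its complementary kept-turret map."""

    map: DensityMap               # density of everything except the kept turret
    kept: DensityMap              # full * mask
    mask: np.ndarray
    vertex_index: int
    params: MaskParams


def _soft_step_up(x: np.ndarray, x0: float, width: float) -> np.ndarray:
    """0 below x0 - width, 1 above x0, raised-cosine in between."""
    out = np.ones_like(x)
    out[x < x0 - width] = 0.0
    ramp = (x >= x0 - width) & (x < x0)
    out[ramp] = 0.5 * (1.0 - np.cos(np.pi * (x[ramp] - (x0 - width)) / width))
    return out


def make_vertex_mask(box: int, voxel_size: float, axis: np.ndarray,
                     params: MaskParams) -> np.ndarray:
    """Soft [0, 1] cylindrical-cap mask along ``axis`` through the box center."""
    edge = params.edge_voxels * voxel_size
    half = box // 2 * voxel_size
    if params.radial + edge > half or params.axial_min >= half:
        raise ValueError(
            f"mask (radial {params.radial} A + edge, axial_min "
            f"{params.axial_min} A) exceeds the box half-width {half:.1f} A")
    c = box // 2
    ax = (np.arange(box) - c) * voxel_size
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([x, y, z], axis=-1)
    t = pts @ axis                              # axial coordinate
    rho = np.linalg.norm(pts - t[..., None] * axis, axis=-1)
    w = _soft_step_up(t, params.axial_min, edge)
    w *= _soft_step_up(-rho, -(params.radial - edge), edge)
    return w


def make_subtraction_reference(full: DensityMap, vertices: VertexSet,
                               vertex_index: int,
                               params: MaskParams | None = None,
                               ) -> SubtractionReference:
    """Split the full map into kept-turret and all-but-one components."""
    if not 0 <= vertex_index < len(vertices):
        raise ValueError(f"vertex index {vertex_index} out of range 0-11")
    params = params or MaskParams()
    mask = make_vertex_mask(full.box, full.voxel_size,
                            vertices.axes[vertex_index], params)
    kept = DensityMap(full.data * mask, full.voxel_size)
    ref = DensityMap(full.data * (1.0 - mask), full.voxel_size)
    return SubtractionReference(map=ref, kept=kept, mask=mask,
                                vertex_index=vertex_index, params=params)


def fit_scale(image: np.ndarray, reference_projection: np.ndarray,
              annulus: tuple[float, float] | None = None) -> float:
    """Least-squares amplitude of the reference within a background annulus.

    The annulus (inner, outer radius in pixels) defaults to 25-48% of the box,
    the region dominated by shell signal rather than the kept turret.
    """
    box = image.shape[0]
    if annulus is None:
        annulus = (0.25 * box, 0.48 * box)
    c = box // 2
    yy, xx = np.mgrid[0:box, 0:box]
    r = np.hypot(xx - c, yy - c)
    sel = (r >= annulus[0]) & (r <= annulus[1])
    p = reference_projection[sel]
    denom = float((p * p).sum())
    if denom <= 0:
        return 1.0
    return float((p * image[sel]).sum() / denom)


def subtract_projection(image: np.ndarray, ref: SubtractionReference,
                        o: Orientation, ctf: CTFParams | None = None,
                        scale_mode: str = "fit",
                        reference_projection: np.ndarray | None = None,
                        ) -> np.ndarray:
    """Subtract the (CTF-modulated) reference projection from one image.

    ``scale_mode`` is ``"unit"`` (s = 1, for calibrated/noise-free data) or
    ``"fit"`` (per-image least-squares amplitude over a background annulus).
    A precomputed ``reference_projection`` (un-modulated) may be passed to
    avoid recomputation.
    """
    if image.shape[0] != ref.map.box:
        raise ValueError(
            f"image box {image.shape[0]} does not match reference box "
            f"{ref.map.box}")
    p = (reference_projection if reference_projection is not None
         else project(ref.map, o))
    if ctf is not None:
        p = apply_ctf(p, ctf, ref.map.voxel_size)
    if scale_mode == "unit":
        s = 1.0
    elif scale_mode == "fit":
        s = fit_scale(image, p)
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    return image - s * p


class SubtractionEngine:
    """Fast all-but-one subtraction for whole stacks.

    Projecting the full-box reference for every (particle, vertex) pair is
    wasteful: the all-but-one projection equals the full-map projection minus
    the kept-turret projection, the full-map projection is shared by all 12
    vertices of a particle, and the kept turret has small support.  The engine
    therefore projects the full map once per particle and the kept component
    from a small crop centered on the turret, pasted back at the projected
    turret position.
    """

    def __init__(self, full: DensityMap, vertices: VertexSet,
                 params: MaskParams | None = None, crop_box: int = 44):
        self.full = full
        self.vertices = vertices
        self.params = params or MaskParams()
        self.crop_box = crop_box
        self.references = [make_subtraction_reference(full, vertices, k,
                                                      self.params)
                           for k in range(12)]
        self._crops: list[DensityMap] = []
        self._offsets: list[np.ndarray] = []
        c = full.center
        b2 = crop_box // 2
        for k in range(12):
            kept = self.references[k].kept.data
            total = kept.sum()
            if total <= 0:
                cv = np.round(self.vertices.axes[k]
                              * (self.params.axial_min / full.voxel_size)
                              ).astype(int) + c
            else:
                grids = np.meshgrid(*(np.arange(full.box),) * 3, indexing="ij")
                zc, yc, xc = [float((kept * g).sum() / total) for g in grids]
                cv = np.round([xc, yc, zc]).astype(int)   # math (x, y, z)
            lo = cv[::-1] - b2                            # index (z, y, x)
            hi = lo + crop_box
            if lo.min() < 0 or hi.max() > full.box:
                raise ValueError("kept-turret crop exceeds the map box; "
                                 "reduce crop_box or the mask radius")
            data = kept[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            outside = total - data.sum()
            if total > 0 and outside > 1e-6 * total:
                raise ValueError(
                    f"kept-turret density leaks outside the crop box "
                    f"({outside / total:.2e} of total); increase crop_box")
            self._crops.append(DensityMap(np.ascontiguousarray(data),
                                          full.voxel_size))
            self._offsets.append((cv - c).astype(float))

    def kept_projection(self, o: Orientation, k: int, box: int) -> np.ndarray:
        """Projection of the kept-turret map of vertex k in the parent frame."""
        R = o.matrix()
        u = R @ self._offsets[k]                    # voxels, image frame
        total = u[:2] + np.array([o.dx, o.dy])
        ti = np.round(total).astype(int)
        tf = total - ti
        patch = project(self._crops[k],
                        Orientation.from_matrix(R, dx=tf[0], dy=tf[1]))
        out = np.zeros((box, box))
        b2 = self.crop_box // 2
        cx, cy = box // 2 + ti[0], box // 2 + ti[1]
        x0, x1 = cx - b2, cx - b2 + self.crop_box
        y0, y1 = cy - b2, cy - b2 + self.crop_box
        sx0, sy0 = max(0, -x0), max(0, -y0)
        sx1 = self.crop_box - max(0, x1 - box)
        sy1 = self.crop_box - max(0, y1 - box)
        if sx1 > sx0 and sy1 > sy0:
            out[max(0, y0):max(0, y0) + (sy1 - sy0),
                max(0, x0):max(0, x0) + (sx1 - sx0)] = patch[sy0:sy1, sx0:sx1]
        return out

    def subtract(self, image: np.ndarray, o: Orientation, k: int,
                 ctf: CTFParams | None = None, scale_mode: str = "fit",
                 full_projection: np.ndarray | None = None) -> np.ndarray:
        """All-but-one subtraction of vertex k from one particle image."""
        if full_projection is None:
            full_projection = project(self.full, o)
        p = full_projection - self.kept_projection(o, k, image.shape[0])
        if ctf is not None:
            p = apply_ctf(p, ctf, self.full.voxel_size)
        s = 1.0 if scale_mode == "unit" else fit_scale(image, p)
        return image - s * p
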