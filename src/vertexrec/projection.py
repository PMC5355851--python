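"""Real-space projection and map resampling.

A particle image is the line integral of the reference map, rotated by the
pose matrix (map frame -> image frame), along the image z axis, then shifted
by the pose's origin offsets.  Sampling uses trilinear interpolation, which
sets the accuracy floor (~0.1%) quoted by the exactness tests.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .ctf import CTFParams, apply_ctf
from .phantom import DensityMap
from .symmetry import Orientation, SymmetryGroup


def _index_coords(box: int) -> np.ndarray:
    """Math (x, y, z) coordinates, relative to box//2, of every voxel; (3, N)."""
    c = box // 2
    ax = np.arange(box) - c
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([x.ravel(), y.ravel(), z.ravel()])


_COORD_CACHE: dict[int, np.ndarray] = {}


def _cached_coords(box: int) -> np.ndarray:
    if box not in _COORD_CACHE:
        _COORD_CACHE[box] = _index_coords(box)
    return _COORD_CACHE[box]


def sample_rotated(data: np.ndarray, matrix: np.ndarray,
                   shift_xy: tuple[float, float] = (0.0, 0.0),
                   order: int = 1) -> np.ndarray:
    """Resample ``data`` in the frame rotated by ``matrix`` (map -> frame).

    Output voxel at math position q holds the map value at R^T (q - s), i.e.
    the returned volume is the map rotated by R and translated by s in-plane.
    ``order`` selects the spline degree (1 = trilinear default, 3 = cubic
    for higher accuracy at ~3x the cost).
    """
    box = data.shape[0]
    c = box // 2
    q = _cached_coords(box).astype(float)
    q = q - np.array([shift_xy[0], shift_xy[1], 0.0])[:, None]
    p = matrix.T @ q                      # back to map frame
    # math (x, y, z) -> index (z, y, x)
    idx = p[::-1] + c
    vals = ndimage.map_coordinates(data, idx, order=order,
                                   mode="grid-constant", cval=0.0)
    return vals.reshape(box, box, box)


def project(density: DensityMap, o: Orientation,
            ctf: CTFParams | None = None, order: int = 1) -> np.ndarray:
    """Project the map along the viewing axis after rotating by ``o``.

    The projection is shifted by the pose's (dx, dy); if CTF parameters are
    given the image is modulated by the weak-phase CTF in Fourier space.
    """
    rotated = sample_rotated(density.data, o.matrix(), (o.dx, o.dy),
                             order=order)
    image = rotated.sum(axis=0) * density.voxel_size
    if ctf is not None:
        image = apply_ctf(image, ctf, density.voxel_size)
    return image


def project_batch(density: DensityMap, matrices: np.ndarray) -> np.ndarray:
    """Project the map under a stack of rotation matrices in one pass.

    Used for azimuth grid searches; no shifts or CTF are applied here.
    """
    box = density.box
    c = box // 2
    q = _cached_coords(box).astype(float)
    p = np.einsum("nij,jk->nik", matrices.transpose(0, 2, 1), q)  # (n, 3, N)
    idx = p[:, ::-1, :] + c
    n = len(matrices)
    vals = ndimage.map_coordinates(density.data,
                                   idx.transpose(1, 0, 2).reshape(3, -1),
                                   order=1, mode="grid-constant", cval=0.0)
    vols = vals.reshape(n, box, box, box)
    return vols.sum(axis=1) * density.voxel_size


class FourierProjector:
    """Fast repeated projections of one map via central-slice extraction.

    The map's 3D transform is computed once on a zero-padded grid (default
    2x oversampling); each projection is a trilinear slice gather plus a 2D
    inverse FFT.  Agrees with the real-space projector to the interpolation
    floor; used where many projections of the same map are needed (azimuth
    grid searches).
    """

    def __init__(self, density: DensityMap, pad: int = 2):
        box = density.box
        self.box = box
        self.voxel_size = density.voxel_size
        self.pad_box = pad * box
        big = np.zeros((self.pad_box,) * 3)
        big[:box, :box, :box] = density.data
        c = box // 2
        big = np.roll(big, (-c, -c, -c), axis=(0, 1, 2))
        self.F3 = np.fft.fftn(big)
        f1 = np.fft.fftfreq(box)
        fx = np.tile(f1, box)
        fy = np.repeat(f1, box)
        self._plane = np.stack([fx, fy, np.zeros_like(fx)])

    def project(self, matrices: np.ndarray) -> np.ndarray:
        """Projections for a stack of pose matrices; (n, box, box) output."""
        matrices = np.asarray(matrices)
        if matrices.ndim == 2:
            matrices = matrices[None]
        n = len(matrices)
        pb = self.pad_box
        q = np.einsum("nij,jk->nik", matrices.transpose(0, 2, 1), self._plane)
        q = q.transpose(1, 0, 2).reshape(3, -1) * pb     # padded index units
        i0 = np.floor(q).astype(int)
        frac = q - i0
        vals = np.zeros(q.shape[1], dtype=complex)
        F3 = self.F3
        for corner in range(8):
            bits = [(corner >> d) & 1 for d in range(3)]
            w = np.ones(q.shape[1])
            idx = np.empty_like(i0)
            for d in range(3):
                w *= frac[d] if bits[d] else (1.0 - frac[d])
                idx[d] = (i0[d] + bits[d]) % pb
            vals += w * F3[idx[2], idx[1], idx[0]]
        F2 = vals.reshape(n, self.box, self.box)
        imgs = np.fft.ifft2(F2).real
        return np.fft.fftshift(imgs, axes=(-2, -1)) * self.voxel_size


def resample_region(density: DensityMap, matrix: np.ndarray,
                    center_offset: np.ndarray, box_out: int) -> DensityMap:
    """Resample a subregion of a map into a local frame.

    The output voxel at local math position q holds the map value at
    ``matrix @ q + center_offset`` (offset in Angstrom from the map center).
    Used to pull a vertex region of a whole-particle map into the subparticle
    reference frame for comparison with localized reconstructions.
    """
    c_out = box_out // 2
    ax = np.arange(box_out) - c_out
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    q = np.stack([x.ravel(), y.ravel(), z.ravel()]).astype(float)
    p = matrix @ q + (np.asarray(center_offset, float)
                      / density.voxel_size)[:, None]
    idx = p[::-1] + density.center
    vals = ndimage.map_coordinates(density.data, idx, order=1,
                                   mode="grid-constant", cval=0.0)
    return DensityMap(vals.reshape(box_out, box_out, box_out),
                      density.voxel_size)


def rotate_map(density: DensityMap, matrix: np.ndarray,
               order: int = 1) -> DensityMap:
    """The map rotated by a proper rotation about the box center."""
    return DensityMap(sample_rotated(density.data, matrix, order=order),
                      density.voxel_size)


def symmetrize_map(density: DensityMap, group: SymmetryGroup) -> DensityMap:
    """Average the map over all operators of a point group (real space)."""
    acc = np.zeros_like(density.data, dtype=float)
    for op in group.ops:
        acc += sample_rotated(density.data, op)
    return DensityMap(acc / len(group.ops), density.voxel_size)
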