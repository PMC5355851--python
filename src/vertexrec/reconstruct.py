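"""Direct-Fourier reconstruction, azimuth assignment, FSC and sharpening.

Backprojection inserts each image's 2D Fourier transform as a central slice
into the 3D transform (trilinear spreading, CTF-weighted Wiener-style
normalization), with point-group symmetry applied by pose expansion.
Gold-standard half-maps are reconstructed from even/odd parent-particle
subsets so the half-sets never share a particle.

Azimuth assignment is a deterministic grid search replacing maximum-
likelihood classification: for each subtracted subparticle the in-plane
hexamer azimuth maximizing the normalized cross-correlation against
projections of a C6 reference is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .ctf import CTFParams, ctf_2d
from .phantom import DensityMap
from .projection import FourierProjector, project_batch
from .symmetry import Orientation, build_point_group


# ---------------------------------------------------------------------------
# backprojection

class _Accumulator:
    """Fourier-space accumulation buffers for one reconstruction."""

    def __init__(self, box: int):
        self.box = box
        self.num = np.zeros(box ** 3, dtype=complex)
        self.den = np.zeros(box ** 3)

    def insert(self, qidx: np.ndarray, vals: np.ndarray,
               wts: np.ndarray) -> None:
        """Trilinear scatter of slice samples into the unshifted transform."""
        box = self.box
        keep = np.max(np.abs(qidx), axis=0) <= box / 2 - 1
        q = qidx[:, keep]
        v = vals[keep]
        w = wts[keep]
        i0 = np.floor(q).astype(int)
        frac = q - i0
        flats, weights = [], []
        for corner in range(8):
            bits = [(corner >> d) & 1 for d in range(3)]
            weight = np.ones(q.shape[1])
            idx = np.empty_like(i0)
            for d in range(3):
                weight *= frac[d] if bits[d] else (1.0 - frac[d])
                idx[d] = (i0[d] + bits[d]) % box
            flats.append((idx[2] * box + idx[1]) * box + idx[0])  # [z, y, x]
            weights.append(weight)
        flat = np.concatenate(flats)
        wt = np.concatenate(weights)
        v8 = np.tile(v, 8) * wt
        w8 = np.tile(w, 8) * wt
        n = box ** 3
        self.num += np.bincount(flat, v8.real, n)
        self.num += 1j * np.bincount(flat, v8.imag, n)
        self.den += np.bincount(flat, w8, n)

    def finish(self, pixel_size: float) -> DensityMap:
        box = self.box
        den = self.den
        eps = 1e-3 * den[den > 0].mean() if (den > 0).any() else 1e-3
        F3 = (self.num / (den + eps)).reshape(box, box, box)
        vol = np.fft.fftshift(np.fft.ifftn(F3).real)
        return DensityMap(vol / _gridding_correction(box), pixel_size)


def _accumulate(acc_for_image, images, orientations, ctfs, group_ops,
                pixel_size: float) -> None:
    """Insert every image (expanded over the symmetry operators) into the
    accumulator selected by ``acc_for_image(i)``."""
    images = np.asarray(images)
    box = images.shape[-1]
    f1 = np.fft.fftfreq(box)                       # cycles / pixel
    fx = np.tile(f1, box)
    fy = np.repeat(f1, box)
    plane = np.stack([fx, fy, np.zeros_like(fx)])  # (3, box*box)
    n_ops = len(group_ops)
    for i, (img, o) in enumerate(zip(images, orientations)):
        ctf = ctfs[i] if ctfs is not None else None
        F = np.fft.fft2(np.fft.ifftshift(img))
        if o.dx or o.dy:
            F = F * np.exp(2j * np.pi * (f1[None, :] * o.dx
                                         + f1[:, None] * o.dy))
        c2d = (ctf_2d(ctf, img.shape, pixel_size) if ctf is not None
               else np.ones(img.shape))
        vals = np.tile((F * c2d).ravel(), n_ops)
        wts = np.tile((c2d * c2d).ravel(), n_ops)
        R = o.matrix()
        mats = np.array([(R @ G).T for G in group_ops])   # (n_ops, 3, 3)
        q = np.einsum("nij,jk->nik", mats, plane)
        q = q.transpose(1, 0, 2).reshape(3, -1) * box
        acc_for_image(i).insert(q, vals, wts)


def backproject(images: np.ndarray, orientations: list[Orientation],
                ctfs: list[CTFParams | None] | None, pixel_size: float,
                symmetry: str = "C1") -> DensityMap:
    """Reconstruct a map from images and poses by direct Fourier inversion.

    Each image's 2D transform is inserted as a central slice at every pose of
    the symmetry expansion ``R @ G`` over the requested point group.  The
    accumulated transform is normalized as
    ``sum(CTF * data) / (sum(CTF^2) + eps)`` with
    ``eps = 1e-3 * mean(CTF^2)`` over filled voxels (Wiener-style), followed
    by trilinear gridding correction in real space.
    """
    images = np.asarray(images)
    if len(images) < 2:
        raise ValueError("backprojection needs at least 2 images")
    box = images.shape[-1]
    if box % 2:
        raise ValueError("box size must be even")
    group = build_point_group(symmetry)
    mats = np.array([o.matrix() for o in orientations])
    if np.allclose(mats, mats[0], atol=1e-8):
        import warnings
        warnings.warn("all poses identical: Fourier space will be filled "
                      "anisotropically", stacklevel=2)
    acc = _Accumulator(box)
    _accumulate(lambda i: acc, images, orientations, ctfs, group.ops,
                pixel_size)
    return acc.finish(pixel_size)


def _gridding_correction(box: int) -> np.ndarray:
    c = box // 2
    d = (np.arange(box) - c) / box
    s = np.sinc(d) ** 2
    return s[:, None, None] * s[None, :, None] * s[None, None, :]


def backproject_halves(images, orientations, ctfs, pixel_size: float,
                       parent_ids: np.ndarray, symmetry: str = "C1",
                       ) -> tuple[DensityMap, DensityMap, DensityMap]:
    """Full map plus gold-standard half-maps split by even/odd parent id.

    The half-sets partition at the parent-particle level (never by
    subparticle), so the two half-maps share no particle; the full map reuses
    the same single accumulation pass.
    """
    images = np.asarray(images)
    if len(images) < 2:
        raise ValueError("backprojection needs at least 2 images")
    box = images.shape[-1]
    if box % 2:
        raise ValueError("box size must be even")
    parent_ids = np.asarray(parent_ids)
    group = build_point_group(symmetry)
    accs = (_Accumulator(box), _Accumulator(box))
    _accumulate(lambda i: accs[int(parent_ids[i]) % 2],
                images, orientations, ctfs, group.ops, pixel_size)
    total = _Accumulator(box)
    total.num = accs[0].num + accs[1].num
    total.den = accs[0].den + accs[1].den
    return (total.finish(pixel_size), accs[0].finish(pixel_size),
            accs[1].finish(pixel_size))


# ---------------------------------------------------------------------------
# azimuth assignment

def assign_hexamer_azimuth(subs, reference: DensityMap, step: float = 2.0,
                           mask_radius: float | None = None,
                           ctf_pad: int | None = None) -> pd.DataFrame:
    """Assign the in-plane hexamer azimuth of each subparticle by grid search.

    For every record the azimuth in [0, 60) maximizing the normalized
    cross-correlation between the (shift-corrected) subparticle image and the
    CTF-modulated projection of the C6 reference is returned, together with
    the correlation score.  Blank images yield NaN azimuths, flagged in the
    ``vrxAzimuthOk`` column.  Accuracy is best for side views; for top views
    (axis near the beam) the arms overlap their own symmetry copies and the
    assignment degrades.
    """
    if reference.box != subs.images.shape[-1]:
        raise ValueError("reference box must match subparticle box")
    azimuths = np.arange(0.0, 60.0, step)
    box = reference.box
    if mask_radius is None:
        mask_radius = 0.45 * box
    c = box // 2
    yy, xx = np.mgrid[0:box, 0:box]
    mask = np.hypot(xx - c, yy - c) <= mask_radius

    rz = np.array([_rz(a) for a in azimuths])
    out_az = np.full(len(subs.table), np.nan)
    out_cc = np.full(len(subs.table), np.nan)
    ok = np.zeros(len(subs.table), dtype=bool)
    for i in range(len(subs.table)):
        row = subs.table.iloc[i]
        img = subs.images[i].astype(float)
        if row.get("rlnOriginX", 0.0) or row.get("rlnOriginY", 0.0):
            img = ndimage.shift(img, (-row.rlnOriginY, -row.rlnOriginX),
                                order=1, mode="nearest")
        sel = img[mask]
        if sel.std() == 0:
            continue
        R = subs.orientation(i).matrix()
        mats = np.einsum("ij,njk->nik", R, rz)
        projs = project_batch(reference, mats)
        ctf = subs.ctf(i)
        if ctf is not None:
            # Modulate at the parent-image scale, pasted at the subparticle's
            # parent coordinates, so the CTF point-spread tails (and their
            # wrap-around on the parent grid) match the data exactly.
            pad = ctf_pad if ctf_pad and ctf_pad > box else box
            if ("rlnCoordinateX" in row and pad > box):
                ox = int(row.rlnCoordinateX) - box // 2
                oy = int(row.rlnCoordinateY) - box // 2
                ox = min(max(ox, 0), pad - box)
                oy = min(max(oy, 0), pad - box)
            else:
                ox = oy = (pad - box) // 2
            buf = np.zeros((len(projs), pad, pad))
            buf[:, oy:oy + box, ox:ox + box] = projs
            c2d = ctf_2d(ctf, (pad, pad), reference.voxel_size)
            buf = np.fft.ifft2(np.fft.fft2(buf, axes=(-2, -1)) * c2d,
                               axes=(-2, -1)).real
            projs = buf[:, oy:oy + box, ox:ox + box]
        pm = projs[:, mask]
        pm = pm - pm.mean(axis=1, keepdims=True)
        sn = sel - sel.mean()
        cc = (pm @ sn) / (np.linalg.norm(pm, axis=1) * np.linalg.norm(sn)
                          + 1e-30)
        j = int(np.argmax(cc))
        out_az[i] = azimuths[j]
        out_cc[i] = cc[j]
        ok[i] = True
    return pd.DataFrame({"vrxAzimuth": out_az, "vrxAzimuthCC": out_cc,
                         "vrxAzimuthOk": ok.astype(int)})


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def assign_azimuth_fullframe(subtracted_parent: np.ndarray,
                             sub_matrix: np.ndarray,
                             coords: tuple[int, int],
                             reference: "DensityMap | FourierProjector",
                             ctf: CTFParams | None,
                             step: float = 2.0,
                             mask_radius: float | None = None,
                             ) -> tuple[float, float]:
    """Azimuth grid search against a full-size subtracted parent image.

    At high defocus the CTF delocalizes the turret signal well beyond the
    subparticle crop; matching on the uncropped subtracted image, with the
    reference pasted at the subparticle's parent coordinates and modulated on
    the parent grid, keeps all of that signal.  Returns (azimuth, NCC score);
    (nan, nan) for blank images.
    """
    if not isinstance(reference, FourierProjector):
        reference = FourierProjector(reference)
    parent_box = subtracted_parent.shape[0]
    box = reference.box
    azimuths = np.arange(0.0, 60.0, step)
    mats = np.einsum("ij,njk->nik", sub_matrix,
                     np.array([_rz(a) for a in azimuths]))
    projs = reference.project(mats)
    cx, cy = int(coords[0]), int(coords[1])
    ox = min(max(cx - box // 2, 0), parent_box - box)
    oy = min(max(cy - box // 2, 0), parent_box - box)
    buf = np.zeros((len(azimuths), parent_box, parent_box))
    buf[:, oy:oy + box, ox:ox + box] = projs
    if ctf is not None:
        c2d = ctf_2d(ctf, (parent_box, parent_box), reference.voxel_size)
        c2d = c2d[:, :parent_box // 2 + 1]       # CTF is even in frequency
        buf = np.fft.irfft2(np.fft.rfft2(buf, axes=(-2, -1)) * c2d,
                            s=(parent_box, parent_box), axes=(-2, -1))
    if mask_radius is None:
        mask_radius = 0.42 * parent_box
    yy, xx = np.mgrid[0:parent_box, 0:parent_box]
    mask = np.hypot(xx - cx, yy - cy) <= mask_radius
    sel = subtracted_parent[mask]
    if sel.std() == 0:
        return float("nan"), float("nan")
    pm = buf[:, mask]
    pm = pm - pm.mean(axis=1, keepdims=True)
    sn = sel - sel.mean()
    cc = pm @ sn / (np.linalg.norm(pm, axis=1) * np.linalg.norm(sn) + 1e-30)
    j = int(np.argmax(cc))
    return float(azimuths[j]), float(cc[j])


# ---------------------------------------------------------------------------
# FSC and amplitude operations

@dataclass(frozen=True)
class FSCCurve:
    """Shell frequencies (1/Angstrom) and correlation values."""

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"frequency_invA": self.frequencies,
                      "fsc": self.values}).to_csv(path, sep="\t", index=False)

    def plot(self, path, threshold: float = 0.143) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(self.frequencies, self.values)
        ax.axhline(threshold, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("spatial frequency (1/$\\AA$)")
        ax.set_ylabel("FSC")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def fsc(half1: DensityMap, half2: DensityMap,
        mask: np.ndarray | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on matching grids."""
    if half1.box != half2.box or half1.voxel_size != half2.voxel_size:
        raise ValueError("FSC requires maps on identical grids "
                         f"({half1.box}/{half1.voxel_size} vs "
                         f"{half2.box}/{half2.voxel_size})")
    a, b = half1.data, half2.data
    if mask is not None:
        a, b = a * mask, b * mask
    box = half1.box
    F1 = np.fft.fftn(a)
    F2 = np.fft.fftn(b)
    f = np.fft.fftfreq(box)
    q = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2
                + f[None, None, :] ** 2)
    shell = np.minimum(np.round(q * box).astype(int), box // 2)
    nshell = box // 2 + 1
    cross = np.bincount(shell.ravel(), (F1 * F2.conj()).real.ravel(), nshell)
    p1 = np.bincount(shell.ravel(), np.abs(F1.ravel()) ** 2, nshell)
    p2 = np.bincount(shell.ravel(), np.abs(F2.ravel()) ** 2, nshell)
    vals = cross / np.sqrt(p1 * p2 + 1e-300)
    freqs = np.arange(nshell) / (box * half1.voxel_size)
    # report shells 0..Nyquist with strictly increasing frequency
    return FSCCurve(frequencies=freqs, values=np.clip(vals, -1.0, 1.0))


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (Angstrom) at the first downward threshold crossing.

    Linear interpolation between the bracketing shells; if the curve never
    drops below the threshold the Nyquist resolution is returned.
    """
    f, v = curve.frequencies, curve.values
    for i in range(1, len(v)):
        if v[i] < threshold <= v[i - 1]:
            t = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            fc = f[i - 1] + t * (f[i] - f[i - 1])
            return float(1.0 / fc)
    return float(1.0 / f[-1])


def amplitude_ops(density: DensityMap, bfactor: float = 0.0,
                  lowpass: float | None = None,
                  lowpass_edge_shells: float = 2.0) -> DensityMap:
    """Sharpen (exp(-B s^2 / 4), negative B boosts high frequency) and/or
    low-pass filter with a raised-cosine edge ending at the cutoff."""
    if not np.isfinite(bfactor):
        raise ValueError("B-factor must be finite")
    box = density.box
    f = np.fft.fftfreq(box, d=density.voxel_size)
    s = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2
                + f[None, None, :] ** 2)
    filt = np.exp(-bfactor * s * s / 4.0)
    if lowpass is not None:
        if lowpass < 2.0 * density.voxel_size:
            raise ValueError(
                f"low-pass cutoff {lowpass} A is beyond Nyquist "
                f"({2 * density.voxel_size} A)")
        sc = 1.0 / lowpass
        width = lowpass_edge_shells / (box * density.voxel_size)
        lp = np.ones_like(s)
        lp[s >= sc] = 0.0
        ramp = (s > sc - width) & (s < sc)
        lp[ramp] = 0.5 * (1.0 + np.cos(np.pi * (s[ramp] - (sc - width))
                                       / width))
        filt *= lp
    out = np.fft.ifftn(np.fft.fftn(density.data) * filt).real
    return DensityMap(out, density.voxel_size)


def sharpening_factor(bfactor: float, resolution: float) -> float:
    """Amplitude scale applied at 1/resolution by exp(-B s^2 / 4)."""
    return float(np.exp(-bfactor / (4.0 * resolution ** 2)))
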