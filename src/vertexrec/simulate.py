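"""Simulated particle stacks: projections of the phantom with CTF and noise.

Every stochastic choice (orientations, shifts, defocus, noise) flows from one
explicit seed, so stacks are bitwise reproducible.  Noise is additive white
Gaussian applied after the CTF; structural noise is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .ctf import CTFParams
from .io import ctf_to_row, orientation_to_row
from .phantom import Phantom
from .projection import project
from .symmetry import Orientation


@dataclass
class ParticleStack:
    """Simulated images plus per-image pose/CTF metadata and ground truth."""

    images: np.ndarray               # (n, box, box) float32
    table: pd.DataFrame              # one row per image
    pixel_size: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.table):
            raise ValueError("image count must equal metadata row count")

    def __len__(self) -> int:
        return len(self.images)

    def orientation(self, i: int) -> Orientation:
        row = self.table.iloc[i]
        return Orientation(rot=row.rlnAngleRot, tilt=row.rlnAngleTilt,
                           psi=row.rlnAnglePsi, dx=row.rlnOriginX,
                           dy=row.rlnOriginY)

    def ctf(self, i: int) -> CTFParams | None:
        row = self.table.iloc[i]
        if "rlnDefocusU" not in row or not np.isfinite(row.rlnDefocusU):
            return None
        return CTFParams(voltage=row.rlnVoltage, defocus_u=row.rlnDefocusU,
                         defocus_v=row.rlnDefocusV,
                         astig_angle=row.rlnDefocusAngle,
                         cs=row.rlnSphericalAberration,
                         amplitude_contrast=row.rlnAmplitudeContrast)


def random_orientations(n: int, rng: np.random.Generator,
                        shift_sigma: float = 0.0) -> list[Orientation]:
    """Uniform poses on SO(3) with optional Gaussian origin shifts (pixels)."""
    quats = rng.normal(size=(n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    out = []
    for q in quats:
        psi, tilt, rot = Rotation.from_quat(q).as_euler("ZYZ", degrees=True)
        dx, dy = ((rng.normal(scale=shift_sigma, size=2))
                  if shift_sigma > 0 else (0.0, 0.0))
        out.append(Orientation(rot=rot, tilt=tilt, psi=psi,
                               dx=float(dx), dy=float(dy)))
    return out


def simulate_particles(phantom: Phantom, n: int, seed: int, *,
                       orientations: list[Orientation] | None = None,
                       noise_sigma: float = 0.0,
                       with_ctf: bool = True,
                       defocus_range: tuple[float, float] = (3000.0, 30000.0),
                       voltage: float = 300.0,
                       cs: float = 2.0,
                       amplitude_contrast: float = 0.1,
                       shift_sigma: float = 1.0) -> ParticleStack:
    """Project the phantom into ``n`` noisy particle images.

    Orientations are uniform on SO(3) unless a list is supplied; defocus is
    drawn uniformly from ``defocus_range`` (Angstrom, spanning 0.3-3.0 um by
    default).  ``noise_sigma`` is the standard deviation of the additive
    Gaussian noise in image units.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed)
    if orientations is None:
        orientations = random_orientations(n, rng, shift_sigma=shift_sigma)
    elif len(orientations) != n:
        raise ValueError("orientation list length must equal n")

    box = phantom.full_map.box
    images = np.empty((n, box, box), dtype=np.float32)
    rows = []
    for i, o in enumerate(orientations):
        ctf = None
        if with_ctf:
            dz = float(rng.uniform(*defocus_range))
            astig = float(rng.uniform(0.0, 180.0))
            # mild astigmatism: +-2% of the nominal defocus
            ddz = float(rng.uniform(-0.02, 0.02) * dz)
            ctf = CTFParams(voltage=voltage, defocus_u=dz + ddz,
                            defocus_v=dz - ddz, astig_angle=astig, cs=cs,
                            amplitude_contrast=amplitude_contrast)
        img = project(phantom.full_map, o, ctf=ctf)
        if noise_sigma > 0:
            img = img + rng.normal(scale=noise_sigma, size=img.shape)
        images[i] = img.astype(np.float32)
        row = {"vrxParticleId": i, **orientation_to_row(o)}
        if ctf is not None:
            row.update(ctf_to_row(ctf))
        rows.append(row)

    table = pd.DataFrame(rows)
    truth = {"azimuths": np.asarray(phantom.spec.azimuths, dtype=float),
             "seed": seed, "noise_sigma": noise_sigma}
    for k in range(12):
        table[f"vrxTrueAzimuth{k:02d}"] = phantom.spec.azimuths[k]
    return ParticleStack(images=images, table=table,
                         pixel_size=phantom.spec.voxel_size, truth=truth)
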