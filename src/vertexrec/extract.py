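"""Vertex subparticle extraction with symmetry expansion.

For every particle image, the 12 five-fold vertices are projected into the
image plane; each vertex yields one subparticle record carrying a derived pose
(the particle pose composed with the vertex frame and one randomly chosen
member of the five-fold stabilizer, so as not to bias orientations), the crop
coordinate in the parent image, and the deviation of the vertex axis from a
side view.  A "side view" is a vertex axis lying in the image plane; the
deviation is the axis's tilt out of that plane, so subparticles from the edge
of the particle have small deviation and those near the beam axis approach 90
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ParticleStack
from .symmetry import Orientation, VertexSet


@dataclass(frozen=True)
class SelectionParams:
    """Extraction/selection settings for vertex subparticles."""

    subparticle_box: int = 128
    vertex_radius: float = 42.0      # Angstrom, turret center from particle center
    max_side_dev: float = 40.0       # degrees

    def __post_init__(self) -> None:
        if not (0.0 < self.max_side_dev <= 90.0):
            raise ValueError("max_side_dev must lie in (0, 90] degrees")
        if self.subparticle_box < 2:
            raise ValueError("subparticle box too small")


def vertex_projection_coords(o: Orientation, vertices: VertexSet,
                             radius: float, pixel_size: float,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Project the 12 vertex positions of one particle into its image.

    Returns ``(coords, side_dev)``: coords are (12, 2) pixel offsets from the
    particle center (origin shifts included), side_dev the angular deviation
    of each vertex axis from the image plane in degrees, in [0, 90].
    """
    R = o.matrix()
    u = vertices.axes @ R.T                        # rotated axes, (12, 3)
    coords = u[:, :2] * (radius / pixel_size) + np.array([o.dx, o.dy])
    axis_angle = np.degrees(np.arccos(np.clip(u[:, 2], -1.0, 1.0)))
    side_dev = np.abs(90.0 - axis_angle)
    return coords, side_dev


def subparticle_records(table: pd.DataFrame, vertices: VertexSet,
                        params: SelectionParams, pixel_size: float,
                        parent_box: int, seed: int,
                        truth_azimuths: np.ndarray | None = None,
                        ) -> pd.DataFrame:
    """Derive the 12-per-particle subparticle metadata without touching images.

    One record per (particle, vertex).  The subparticle pose matrix is
    ``R_particle @ V_k @ Rz(72 j)`` where ``V_k`` is the canonical vertex frame
    and ``j`` the seeded uniform choice among the five stabilizer-equivalent
    Euler triplets; it maps the subparticle reference +z axis onto the
    laboratory direction of the vertex axis.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    n = len(table)
    b2 = params.subparticle_box // 2
    cp = parent_box // 2

    euler = table[["rlnAnglePsi", "rlnAngleTilt", "rlnAngleRot"]].to_numpy(float)
    shifts = np.zeros((n, 2))
    for c, col in enumerate(("rlnOriginX", "rlnOriginY")):
        if col in table.columns:
            shifts[:, c] = table[col].to_numpy(float)
    R = Rotation.from_euler("ZYZ", euler, degrees=True).as_matrix()  # (n,3,3)

    # vertex axes in the image frame of every particle: (n, 12, 3)
    u = np.einsum("nij,kj->nki", R, vertices.axes)
    coords = (u[:, :, :2] * (params.vertex_radius / pixel_size)
              + shifts[:, None, :]) + cp
    side_dev = np.abs(90.0 - np.degrees(
        np.arccos(np.clip(u[:, :, 2], -1.0, 1.0))))

    triplets = rng.integers(5, size=(n, 12))
    frames = np.array([vertices.frame(k) @ _rz(72.0 * j)
                       for k in range(12) for j in range(5)]
                      ).reshape(12, 5, 3, 3)
    sub_mats = np.einsum("nij,nkjl->nkil", R,
                         frames[np.arange(12)[None, :], triplets])
    with np.errstate(invalid="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # gimbal-lock canonicalization
            psi, tilt, rot = Rotation.from_matrix(
                sub_mats.reshape(-1, 3, 3)).as_euler("ZYZ", degrees=True).T

    c_int = np.round(coords).astype(int)
    resid = coords - c_int
    hi = parent_box - (params.subparticle_box - b2)
    oob = ~((c_int[:, :, 0] >= b2) & (c_int[:, :, 0] <= hi)
            & (c_int[:, :, 1] >= b2) & (c_int[:, :, 1] <= hi))

    pids = (table["vrxParticleId"].to_numpy(int)
            if "vrxParticleId" in table.columns else np.arange(n))
    out = pd.DataFrame({
        "vrxParticleId": np.repeat(pids, 12),
        "vrxVertex": np.tile(np.arange(12), n),
        "vrxTriplet": triplets.ravel(),
        "rlnAngleRot": rot, "rlnAngleTilt": tilt, "rlnAnglePsi": psi,
        "rlnOriginX": resid[:, :, 0].ravel(),
        "rlnOriginY": resid[:, :, 1].ravel(),
        "rlnCoordinateX": c_int[:, :, 0].ravel(),
        "rlnCoordinateY": c_int[:, :, 1].ravel(),
        "vrxSideDev": side_dev.ravel(),
        "vrxOutOfBounds": oob.ravel().astype(int),
    })
    for col in ("rlnDefocusU", "rlnDefocusV", "rlnDefocusAngle",
                "rlnVoltage", "rlnSphericalAberration",
                "rlnAmplitudeContrast"):
        if col in table.columns:
            out[col] = np.repeat(table[col].to_numpy(), 12)
    if truth_azimuths is not None:
        out["vrxTrueAzimuth"] = (
            np.asarray(truth_azimuths)[np.tile(np.arange(12), n)]
            - 72.0 * triplets.ravel()) % 60.0
    return out


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def extract_subparticles(stack: ParticleStack, vertices: VertexSet,
                         params: SelectionParams, seed: int) -> ParticleStack:
    """Crop vertex-centered subparticles from a particle stack.

    Returns a stack of ``12 x len(stack)`` records; crops are centered on the
    nearest integer pixel with the sub-pixel residual stored in the origin
    offsets (the image itself is never interpolated, preserving the noise
    statistics).  Records whose crop window leaves the parent image are
    flagged ``vrxOutOfBounds`` and carry a zero image.
    """
    parent_box = stack.images.shape[-1]
    truth = stack.truth.get("azimuths")
    table = subparticle_records(stack.table, vertices, params,
                                stack.pixel_size, parent_box, seed,
                                truth_azimuths=truth)
    b = params.subparticle_box
    b2 = b // 2
    images = np.zeros((len(table), b, b), dtype=np.float32)
    for i, row in table.iterrows():
        if row.vrxOutOfBounds:
            continue
        cx, cy = int(row.rlnCoordinateX), int(row.rlnCoordinateY)
        parent = stack.images[int(row.vrxParticleId)]
        images[i] = parent[cy - b2:cy - b2 + b, cx - b2:cx - b2 + b]
    return ParticleStack(images=images, table=table,
                         pixel_size=stack.pixel_size, truth=dict(stack.truth))


def side_view_filter(subs: ParticleStack, max_side_dev: float = 40.0,
                     ) -> ParticleStack:
    """Retain records whose vertex axis lies within ``max_side_dev`` degrees
    of the image plane (inclusive threshold); order is preserved."""
    keep = (subs.table["vrxSideDev"].to_numpy() <= max_side_dev)
    table = subs.table.loc[keep].reset_index(drop=True)
    return ParticleStack(images=subs.images[keep], table=table,
                         pixel_size=subs.pixel_size, truth=dict(subs.truth))


def drop_out_of_bounds(subs: ParticleStack) -> ParticleStack:
    keep = subs.table["vrxOutOfBounds"].to_numpy() == 0
    table = subs.table.loc[keep].reset_index(drop=True)
    return ParticleStack(images=subs.images[keep], table=table,
                         pixel_size=subs.pixel_size, truth=dict(subs.truth))
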