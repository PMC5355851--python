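"""Caspar-Klug quasi-equivalence lattices for trimer-built icosahedral shells.

A T-number lattice (T = h^2 + hk + k^2) is generated by laying the icosahedral
facet triangle over a planar triangular lattice, collecting the centroids of
the small lattice triangles inside each facet (each is a trimer position, 3
chains), and mapping them to the sphere barycentrically.  Trimer positions are
then classified by angular proximity to the icosahedral symmetry axes:

* ``T``-type: on the three-fold axes (20 trimers),
* ``P``-type: the ring nearest the five-fold axes (60) — absent from the outer
  shell of the phi6 nucleocapsid, where vertex turrets take their place,
* ``Q``-type: the peripentonal ring next out from the five-folds (60),
* ``S``-type: nearest the two-fold axes (60),
* ``R``-type: the remainder (60).

For T=13 this reproduces the 260-trimer lattice, and 200 trimers (600 chains)
after P removal, i.e. 10 chains per icosahedral asymmetric unit.  Handedness:
``laevo`` corresponds to (h, k) = (1, 3) in a right-handed frame viewed from
outside the particle; ``dextro`` swaps h and k.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import itertools
import json

import numpy as np
import pandas as pd

from .symmetry import SymmetryGroup, build_point_group, vertex_axes

_A1 = np.array([1.0, 0.0])
_A2 = np.array([0.5, np.sqrt(3.0) / 2.0])

OPEN, CLOSED = "open", "closed"


def _hk_for_T(T: int) -> tuple[int, int]:
    """Smallest (h, k) with h^2 + hk + k^2 = T and h <= k, or raise."""
    for h in range(int(np.sqrt(T)) + 1):
        for k in range(h, int(np.sqrt(T)) + 1):
            if h * h + h * k + k * k == T:
                return h, k
    raise ValueError(f"T={T} is not a triangulation number (h^2+hk+k^2)")


@dataclass(frozen=True)
class LatticeLayout:
    """Trimer centers, quasi-equivalence types and chain labels of a shell."""

    T: int
    hand: str
    centers: np.ndarray          # (N, 3) unit vectors, trimer centers
    types: np.ndarray            # (N,) strings in {P, Q, R, S, T}
    chain_positions: np.ndarray  # (N, 3, 3) unit vectors, 3 chains per trimer
    conformations: np.ndarray | None = None  # (N, 3) strings open/closed

    @property
    def n_trimers(self) -> int:
        return len(self.centers)

    @property
    def n_chains(self) -> int:
        return 3 * self.n_trimers

    @property
    def chains_per_asymmetric_unit(self) -> float:
        """Chains contributed per icosahedral asymmetric unit (60 per shell).

        Trimers sitting exactly on a three-fold axis contribute one chain per
        asymmetric unit; the division by 60 accounts for this fractional
        sharing automatically.
        """
        return self.n_chains / 60.0

    def type_counts(self) -> dict[str, int]:
        kinds, counts = np.unique(self.types, return_counts=True)
        return dict(zip(kinds.tolist(), counts.tolist()))

    def conformation_counts(self) -> dict[str, int]:
        if self.conformations is None:
            raise ValueError("conformations not assigned; call assign_conformations")
        kinds, counts = np.unique(self.conformations, return_counts=True)
        return dict(zip(kinds.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (c, t) in enumerate(zip(self.centers, self.types)):
            conf = (list(self.conformations[i]) if self.conformations is not None
                    else [""] * 3)
            rows.append({"trimer": i, "type": t,
                         "x": c[0], "y": c[1], "z": c[2],
                         "chain_1": conf[0], "chain_2": conf[1],
                         "chain_3": conf[2]})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "T": self.T,
            "hand": self.hand,
            "types": self.types.tolist(),
            "centers": self.centers.tolist(),
            "conformations": (self.conformations.tolist()
                              if self.conformations is not None else None),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# construction

def _icosahedral_faces(axes5: np.ndarray) -> list[tuple[int, int, int]]:
    """The 20 faces as positively oriented vertex index triples."""
    cos_adj = 1.0 / np.sqrt(5.0)
    faces = []
    n = len(axes5)
    for i, j, k in itertools.combinations(range(n), 3):
        if (np.dot(axes5[i], axes5[j]) > cos_adj - 1e-6
                and np.dot(axes5[j], axes5[k]) > cos_adj - 1e-6
                and np.dot(axes5[i], axes5[k]) > cos_adj - 1e-6):
            tri = (i, j, k)
            if np.linalg.det(axes5[list(tri)]) < 0:
                tri = (i, k, j)
            faces.append(tri)
    if len(faces) != 20:  # pragma: no cover - geometric invariant
        raise RuntimeError(f"found {len(faces)} icosahedral faces, expected 20")
    return faces


def _facet_centroids_2d(h: int, k: int) -> np.ndarray:
    """Barycentric coordinates of trimer centroids inside the (h, k) facet.

    For triangulation numbers whose facet edges avoid lattice-triangle
    centroids (true for T=13) every centroid lies strictly inside exactly one
    facet, so strict inclusion yields an exact, overlap-free enumeration.
    """
    A = np.zeros(2)
    B = h * _A1 + k * _A2
    rot60 = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])
    C = rot60 @ B
    M = np.column_stack([B - A, C - A])
    Minv = np.linalg.inv(M)
    bary = []
    span = h + k + 2
    for m in range(-span, span + 1):
        for n in range(-span, span + 1):
            for t in (1.0, 2.0):
                p = (m + t / 3.0) * _A1 + (n + t / 3.0) * _A2
                uv = Minv @ (p - A)
                w = np.array([1.0 - uv[0] - uv[1], uv[0], uv[1]])
                if np.all(w > 1e-9) and np.all(w < 1 - 1e-9):
                    bary.append(w)
    return np.array(bary)


def _chain_offsets_2d(h: int, k: int) -> np.ndarray:
    """Barycentric coords of the 3 chain positions around each facet centroid.

    Chains are placed halfway between the trimer centroid and the corners of
    its lattice triangle (the surrounding quasi-six-fold positions), which
    gives each chain a distinct, symmetry-consistent position on the sphere.
    """
    A = np.zeros(2)
    B = h * _A1 + k * _A2
    rot60 = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])
    C = rot60 @ B
    M = np.column_stack([B - A, C - A])
    Minv = np.linalg.inv(M)
    out = []
    span = h + k + 2
    for m in range(-span, span + 1):
        for n in range(-span, span + 1):
            for t in (1.0, 2.0):
                base = m * _A1 + n * _A2
                if t == 1.0:
                    corners = [base, base + _A1, base + _A2]
                else:
                    corners = [base + _A1, base + _A2, base + _A1 + _A2]
                cen = base + (t / 3.0) * (_A1 + _A2)
                uv = Minv @ (cen - A)
                w = np.array([1.0 - uv[0] - uv[1], uv[0], uv[1]])
                if np.all(w > 1e-9) and np.all(w < 1 - 1e-9):
                    ws = []
                    for corner in corners:
                        p = cen + 0.5 * (corner - cen)
                        uvc = Minv @ (p - A)
                        ws.append([1 - uvc[0] - uvc[1], uvc[0], uvc[1]])
                    out.append(ws)
    return np.array(out)  # (n, 3, 3) barycentric


def _angular_dist(points: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Min angle (rad) from each point to any axis in ``axes`` (unsigned)."""
    cos = np.clip(points @ axes.T, -1.0, 1.0)
    return np.arccos(cos).min(axis=1)


def symmetry_axes(group: SymmetryGroup | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit five-, three- and two-fold axes of the icosahedron (both signs)."""
    group = group or build_point_group("I")
    v5 = vertex_axes(group).axes
    faces = _icosahedral_faces(v5)
    v3 = np.array([v5[list(f)].sum(axis=0) for f in faces])
    v3 /= np.linalg.norm(v3, axis=1, keepdims=True)
    mids = []
    for i, j in itertools.combinations(range(12), 2):
        if np.dot(v5[i], v5[j]) > 1.0 / np.sqrt(5.0) - 1e-6:
            m = v5[i] + v5[j]
            mids.append(m / np.linalg.norm(m))
    v2 = np.array(mids)
    if len(v2) != 30:  # pragma: no cover - geometric invariant
        raise RuntimeError(f"found {len(v2)} two-fold axes, expected 30")
    return v5, v3, v2


def _classify(centers: np.ndarray) -> np.ndarray:
    """Assign P/Q/R/S/T types by ranked angular proximity to symmetry axes.

    Fixed tie-break order T -> P -> Q -> S -> R: the 20 trimers on three-fold
    axes are typed T; of the rest the 60 nearest the five-folds are P and the
    next 60 are Q; of the remainder the 60 nearest the two-folds are S; the
    final 60 are R.
    """
    v5, v3, v2 = symmetry_axes()
    n = len(centers)
    d5 = _angular_dist(centers, v5)
    d3 = _angular_dist(centers, v3)
    d2 = _angular_dist(centers, v2)
    types = np.array([""] * n, dtype=object)
    remaining = np.ones(n, dtype=bool)

    def take(dist: np.ndarray, count: int, label: str) -> None:
        idx = np.where(remaining)[0]
        order = idx[np.argsort(dist[idx], kind="stable")]
        chosen = order[:count]
        gap = dist[order[count]] - dist[order[count - 1]] if count < len(order) else np.inf
        if gap < 1e-6:  # pragma: no cover - would indicate a degenerate ranking
            raise RuntimeError(f"ambiguous {label}-type ranking (gap {gap:.2e})")
        types[chosen] = label
        remaining[chosen] = False

    take(d3, min(20, n), "T")
    if remaining.any():
        take(d5, 60, "P")
    if remaining.any():
        take(d5, 60, "Q")
    if remaining.any():
        take(d2, 60, "S")
    types[remaining] = "R"
    return types.astype(str)


def build_quasi_lattice(T: int = 13, hand: str = "laevo", *,
                        remove_p: bool = True) -> LatticeLayout:
    """Generate the trimer lattice of a T-number icosahedral shell.

    Parameters
    ----------
    T : triangulation number, must equal h^2 + hk + k^2 for integers h, k.
    hand : 'laevo' ((h, k) with h < k) or 'dextro' (mirrored, (k, h)).
    remove_p : drop the P-type trimers nearest the five-fold vertices, as in
        shells whose vertices carry turrets instead of trimers (default).
    """
    h, k = _hk_for_T(T)
    if hand == "laevo":
        pass
    elif hand == "dextro":
        h, k = k, h
    else:
        raise ValueError(f"hand must be 'laevo' or 'dextro', got {hand!r}")

    group = build_point_group("I")
    v5 = vertex_axes(group).axes
    faces = _icosahedral_faces(v5)
    bary = _facet_centroids_2d(h, k)             # (13, 3) for T=13
    chains_bary = _chain_offsets_2d(h, k)        # (13, 3, 3)

    centers, chains = [], []
    for tri in faces:
        V = v5[list(tri)]                        # (3, 3)
        pts = bary @ V
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        centers.append(pts)
        ch = chains_bary @ V                     # (13, 3, 3)
        ch /= np.linalg.norm(ch, axis=2, keepdims=True)
        chains.append(ch)
    centers = np.concatenate(centers)
    chains = np.concatenate(chains)

    expected = 20 * T
    if len(centers) != expected:  # pragma: no cover - construction invariant
        raise RuntimeError(f"enumerated {len(centers)} trimers, expected {expected}")

    types = _classify(centers)
    layout = LatticeLayout(T=T, hand=hand, centers=centers, types=types,
                           chain_positions=chains)
    if remove_p:
        keep = types != "P"
        layout = replace(layout, centers=centers[keep], types=types[keep],
                         chain_positions=chains[keep])
    return layout


def assign_conformations(layout: LatticeLayout) -> LatticeLayout:
    """Label chains open/closed: one closed chain per peripentonal Q trimer.

    Within each Q trimer the chain whose position is angularly nearest a
    five-fold axis is labelled closed (the position sterically blocked by the
    vertex turret); every other chain in the shell is open.
    """
    if layout.types is None or not len(layout.types):
        raise ValueError("layout has no trimer types; build the lattice first")
    v5, _, _ = symmetry_axes()
    conf = np.full((layout.n_trimers, 3), OPEN, dtype=object)
    for i in np.where(layout.types == "Q")[0]:
        d = _angular_dist(layout.chain_positions[i], v5)
        conf[i, int(np.argmin(d))] = CLOSED
    return replace(layout, conformations=conf.astype(str))
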