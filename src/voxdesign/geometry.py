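"""Rigid-body geometry: canonical residue frames, virtual C-beta, Kabsch.

The voxeliser's rotation/translation invariance rests entirely on
:func:`residue_canonical_transform`: every residue environment is expressed
in a local frame with CA at the origin and the N-CA-C plane on the XY plane,
so two rigidly related copies of a structure produce identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BOND_CA_CB
from .errors import DegenerateGeometryError

__all__ = [
    "RigidTransform",
    "place_virtual_cbeta",
    "add_virtual_cbetas",
    "residue_canonical_transform",
    "kabsch_superpose",
    "dihedral",
    "random_rigid_transform",
]

_COLLINEAR_TOL = 1e-6


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COLLINEAR_TOL:
        raise DegenerateGeometryError("zero-length vector in frame construction")
    return v / n


def place_virtual_cbeta(residue) -> np.ndarray:
    """Ideal tetrahedral C-beta from N, CA, C with a 1.522 A bond.

    Computed for every residue including glycine: the virtual C-beta depends
    only on backbone geometry and L-chirality, so it leaks nothing about the
    native residue identity.  The direction uses the standard linear
    combination of the local bond vectors and their cross product, rescaled
    to the exact bond length.
    """
    n, ca, c = residue.n_coord, residue.ca_coord, residue.c_coord
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    if np.linalg.norm(a) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("N, CA, C are collinear")
    v = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return ca + BOND_CA_CB * _unit(v)


def add_virtual_cbetas(structure) -> None:
    """Fill ``cb_coord`` for every residue of ``structure`` in place."""
    for _, _, res in structure.iter_residues():
        res.cb_coord = place_virtual_cbeta(res)


def residue_canonical_transform(residue) -> RigidTransform:
    """Rigid transform mapping the residue into its canonical frame.

    CA maps to the origin, the CA->N direction to +X, C into the XY plane
    with positive Y; +Z is the right-handed normal of the N-CA-C plane.
    """
    n, ca, c = residue.n_coord, residue.ca_coord, residue.c_coord
    x = _unit(n - ca)
    c_rel = c - ca
    y_raw = c_rel - np.dot(c_rel, x) * x
    if np.linalg.norm(y_raw) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("N, CA, C are collinear")
    y = _unit(y_raw)
    z = np.cross(x, y)
    rotation = np.stack([x, y, z])
    return RigidTransform(rotation, -rotation @ ca)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation superposition of A onto B.

    Returns the rigid transform taking ``coords_a`` onto ``coords_b`` and
    the post-superposition RMSD ``sqrt(sum ||b_i - T(a_i)||^2 / n)``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca_, b - cb_
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rotation, cb_ - rotation @ ca_)
    diff = b - transform.apply(a)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return transform, rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def random_rigid_transform(rng: np.random.Generator,
                           translation_scale: float = 20.0) -> RigidTransform:
    """Uniformly random proper rotation plus a Gaussian translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    translation = rng.normal(scale=translation_scale, size=3)
    return RigidTransform(rotation, translation)
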