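"""Synthetic backbones and geometry-labelled frame datasets.

Ideal polypeptide backbones are grown from internal coordinates (bond
lengths, bond angles and per-residue phi/psi/omega torsions) with the
natural-extension reference frame construction, so every other module can
be exercised without any external structure file.

``synthetic_labelled_dataset`` builds a desk-scale training task: backbones
are mixtures of helix/strand/coil segments with small coordinate jitter,
and each residue's label is a deterministic function of its local torsion
class (helix -> 'A', strand -> 'V', coil -> 'G').  The label is therefore
learnable from frame geometry alone, which is exactly what a residue
classifier must exploit on real structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
)
from .dataset import FrameDataset, build_dataset, split_dataset
from .geometry import add_virtual_cbetas, dihedral
from .structure_io import BackboneResidue, BackboneStructure, Chain
from .voxelizer import VoxelConfig

__all__ = [
    "TorsionSpec",
    "build_backbone",
    "make_helix",
    "make_strand",
    "make_coil",
    "measure_torsions",
    "torsion_class",
    "synthetic_labelled_dataset",
    "HELIX_TORSIONS",
    "STRAND_TORSIONS",
    "COIL_TORSIONS",
]

HELIX_TORSIONS = (-57.0, -47.0)
STRAND_TORSIONS = (-135.0, 135.0)
#: A polyproline-II-like region: clearly outside both the helix and strand
#: torsion classes, giving the coil class a distinct local geometry.
COIL_TORSIONS = (-75.0, 65.0)

#: Geometry-to-label rule of the synthetic task (one-letter codes).
CLASS_LABELS = {"helix": "A", "strand": "V", "coil": "G"}


@dataclass
class TorsionSpec:
    """Per-residue (phi, psi, omega) torsions plus ideal covalent geometry.

    phi of the first residue and omega of the first residue are undefined
    for a chain start and ignored.
    """

    torsions: list[tuple[float, float, float]]
    bond_n_ca: float = BOND_N_CA
    bond_ca_c: float = BOND_CA_C
    bond_c_n: float = BOND_C_N
    angle_n_ca_c: float = ANGLE_N_CA_C
    angle_ca_c_n: float = ANGLE_CA_C_N
    angle_c_n_ca: float = ANGLE_C_N_CA

    def __post_init__(self):
        if len(self.torsions) < 1:
            raise ValueError("need at least one residue")
        for v in (self.bond_n_ca, self.bond_ca_c, self.bond_c_n,
                  self.angle_n_ca_c, self.angle_ca_c_n, self.angle_c_n_ca):
            if v <= 0:
                raise ValueError("bond lengths and angles must be positive")

    @classmethod
    def regular(cls, n: int, phi: float, psi: float, omega: float = 180.0
                ) -> "TorsionSpec":
        return cls([(phi, psi, omega)] * n)


def _extend(a: np.ndarray, b: np.ndarray, c: np.ndarray, length: float,
            angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c with |cd|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(angle),
        length * np.sin(angle) * np.cos(torsion),
        length * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: TorsionSpec, sequence: str,
                   structure_id: str = "synthetic", chain_id: str = "A"
                   ) -> BackboneStructure:
    """Grow N/CA/C atoms from internal coordinates; O in the peptide plane."""
    if len(sequence) != len(spec.torsions):
        raise ValueError("sequence length must equal torsion list length")
    n_res = len(sequence)
    # seed the first residue in a fixed local frame
    n0 = np.zeros(3)
    ca0 = np.array([spec.bond_n_ca, 0.0, 0.0])
    ang = np.radians(spec.angle_n_ca_c)
    c0 = ca0 + spec.bond_ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords = [(n0, ca0, c0)]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-1]
        psi_prev = spec.torsions[i - 1][1]
        omega = spec.torsions[i][2]
        phi = spec.torsions[i][0]
        n_i = _extend(n_prev, ca_prev, c_prev, spec.bond_c_n,
                      spec.angle_ca_c_n, psi_prev)
        ca_i = _extend(ca_prev, c_prev, n_i, spec.bond_n_ca,
                       spec.angle_c_n_ca, omega)
        c_i = _extend(c_prev, n_i, ca_i, spec.bond_ca_c,
                      spec.angle_n_ca_c, phi)
        coords.append((n_i, ca_i, c_i))

    chain = Chain(chain_id)
    for i, (aa, (n_i, ca_i, c_i)) in enumerate(zip(sequence, coords)):
        if i + 1 < n_res:
            n_next = coords[i + 1][0]
            # carbonyl O in the peptide plane, trans to the next N
            direction = (c_i - ca_i) / np.linalg.norm(c_i - ca_i) \
                + (c_i - n_next) / np.linalg.norm(c_i - n_next)
            o_i = c_i + BOND_C_O * direction / np.linalg.norm(direction)
        else:
            # chain terminus: place O with a psi-like torsion of the last frame
            o_i = _extend(n_i, ca_i, c_i, BOND_C_O, 120.5,
                          spec.torsions[i][1] + 180.0)
        chain.residues.append(BackboneResidue(
            chain_id=chain_id, residue_number=i + 1, insertion_code="",
            amino_acid=aa, n_coord=n_i, ca_coord=ca_i, c_coord=c_i,
            o_coord=o_i))
    structure = BackboneStructure(structure_id, [chain])
    add_virtual_cbetas(structure)
    return structure


def make_helix(n: int, structure_id: str = "ideal_helix") -> BackboneStructure:
    """Ideal alpha helix, (phi, psi) = (-57, -47), omega = 180."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    return build_backbone(TorsionSpec.regular(n, *HELIX_TORSIONS),
                          "A" * n, structure_id=structure_id)


def make_strand(n: int, structure_id: str = "ideal_strand") -> BackboneStructure:
    """Ideal extended beta strand, (phi, psi) = (-135, 135), omega = 180."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    return build_backbone(TorsionSpec.regular(n, *STRAND_TORSIONS),
                          "V" * n, structure_id=structure_id)


def make_coil(n: int, structure_id: str = "ideal_coil") -> BackboneStructure:
    """Regular coil-class segment, (phi, psi) = (-75, 65)."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    return build_backbone(TorsionSpec.regular(n, *COIL_TORSIONS),
                          "G" * n, structure_id=structure_id)


def measure_torsions(structure: BackboneStructure
                     ) -> list[tuple[float, float, float]]:
    """(phi, psi, omega) per residue; undefined terminal angles are nan."""
    out = []
    for chain in structure.chains:
        res = chain.residues
        for i, r in enumerate(res):
            phi = psi = omega = float("nan")
            if i > 0:
                phi = dihedral(res[i - 1].c_coord, r.n_coord, r.ca_coord,
                               r.c_coord)
                omega = dihedral(res[i - 1].ca_coord, res[i - 1].c_coord,
                                 r.n_coord, r.ca_coord)
            if i + 1 < len(res):
                psi = dihedral(r.n_coord, r.ca_coord, r.c_coord,
                               res[i + 1].n_coord)
            out.append((phi, psi, omega))
    return out


def torsion_class(phi: float, psi: float) -> str:
    """Coarse Ramachandran class used as the synthetic label rule."""
    if -100 <= phi <= -30 and -80 <= psi <= -5:
        return "helix"
    if -170 <= phi <= -90 and 90 <= psi <= 180:
        return "strand"
    return "coil"


#: Deliberately skewed generating probabilities (helix/strand/coil) so that
#: balanced undersampling has real work to do on the synthetic task.
_SEGMENT_PROBS = {"helix": 0.6, "strand": 0.3, "coil": 0.1}
_SEGMENT_JITTER_SIGMA = 0.05  # Angstrom, per coordinate


def _jitter(structure: BackboneStructure, rng: np.random.Generator,
            sigma: float) -> None:
    for _, _, res in structure.iter_residues():
        res.n_coord = res.n_coord + rng.normal(0, sigma, 3)
        res.ca_coord = res.ca_coord + rng.normal(0, sigma, 3)
        res.c_coord = res.c_coord + rng.normal(0, sigma, 3)
        if res.o_coord is not None:
            res.o_coord = res.o_coord + rng.normal(0, sigma, 3)
        res.cb_coord = None
    add_virtual_cbetas(structure)


def synthetic_structure(length: int, rng: np.random.Generator,
                        structure_id: str = "synthetic",
                        segment_length: tuple[int, int] = (6, 12),
                        jitter_sigma: float = _SEGMENT_JITTER_SIGMA
                        ) -> BackboneStructure:
    """One backbone built from random helix/strand/coil segments."""
    kinds = list(_SEGMENT_PROBS)
    probs = np.array([_SEGMENT_PROBS[k] for k in kinds])
    torsion_by_kind = {"helix": HELIX_TORSIONS, "strand": STRAND_TORSIONS,
                       "coil": COIL_TORSIONS}
    torsions: list[tuple[float, float, float]] = []
    sequence = []
    while len(torsions) < length:
        kind = kinds[rng.choice(len(kinds), p=probs)]
        seg = int(rng.integers(segment_length[0], segment_length[1] + 1))
        seg = min(seg, length - len(torsions))
        phi, psi = torsion_by_kind[kind]
        torsions.extend([(phi, psi, 180.0)] * seg)
        sequence.extend(CLASS_LABELS[kind] * seg)
    structure = build_backbone(TorsionSpec(torsions), "".join(sequence),
                               structure_id=structure_id)
    _jitter(structure, rng, jitter_sigma)
    return structure


def synthetic_labelled_dataset(n_structures: int, length: int, seed: int,
                               config: VoxelConfig, path,
                               fractions=(0.6, 0.2, 0.2)) -> FrameDataset:
    """Generate, voxelise and persist the geometry-labelled training task.

    Splits are assigned at structure level with the same seed, so the whole
    dataset is reproducible from ``(n_structures, length, seed, config)``.
    """
    if n_structures < 1 or length < 4:
        raise ValueError("need n_structures >= 1 and length >= 4")
    rng = np.random.default_rng(seed)
    structures = [
        synthetic_structure(length, rng, structure_id=f"syn{i:04d}")
        for i in range(n_structures)
    ]
    ds = build_dataset(structures, config, path)
    split_dataset(ds, fractions, seed=seed)
    return ds
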