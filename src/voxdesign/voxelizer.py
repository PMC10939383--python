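"""Voxelisation of backbone microenvironments into fixed-size density grids.

For each residue a cubic "frame" of edge ``frame_edge_length`` (default
12 A) centred on its CA is discretised into ``voxels_per_side`` voxels per
edge (default 21, odd so the CA sits in the exact centre voxel).  The whole
structure is first mapped into the residue's canonical frame
(:func:`voxdesign.geometry.residue_canonical_transform`), which makes the
resulting tensors invariant to rigid motions of the input.

Atoms are rendered either as truncated Gaussians whose width follows the
element's van der Waals radius, or as single-voxel occupancies.  Optional
polarity / charge input channels mark each residue's CA voxel with a value
in {-1, 0, +1}; at design time user-supplied constraint vectors override the
sequence-derived values ("fix sites").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AA_TO_INDEX,
    RESIDUE_CHARGE,
    UNKNOWN_LABEL,
    VDW_RADII,
    ZIMMERMAN_POLAR_THRESHOLD,
    ZIMMERMAN_POLARITY,
)
from .errors import ConfigError, ConstraintError
from .geometry import place_virtual_cbeta, residue_canonical_transform
from .structure_io import BackboneStructure

__all__ = [
    "VoxelConfig",
    "Frame",
    "voxelise_frame",
    "voxelise_structure",
    "assign_polarity",
    "assign_charge",
    "encode_property_channel",
]

# element channel layout per atom encoding; CA and the virtual CB share the
# carbon channel unless the encoding gives them channels of their own
_CHANNEL_MAPS = {
    "CNO": {"C": 0, "CA": 0, "CB": None, "N": 1, "O": 2},
    "CNOCB": {"C": 0, "CA": 0, "N": 1, "O": 2, "CB": 3},
    "CNOCBCA": {"C": 0, "N": 1, "O": 2, "CB": 3, "CA": 4},
}
_N_ATOM_CHANNELS = {"CNO": 3, "CNOCB": 4, "CNOCBCA": 5}
_ATOM_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class VoxelConfig:
    """Geometry and encoding of the voxel frames."""

    frame_edge_length: float = 12.0
    voxels_per_side: int = 21
    atom_encoding: str = "CNOCBCA"
    density_mode: str = "gaussian"
    property_channel: str = "none"
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self):
        if self.frame_edge_length <= 0:
            raise ConfigError("frame_edge_length must be positive")
        if self.voxels_per_side < 1 or self.voxels_per_side % 2 == 0:
            raise ConfigError("voxels_per_side must be a positive odd integer "
                              "so that the CA sits in a centre voxel")
        if self.atom_encoding not in _CHANNEL_MAPS:
            raise ConfigError(f"unknown atom_encoding {self.atom_encoding!r}")
        if self.density_mode not in ("gaussian", "occupancy"):
            raise ConfigError(f"unknown density_mode {self.density_mode!r}")
        if self.property_channel not in ("none", "polarity", "charge"):
            raise ConfigError(f"unknown property_channel {self.property_channel!r}")

    @property
    def n_atom_channels(self) -> int:
        return _N_ATOM_CHANNELS[self.atom_encoding]

    @property
    def n_channels(self) -> int:
        return self.n_atom_channels + (0 if self.property_channel == "none" else 1)

    @property
    def voxel_size(self) -> float:
        return self.frame_edge_length / self.voxels_per_side

    def tensor_shape(self) -> tuple[int, int, int, int]:
        v = self.voxels_per_side
        return (v, v, v, self.n_channels)

    def to_dict(self) -> dict:
        return {
            "frame_edge_length": self.frame_edge_length,
            "voxels_per_side": self.voxels_per_side,
            "atom_encoding": self.atom_encoding,
            "density_mode": self.density_mode,
            "property_channel": self.property_channel,
            "vdw_radii": dict(self.vdw_radii),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelConfig":
        return cls(**d)


@dataclass
class Frame:
    """Voxel tensor for one residue plus its label and provenance."""

    tensor: np.ndarray
    label: int
    structure_id: str
    chain_id: str
    residue_index: int
    amino_acid: str
    property_value: int | None = None


def assign_polarity(amino_acid: str) -> int:
    """-1 for non-polar, +1 for polar, by Zimmerman score with threshold 20.

    Under this published scale only D, E, H, K, R clear the threshold;
    a score of exactly 20 would count as polar.
    """
    if amino_acid not in ZIMMERMAN_POLARITY:
        raise KeyError(f"unknown amino acid {amino_acid!r}")
    return -1 if ZIMMERMAN_POLARITY[amino_acid] < ZIMMERMAN_POLAR_THRESHOLD else 1


def assign_charge(amino_acid: str) -> int:
    """Side-chain formal charge class: D,E -> -1; K,R,H -> +1; else 0."""
    if amino_acid not in RESIDUE_CHARGE:
        raise KeyError(f"unknown amino acid {amino_acid!r}")
    return RESIDUE_CHARGE[amino_acid]


def _property_values(structure: BackboneStructure, config: VoxelConfig,
                     constraints=None) -> list[int]:
    assign = assign_polarity if config.property_channel == "polarity" else assign_charge
    values = [assign(r.amino_acid) if r.amino_acid in AA_TO_INDEX else 0
              for r in structure.residues()]
    if constraints is not None:
        if len(constraints) != len(values):
            raise ConstraintError(
                f"constraint vector has length {len(constraints)}, structure "
                f"has {len(values)} residues")
        for i, v in enumerate(constraints):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if int(v) not in (-1, 0, 1):
                raise ConstraintError(f"constraint value {v!r} not in -1/0/+1")
            values[i] = int(v)
    return values


def _nearest_voxel(p: np.ndarray, config: VoxelConfig) -> tuple[int, ...] | None:
    half = config.frame_edge_length / 2.0
    if np.any(np.abs(p) > half + 1e-9):
        return None
    centre = (config.voxels_per_side - 1) // 2
    idx = np.rint(p / config.voxel_size).astype(int) + centre
    idx = np.clip(idx, 0, config.voxels_per_side - 1)
    return tuple(idx)


def _render_gaussian(tensor: np.ndarray, p: np.ndarray, channel: int,
                     sigma: float, config: VoxelConfig) -> None:
    v, delta = config.voxels_per_side, config.voxel_size
    centre = (v - 1) / 2.0
    cutoff = 2.0 * sigma
    grid = (p / delta) + centre  # fractional voxel coordinates of the atom
    lo = np.maximum(np.ceil(grid - cutoff / delta), 0).astype(int)
    hi = np.minimum(np.floor(grid + cutoff / delta), v - 1).astype(int)
    if np.any(lo > hi):
        return
    ax = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    di, dj, dk = [(a - grid[k]) * delta for k, a in enumerate(ax)]
    d2 = (di[:, None, None] ** 2 + dj[None, :, None] ** 2
          + dk[None, None, :] ** 2)
    dens = np.exp(-d2 / (2.0 * sigma ** 2))
    dens[d2 > cutoff ** 2] = 0.0
    tensor[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1, channel] += dens


def _collect_atoms(structure: BackboneStructure, config: VoxelConfig):
    """(atom kind, coordinate) for every atom the encoding voxelises."""
    channel_map = _CHANNEL_MAPS[config.atom_encoding]
    atoms = []
    for res in structure.residues():
        if res.cb_coord is None:
            res.cb_coord = place_virtual_cbeta(res)
        for name, coord in res.backbone_atoms(include_cb=True):
            if channel_map.get(name) is None:
                continue
            atoms.append((name, coord))
    return atoms


def voxelise_frame(structure: BackboneStructure, chain_id: str,
                   residue_index: int, config: VoxelConfig,
                   constraints=None) -> Frame:
    """Render the environment of one residue into a voxel tensor.

    All backbone atoms of *all* residues falling inside the canonical cube
    contribute; an atom is in the cube when every canonical coordinate
    satisfies ``|x| <= frame_edge_length / 2``.
    """
    target = structure.chain(chain_id).residues[residue_index]
    transform = residue_canonical_transform(target)
    channel_map = _CHANNEL_MAPS[config.atom_encoding]
    half = config.frame_edge_length / 2.0

    tensor = np.zeros(config.tensor_shape(), dtype=np.float32)
    for name, coord in _collect_atoms(structure, config):
        p = transform.apply(coord)
        if np.any(np.abs(p) > half + 1e-9):
            continue
        channel = channel_map[name]
        if config.density_mode == "gaussian":
            sigma = config.vdw_radii[_ATOM_ELEMENT[name]] / 2.0
            _render_gaussian(tensor, p, channel, sigma, config)
        else:
            idx = _nearest_voxel(p, config)
            if idx is not None:
                tensor[idx + (channel,)] = 1.0

    property_value = None
    if config.property_channel != "none":
        values = _property_values(structure, config, constraints)
        prop_channel = config.n_atom_channels
        for gi, res in enumerate(structure.residues()):
            p = transform.apply(res.ca_coord)
            idx = _nearest_voxel(p, config)
            if idx is not None:
                tensor[idx + (prop_channel,)] = values[gi]
        flat_index = _global_index(structure, chain_id, residue_index)
        property_value = values[flat_index]

    return Frame(
        tensor=tensor,
        label=AA_TO_INDEX.get(target.amino_acid, UNKNOWN_LABEL),
        structure_id=structure.structure_id,
        chain_id=chain_id,
        residue_index=residue_index,
        amino_acid=target.amino_acid,
        property_value=property_value,
    )


def _global_index(structure: BackboneStructure, chain_id: str,
                  residue_index: int) -> int:
    offset = 0
    for chain in structure.chains:
        if chain.chain_id == chain_id:
            return offset + residue_index
        offset += len(chain)
    raise KeyError(f"no chain {chain_id!r}")


def encode_property_channel(frame: Frame, structure: BackboneStructure,
                            config: VoxelConfig, constraints=None) -> Frame:
    """Append a polarity/charge channel to an atom-only frame."""
    if config.property_channel == "none":
        raise ConfigError("config.property_channel is 'none'")
    return voxelise_frame(structure, frame.chain_id, frame.residue_index,
                          config, constraints=constraints)


def voxelise_structure(structure: BackboneStructure, config: VoxelConfig,
                       constraints=None) -> tuple[list[Frame], list[tuple[str, int]]]:
    """One frame per residue with a complete backbone, in chain order.

    Returns ``(frames, skipped)`` where ``skipped`` lists ``(chain_id,
    residue_index)`` of residues that could not be voxelised.
    """
    if structure.n_residues == 0:
        raise ValueError("empty structure")
    frames: list[Frame] = []
    skipped: list[tuple[str, int]] = []
    for chain_id, i, _res in structure.iter_residues():
        try:
            frames.append(voxelise_frame(structure, chain_id, i, config,
                                         constraints=constraints))
        except Exception:  # degenerate geometry etc.
            skipped.append((chain_id, i))
    return frames, skipped
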