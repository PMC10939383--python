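"""Backbone-only protein structure model and PDB input/output.

Side chains are deliberately discarded on ingestion: the design pipeline
operates on N, CA, C, O plus a *virtual* C-beta reconstructed from ideal
geometry, so that the input representation carries no information about the
native residue identity beyond the backbone trace itself.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .constants import ONE_TO_THREE, THREE_TO_ONE
from .errors import EmptyStructureError, PDBFormatError

log = logging.getLogger(__name__)

__all__ = [
    "BackboneResidue",
    "Chain",
    "BackboneStructure",
    "read_backbone",
    "write_pdb",
    "sequence_of",
]

# sanity windows for accepted covalent bond lengths (Angstrom)
_N_CA_RANGE = (1.2, 1.8)
_CA_C_RANGE = (1.3, 1.8)


@dataclass
class BackboneResidue:
    """One residue reduced to its backbone atoms.

    ``cb_coord`` is the virtual C-beta; it is unset on ingestion and filled
    by :func:`voxdesign.geometry.place_virtual_cbeta`.
    """

    chain_id: str
    residue_number: int
    insertion_code: str
    amino_acid: str
    n_coord: np.ndarray
    ca_coord: np.ndarray
    c_coord: np.ndarray
    o_coord: np.ndarray | None = None
    cb_coord: np.ndarray | None = None

    def backbone_atoms(self, include_cb: bool = False):
        """Yield ``(atom_name, coord)`` pairs for the atoms present."""
        yield "N", self.n_coord
        yield "CA", self.ca_coord
        yield "C", self.c_coord
        if self.o_coord is not None:
            yield "O", self.o_coord
        if include_cb and self.cb_coord is not None:
            yield "CB", self.cb_coord


@dataclass
class Chain:
    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class BackboneStructure:
    """Ordered chains of backbone residues.

    In-memory residue indices are 0-based and dense per chain; the author
    numbering from the source file is kept as metadata on each residue.
    """

    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: float | None = None
    skipped_residues: int = 0

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def iter_residues(self):
        for chain in self.chains:
            for i, res in enumerate(chain.residues):
                yield chain.chain_id, i, res

    def residues(self) -> list[BackboneResidue]:
        return [r for _, _, r in self.iter_residues()]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.structure_id}")

    def sequences(self) -> list[str]:
        return [c.sequence() for c in self.chains]

    def sequence(self) -> str:
        return "".join(self.sequences())

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA coordinates over all chains in order."""
        return np.array([r.ca_coord for r in self.residues()], dtype=float)

    def backbone_coords(self, include_cb: bool = False) -> np.ndarray:
        """All backbone atom coordinates, stacked in residue order."""
        coords = []
        for res in self.residues():
            coords.extend(c for _, c in res.backbone_atoms(include_cb=include_cb))
        return np.array(coords, dtype=float)

    def transformed(self, transform) -> "BackboneStructure":
        """Return a copy with every coordinate mapped through ``transform``."""
        out = BackboneStructure(self.structure_id, [], self.resolution,
                                self.skipped_residues)
        for chain in self.chains:
            new = Chain(chain.chain_id)
            for r in chain.residues:
                new.residues.append(BackboneResidue(
                    r.chain_id, r.residue_number, r.insertion_code,
                    r.amino_acid,
                    transform.apply(r.n_coord),
                    transform.apply(r.ca_coord),
                    transform.apply(r.c_coord),
                    None if r.o_coord is None else transform.apply(r.o_coord),
                    None if r.cb_coord is None else transform.apply(r.cb_coord),
                ))
            out.chains.append(new)
        return out


def _bond_ok(a: np.ndarray, b: np.ndarray, window: tuple[float, float]) -> bool:
    d = float(np.linalg.norm(a - b))
    return window[0] <= d <= window[1]


def read_backbone(source: str | os.PathLike, chain_filter: set[str] | None = None,
                  force: bool = False) -> BackboneStructure:
    """Read a PDB file (or PDB text) keeping backbone atoms only.

    Waters, hetero groups, hydrogens and side chains are dropped.  Residues
    missing any of N, CA, C are skipped and counted in
    ``BackboneStructure.skipped_residues``, as are residues whose N-CA or
    CA-C bond length falls outside a covalent sanity window (unless
    ``force``).  Only the first alternate location (altloc '' or 'A') is
    kept, and only MODEL 1 of multi-model files is read.
    """
    text_input = isinstance(source, str) and "\n" in source
    try:
        if text_input:
            st = gemmi.read_pdb_string(source)
        else:
            path = Path(source)
            if not path.exists():
                raise PDBFormatError(f"no such file: {path}")
            st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"could not parse PDB input: {exc}") from exc

    structure_id = st.name or (Path(source).stem if not text_input else "structure")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    out = BackboneStructure(structure_id, resolution=resolution)

    if len(st) == 0:
        raise EmptyStructureError("PDB input contains no model")
    model = st[0]  # MODEL 1 only

    for gchain in model:
        if chain_filter is not None and gchain.name not in chain_filter:
            continue
        chain = Chain(gchain.name)
        for gres in gchain:
            name = gres.name.strip().upper()
            if name == "HOH":
                continue
            if name not in THREE_TO_ONE:
                if gres.het_flag == "A" or name == "UNK":
                    log.warning("skipping non-canonical residue %s %s%d",
                                name, gchain.name, gres.seqid.num)
                    out.skipped_residues += 1
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in gres:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                aname = atom.name.strip()
                if aname in ("N", "CA", "C", "O") and aname not in atoms:
                    atoms[aname] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            if not all(k in atoms for k in ("N", "CA", "C")):
                out.skipped_residues += 1
                continue
            if not force and not (
                _bond_ok(atoms["N"], atoms["CA"], _N_CA_RANGE)
                and _bond_ok(atoms["CA"], atoms["C"], _CA_C_RANGE)
            ):
                log.warning("skipping residue %s%d with implausible bond "
                            "lengths", gchain.name, gres.seqid.num)
                out.skipped_residues += 1
                continue
            chain.residues.append(BackboneResidue(
                chain_id=gchain.name,
                residue_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or " ").strip(),
                amino_acid=THREE_TO_ONE[name],
                n_coord=atoms["N"],
                ca_coord=atoms["CA"],
                c_coord=atoms["C"],
                o_coord=atoms.get("O"),
            ))
        if chain.residues:
            out.chains.append(chain)

    if out.n_residues == 0:
        raise EmptyStructureError(
            f"{structure_id}: no residue with complete N/CA/C backbone")
    return out


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def write_pdb(structure: BackboneStructure, path: str | os.PathLike,
              include_cb: bool = True) -> None:
    """Write backbone ATOM records (plus virtual CB when present) to PDB."""
    if structure.n_residues == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.amino_acid, "UNK")
            for atom_name, coord in res.backbone_atoms(include_cb=include_cb):
                lines.append(
                    "ATOM  {serial:>5d} {name:<4s} {resname:>3s} {chain:1s}"
                    "{resnum:>4d}{icode:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                    "{element:>2s}".format(
                        serial=serial,
                        name=f" {atom_name}" if len(atom_name) < 4 else atom_name,
                        resname=resname,
                        chain=chain.chain_id[:1] or "A",
                        resnum=res.residue_number,
                        icode=res.insertion_code or " ",
                        x=coord[0], y=coord[1], z=coord[2],
                        occ=1.0, b=0.0,
                        element=_ELEMENT[atom_name],
                    ))
                serial += 1
        last = chain.residues[-1]
        lines.append(
            "TER   {serial:>5d}      {resname:>3s} {chain:1s}{resnum:>4d}".format(
                serial=serial,
                resname=ONE_TO_THREE.get(last.amino_acid, "UNK"),
                chain=chain.chain_id[:1] or "A",
                resnum=last.residue_number))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def sequence_of(structure: BackboneStructure) -> list[str]:
    """One-letter sequence string per chain, in chain order."""
    return structure.sequences()
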