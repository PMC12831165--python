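"""Minimal structural utilities for receptor-complex geometry.

Two measurements are supported on a parsed PDB structure:

* ligand-receptor contact annotation — a ligand residue is a contact if
  any of its atoms lies within a distance cutoff (default 4.5 Å,
  inclusive) of any atom of a receptor chain; and
* the Cα-Cα distance between the C-terminal residues of two receptor
  chains, a proxy for the separation of their cytoplasmic domains (in the
  IL-1 receptor crystal complex this distance between IL-1R1 and IL-1R3
  is about 19.9 Å).

Parsing goes through Biopython's PDB parser; only the first model is kept,
alternate locations are reduced to one atom each, and heteroatoms are
excluded by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "Contact",
    "read_pdb",
    "contact_residues",
    "c_terminal_distance",
]


@dataclass
class StructureModel:
    """Flat atom table of one model: parallel arrays over atoms."""

    chain_ids: np.ndarray     # str per atom
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    coordinates: np.ndarray   # (n_atoms, 3) in Å

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite atom coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def chains(self) -> list[str]:
        return sorted(set(self.chain_ids.tolist()))

    def chain_mask(self, chain_id: str) -> np.ndarray:
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise KeyError(
                f"chain {chain_id!r} not in structure (has {self.chains()})"
            )
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (rotation matrix + translation)."""
        coords = self.coordinates @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(self.chain_ids, self.residue_numbers,
                              self.residue_names, self.atom_names, coords)


@dataclass
class Contact:
    """One ligand residue within the cutoff of a receptor chain."""

    ligand_residue_number: int
    ligand_residue_name: str
    partner_chain: str
    min_distance: float


def read_pdb(source, include_hetatm: bool = False) -> StructureModel:
    """Parse PDB-format text into a flat atom table.

    ``source`` may be a filesystem path, an open text handle, or a string
    containing PDB records. Only the first model is retained; for atoms
    with alternate locations, the blank or 'A' altloc is kept.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False
    try:
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("model", handle)
    finally:
        if close:
            handle.close()
    models = list(structure.get_models())
    if not models:
        raise ValueError("no models found in PDB input")
    model = models[0]

    chains, resnums, resnames, atomnames, coords = [], [], [], [], []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " " and not include_hetatm:
                continue
            for atom in residue:
                if atom.is_disordered():
                    alts = {a.get_altloc(): a for a in atom}
                    atom = alts.get("A") or alts.get(" ") or next(iter(alts.values()))
                elif atom.get_altloc() not in (" ", "A", ""):
                    continue
                chains.append(chain.id)
                resnums.append(residue.id[1])
                resnames.append(residue.get_resname())
                atomnames.append(atom.get_name())
                coords.append(atom.get_coord())
    if not coords:
        raise ValueError("no atoms parsed from PDB input")
    return StructureModel(
        chain_ids=np.array(chains, dtype=object),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        atom_names=np.array(atomnames, dtype=object),
        coordinates=np.asarray(coords, dtype=float),
    )


def contact_residues(
    struct: StructureModel,
    ligand_chain: str,
    receptor_chains: list[str],
    cutoff: float = 4.5,
) -> list[Contact]:
    """Ligand residues with any atom within `cutoff` Å of a receptor chain.

    The cutoff is inclusive (a pair at exactly 4.5 Å counts). All atoms
    present in the file are considered (hydrogens included if recorded).
    Returns one entry per (ligand residue, receptor chain) pair in contact,
    with the minimal inter-atomic distance.
    """
    lig_mask = struct.chain_mask(ligand_chain)
    lig_coords = struct.coordinates[lig_mask]
    lig_resnums = struct.residue_numbers[lig_mask]
    lig_resnames = struct.residue_names[lig_mask]

    contacts: list[Contact] = []
    for rec_chain in receptor_chains:
        rec_coords = struct.coordinates[struct.chain_mask(rec_chain)]
        tree = cKDTree(rec_coords)
        dists, _ = tree.query(lig_coords, k=1)
        for resnum in np.unique(lig_resnums):
            res_sel = lig_resnums == resnum
            dmin = float(dists[res_sel].min())
            if dmin <= cutoff:
                contacts.append(Contact(
                    ligand_residue_number=int(resnum),
                    ligand_residue_name=str(lig_resnames[res_sel][0]),
                    partner_chain=rec_chain,
                    min_distance=dmin,
                ))
    return contacts


def contacts_table(contacts: list[Contact]) -> pd.DataFrame:
    cols = ["ligand_residue_number", "ligand_residue_name",
            "partner_chain", "min_distance"]
    return pd.DataFrame([c.__dict__ for c in contacts], columns=cols)


def c_terminal_distance(
    struct: StructureModel, chain_a: str, chain_b: str
) -> tuple[float, int, int]:
    """Cα-Cα distance (Å) between the C-terminal residues of two chains.

    The C-terminal residue is the highest-numbered residue possessing a Cα
    atom in the selected model (crystal structures often truncate true
    termini, so the residue numbers used are returned alongside the
    distance for transparency).
    """

    def terminal_ca(chain_id: str) -> tuple[np.ndarray, int]:
        mask = struct.chain_mask(chain_id) & (struct.atom_names == "CA")
        if not mask.any():
            raise ValueError(f"chain {chain_id!r} has no Cα atoms")
        resnums = struct.residue_numbers[mask]
        coords = struct.coordinates[mask]
        i = int(np.argmax(resnums))
        return coords[i], int(resnums[i])

    ca_a, res_a = terminal_ca(chain_a)
    ca_b, res_b = terminal_ca(chain_b)
    return float(np.linalg.norm(ca_a - ca_b)), res_a, res_b
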