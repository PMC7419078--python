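"""Read and write conformational ensembles and ligand-bound structures.

The pipeline's raw input is a Cα-only conformational ensemble for one
(variant, substrate) condition: either a multi-model PDB file (one MODEL per
frame) or a plain TSV trajectory with columns ``frame, residue_id, x, y, z``.
Residue numbering is 1-based author numbering throughout and is never
remapped, so residue ids in selection strings (e.g. "K275" → 275) address
structures directly. Insertion codes are rejected.

Ligand-bound single-model structures keep all heavy atoms and flag side-chain
atoms (anything outside the backbone set {N, CA, C, O, OXT}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class CaEnsemble:
    """Per-frame Cα coordinates for a labelled (variant, substrate) condition.

    ``coords`` has shape (n_frames, n_residues, 3) in Å; ``residue_ids`` are
    strictly increasing 1-based author numbers. ``state_labels`` (optional)
    carries the generator's hidden ground-truth state per frame; it exists for
    test oracles only and is never read by any pipeline stage.
    """

    residue_ids: np.ndarray
    coords: np.ndarray
    variant_label: str
    substrate_label: str
    state_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[1] != self.residue_ids.size:
            raise ValueError("coords second axis must match residue_ids length")
        if self.residue_ids.size and np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class ProteinAtom:
    residue_id: int
    residue_name: str
    atom_name: str
    is_sidechain: bool
    coord: np.ndarray


@dataclass
class LigandStructure:
    """All protein heavy atoms plus the atoms of one bound ligand."""

    protein_atoms: list[ProteinAtom]
    ligand_atoms: list[tuple[str, np.ndarray]]
    ligand_resname: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise EmptyInputError("ligand has no atoms")
        for atom in self.protein_atoms:
            if not np.all(np.isfinite(atom.coord)):
                raise ValueError("non-finite protein coordinate")

    def residue_names(self) -> dict[int, str]:
        return {a.residue_id: a.residue_name for a in self.protein_atoms}


def _biopython_models(path: str | Path):
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    return list(structure)


def read_ensemble_pdb(path: str | Path, variant_label: str, substrate_label: str) -> CaEnsemble:
    """Read a multi-model Cα trajectory from PDB.

    Frames are ordered by MODEL number; residues by author residue number.
    Every model must contain a CA atom for each residue present in the first
    model. Alternate locations other than blank/'A' are ignored; insertion
    codes are rejected.
    """
    models = _biopython_models(path)
    if not models:
        raise EmptyInputError(f"{path}: no models found")

    frames: list[dict[int, np.ndarray]] = []
    for model in models:
        cas: dict[int, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                het, resseq, icode = residue.id
                if het.strip():
                    continue
                if icode.strip():
                    raise ParseError(
                        f"{path}: insertion codes are unsupported "
                        f"(residue {resseq}{icode.strip()})"
                    )
                if "CA" not in residue:
                    continue
                atom = residue["CA"]
                if atom.is_disordered():
                    atom = atom.disordered_get("A")
                elif atom.get_altloc() not in (" ", "A"):
                    continue
                cas[resseq] = np.asarray(atom.get_coord(), dtype=float)
        frames.append(cas)

    reference = sorted(frames[0])
    if not reference:
        raise EmptyInputError(f"{path}: first model contains no CA atoms")
    coords = np.empty((len(frames), len(reference), 3))
    for m, cas in enumerate(frames):
        for r, resseq in enumerate(reference):
            if resseq not in cas:
                raise ParseError(f"{path}: missing CA in MODEL {m + 1}, residue {resseq}")
            coords[m, r] = cas[resseq]
    return CaEnsemble(np.array(reference), coords, variant_label, substrate_label)


def read_ensemble_tsv(path: str | Path, variant_label: str, substrate_label: str) -> CaEnsemble:
    """Read a TSV trajectory with columns frame, residue_id, x, y, z.

    The (frame × residue) grid must be complete; a ragged grid is an error.
    """
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["frame", "residue_id", "x", "y", "z"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if table.empty:
        raise EmptyInputError(f"{path}: no coordinate rows")

    frames = np.sort(table["frame"].unique())
    residues = np.sort(table["residue_id"].unique())
    pivot = table.set_index(["frame", "residue_id"])
    if pivot.index.has_duplicates:
        raise ParseError(f"{path}: duplicate (frame, residue_id) rows")
    if len(table) != frames.size * residues.size:
        raise ParseError(
            f"{path}: ragged grid — expected {frames.size * residues.size} rows "
            f"({frames.size} frames × {residues.size} residues), found {len(table)}"
        )
    coords = (
        pivot[["x", "y", "z"]]
        .sort_index()
        .to_numpy()
        .reshape(frames.size, residues.size, 3)
    )
    return CaEnsemble(residues, coords, variant_label, substrate_label)


def write_ensemble_pdb(ensemble: CaEnsemble, path: str | Path) -> None:
    """Write a CA-only multi-model PDB (one MODEL per frame)."""
    with open(path, "w") as fh:
        for m in range(ensemble.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, resid in enumerate(ensemble.residue_ids):
                x, y, z = ensemble.coords[m, i]
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  ALA A{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_ensemble_tsv(ensemble: CaEnsemble, path: str | Path) -> None:
    frames = np.repeat(np.arange(ensemble.n_frames), ensemble.n_residues)
    resids = np.tile(ensemble.residue_ids, ensemble.n_frames)
    flat = ensemble.coords.reshape(-1, 3)
    pd.DataFrame(
        {"frame": frames, "residue_id": resids, "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    ).to_csv(path, sep="\t", index=False)


def read_ligand_structure(path: str | Path, ligand_resname: str) -> LigandStructure:
    """Read a single-model PDB with a bound ligand (HETATM records).

    Protein atoms are flagged ``is_sidechain`` when their atom name is outside
    the backbone set {N, CA, C, O, OXT}; hydrogens are dropped.
    """
    models = _biopython_models(path)
    if not models:
        raise EmptyInputError(f"{path}: no models found")
    model = models[0]

    protein: list[ProteinAtom] = []
    ligand: list[tuple[str, np.ndarray]] = []
    for chain in model:
        for residue in chain:
            het, resseq, icode = residue.id
            if icode.strip():
                raise ParseError(f"{path}: insertion codes are unsupported (residue {resseq})")
            name = residue.get_resname().strip()
            for atom in residue:
                if atom.element == "H":
                    continue
                coord = np.asarray(atom.get_coord(), dtype=float)
                if het.strip():
                    if name == ligand_resname:
                        ligand.append((atom.get_name(), coord))
                else:
                    protein.append(
                        ProteinAtom(
                            residue_id=resseq,
                            residue_name=name,
                            atom_name=atom.get_name(),
                            is_sidechain=atom.get_name() not in BACKBONE_ATOMS,
                            coord=coord,
                        )
                    )
    if not ligand:
        raise ParseError(f"{path}: ligand residue '{ligand_resname}' not found")
    return LigandStructure(protein, ligand, ligand_resname)
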