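"""Binding-site census and cross-variant divergence for rational mutant design.

The census lists every residue whose side-chain heavy atoms come within a
cutoff (default 5 Å) of any atom of the bound donor ligand. Glycine, having
no side-chain heavy atoms, never enters a census. Each census residue of a
reference variant is then mapped through a multiple sequence alignment to
read off the equivalent residue in every other variant; positions where a
single variant diverges from an otherwise-consistent set are flagged as
mutation candidates.

"Diverges" is judged at two levels: strict identity (all others identical,
one different — e.g. an Asp against four Glu) and physicochemical class
(all others share a class, one falls outside it — e.g. a lysine against
leucines and an isoleucine, which are all hydrophobic). Columns where two or
more variants stray are reported as non-conserved but not auto-flagged,
since no single substitution would reconcile them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .coevolution import GAP, Msa
from .errors import EmptyInputError
from .structure_io import LigandStructure

#: Coarse physicochemical classes used for the divergence rule.
RESIDUE_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIMFW"},
    **{aa: "polar" for aa in "STNQCY"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    "G": "special",
    "P": "special",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class SiteCensus:
    variant: str
    cutoff: float
    residues: list[tuple[int, str, float]]  # (residue_id, residue_name, min distance)

    def residue_ids(self) -> list[int]:
        return [r[0] for r in self.residues]


def census(structure: LigandStructure, cutoff: float = 5.0,
           variant: str = "") -> SiteCensus:
    """Residues whose side-chain heavy atoms lie within ``cutoff`` of the ligand."""
    if not structure.protein_atoms:
        raise EmptyInputError("structure has no protein atoms")
    ligand_xyz = np.array([c for _, c in structure.ligand_atoms])

    by_residue: dict[int, list[np.ndarray]] = {}
    names: dict[int, str] = {}
    for atom in structure.protein_atoms:
        names[atom.residue_id] = atom.residue_name
        if atom.is_sidechain:
            by_residue.setdefault(atom.residue_id, []).append(atom.coord)

    rows: list[tuple[int, str, float]] = []
    for resid in sorted(by_residue):
        d = float(cdist(np.array(by_residue[resid]), ligand_xyz).min())
        if d <= cutoff:
            rows.append((resid, names[resid], d))
    return SiteCensus(variant=variant or "structure", cutoff=cutoff, residues=rows)


@dataclass
class DivergenceRow:
    residue_id: int
    alignment_column: int  # 1-based
    identities: dict[str, str]  # variant -> one-letter symbol (or gap)
    conserved: bool
    candidate: bool
    divergent_variant: str | None


@dataclass
class DivergenceTable:
    reference_variant: str
    rows: list[DivergenceRow]

    def candidates(self) -> list[DivergenceRow]:
        return [r for r in self.rows if r.candidate]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {"residue_id": r.residue_id, "alignment_column": r.alignment_column}
            rec.update(r.identities)
            rec.update(
                conserved=r.conserved,
                candidate=r.candidate,
                divergent_variant=r.divergent_variant or "",
            )
            records.append(rec)
        return pd.DataFrame(records)

    def summary(self) -> str:
        lines = []
        for r in self.candidates():
            div_sym = r.identities[r.divergent_variant]
            others = [s for v, s in r.identities.items() if v != r.divergent_variant]
            consensus = max(set(others), key=others.count)
            lines.append(
                f"column {r.alignment_column} (residue {r.residue_id} in "
                f"{self.reference_variant}): {r.divergent_variant} carries "
                f"{div_sym} against {consensus}-type consensus — mutation candidate"
            )
        return "\n".join(lines)


def _single_divergent(identities: dict[str, str]) -> str | None:
    """The unique outlier variant, or None.

    A variant is the outlier when all the others agree strictly and it
    differs, or when all the others share a physicochemical class and its
    class is different. Exactly one such variant must exist.
    """
    outliers = []
    for v, sym in identities.items():
        others = [s for w, s in identities.items() if w != v]
        if any(s == GAP for s in others) or sym == GAP:
            continue
        strict = len(set(others)) == 1 and sym != others[0]
        other_classes = {RESIDUE_CLASSES.get(s) for s in others}
        by_class = (
            len(other_classes) == 1
            and None not in other_classes
            and RESIDUE_CLASSES.get(sym) not in other_classes
        )
        if strict or by_class:
            outliers.append(v)
    return outliers[0] if len(outliers) == 1 else None


def _column_of_position(reference_row: str, position: int) -> int:
    """0-based alignment column of the 1-based ungapped reference position."""
    count = 0
    for col, sym in enumerate(reference_row):
        if sym != GAP:
            count += 1
            if count == position:
                return col
    raise KeyError(
        f"residue {position} is beyond the reference sequence in the alignment "
        f"({count} non-gap columns)"
    )


def divergence(
    censuses: Mapping[str, SiteCensus],
    alignment: Msa,
    reference_variant: str,
    residue_offset: int = 0,
) -> DivergenceTable:
    """Cross-variant conservation table over the reference's census residues.

    Alignment rows are matched to variants by id. Structure residue id minus
    ``residue_offset`` gives the 1-based position in the reference sequence
    (offset 0 when author numbering starts at 1 with no gaps in the
    construct). The reference row's residue identity is validated against
    the census residue name where available.
    """
    if reference_variant not in censuses:
        raise KeyError(f"no census for reference variant '{reference_variant}'")
    row_of = {name: k for k, name in enumerate(alignment.ids)}
    for variant in censuses:
        if variant not in row_of:
            raise KeyError(f"variant '{variant}' has no row in the alignment")

    ref_row = alignment.sequences[row_of[reference_variant]]
    rows: list[DivergenceRow] = []
    for resid, resname, _ in censuses[reference_variant].residues:
        position = resid - residue_offset
        col = _column_of_position(ref_row, position)
        expected = THREE_TO_ONE.get(resname)
        if expected is not None and ref_row[col] != expected:
            raise ValueError(
                f"alignment/structure mismatch at residue {resid}: structure has "
                f"{resname} ({expected}) but reference alignment row has {ref_row[col]}"
            )
        identities = {
            variant: alignment.sequences[row_of[variant]][col] for variant in censuses
        }
        symbols = set(identities.values())
        conserved = len(symbols) == 1 and GAP not in symbols
        divergent = None if conserved else _single_divergent(identities)
        rows.append(
            DivergenceRow(
                residue_id=resid,
                alignment_column=col + 1,
                identities=identities,
                conserved=conserved,
                candidate=divergent is not None,
                divergent_variant=divergent,
            )
        )
    return DivergenceTable(reference_variant=reference_variant, rows=rows)


def export_census_tsv(site: SiteCensus, path) -> None:
    pd.DataFrame(
        site.residues, columns=["residue_id", "residue_name", "min_sidechain_distance"]
    ).to_csv(path, sep="\t", index=False)
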