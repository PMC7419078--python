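"""Binary Cα contact matrices over interface residue selections.

Each ensemble frame is featurized as a symmetric binary matrix over a
residue selection: entry (i, j) is 1 iff the Cα–Cα distance is ≤ 8 Å (the
cutoff is inclusive). The diagonal is 1 (self-distance zero). Selections of
different sizes are equalised by appending trailing zero rows/columns
(21 → 22 keeps the residue→row mapping stable and matches the 22×22 corpus
used for the five UGT interfaces). Matrices from all conditions are merged
and split 80/20 into training and validation sets with a seeded draw.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError
from .structure_io import CaEnsemble

DEFAULT_CUTOFF = 8.0

#: Enzyme–substrate interface residues of the five group H UGT variants.
INTERFACE_SELECTIONS: dict[str, str] = {
    "76E1": "14-15, 109, 129-130, 266-269, 343-348, 365-370",
    "76E2": "14-15, 110, 130-131, 266-271, 330, 344-349, 353, 368-369, 372",
    "76E4": "14-15, 130-131, 267-271, 330, 345-350, 353, 367, 369, 370-371, 373",
    "76E5": "12-15, 129-130, 265-269, 336, 338-341, 344, 358-361, 364",
    "76D1": "13-15, 17, 125-126, 264-267, 342, 344-347, 350, 364-367, 370",
}

_TOKEN = re.compile(r"^\s*(\d+)\s*(?:[-–]\s*(\d+)\s*)?$")


@dataclass(frozen=True)
class ResidueSelection:
    """An expanded, deduplicated, sorted list of 1-based residue ids."""

    residue_ids: tuple[int, ...]
    source_string: str = ""

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise ValueError("selection must contain at least one residue")
        ids = tuple(sorted(set(self.residue_ids)))
        object.__setattr__(self, "residue_ids", ids)

    def __len__(self) -> int:
        return len(self.residue_ids)


def parse_selection(text: str) -> ResidueSelection:
    """Parse "a, b-c, ..." (hyphen or en-dash ranges) into a ResidueSelection."""
    if not text or not text.strip():
        raise ParseError("empty selection string")
    ids: list[int] = []
    for token in text.split(","):
        match = _TOKEN.match(token)
        if match is None:
            raise ParseError(f"cannot parse selection token '{token.strip()}'")
        lo = int(match.group(1))
        hi = int(match.group(2)) if match.group(2) else lo
        if hi < lo:
            raise ParseError(f"reversed range '{token.strip()}' ({hi} < {lo})")
        ids.extend(range(lo, hi + 1))
    return ResidueSelection(tuple(ids), source_string=text)


@dataclass
class ContactMatrix:
    """A symmetric binary contact matrix with its condition labels."""

    matrix: np.ndarray
    labels: tuple[str, str, int]  # (variant, substrate, frame_index)
    padded_from: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def contact_matrix(
    coords: np.ndarray,
    residue_ids: Sequence[int],
    selection: ResidueSelection,
    cutoff: float = DEFAULT_CUTOFF,
    labels: tuple[str, str, int] = ("", "", 0),
) -> ContactMatrix:
    """Contact matrix of one frame over the selected residues.

    ``coords`` is (n_residues, 3); ``residue_ids`` maps rows to author
    numbers. Raises if a selected residue is absent from the frame.
    """
    coords = np.asarray(coords, dtype=float)
    index = {int(r): k for k, r in enumerate(residue_ids)}
    missing = [r for r in selection.residue_ids if r not in index]
    if missing:
        raise KeyError(f"selected residue(s) not present in frame: {missing}")
    rows = [index[r] for r in selection.residue_ids]
    sub = coords[rows]
    from scipy.spatial.distance import squareform, pdist

    dists = squareform(pdist(sub))
    mat = (dists <= cutoff).astype(np.uint8)
    return ContactMatrix(matrix=mat, labels=labels, padded_from=mat.shape[0])


def ensemble_contact_matrices(
    ensemble: CaEnsemble,
    selection: ResidueSelection,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ContactMatrix]:
    """Featurize every frame of an ensemble (vectorised over frames)."""
    index = {int(r): k for k, r in enumerate(ensemble.residue_ids)}
    missing = [r for r in selection.residue_ids if r not in index]
    if missing:
        raise KeyError(f"selected residue(s) not present in ensemble: {missing}")
    rows = [index[r] for r in selection.residue_ids]
    sub = ensemble.coords[:, rows, :]  # (F, S, 3)
    diff = sub[:, :, None, :] - sub[:, None, :, :]
    within = (np.einsum("fijk,fijk->fij", diff, diff) <= cutoff * cutoff).astype(np.uint8)
    return [
        ContactMatrix(
            matrix=within[f],
            labels=(ensemble.variant_label, ensemble.substrate_label, f),
            padded_from=len(rows),
        )
        for f in range(ensemble.n_frames)
    ]


def pad_matrix(m: ContactMatrix, target_size: int) -> ContactMatrix:
    """Append trailing zero rows/columns until the matrix reaches target_size."""
    if target_size < m.size:
        raise ValueError(f"target_size {target_size} < current size {m.size}")
    if target_size == m.size:
        return m
    extra = target_size - m.size
    padded = np.pad(m.matrix, ((0, extra), (0, extra)))
    return ContactMatrix(matrix=padded, labels=m.labels, padded_from=m.padded_from)


@dataclass
class ContactDataset:
    """Merged, labelled, padded contact matrices with a seeded 80/20 split."""

    matrices: np.ndarray  # (n, S, S) uint8
    labels: list[tuple[str, str, int]]
    train_indices: np.ndarray
    val_indices: np.ndarray
    split_seed: int
    cutoff: float = DEFAULT_CUTOFF
    selections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.uint8)
        n = self.matrices.shape[0]
        combined = np.concatenate([self.train_indices, self.val_indices])
        if sorted(combined.tolist()) != list(range(n)):
            raise ValueError("train/val indices must partition the dataset")

    @property
    def n(self) -> int:
        return self.matrices.shape[0]

    @property
    def size(self) -> int:
        return self.matrices.shape[1]


def split_indices(n: int, split_ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform split with |train| = round(split_ratio · n)."""
    if not 0.0 < split_ratio < 1.0:
        raise ValueError("split_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    # Python's round() is banker's rounding; round-half-up matches the usual
    # reading of "round(0.8·n)" and keeps 80/20 exact whenever 0.8·n is whole.
    n_train = int(np.floor(split_ratio * n + 0.5))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def build_dataset(
    ensembles: Sequence[tuple[CaEnsemble, ResidueSelection]],
    cutoff: float = DEFAULT_CUTOFF,
    split_ratio: float = 0.8,
    seed: int = 0,
) -> ContactDataset:
    """Featurize, pad to the common size, merge, and split all conditions.

    The common size is the largest selection across conditions; smaller
    matrices get trailing zero padding.
    """
    if not ensembles:
        raise EmptyInputError("no ensembles supplied")
    target = max(len(sel) for _, sel in ensembles)
    all_matrices: list[np.ndarray] = []
    all_labels: list[tuple[str, str, int]] = []
    selections: dict[str, str] = {}
    for ensemble, selection in ensembles:
        selections[f"{ensemble.variant_label}/{ensemble.substrate_label}"] = (
            selection.source_string or ",".join(map(str, selection.residue_ids))
        )
        for cm in ensemble_contact_matrices(ensemble, selection, cutoff):
            cm = pad_matrix(cm, target)
            all_matrices.append(cm.matrix)
            all_labels.append(cm.labels)
    stacked = np.stack(all_matrices)
    train, val = split_indices(stacked.shape[0], split_ratio, seed)
    return ContactDataset(
        matrices=stacked,
        labels=all_labels,
        train_indices=train,
        val_indices=val,
        split_seed=seed,
        cutoff=cutoff,
        selections=selections,
    )


def save_dataset(dataset: ContactDataset, path: str | Path) -> None:
    """Serialize to one .npz container plus a sidecar label TSV."""
    path = Path(path)
    meta = json.dumps({
        "cutoff": dataset.cutoff,
        "split_seed": dataset.split_seed,
        "selections": dataset.selections,
    })
    np.savez_compressed(
        path,
        matrices=dataset.matrices,
        variants=np.array([l[0] for l in dataset.labels]),
        substrates=np.array([l[1] for l in dataset.labels]),
        frames=np.array([l[2] for l in dataset.labels]),
        train_indices=dataset.train_indices,
        val_indices=dataset.val_indices,
        meta=np.array(meta),
    )
    sidecar = path.with_suffix(".labels.tsv")
    pd.DataFrame(dataset.labels, columns=["variant", "substrate", "frame"]).to_csv(
        sidecar, sep="\t", index=False
    )


def load_dataset(path: str | Path) -> ContactDataset:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        labels = [
            (str(v), str(s), int(f))
            for v, s, f in zip(data["variants"], data["substrates"], data["frames"])
        ]
        return ContactDataset(
            matrices=data["matrices"],
            labels=labels,
            train_indices=data["train_indices"],
            val_indices=data["val_indices"],
            split_seed=meta["split_seed"],
            cutoff=meta["cutoff"],
            selections=meta["selections"],
        )
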