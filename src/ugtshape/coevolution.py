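"""Coevolution post-processing: MSA filtering, scoring, scaling, nulling.

The workflow mirrors standard residue-coevolution practice: an alignment is
pruned by coverage against the query and by pairwise identity redundancy,
pairwise scores are computed over the remaining columns, scaled, and every
score below the matrix average is treated as null (not significant). The
built-in scorer is plug-in mutual information with the average-product
correction (APC), which suppresses the entropic/phylogenetic background that
inflates raw MI. Pseudo-likelihood scorers (ccmpred/plmDCA-style) are not
reimplemented; an externally computed score matrix can be loaded from TSV
with :func:`read_score_tsv` and pushed through the same significance step.

Positions are 1-based in the public reporting API, matching residue
numbering conventions (e.g. the G347–C352 / G347–C364 pair queries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError

GAP = "-"


@dataclass
class Msa:
    """An aligned set of sequences with one row designated as the query."""

    ids: list[str]
    sequences: list[str]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError("alignment has no sequences")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if not 0 <= self.reference_index < len(self.sequences):
            raise ValueError("reference_index out of range")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def reference(self) -> str:
        return self.sequences[self.reference_index]


def read_fasta_msa(path: str | Path, reference_id: str | None = None) -> Msa:
    """Load an aligned FASTA or A3M file (lowercase insert states stripped)."""
    from Bio import SeqIO

    ids, seqs = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        # A3M marks insertions relative to the query as lowercase; removing
        # them restores a rectangular alignment in query coordinates.
        seqs.append("".join(c for c in str(record.seq) if not c.islower()).replace(".", ""))
    if not seqs:
        raise EmptyInputError(f"{path}: no sequences")
    ref = 0
    if reference_id is not None:
        try:
            ref = ids.index(reference_id)
        except ValueError:
            raise ParseError(f"{path}: reference id '{reference_id}' not found") from None
    return Msa(ids=ids, sequences=seqs, reference_index=ref)


@dataclass
class CoevolutionMatrix:
    """L×L raw scores plus, after significance filtering, the scaled scores,
    the below-average null mask and the mean used to draw it."""

    raw: np.ndarray
    scaled: np.ndarray | None = None
    null_mask: np.ndarray | None = None
    mean_score: float | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[0] != self.raw.shape[1]:
            raise ValueError("raw must be a square matrix")
        if not np.allclose(self.raw, self.raw.T):
            raise ValueError("raw must be symmetric")

    @property
    def length(self) -> int:
        return self.raw.shape[0]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _coverage(row: str, reference: str) -> float:
    ref_cols = [k for k, c in enumerate(reference) if c != GAP]
    if not ref_cols:
        return 0.0
    return sum(row[k] != GAP for k in ref_cols) / len(ref_cols)


def _identity(a: str, b: str) -> float:
    shared = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not shared:
        return 0.0
    return sum(x == y for x, y in shared) / len(shared)


def filter_msa(msa: Msa, min_coverage: float = 0.75, max_identity: float = 0.90) -> Msa:
    """Coverage and redundancy pruning in the style of hhfilter.

    Coverage is the non-gap fraction over the reference's non-gap columns;
    rows below ``min_coverage`` are dropped. Remaining rows are then scanned
    greedily in input order (reference first, always kept) and a row is
    dropped when its identity to any already-kept row exceeds
    ``max_identity``. Identity is matches over mutually non-gap positions.
    """
    ref = msa.reference
    order = [msa.reference_index] + [
        k for k in range(msa.n_sequences) if k != msa.reference_index
    ]
    kept: list[int] = []
    for k in order:
        row = msa.sequences[k]
        if k != msa.reference_index and _coverage(row, ref) < min_coverage:
            continue
        if any(_identity(row, msa.sequences[j]) > max_identity for j in kept):
            continue
        kept.append(k)
    kept_sorted = sorted(kept)
    return Msa(
        ids=[msa.ids[k] for k in kept_sorted],
        sequences=[msa.sequences[k] for k in kept_sorted],
        reference_index=kept_sorted.index(msa.reference_index),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _encode(msa: Msa, gap_as_symbol: bool) -> tuple[np.ndarray, int]:
    alphabet = sorted({c for s in msa.sequences for c in s} - {GAP})
    index = {c: k for k, c in enumerate(alphabet)}
    n_sym = len(alphabet) + (1 if gap_as_symbol else 0)
    gap_code = len(alphabet) if gap_as_symbol else -1
    arr = np.array(
        [[index.get(c, gap_code) for c in row] for row in msa.sequences], dtype=np.int64
    )
    return arr, n_sym


def mutual_information(msa: Msa, gap_as_symbol: bool = True) -> np.ndarray:
    """Plug-in (maximum-likelihood) MI in nats for every column pair.

    Gaps count as an extra 21st symbol by default; with
    ``gap_as_symbol=False`` rows gapped in either column are dropped per pair.
    """
    arr, n_sym = _encode(msa, gap_as_symbol)
    n, L = arr.shape
    mi = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            ci, cj = arr[:, i], arr[:, j]
            if not gap_as_symbol:
                mask = (ci >= 0) & (cj >= 0)
                ci, cj = ci[mask], cj[mask]
                if ci.size == 0:
                    continue
            joint = np.bincount(ci * n_sym + cj, minlength=n_sym * n_sym).reshape(n_sym, n_sym)
            p = joint / ci.size
            pi = p.sum(axis=1, keepdims=True)
            pj = p.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = p * np.log(p / (pi * pj))
            mi[i, j] = mi[j, i] = np.nansum(terms)
    return mi


def score_coevolution(msa: Msa, gap_as_symbol: bool = True) -> CoevolutionMatrix:
    """APC-corrected mutual information: raw(i,j) = MI(i,j) − MI_i·MI_j/MI̅.

    MI_i is column i's mean MI against all other columns and MI̅ the grand
    off-diagonal mean; the product correction removes the per-column
    background shared by conserved/variable columns. Diagonal is zeroed.
    """
    if msa.n_sequences < 2:
        raise EmptyInputError("coevolution scoring needs at least 2 sequences")
    if msa.length < 2:
        raise EmptyInputError("coevolution scoring needs at least 2 columns")
    mi = mutual_information(msa, gap_as_symbol=gap_as_symbol)
    L = mi.shape[0]
    col_mean = mi.sum(axis=1) / (L - 1)
    grand_mean = mi[np.triu_indices(L, k=1)].mean() if L > 1 else 0.0
    if grand_mean > 0:
        apc = np.outer(col_mean, col_mean) / grand_mean
        raw = mi - apc
    else:
        raw = mi.copy()
    np.fill_diagonal(raw, 0.0)
    raw = (raw + raw.T) / 2.0
    return CoevolutionMatrix(raw=raw)


def apply_significance(matrix: CoevolutionMatrix) -> CoevolutionMatrix:
    """Null everything below the mean raw score; z-score the rest for reporting.

    The mean is taken over the off-diagonal upper triangle. Entries exactly
    equal to the mean are retained. Scaled scores are (raw − mean)/std over
    the same support; a zero-variance matrix scales to all-zero with a
    warning.
    """
    L = matrix.length
    iu = np.triu_indices(L, k=1)
    values = matrix.raw[iu]
    mean = float(values.mean()) if values.size else 0.0
    std = float(values.std()) if values.size else 0.0
    if std <= 1e-12 * max(1.0, abs(mean)):
        warnings.warn("coevolution scores have zero variance; scaled scores set to 0")
        scaled = np.zeros_like(matrix.raw)
    else:
        scaled = (matrix.raw - mean) / std
    # strict "below the mean" with a float-noise guard so entries equal to
    # the mean (up to rounding of the mean itself) are retained
    tol = 1e-9 * max(1.0, abs(mean))
    null_mask = matrix.raw < mean - tol
    np.fill_diagonal(null_mask, True)
    np.fill_diagonal(scaled, 0.0)
    return replace(matrix, scaled=scaled, null_mask=null_mask, mean_score=mean)


def position_report(matrix: CoevolutionMatrix, position: int) -> list[tuple[int, float]]:
    """Non-null partners of a 1-based position, best scaled score first.

    Ties break on the lower partner index. Requires
    :func:`apply_significance` to have been applied.
    """
    if matrix.null_mask is None or matrix.scaled is None:
        raise ValueError("apply_significance must be called before position_report")
    L = matrix.length
    if not 1 <= position <= L:
        raise IndexError(f"position {position} out of range [1, {L}]")
    i = position - 1
    partners = [
        (j + 1, float(matrix.scaled[i, j]))
        for j in range(L)
        if j != i and not matrix.null_mask[i, j]
    ]
    partners.sort(key=lambda t: (-t[1], t[0]))
    return partners


# ---------------------------------------------------------------------------
# External score matrices and export
# ---------------------------------------------------------------------------

def read_score_tsv(path: str | Path) -> CoevolutionMatrix:
    """Load a square score matrix (e.g. from an external pseudo-likelihood
    scorer) so the same significance step can be applied to it."""
    arr = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ParseError(f"{path}: expected a square matrix, got shape {arr.shape}")
    sym = (arr + arr.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return CoevolutionMatrix(raw=sym)


def write_score_tsv(matrix: CoevolutionMatrix, path: str | Path, which: str = "raw") -> None:
    data = getattr(matrix, which)
    if data is None:
        raise ValueError(f"matrix field '{which}' not computed")
    pd.DataFrame(data).to_csv(path, sep="\t", header=False, index=False)


def plot_heatmap(matrix: CoevolutionMatrix, path: str | Path) -> None:
    """Contact-style heatmap of the scaled scores with nulled entries blanked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.scaled if matrix.scaled is not None else matrix.raw
    shown = np.where(matrix.null_mask, np.nan, data) if matrix.null_mask is not None else data
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(shown, origin="lower", cmap="viridis",
                   extent=(0.5, matrix.length + 0.5, 0.5, matrix.length + 0.5))
    fig.colorbar(im, ax=ax, label="scaled coevolution score")
    ax.set_xlabel("position")
    ax.set_ylabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
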