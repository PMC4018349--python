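"""Conservation statistics for peptide sets: pairwise global alignment,
percent identity, strict consensus motifs and neighbor-joining trees.

The alignment core is Needleman-Wunsch with linear gap costs and a fixed
traceback tie-break (diagonal > up > left), which makes identity counts
deterministic. The peptide sets handled here are short and near-identical
(family paralogs and repeat copies from one precursor), where a binary
match/mismatch score is the appropriate model - a substitution matrix would
add parameters without changing any of the counts reported.

Consensus motifs follow the strict-invariance convention used for
neuropeptide family logos: a column shows its residue only when every member
agrees, otherwise ``X``, with an ``amide`` suffix when every member is
amidated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

__all__ = [
    "Alignment",
    "ConsensusMotif",
    "DistanceMatrixTree",
    "global_align",
    "identity_pct",
    "consensus_motif",
    "identity_distance_matrix",
    "nj_tree",
]


@dataclass(frozen=True)
class Alignment:
    seq_a_aligned: str
    seq_b_aligned: str
    score: float
    identical_positions: int
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.seq_a_aligned) != len(self.seq_b_aligned):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class ConsensusMotif:
    columns: str
    members: tuple[str, ...]
    amidated: bool = False

    @property
    def motif(self) -> str:
        return self.columns + ("amide" if self.amidated else "")

    @property
    def invariant_positions(self) -> int:
        return sum(1 for c in self.columns if c != "X")


@dataclass(frozen=True)
class DistanceMatrixTree:
    labels: tuple[str, ...]
    distances: np.ndarray
    newick: str
    tree: object  # skbio.TreeNode


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment under a linear gap model.

    Traceback prefers diagonal over up (gap in ``b``) over left (gap in
    ``a``), so co-optimal alignments resolve deterministically.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)
    # traceback, diagonal > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j],
            score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch),
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return Alignment(
        seq_a_aligned=aligned_a,
        seq_b_aligned=aligned_b,
        score=float(score[n, m]),
        identical_positions=identical,
        identity_pct=100.0 * identical / len(aligned_a),
    )


def identity_pct(a: str, b: str, **kwargs) -> float:
    return global_align(a, b, **kwargs).identity_pct


def consensus_motif(
    peptides: Sequence[str],
    amidated: Sequence[bool] | None = None,
    gap_budget: int = 5,
) -> ConsensusMotif:
    """Strict consensus over a peptide set.

    Equal-length members are stacked directly; unequal members are aligned
    pairwise against a member of the modal length, and members whose length
    differs from the mode by more than ``gap_budget`` raise an error naming
    the outliers. A column keeps its residue only when invariant across all
    members (gaps count as disagreement).
    """
    peptides = [p.upper() for p in peptides]
    if len(peptides) < 2:
        raise ValueError("consensus needs at least two peptides")
    lengths = [len(p) for p in peptides]
    modal = max(sorted(set(lengths)), key=lengths.count)
    outliers = [p for p in peptides if abs(len(p) - modal) > gap_budget]
    if outliers:
        raise ValueError(f"unalignable members (length outliers): {outliers}")
    reference = next(p for p in peptides if len(p) == modal)
    rows: list[str] = []
    for p in peptides:
        if len(p) == modal:
            rows.append(p)
            continue
        aln = global_align(reference, p)
        # project the member onto reference columns; reference gaps (member
        # insertions) are disagreements folded into the flanking columns
        projected = [
            y for x, y in zip(aln.seq_a_aligned, aln.seq_b_aligned) if x != "-"
        ]
        rows.append("".join(projected))
    columns = "".join(
        col[0] if len(set(col)) == 1 else "X" for col in zip(*rows)
    )
    all_amidated = bool(amidated) and all(amidated)
    return ConsensusMotif(columns, tuple(peptides), all_amidated)


def identity_distance_matrix(
    labels: Sequence[str], sequences: Sequence[str], **align_kwargs
) -> np.ndarray:
    """Pairwise p-distance matrix d = 1 - identity/100 from global alignments."""
    k = len(sequences)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ident = global_align(sequences[i], sequences[j], **align_kwargs).identity_pct
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return d


def nj_tree(labels: Sequence[str], distances: np.ndarray) -> DistanceMatrixTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to the
    adjacent branch; the result is an unrooted tree serialised as newick.
    Exact on additive matrices.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (len(labels), len(labels)):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = DistanceMatrix(distances, ids=list(labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    newick = str(tree).strip()
    return DistanceMatrixTree(tuple(labels), distances, newick, tree)
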