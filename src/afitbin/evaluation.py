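"""Binning evaluation: precision/recall/F-score and composition separation.

Given a bins x species contingency matrix M = [m_ij] over the contigs that
carry both a predicted bin and a truth label,

    precision = sum_i max_j m_ij / sum_ij m_ij   (bin purity)
    recall    = sum_j max_i m_ij / sum_ij m_ij   (species completeness)
    F-score   = harmonic mean of the two.

Transposing M swaps precision and recall and leaves the F-score unchanged, so
the F-score does not depend on the row/column orientation convention.

The module also provides the intra- vs inter-species Euclidean distance
summary used to compare composition vectors, and the plain 256-dimensional
tetranucleotide frequency (TNF) vector as a comparator for AFIT.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_formats import BinningResult

__all__ = [
    "ConfusionMatrix",
    "SeparationSummary",
    "confusion_matrix",
    "precision",
    "recall",
    "f_score",
    "distance_separation_summary",
    "compute_tnf",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Bins x species contig counts with label maps."""

    matrix: np.ndarray  # (k, n) integer counts
    bin_labels: tuple
    species_labels: tuple
    n_dropped: int  # contigs without a truth label

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.bin_labels),
                            columns=list(self.species_labels))


@dataclass(frozen=True)
class SeparationSummary:
    """Mean/SD of pairwise Euclidean distances within and between species."""

    mean_intra: float
    sd_intra: float
    mean_inter: float
    sd_inter: float


def confusion_matrix(predicted, truth: dict[str, str]) -> ConfusionMatrix:
    """Contingency matrix of predicted bins (rows) against true species.

    ``predicted`` is a :class:`BinningResult` or a contig -> bin mapping.
    Contigs with a prediction but no truth label are dropped and counted in
    ``n_dropped``; an empty intersection is an error.
    """
    assignments = (
        predicted.assignments if isinstance(predicted, BinningResult) else dict(predicted)
    )
    shared = [cid for cid in assignments if cid in truth]
    if not shared:
        raise ValueError("no contigs are shared between predictions and truth")
    bins = sorted({assignments[c] for c in shared})
    species = sorted({truth[c] for c in shared})
    b_idx = {b: i for i, b in enumerate(bins)}
    s_idx = {s: j for j, s in enumerate(species)}
    M = np.zeros((len(bins), len(species)), dtype=np.int64)
    for c in shared:
        M[b_idx[assignments[c]], s_idx[truth[c]]] += 1
    return ConfusionMatrix(
        matrix=M,
        bin_labels=tuple(bins),
        species_labels=tuple(species),
        n_dropped=len(assignments) - len(shared),
    )


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, ConfusionMatrix):
        M = M.matrix
    M = np.asarray(M)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("confusion matrix must be 2-D and non-empty")
    if M.sum() <= 0:
        raise ValueError("confusion matrix has no counted contigs")
    return M


def precision(M) -> float:
    """Fraction of contigs in the majority species of their bin (row maxima)."""
    M = _as_matrix(M)
    return float(M.max(axis=1).sum() / M.sum())


def recall(M) -> float:
    """Fraction of contigs in the majority bin of their species (column maxima)."""
    M = _as_matrix(M)
    return float(M.max(axis=0).sum() / M.sum())


def f_score(M) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    p, r = precision(M), recall(M)
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


def distance_separation_summary(vectors, labels) -> SeparationSummary:
    """Intra- vs inter-species Euclidean distance statistics.

    ``vectors`` is an (N, d) array of composition vectors (AFIT or TNF) and
    ``labels`` the aligned species labels.  Requires at least two species and
    at least one intra-species pair.
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    if vectors.shape[0] != labels.shape[0]:
        raise ValueError("vectors and labels must be aligned")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two species for an inter-species distance")
    D = squareform(pdist(vectors, metric="euclidean"))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    intra = D[iu][same[iu]]
    inter = D[iu][~same[iu]]
    if intra.size == 0:
        raise ValueError("no species has two contigs; intra distances undefined")
    return SeparationSummary(
        mean_intra=float(intra.mean()),
        sd_intra=float(intra.std()),
        mean_inter=float(inter.mean()),
        sd_inter=float(inter.std()),
    )


_TNF_KMERS = ["".join(p) for p in product("ACGT", repeat=4)]
_TNF_INDEX = {kmer: i for i, kmer in enumerate(_TNF_KMERS)}


def compute_tnf(sequence: str) -> np.ndarray:
    """Plain 256-dimensional tetranucleotide frequency vector (sums to 1).

    Counts every 4-mer window whose four bases are all in {A, C, G, T}; no
    reverse-complement canonicalization is applied.
    """
    sequence = sequence.upper()
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4 nt has no tetranucleotides")
    counts = np.zeros(256, dtype=float)
    n_valid = 0
    for i in range(len(sequence) - 3):
        idx = _TNF_INDEX.get(sequence[i : i + 4])
        if idx is not None:
            counts[idx] += 1
            n_valid += 1
    if n_valid == 0:
        raise ValueError("no valid ACGT-only tetranucleotide windows")
    return counts / n_valid
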