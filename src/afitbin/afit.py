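"""Aggregate l-mer initial/terminal (AFIT) composition vectors.

A DNA duplex carries every oligomer together with its reverse complement, so
any composition statistic should not depend on which strand a contig was
assembled from.  The sixteen dinucleotides fall into ten reverse-complement
equivalence classes: six pairs ``{x, revcomp(x)}`` and the four palindromes
``AT``, ``CG``, ``GC``, ``TA``.  The AFIT vector of a contig counts, for every
substring length l from 2 to 10, how many substrings have a (first base, last
base) dinucleotide in each of the ten classes, giving a 9 x 10 = 90-dimensional
summary that is strand-invariant by construction and far denser than 4-mer
(TNF) frequency vectors on short contigs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassPartition",
    "AfitVector",
    "AfitMatrix",
    "build_twomer_classes",
    "compute_afit",
    "compute_afit_matrix",
    "reverse_complement",
    "MIN_SUBSTRING_LEN",
    "MAX_SUBSTRING_LEN",
    "NUM_CLASSES",
    "VECTOR_DIM",
]

MIN_SUBSTRING_LEN = 2
MAX_SUBSTRING_LEN = 10
NUM_CLASSES = 10
NUM_STRATA = MAX_SUBSTRING_LEN - MIN_SUBSTRING_LEN + 1
VECTOR_DIM = NUM_STRATA * NUM_CLASSES  # 90

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> code; anything outside ACGT maps to -1 and is skipped
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC beyond ACGT untouched)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClassPartition:
    """The ten reverse-complement dinucleotide classes.

    Attributes
    ----------
    classes
        Ordered tuple of 10 frozensets of 2-mers.  The six two-element classes
        come first, sorted by their lexicographically smaller member, followed
        by the four palindromic singletons in lexicographic order.
    index
        Map from each of the 16 dinucleotides to its class ordinal (1-based).
    """

    classes: tuple[frozenset[str], ...]
    index: dict[str, int]


def build_twomer_classes() -> ClassPartition:
    """Group the 16 dinucleotides into the ten reverse-complement classes."""
    bases = "ACGT"
    pairs: list[frozenset[str]] = []
    palindromes: list[frozenset[str]] = []
    seen: set[str] = set()
    for a in bases:
        for b in bases:
            mer = a + b
            if mer in seen:
                continue
            rc = reverse_complement(mer)
            seen.update((mer, rc))
            if rc == mer:
                palindromes.append(frozenset((mer,)))
            else:
                pairs.append(frozenset((mer, rc)))
    pairs.sort(key=min)
    palindromes.sort(key=min)
    classes = tuple(pairs + palindromes)
    index = {mer: i + 1 for i, cls in enumerate(classes) for mer in cls}
    return ClassPartition(classes=classes, index=index)


_PARTITION = build_twomer_classes()

# (first_code * 4 + last_code) -> 0-based class ordinal
_PAIR_TO_CLASS = np.empty(16, dtype=np.int64)
for _mer, _ordinal in _PARTITION.index.items():
    _PAIR_TO_CLASS[_BASE_CODE[ord(_mer[0])] * 4 + _BASE_CODE[ord(_mer[1])]] = _ordinal - 1


@dataclass(frozen=True)
class AfitVector:
    """90-dimensional AFIT vector, stratum-major: (a_{2,1},...,a_{2,10},...,a_{10,10})."""

    values: np.ndarray
    normalized: bool
    contig_length: int

    def __post_init__(self) -> None:
        if self.values.shape != (VECTOR_DIM,):
            raise ValueError(f"AFIT vector must have shape ({VECTOR_DIM},)")


@dataclass(frozen=True)
class AfitMatrix:
    """Stacked AFIT vectors, one row per contig, aligned with ``contig_ids``."""

    values: np.ndarray  # (N, 90)
    contig_ids: tuple[str, ...]
    normalized: bool

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != VECTOR_DIM:
            raise ValueError(f"AFIT matrix must have {VECTOR_DIM} columns")
        if self.values.shape[0] != len(self.contig_ids):
            raise ValueError("row count must match number of contig ids")


def compute_afit(sequence: str, normalize: bool = True) -> AfitVector:
    """Compute the AFIT vector of one contig.

    For each substring length l in 2..10, substrings whose first and last base
    are both in {A, C, G, T} are classified by the reverse-complement class of
    their end dinucleotide.  Substrings with an ambiguous (non-ACGT) end base
    are excluded from both the counts and, in normalized mode, the denominator.

    Parameters
    ----------
    sequence
        Non-empty nucleotide string; lowercase and IUPAC ambiguity codes are
        accepted.
    normalize
        If True (default), each length stratum of 10 entries is divided by the
        number of valid substrings of that length, so non-degenerate strata sum
        to 1 and vectors of different contig lengths are comparable.  If False,
        raw integer counts are returned.
    """
    if not sequence:
        raise ValueError("cannot compute an AFIT vector for an empty sequence")
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    L = codes.shape[0]
    if L < MAX_SUBSTRING_LEN + 1:
        warnings.warn(
            f"sequence of length {L} has empty AFIT strata (needs >= "
            f"{MAX_SUBSTRING_LEN} nt for all substring lengths)",
            stacklevel=2,
        )
    out = np.zeros((NUM_STRATA, NUM_CLASSES), dtype=float)
    for stratum, l in enumerate(range(MIN_SUBSTRING_LEN, MAX_SUBSTRING_LEN + 1)):
        if L < l:
            continue
        first = codes[: L - l + 1]
        last = codes[l - 1 :]
        ok = (first >= 0) & (last >= 0)
        n_valid = int(ok.sum())
        if n_valid == 0:
            continue
        pair = first[ok] * 4 + last[ok]
        counts = np.bincount(_PAIR_TO_CLASS[pair], minlength=NUM_CLASSES)
        out[stratum] = counts / n_valid if normalize else counts
    return AfitVector(values=out.ravel(), normalized=normalize, contig_length=L)


def compute_afit_matrix(contigs, normalize: bool = True) -> AfitMatrix:
    """Stack AFIT vectors for a list of contigs into an N x 90 matrix.

    ``contigs`` is an iterable of objects with ``contig_id`` and ``sequence``
    attributes (see :class:`afitbin.io_formats.ContigRecord`).  Row order
    follows input order.
    """
    contigs = list(contigs)
    if not contigs:
        raise ValueError("contig list is empty")
    rows = np.empty((len(contigs), VECTOR_DIM), dtype=float)
    ids = []
    for i, contig in enumerate(contigs):
        try:
            rows[i] = compute_afit(contig.sequence, normalize=normalize).values
        except ValueError as exc:
            raise ValueError(f"contig {contig.contig_id!r}: {exc}") from exc
        ids.append(contig.contig_id)
    return AfitMatrix(values=rows, contig_ids=tuple(ids), normalized=normalize)
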