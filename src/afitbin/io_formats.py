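"""Reading contigs and coverage tables; writing binning results.

Coverage is consumed pre-summarized as a per-contig, per-sample mean and
variance of read depth.  Two tab-separated dialects are supported:

* the MetaBAT ``jgi_summarize_bam_contig_depths`` output
  (``contigName  contigLen  totalAvgDepth  <s>.bam  <s>.bam-var  ...``);
* a simple dialect (``contig_id  mean_1  var_1  ...  mean_S  var_S``).

The dialect is detected from the header, never from column counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "DepthTable",
    "BinningResult",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "read_truth_table",
    "write_bins",
]

IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: unique id plus an uppercase nucleotide sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-IUPAC characters: "
                f"{sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DepthTable:
    """Per-contig, per-sample coverage means and variances (reads/base)."""

    contig_ids: tuple[str, ...]
    means: np.ndarray  # (N, S)
    variances: np.ndarray  # (N, S)

    def __post_init__(self) -> None:
        n = len(self.contig_ids)
        if self.means.shape != self.variances.shape or self.means.shape[0] != n:
            raise ValueError("means/variances must be (N, S) arrays aligned with ids")
        if self.means.ndim != 2 or self.means.shape[1] < 1:
            raise ValueError("at least one sample is required")
        if np.any(self.means < 0) or np.any(self.variances < 0):
            raise ValueError("coverage means and variances must be non-negative")
        if len(set(self.contig_ids)) != n:
            raise ValueError("duplicate contig ids in depth table")

    @property
    def num_samples(self) -> int:
        return self.means.shape[1]

    def row_index(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.contig_ids)}

    def subset(self, contig_ids) -> "DepthTable":
        """Rows for the given contigs, in the given order."""
        idx = self.row_index()
        try:
            rows = [idx[c] for c in contig_ids]
        except KeyError as exc:
            raise KeyError(f"contig {exc.args[0]!r} missing from depth table") from exc
        return DepthTable(
            contig_ids=tuple(contig_ids),
            means=self.means[rows],
            variances=self.variances[rows],
        )


@dataclass
class BinningResult:
    """Final contig -> bin assignment with the pipeline stage of each call."""

    assignments: dict[str, int]  # contig_id -> bin label in 1..k
    k: int
    stage: dict[str, str]  # contig_id -> "long-stage" | "short-stage"
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels and not labels <= set(range(1, self.k + 1)):
            raise ValueError(f"bin labels {sorted(labels)} outside 1..{self.k}")
        if set(self.assignments) != set(self.stage):
            raise ValueError("stage must be recorded for exactly the assigned contigs")


def read_fasta(path) -> list[ContigRecord]:
    """Read contigs from a FASTA file.

    The contig id is the header token before the first whitespace; sequences
    are uppercased.  Fails on empty files, duplicate ids, or characters beyond
    the IUPAC nucleotide alphabet.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ContigRecord(contig_id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(contigs, path) -> None:
    """Write contigs to a FASTA file (60-column wrapping)."""
    recs = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs
    ]
    SeqIO.write(recs, str(path), "fasta")


def _parse_metabat(df: pd.DataFrame, path) -> DepthTable:
    cols = list(df.columns)
    sample_cols = cols[3:]
    if not sample_cols or len(sample_cols) % 2 != 0:
        raise ValueError(
            f"{path}: MetaBAT dialect needs alternating mean/variance sample "
            f"columns after totalAvgDepth"
        )
    mean_cols, var_cols = sample_cols[0::2], sample_cols[1::2]
    for m, v in zip(mean_cols, var_cols):
        if v != m + "-var":
            raise ValueError(
                f"{path}: expected variance column {m + '-var'!r} after {m!r}, "
                f"found {v!r}"
            )
    return DepthTable(
        contig_ids=tuple(df["contigName"].astype(str)),
        means=df[mean_cols].to_numpy(dtype=float),
        variances=df[var_cols].to_numpy(dtype=float),
    )


def _parse_simple(df: pd.DataFrame, path) -> DepthTable:
    cols = list(df.columns)
    if (len(cols) - 1) % 2 != 0 or len(cols) < 3:
        raise ValueError(
            f"{path}: simple dialect needs contig_id plus mean/var column pairs"
        )
    mean_cols, var_cols = cols[1::2], cols[2::2]
    return DepthTable(
        contig_ids=tuple(df[cols[0]].astype(str)),
        means=df[mean_cols].to_numpy(dtype=float),
        variances=df[var_cols].to_numpy(dtype=float),
    )


def read_depth_table(path) -> DepthTable:
    """Read a coverage table, auto-detecting the dialect from the header."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"depth table {path} has no rows")
    cols = list(df.columns)
    if cols[:3] == ["contigName", "contigLen", "totalAvgDepth"]:
        table = _parse_metabat(df, path)
    elif cols[0] == "contig_id":
        table = _parse_simple(df, path)
    else:
        raise ValueError(
            f"{path}: unrecognized depth-table header {cols[:3]!r}; expected the "
            f"MetaBAT jgi_summarize_bam_contig_depths dialect or a 'contig_id' "
            f"simple dialect"
        )
    return table


def write_depth_table(table: DepthTable, path) -> None:
    """Write a depth table in the simple dialect."""
    S = table.num_samples
    data: dict[str, object] = {"contig_id": list(table.contig_ids)}
    for s in range(S):
        data[f"mean_{s + 1}"] = table.means[:, s]
        data[f"var_{s + 1}"] = table.variances[:, s]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> dict[str, str]:
    """Read a two-column contig_id -> species TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"truth table {path} needs two columns")
    first = df.columns[0]
    rows = df.iloc[:, :2].to_numpy()
    truth = {}
    if first not in {"contig_id", "contigName"}:  # headerless file
        truth[str(first)] = str(df.columns[1])
    for cid, label in rows:
        truth[str(cid)] = str(label)
    return truth


def write_bins(result: BinningResult, contigs, out_dir) -> list[str]:
    """Write ``bins.tsv`` plus one FASTA per bin; returns the written paths.

    ``bins.tsv`` has columns ``contig_id``, ``bin``, ``stage``; each bin FASTA
    is named ``bin.<label>.fa`` and contains its member contigs in input order.
    """
    contigs = list(contigs)
    missing = {c.contig_id for c in contigs} - set(result.assignments)
    if missing:
        raise ValueError(f"no bin assignment for contigs: {sorted(missing)[:5]}")
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    tsv = os.path.join(out_dir, "bins.tsv")
    with open(tsv, "w") as fh:
        fh.write("contig_id\tbin\tstage\n")
        for c in contigs:
            fh.write(
                f"{c.contig_id}\t{result.assignments[c.contig_id]}"
                f"\t{result.stage[c.contig_id]}\n"
            )
    paths.append(tsv)
    by_bin: dict[int, list[ContigRecord]] = {}
    for c in contigs:
        by_bin.setdefault(result.assignments[c.contig_id], []).append(c)
    for label in sorted(by_bin):
        fa = os.path.join(out_dir, f"bin.{label}.fa")
        write_fasta(by_bin[label], fa)
        paths.append(fa)
    return paths
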