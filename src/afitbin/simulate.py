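"""Synthetic metagenomic communities for end-to-end testing.

The generator emulates the statistical structure the binner exploits:

* each genome is a second-order Markov chain over {A, C, G, T} whose 16 x 4
  transition matrix is drawn per genome from a Dirichlet distribution — lower
  concentration means more divergent oligonucleotide composition between
  genomes (the composition signal);
* contigs are substrings cut from the genomes at random offsets, with
  log-normal lengths straddling the 1200 bp long/short threshold so the
  short-contig stage is always exercised;
* per-sample genome abundances are log-normal, and each contig's per-sample
  coverage mean is its genome's abundance times multiplicative log-normal
  noise, with variance a fixed multiple of the mean (the coverage signal,
  matching the normal depth model the coverage distance assumes).

Everything is reproducible from (spec, seed), and the outputs round-trip
through :mod:`afitbin.io_formats`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtri

from .io_formats import ContigRecord, DepthTable, write_depth_table, write_fasta

__all__ = ["CommunitySpec", "SyntheticCommunity", "generate_genome",
           "generate_community", "write_community"]

_BASES = "ACGT"
LONG_THRESHOLD = 1200  # bp; the pipeline's long/short split


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    Defaults give 8 genomes, 4 samples and 400 contigs of which roughly 20%
    fall below the 1200 bp threshold.
    """

    num_genomes: int = 8
    genome_length: int = 50_000
    num_samples: int = 4
    contigs_per_genome: int = 50
    contig_length_median: float = 2000.0
    contig_length_sigma: float | None = None  # derived from short_fraction if None
    min_contig_length: int = 300
    short_fraction: float = 0.20  # target P(length < 1200 bp)
    composition_divergence: float = 5.0  # Dirichlet concentration; inf = identical
    base_depth: float = 20.0  # median per-sample depth (reads/base)
    abundance_sigma: float = 1.0  # log-normal sd of per-genome per-sample abundance
    coverage_noise_sigma: float = 0.15  # per-contig multiplicative depth noise
    variance_mean_ratio: float = 1.5  # depth variance per unit mean
    seed: int = 1

    def __post_init__(self) -> None:
        if self.num_genomes < 1 or self.num_samples < 1:
            raise ValueError("need at least one genome and one sample")
        if self.min_contig_length < 1 or self.genome_length < self.min_contig_length:
            raise ValueError("genome must be at least one contig long")
        if not 0.0 < self.short_fraction < 1.0:
            raise ValueError("short_fraction must be in (0, 1)")

    @property
    def length_sigma(self) -> float:
        """Log-normal sigma; solved so P(length < 1200) hits short_fraction."""
        if self.contig_length_sigma is not None:
            return self.contig_length_sigma
        z = ndtri(self.short_fraction)
        return float(math.log(LONG_THRESHOLD / self.contig_length_median) / z)


@dataclass(frozen=True)
class SyntheticCommunity:
    """A generated community: contigs, depth table, truth labels, and its spec."""

    contigs: tuple[ContigRecord, ...]
    depth: DepthTable
    truth: dict[str, str]
    spec: CommunitySpec


def generate_genome(transition_matrix, length: int, seed: int) -> str:
    """Sample one genome from a second-order Markov chain.

    ``transition_matrix`` is (16, 4) row-stochastic: row ``4 * code(x) +
    code(y)`` gives the distribution of the base following the dinucleotide
    ``xy``.  The first two bases are uniform.
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.shape != (16, 4):
        raise ValueError("transition matrix must be (16, 4)")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition rows must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    if length <= 2:
        return "".join(rng.choice(list(_BASES), size=length))
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    codes = np.empty(length, dtype=np.int64)
    codes[:2] = rng.integers(0, 4, size=2)
    u = rng.random(length)
    c = cum  # local alias for the loop
    prev2, prev1 = int(codes[0]), int(codes[1])
    for t in range(2, length):
        row = c[prev2 * 4 + prev1]
        x = u[t]
        b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        codes[t] = b
        prev2, prev1 = prev1, b
    return "".join(_BASES[b] for b in codes)


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate contigs, coverage and truth labels for a community spec."""
    rng = np.random.default_rng(spec.seed)
    G, S = spec.num_genomes, spec.num_samples

    genomes = []
    for g in range(G):
        if math.isinf(spec.composition_divergence):
            T = np.full((16, 4), 0.25)
        else:
            T = rng.dirichlet([spec.composition_divergence] * 4, size=16)
        child_seed = int(rng.integers(0, 2**31 - 1))
        genomes.append(generate_genome(T, spec.genome_length, seed=child_seed))

    # per-genome per-sample abundance (reads/base), log-normal around base_depth
    abundance = spec.base_depth * np.exp(
        rng.normal(0.0, spec.abundance_sigma, size=(G, S))
    )

    contigs: list[ContigRecord] = []
    truth: dict[str, str] = {}
    means = np.empty((G * spec.contigs_per_genome, S), dtype=float)
    for g, genome in enumerate(genomes):
        lengths = rng.lognormal(
            mean=math.log(spec.contig_length_median),
            sigma=spec.length_sigma,
            size=spec.contigs_per_genome,
        )
        lengths = np.clip(np.round(lengths), spec.min_contig_length,
                          spec.genome_length).astype(int)
        for i, L in enumerate(lengths):
            start = int(rng.integers(0, spec.genome_length - L + 1))
            cid = f"g{g:02d}_c{i:03d}"
            contigs.append(ContigRecord(contig_id=cid,
                                        sequence=genome[start : start + L]))
            truth[cid] = f"genome{g:02d}"
            noise = np.exp(rng.normal(0.0, spec.coverage_noise_sigma, size=S))
            means[len(contigs) - 1] = abundance[g] * noise

    depth = DepthTable(
        contig_ids=tuple(c.contig_id for c in contigs),
        means=means,
        variances=spec.variance_mean_ratio * means,
    )
    return SyntheticCommunity(contigs=tuple(contigs), depth=depth,
                              truth=truth, spec=spec)


def write_community(community: SyntheticCommunity, out_dir) -> dict[str, str]:
    """Write community.fa, depth.tsv (simple dialect) and truth.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "contigs": os.path.join(out_dir, "community.fa"),
        "depth": os.path.join(out_dir, "depth.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_fasta(community.contigs, paths["contigs"])
    write_depth_table(community.depth, paths["depth"])
    with open(paths["truth"], "w") as fh:
        fh.write("contig_id\tspecies\n")
        for cid, label in community.truth.items():
            fh.write(f"{cid}\t{label}\n")
    return paths


def with_seed(spec: CommunitySpec, seed: int) -> CommunitySpec:
    """Copy of a spec with a different seed."""
    return replace(spec, seed=seed)
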