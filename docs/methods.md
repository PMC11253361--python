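# Methods

This note records the model, the numerical choices, and the open design
decisions behind `afitbin`, in the order the pipeline uses them.

## AFIT composition vectors

A substring of length l contributes to exactly one of ten classes determined
by the reverse-complement equivalence class of its (first base, last base)
dinucleotide. Because a class contains a dinucleotide together with its
reverse complement, the resulting 90-vector is identical for a sequence and
its reverse complement — strand invariance comes from the class construction,
so only the given strand is scanned. Class order is fixed (six pairs sorted
by their lexicographically smaller member, then the four palindromes
alphabetically) so that serialized vectors are comparable across runs.

*Normalization.* Raw counts grow linearly with contig length, which would
make Euclidean composition distances length- rather than composition-driven.
The default therefore divides each length stratum by its number of valid
substrings, so every non-degenerate stratum sums to 1 and vectors of
different contig lengths are commensurable; raw integer counts remain
available via `normalize=False`.

*Ambiguity codes.* A substring whose first or last base is not A/C/G/T is
excluded from both the numerator and the denominator of its stratum —
inventing frequencies for unknown bases would bias the vector. Interior
ambiguous bases are irrelevant because only the end pair is inspected.

*Short sequences.* Sequences shorter than 11 nt leave some strata with no
substrings; those strata stay all-zero and a warning is emitted. The
pipeline's 1200 bp threshold makes this a non-issue in practice.

The production counter slides index arrays per stratum; a brute-force
substring-enumeration oracle in the test suite checks exact agreement.

## Coverage distance

Depth in each sample is modelled as Normal(μ, σ²) from the per-contig
observed mean and variance. The per-sample distance is 1 − OVL with
OVL = ∫ min(f₁, f₂): each density has unit area, so the total non-shared
area is 2 − 2·OVL and we report its half to land in [0, 1], commensurate
with normalized composition distances. Multi-sample profiles average the
per-sample distances with uniform weights (a product of overlaps was
rejected: it degenerates toward 1 with many samples).

The overlap is computed analytically. Equal variances give
OVL = 2Φ(−|Δμ|/(2σ)). Otherwise the densities cross where their
log-densities agree — a quadratic in x with two real roots when variances
differ — and the overlap is the sum of normal cdf masses: the wider density
integrated between the roots plus the narrower one's two tails. The whole
computation is vectorized, so the N×N matrix is built per-sample by
broadcasting.

*Variance floor.* σ² is floored at max(10⁻⁶, 0.05·μ) to avoid degenerate
point masses from single-read depth estimates; without it, two contigs with
nearly identical depth but tiny variances would appear maximally distant.

## Step 1 — number of bins

The distance between contigs i and j is (d_ij + c_ij)/2 with d the
Euclidean AFIT distance and c the coverage distance. The bin count follows a
grow-until-empty rule: request k clusters, and if fewer than 40% of the
requested slots come out empty, grow k by 1.5× (start:
k₀ = max(2, ⌈N/50⌉)) and repeat; the estimate is the number of non-empty
clusters when the rule fires.

The clustering backing this rule is a single-linkage hierarchy of the
combined distance, cut at k. This choice is deliberate: center-based Lloyd
iterations cannot implement the rule faithfully — a medoid always attracts
at least itself, so no cluster ever empties, and when k exceeds the number
of genomes, surviving centers split genome-sized groups instead of dying,
inflating the estimate. Single-linkage cuts have the needed behavior:
surplus cluster slots either go unfilled (tied merge heights) or peel off
isolated outliers, leaving the count of substantial clusters stable near the
number of genuine groups. A cluster is counted as empty when it attracts
fewer than max(2, 1% of N) members: a handful of stray contigs is not a
genome bin (minimum-bin-size conventions are standard among binners).
The same hierarchy cut at k supplies the warm-start labels for Step 2, so
Steps 1–2 see a consistent partition. The estimator is fully deterministic.

Known limitation: genomes represented by fewer than max(2, 1% of N) contigs
are invisible to the estimator, and single linkage can chain through
genuinely overlapping groups (it merges two genomes when both their
composition and their abundance profiles are close — in that regime no
distance-based method can separate them).

## Step 2 — factorization of long contigs

Contigs shorter than 1200 bp are set aside (the boundary itself counts as
long). The long-contig AFIT matrix X (m×90) is factored as X ≈ HW by
minimizing

    ‖X − HW‖² + α‖H‖² + β‖Y ∗ (HHᵀ)‖²,    α = 2, β = 3/4,

where W (k×90) holds per-bin composition indices, H (m×k) the relaxed
affiliations, Y the long-contig coverage matrix and ∗ the elementwise
product. The β term charges co-affiliation of coverage-distant pairs; the α
ridge regularizes affiliation magnitudes.

*The relaxation.* The exact problem constrains each row of H to be one-hot,
which is NP-hard integer programming. We relax rows to the probability
simplex (non-negative, summing to 1) — soft memberships. Relaxing H all the
way to unconstrained reals makes the problem degenerate in three distinct
ways, each observed during development: sign patterns cancel the HHᵀ
products so the coverage penalty constrains nothing; the rescaling
H → H/c, W → cW lets the ridge shrink H to zero without changing the fit,
so argmax hardening reads noise; and the unconstrained optimum is a
PCA-like subspace fit whose rows are not memberships at all. On the
simplex, none of these escapes exist, and the α = 2, β = 3/4 defaults hold
a well-separated partition stably.

*Optimization.* Alternating minimization: the W-step is exact ordinary
least squares (α and β do not involve W), the H-step runs a few (default 5)
projected-gradient iterations — analytic gradient
2(HW − X)Wᵀ + 2αH + 4β(Y∘Y∘HHᵀ)H, Euclidean projection onto the simplex per
row, backtracking line search that only accepts non-increasing steps — so
the recorded objective trace is non-increasing by construction. Outer
iterations stop when the relative objective change drops below 10⁻⁶
(default cap 200). H starts from the one-hot encoding of the Step-1 labels
plus |N(0, 0.001)| noise to break ties, projected onto the simplex; larger
init noise (10⁻²) was observed to occasionally kick the warm start into a
worse local optimum of this quartic objective. Given identical seeds the
whole fit is bit-reproducible.

Hardening assigns contig i to argmaxᵣ h_ir, ties to the lowest bin index.

## Step 3 — short contigs

For each short contig v and candidate bin B (bins with at least one long
member), S₁(B, v) is the Euclidean distance between W(B) and AFIT_v
(computed with the same normalization as X, otherwise the scales are
incoherent), and S₂(B, v) is the mean coverage distance between v and the
long members of B — the coverage matrix built in Step 2 has no row for v,
so S₂ is computed directly from the depth profiles. v joins the bin
minimizing S₁ + S₂, ties to the lowest label.

## Evaluation

With M the bins×species contingency matrix, precision sums row maxima,
recall column maxima, both over the total; F is their harmonic mean.
Transposing M swaps precision and recall and leaves F unchanged, so the
F-score is insensitive to the orientation convention. Contigs without a
truth label are dropped from M and reported. The TNF comparator is the
plain 256-dimensional 4-mer frequency vector (no reverse-complement
canonicalization), normalized to sum 1 over valid all-ACGT windows.

## Synthetic communities

The generator emulates exactly the two signals the binner exploits, with
defaults chosen as a realistic desk-scale study condition:

| parameter | default | meaning |
|---|---|---|
| num_genomes | 8 | planted genomes |
| genome_length | 50 kb | per genome |
| num_samples | 4 | coverage samples |
| contigs_per_genome | 50 | 400 contigs total |
| contig_length_median | 2000 bp | log-normal lengths |
| short_fraction | 0.20 | target P(length < 1200 bp); sets the log-normal σ |
| min_contig_length | 300 bp | truncation |
| composition_divergence | 5 | Dirichlet concentration of transition rows |
| base_depth | 20 reads/base | median sample depth |
| abundance_sigma | 1.0 | log-normal spread of genome abundance |
| coverage_noise_sigma | 0.15 | per-contig multiplicative depth noise |
| variance_mean_ratio | 1.5 | depth variance per unit mean |

Genomes are second-order Markov chains over {A, C, G, T} whose 16×4
transition matrices are drawn per genome from Dirichlet(concentration);
second order (rather than i.i.d. bases) gives both AFIT and TNF realistic
within-genome oligonucleotide structure. Lower concentration means more
divergent genome compositions; infinity yields identical uniform chains
(used by tests that need composition to be uninformative). Contigs are cut
at uniform random offsets with log-normal lengths whose σ is solved so the
fraction below 1200 bp hits the target, keeping the short-contig stage
exercised. Per-genome per-sample abundances are log-normal around the base
depth; per-contig means add multiplicative log-normal noise and variances
are a fixed multiple of the mean, matching the normal model the coverage
distance assumes.

What the generator does *not* emulate: chimeric or contaminated contigs,
shared/repeated regions between genomes, strain-level mosaicism,
GC-dependent depth bias, and non-normal depth. Passing end-to-end tests
therefore demonstrates correct mechanics and recovery under the model's own
assumptions, not performance on real assemblies. With the defaults some
community draws place two genomes close in both composition and abundance;
the estimator then legitimately merges them, which is a property of the
draw, not a defect (verified by forcing the true k, which does not restore
a perfect score on such draws).

## Problem sizes and determinism

The default test and reproduction runs use the 400-contig community above;
the dense N×N coverage and distance matrices bound the implementation to
desk scale (a guard refuses N > 20 000 with a clear message). All
randomness flows from explicit integer seeds through `numpy.random.
default_rng`; reruns with the same seed give identical assignments.
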