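"""Binning core: length split, combined distance, k estimation,
factorization, hardening, and short-contig assignment."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from afitbin.afit import compute_afit, compute_afit_matrix
from afitbin.binning import (
    assign_short_contigs,
    combined_distance_matrix,
    estimate_num_bins,
    fit_factorization,
    harden_assignments,
    run_afitbin,
    split_by_length,
)
from afitbin.coverage import coverage_distance, CoverageProfile
from afitbin.io_formats import ContigRecord, DepthTable


class TestSplitByLength:
    def test_boundary_is_long(self):
        contigs = [ContigRecord(f"c{i}", "A" * n) for i, n in
                   enumerate([1500, 1200, 1199])]
        long_c, short_c = split_by_length(contigs)
        assert [c.length for c in long_c] == [1500, 1200]
        assert [c.length for c in short_c] == [1199]

    def test_threshold_zero_all_long(self):
        contigs = [ContigRecord("c", "ACGT")]
        long_c, short_c = split_by_length(contigs, threshold_bp=0)
        assert len(long_c) == 1 and not short_c

    def test_all_short_pipeline_aborts(self):
        contigs = [ContigRecord("c0", "ACGTACGTAC" * 20)]
        depth = DepthTable(("c0",), np.array([[5.0]]), np.array([[1.0]]))
        with pytest.raises(ValueError, match="no contigs of length"):
            run_afitbin(contigs, depth, k=1)


class TestCombinedDistance:
    def test_elementwise_mean_of_constituents(self):
        rng = np.random.default_rng(0)
        A = rng.random((6, 90))
        C = rng.random((6, 6))
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 0.0)
        D = combined_distance_matrix(A, C)
        expect = 0.5 * (squareform(pdist(A)) + C)
        np.testing.assert_allclose(D, expect)
        assert D[1, 2] == pytest.approx((np.linalg.norm(A[1] - A[2]) + C[1, 2]) / 2)

    def test_identical_rows_and_coverage_give_zero(self):
        A = np.tile(np.linspace(0, 1, 90), (2, 1))
        D = combined_distance_matrix(A, np.zeros((2, 2)))
        np.testing.assert_allclose(D, 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combined_distance_matrix(np.zeros((3, 90)), np.zeros((2, 2)))


class TestEstimateNumBins:
    def test_single_contig(self):
        assert estimate_num_bins(np.zeros((1, 1))) == 1

    def test_five_well_separated_groups(self):
        rng = np.random.default_rng(5)
        centers = 4.0 * rng.normal(size=(5, 10))
        pts = np.vstack([c + 0.15 * rng.normal(size=(30, 10)) for c in centers])
        D = squareform(pdist(pts))
        assert abs(estimate_num_bins(D, seed=0) - 5) <= 1

    def test_two_coincident_clouds(self):
        pts = np.vstack([np.zeros((50, 3)), np.ones((50, 3))])
        D = squareform(pdist(pts))
        assert estimate_num_bins(D, seed=0) in (1, 2)

    def test_default_community_long_subset(self, default_community,
                                           default_distance):
        com = default_community
        contigs = list(com.contigs)
        long_idx = [i for i, c in enumerate(contigs) if c.length >= 1200]
        D = default_distance[np.ix_(long_idx, long_idx)]
        assert abs(estimate_num_bins(D) - com.spec.num_genomes) <= 1


class TestFactorization:
    def test_k1_single_component_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 90))
        f = fit_factorization(X, None, k=1, alpha=0.0, beta=0.0, seed=0)
        # simplex rows with k=1 force H = ones; W is the least-squares fit,
        # i.e. the column means of X
        np.testing.assert_allclose(f.H, 1.0)
        np.testing.assert_allclose(f.W[0], X.mean(axis=0), atol=1e-8)

    def test_planted_partition_recovered_exactly(self):
        rng = np.random.default_rng(2)
        labels = np.repeat(np.arange(3), 20)
        W0 = rng.dirichlet(np.ones(10), size=27).reshape(3, 90)
        H0 = np.eye(3)[labels]
        X = H0 @ W0
        f = fit_factorization(X, None, k=3, alpha=0.01, beta=0.0, seed=0)
        assert adjusted_rand_score(labels, harden_assignments(f.H)) == 1.0

    def test_objective_trace_non_increasing_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            m, k = rng.integers(6, 20), rng.integers(1, 5)
            X = rng.random((m, 90))
            Y = rng.random((m, m))
            Y = 0.5 * (Y + Y.T)
            np.fill_diagonal(Y, 0.0)
            f = fit_factorization(X, Y, k=int(k), seed=trial, max_iter=30)
            diffs = np.diff(f.objective_trace)
            assert np.all(diffs <= 1e-9)

    def test_coverage_penalty_resolves_composition_ties(self):
        """When composition is uninformative, only the coverage term can
        recover the coverage-consistent partition."""
        rng = np.random.default_rng(4)
        m = 20
        X = np.tile(rng.dirichlet(np.ones(10), size=9).reshape(1, 90), (m, 1))
        grp = np.arange(m) % 2
        Y = np.where(grp[:, None] == grp[None, :], 0.02, 0.95)
        np.fill_diagonal(Y, 0.0)
        wrong = (np.arange(m) < m // 2).astype(int)
        with_cov = fit_factorization(X, Y, 2, alpha=2.0, beta=0.75, seed=0,
                                     init_labels=wrong)
        without = fit_factorization(X, Y, 2, alpha=2.0, beta=0.0, seed=0,
                                    init_labels=wrong)
        assert adjusted_rand_score(grp, harden_assignments(with_cov.H)) == 1.0
        assert adjusted_rand_score(grp, harden_assignments(without.H)) < 1.0

    def test_seed_determinism_and_validation(self):
        rng = np.random.default_rng(5)
        X, Y = rng.random((10, 90)), np.zeros((10, 10))
        a = fit_factorization(X, Y, 2, seed=9)
        b = fit_factorization(X, Y, 2, seed=9)
        np.testing.assert_array_equal(a.H, b.H)
        with pytest.raises(ValueError, match="m >= k"):
            fit_factorization(X, Y, 11)
        with pytest.raises(ValueError, match="Y is required"):
            fit_factorization(X, None, 2, beta=0.5)


class TestHarden:
    def test_argmax_and_tie_rule(self):
        H = np.array([[0.1, 0.9], [0.5, 0.5], [0.7, 0.3]])
        np.testing.assert_array_equal(harden_assignments(H), [2, 1, 1])

    def test_one_hot_identity(self):
        labels = np.array([2, 0, 1, 1])
        H = np.eye(3)[labels]
        np.testing.assert_array_equal(harden_assignments(H), labels + 1)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            harden_assignments(np.array([[np.nan, 1.0]]))


class TestAssignShortContigs:
    def _setup(self):
        rng = np.random.default_rng(6)
        # two bins with distinct compositions and coverages
        long_ids = [f"l{i}" for i in range(6)]
        short = [ContigRecord("s0", "AC" * 300), ContigRecord("s1", "GGAT" * 150)]
        seqs = ["AC" * 700] * 3 + ["GGAT" * 350] * 3
        long_contigs = [ContigRecord(i, s) for i, s in zip(long_ids, seqs)]
        ids = long_ids + ["s0", "s1"]
        means = np.array([[5.0]] * 3 + [[50.0]] * 3 + [[5.0], [50.0]])
        depth = DepthTable(tuple(ids), means, 0.5 * means)
        W = compute_afit_matrix(long_contigs).values[[0, 3]]
        long_labels = {i: (1 if n < 3 else 2) for n, i in enumerate(long_ids)}
        return short, W, long_labels, depth, long_contigs

    def test_matching_bin_wins(self):
        short, W, long_labels, depth, _ = self._setup()
        got = assign_short_contigs(short, W, long_labels, depth)
        assert got == {"s0": 1, "s1": 2}

    def test_scores_match_bruteforce(self):
        short, W, long_labels, depth, long_contigs = self._setup()
        got = assign_short_contigs(short, W, long_labels, depth)
        idx = depth.row_index()
        prof = {
            cid: CoverageProfile(cid, depth.means[i], depth.variances[i])
            for cid, i in idx.items()
        }
        for c in short:
            totals = {}
            for b in (1, 2):
                members = [cid for cid, l in long_labels.items() if l == b]
                s1 = float(np.linalg.norm(W[b - 1] - compute_afit(c.sequence).values))
                s2 = float(np.mean([
                    coverage_distance(prof[c.contig_id], prof[m]) for m in members
                ]))
                totals[b] = s1 + s2
            assert got[c.contig_id] == min(totals, key=lambda b: (totals[b], b))

    def test_single_bin_takes_all(self):
        short, W, long_labels, depth, _ = self._setup()
        only_bin1 = {cid: 1 for cid in list(long_labels)[:3]}
        got = assign_short_contigs(short, W, only_bin1, depth)
        assert set(got.values()) == {1}

    def test_empty_bin_set_rejected(self):
        short, W, _, depth, _ = self._setup()
        with pytest.raises(ValueError, match="no long-contig bins"):
            assign_short_contigs(short, W, {}, depth)


class TestRunAfitbin:
    def test_k_forced_to_one(self, small_community):
        com = small_community
        res = run_afitbin(list(com.contigs), com.depth, k=1, seed=0)
        assert set(res.assignments.values()) == {1}
        assert set(res.stage.values()) == {"long-stage", "short-stage"}

    def test_same_seed_identical(self, small_community):
        com = small_community
        a = run_afitbin(list(com.contigs), com.depth, seed=4)
        b = run_afitbin(list(com.contigs), com.depth, seed=4)
        assert a.assignments == b.assignments and a.k == b.k

    def test_every_contig_assigned_once(self, default_binning, default_community):
        res = default_binning
        ids = {c.contig_id for c in default_community.contigs}
        assert set(res.assignments) == ids
        assert set(res.assignments.values()) <= set(range(1, res.k + 1))
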