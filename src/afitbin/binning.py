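"""The binning pipeline: estimate k, factorize, harden, place short contigs.

The pipeline combines the composition distance (Euclidean distance between
AFIT rows) and the coverage distance into a single pairwise distance
``(d_ij + c_ij) / 2`` and proceeds in three steps:

1. estimate the number of bins k by growing a center-based clustering of the
   combined distance until at least a fixed fraction (default 40%) of the
   clusters come out empty, returning the number of non-empty clusters;
2. drop contigs shorter than a length threshold (default 1200 bp), then factor
   the long-contig composition matrix X (m x 90) into an affiliation matrix
   H (m x k) and a bin-composition index W (k x 90) by minimizing

       ||X - H W||^2 + alpha ||H||^2 + beta ||Y * (H H^T)||^2

   (Frobenius norms, * elementwise, Y the long-contig coverage-distance
   matrix); the binary one-hot constraint on H is relaxed to soft memberships
   (each row on the probability simplex).  W is solved in closed form by
   least squares and H by projected-gradient descent steps; hardening assigns
   each contig to its max-affiliation bin;
3. each short contig v is assigned to the bin B minimizing
   ``S1 + S2`` where S1 is the Euclidean distance between W(B) and the AFIT
   vector of v, and S2 the mean coverage distance from v to the long members
   of B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from .afit import AfitMatrix, compute_afit_matrix
from .coverage import _floor_variance, _nonshared_area_arrays, coverage_matrix_from_depth
from .io_formats import BinningResult, DepthTable

__all__ = [
    "FactorizationResult",
    "MAX_CONTIGS",
    "split_by_length",
    "combined_distance_matrix",
    "estimate_num_bins",
    "cluster_distance_matrix",
    "fit_factorization",
    "harden_assignments",
    "assign_short_contigs",
    "run_afitbin",
]

# the dense N x N coverage matrix bounds practical problem size
MAX_CONTIGS = 20_000

DEFAULT_MIN_LEN = 1200
DEFAULT_ALPHA = 2.0
DEFAULT_BETA = 0.75
DEFAULT_EMPTY_FRACTION = 0.40


@dataclass
class FactorizationResult:
    """Outcome of the relaxed one-hot factorization X ~ H W."""

    W: np.ndarray  # (k, 90)
    H: np.ndarray  # (m, k)
    alpha: float
    beta: float
    objective_trace: np.ndarray
    seed: int


def split_by_length(contigs, threshold_bp: int = DEFAULT_MIN_LEN):
    """Partition contigs into (long, short) by ``length >= threshold_bp``.

    Contigs exactly at the threshold count as long; input order is preserved
    in both lists.
    """
    long_contigs = [c for c in contigs if c.length >= threshold_bp]
    short_contigs = [c for c in contigs if c.length < threshold_bp]
    return long_contigs, short_contigs


def combined_distance_matrix(A, C) -> np.ndarray:
    """Pairwise contig distance ``(d_ij + c_ij) / 2``.

    ``d_ij`` is the Euclidean distance between AFIT rows i and j of ``A``
    (an :class:`AfitMatrix` or plain (N, 90) array); ``C`` is the coverage
    distance matrix with matching contig order.
    """
    rows = A.values if isinstance(A, AfitMatrix) else np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.shape != (rows.shape[0], rows.shape[0]):
        raise ValueError(
            f"coverage matrix shape {C.shape} does not match {rows.shape[0]} contigs"
        )
    D = squareform(pdist(rows, metric="euclidean"))
    return 0.5 * (D + C)


def _hierarchy(dist: np.ndarray):
    from scipy.cluster.hierarchy import linkage

    return linkage(squareform(dist, checks=False), method="single")


def estimate_num_bins(dist: np.ndarray, empty_fraction: float = DEFAULT_EMPTY_FRACTION,
                      seed: int = 0, k0: int | None = None,
                      growth: float = 1.5, min_members: int | None = None) -> int:
    """Estimate the number of bins from the combined distance matrix.

    Asks a single-linkage hierarchy of the combined distances for k clusters,
    counting a cluster as empty when it attracts fewer than ``min_members``
    contigs (default ``max(2, 1%% of N)``) — surplus cluster slots either go
    unfilled or peel off outliers instead of splitting a genome-sized group,
    and a handful of stray contigs does not constitute a genome bin.
    Starting from ``k0 = max(2, ceil(N / 50))``, k grows by the ``growth``
    factor until at least ``empty_fraction`` of the k requested clusters are
    empty; the number of non-empty clusters at that point is the estimate.

    Deterministic; ``seed`` is accepted for interface uniformity only.
    """
    from scipy.cluster.hierarchy import fcluster

    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n == 1:
        return 1
    if min_members is None:
        min_members = max(2, math.ceil(0.01 * n))
    Z = _hierarchy(dist)
    k = k0 if k0 is not None else max(2, math.ceil(n / 50))
    k = min(k, n)
    while True:
        labels = fcluster(Z, t=k, criterion="maxclust")
        counts = np.bincount(labels)[1:]
        n_nonempty = int((counts >= min_members).sum())
        n_empty = k - n_nonempty
        if n_empty >= empty_fraction * k or k >= n:
            return max(1, n_nonempty)
        k = min(n, math.ceil(k * growth))


def cluster_distance_matrix(dist: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-way clustering of contigs from their pairwise distance matrix.

    Cuts the same single-linkage hierarchy the bin-count estimator uses at k
    clusters; used to warm-start the factorization.  Deterministic (``seed``
    kept for interface uniformity).  Returns 0-based labels.
    """
    from scipy.cluster.hierarchy import fcluster

    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if k >= n:
        return np.arange(n)
    if k == 1:
        return np.zeros(n, dtype=int)
    return fcluster(_hierarchy(dist), t=k, criterion="maxclust") - 1


def _project_rows_to_simplex(H: np.ndarray) -> np.ndarray:
    """Euclidean projection of every row onto the probability simplex."""
    m, k = H.shape
    s = -np.sort(-H, axis=1)  # rows descending
    css = np.cumsum(s, axis=1) - 1.0
    ar = np.arange(1, k + 1)
    cond = s - css / ar > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)  # last index where cond holds
    theta = css[np.arange(m), rho] / (rho + 1)
    return np.maximum(H - theta[:, None], 0.0)


def _objective(X, W, H, alpha, beta, Y2):
    R = H @ W - X
    obj = float((R * R).sum()) + alpha * float((H * H).sum())
    if beta != 0.0 and Y2 is not None:
        S = H @ H.T
        obj += beta * float((Y2 * S * S).sum())
    return obj


def _grad_H(X, W, H, alpha, beta, Y2):
    G = 2.0 * (H @ W - X) @ W.T + 2.0 * alpha * H
    if beta != 0.0 and Y2 is not None:
        G += 4.0 * beta * (Y2 * (H @ H.T)) @ H
    return G


def fit_factorization(X, Y, k: int, alpha: float = DEFAULT_ALPHA,
                      beta: float = DEFAULT_BETA, seed: int = 0,
                      max_iter: int = 200, tol: float = 1e-6,
                      init_labels=None, cg_iters: int = 5) -> FactorizationResult:
    """Alternating minimization of the relaxed binning objective.

    W is re-solved in closed form (ordinary least squares given H) and H is
    updated by a few projected-gradient steps on the full objective given W,
    until the relative objective change drops below ``tol``.

    Each row of H is kept on the probability simplex (non-negative, summing
    to 1): this is the natural relaxation of the one-hot membership
    constraint.  Dropping it entirely makes the problem degenerate — sign
    patterns can cancel the co-affiliation products the coverage penalty acts
    on, and the joint rescaling H -> H/c, W -> cW lets the ridge term shrink
    H to zero without improving the fit, leaving argmax hardening to read
    noise.

    H is initialized from the one-hot encoding of ``init_labels`` (0-based; a
    composition clustering of X when omitted) plus small seeded noise to
    break ties, projected onto the simplex.  The recorded objective trace is
    non-increasing.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"need m >= k >= 1, got m={m}, k={k}")
    Y2 = None
    if beta != 0.0:
        if Y is None:
            raise ValueError("Y is required when beta != 0")
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (m, m):
            raise ValueError(f"Y must be ({m}, {m}), got {Y.shape}")
        Y2 = Y * Y

    rng = np.random.default_rng(seed)
    if init_labels is None:
        init_labels = (
            np.zeros(m, dtype=int)
            if k == 1
            else KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        )
    init_labels = np.asarray(init_labels)
    if init_labels.shape != (m,) or init_labels.min() < 0 or init_labels.max() >= k:
        raise ValueError("init_labels must be m 0-based labels below k")
    H = np.zeros((m, k), dtype=float)
    H[np.arange(m), init_labels] = 1.0
    H = _project_rows_to_simplex(H + np.abs(rng.normal(0.0, 0.001, size=H.shape)))

    W = np.linalg.lstsq(H, X, rcond=None)[0]
    obj = _objective(X, W, H, alpha, beta, Y2)
    trace = [obj]
    step = 1.0  # adaptive projected-gradient step, persists across iterations

    for _ in range(max_iter):
        # H-step: a few projected-gradient descent iterations at fixed W
        for _ in range(cg_iters):
            G = _grad_H(X, W, H, alpha, beta, Y2)
            f0 = _objective(X, W, H, alpha, beta, Y2)
            for _ in range(40):  # backtracking line search on the arc
                H_try = _project_rows_to_simplex(H - step * G)
                if _objective(X, W, H_try, alpha, beta, Y2) <= f0:
                    H = H_try
                    step *= 1.3
                    break
                step *= 0.5
        # W-step: exact least squares (alpha/beta terms do not involve W)
        W_try = np.linalg.lstsq(H, X, rcond=None)[0]
        if _objective(X, W_try, H, alpha, beta, Y2) <= _objective(
            X, W, H, alpha, beta, Y2
        ):
            W = W_try
        new_obj = _objective(X, W, H, alpha, beta, Y2)
        if not np.isfinite(new_obj):
            raise FloatingPointError(
                f"objective diverged after {len(trace)} iterations: {trace[-5:]}"
            )
        trace.append(new_obj)
        if obj - new_obj <= tol * max(abs(obj), 1.0):
            obj = new_obj
            break
        obj = new_obj

    return FactorizationResult(W=W, H=H, alpha=alpha, beta=beta,
                               objective_trace=np.asarray(trace), seed=seed)


def harden_assignments(H) -> np.ndarray:
    """Hard labels (1-based) from an affiliation matrix: argmax per row.

    Ties resolve to the lowest bin index.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("affiliation matrix contains non-finite values")
    return np.argmax(H, axis=1) + 1


def assign_short_contigs(short_contigs, W, long_labels: dict[str, int],
                         depth: DepthTable, normalize: bool = True) -> dict[str, int]:
    """Assign each short contig to the bin minimizing S1 + S2.

    S1 is the Euclidean distance between the bin's composition index row W(B)
    and the contig's AFIT vector (same normalization as the factorized X);
    S2 is the mean coverage distance from the contig to the bin's long-contig
    members.  Ties resolve to the lowest bin label.

    ``long_labels`` maps long contig ids to 1-based bin labels; only bins with
    at least one long member are candidates.
    """
    short_contigs = list(short_contigs)
    if not long_labels:
        raise ValueError("no long-contig bins to assign short contigs to")
    if not short_contigs:
        return {}
    W = np.asarray(W, dtype=float)
    bins = sorted(set(long_labels.values()))
    idx = depth.row_index()
    fl_var = _floor_variance(depth.means, depth.variances)

    A_short = compute_afit_matrix(short_contigs, normalize=normalize).values
    S1 = cdist(A_short, W[[b - 1 for b in bins]])  # (n_short, n_bins)

    S2 = np.empty_like(S1)
    short_rows = [idx[c.contig_id] for c in short_contigs]
    mu_s, var_s = depth.means[short_rows], fl_var[short_rows]
    for j, b in enumerate(bins):
        member_rows = [idx[cid] for cid, lab in long_labels.items() if lab == b]
        mu_b, var_b = depth.means[member_rows], fl_var[member_rows]
        # (n_short, n_members, S) broadcast, averaged over samples then members
        d = _nonshared_area_arrays(
            mu_s[:, None, :], var_s[:, None, :], mu_b[None, :, :], var_b[None, :, :]
        )
        S2[:, j] = d.mean(axis=(1, 2))

    choice = np.argmin(S1 + S2, axis=1)
    return {c.contig_id: bins[j] for c, j in zip(short_contigs, choice)}


def run_afitbin(contigs, depth: DepthTable, k: int | None = None,
                alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                min_len: int = DEFAULT_MIN_LEN,
                empty_fraction: float = DEFAULT_EMPTY_FRACTION,
                seed: int = 0, normalize: bool = True,
                max_iter: int = 200, tol: float = 1e-6) -> BinningResult:
    """Run the full binning pipeline.

    Builds the AFIT and coverage matrices, estimates k (unless given),
    factorizes the long-contig composition under the coverage penalty, hardens
    the affiliations, assigns short contigs, and returns a
    :class:`BinningResult` whose ``details`` record the chosen k, the
    objective trace, and the contig counts per stage.  Deterministic for a
    fixed seed.
    """
    contigs = list(contigs)
    n = len(contigs)
    if n == 0:
        raise ValueError("no contigs to bin")
    if n > MAX_CONTIGS:
        raise ValueError(
            f"{n} contigs exceed the supported maximum of {MAX_CONTIGS} "
            f"(the dense coverage matrix would not fit in memory); split the "
            f"assembly or raise afitbin.binning.MAX_CONTIGS explicitly"
        )
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != n:
        raise ValueError("duplicate contig ids")
    depth = depth.subset(ids)  # aligns order, errors on missing rows

    A = compute_afit_matrix(contigs, normalize=normalize)
    C = coverage_matrix_from_depth(depth.means, depth.variances)
    D = combined_distance_matrix(A, C)

    if k is None:
        k = estimate_num_bins(D, empty_fraction=empty_fraction, seed=seed)
    if k < 1:
        raise ValueError("k must be >= 1")

    long_contigs, short_contigs = split_by_length(contigs, threshold_bp=min_len)
    if not long_contigs:
        raise ValueError(
            f"no contigs of length >= {min_len} bp; cannot build bins "
            f"(lower --min-len or assemble longer contigs)"
        )
    k = min(k, len(long_contigs))
    pos = {cid: i for i, cid in enumerate(ids)}
    long_idx = np.array([pos[c.contig_id] for c in long_contigs])

    step1_labels = cluster_distance_matrix(D, k, seed=seed)
    X = A.values[long_idx]
    Y = C[np.ix_(long_idx, long_idx)]
    init = step1_labels[long_idx]

    fact = fit_factorization(X, Y, k, alpha=alpha, beta=beta, seed=seed,
                             max_iter=max_iter, tol=tol, init_labels=init)
    long_hard = harden_assignments(fact.H)
    long_labels = {c.contig_id: int(lab) for c, lab in zip(long_contigs, long_hard)}

    short_labels = (
        assign_short_contigs(short_contigs, fact.W, long_labels, depth,
                             normalize=normalize)
        if short_contigs
        else {}
    )

    assignments = {**long_labels, **short_labels}
    stage = {cid: "long-stage" for cid in long_labels}
    stage.update({cid: "short-stage" for cid in short_labels})
    return BinningResult(
        assignments=assignments,
        k=k,
        stage=stage,
        details={
            "k": k,
            "alpha": alpha,
            "beta": beta,
            "min_len": min_len,
            "seed": seed,
            "n_long": len(long_contigs),
            "n_short": len(short_contigs),
            "objective_trace": fact.objective_trace,
        },
    )
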