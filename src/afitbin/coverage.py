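"""Coverage distance between contigs from normal depth models.

Read depth of a contig in one sample is modelled as a normal distribution
parameterized by the observed per-contig mean and variance.  The distance
between two contigs in a sample is the non-shared area of their two unit
densities, reported on the [0, 1] scale as ``1 - OVL`` where
``OVL = integral of min(f1, f2)`` is the overlap coefficient: 0 for identical
depth distributions, approaching 1 as they separate.  Multi-sample distances
average the per-sample values, and the symmetric N x N coverage matrix C
collects them for all contig pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CoverageProfile",
    "VARIANCE_FLOOR_ABS",
    "VARIANCE_FLOOR_REL",
    "normal_nonshared_area",
    "coverage_distance",
    "build_coverage_matrix",
    "coverage_matrix_from_depth",
]

# floors avoid degenerate point masses from single-read depth estimates
VARIANCE_FLOOR_ABS = 1e-6
VARIANCE_FLOOR_REL = 0.05  # times the mean


@dataclass(frozen=True)
class CoverageProfile:
    """Per-sample depth mean and variance of one contig."""

    contig_id: str
    means: np.ndarray  # (S,)
    variances: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        if self.means.shape != self.variances.shape or self.means.ndim != 1:
            raise ValueError("means and variances must be 1-D and aligned")
        if np.any(self.means < 0) or np.any(self.variances < 0):
            raise ValueError(f"negative coverage statistics for {self.contig_id!r}")

    @property
    def num_samples(self) -> int:
        return self.means.shape[0]


def _floor_variance(mu, var):
    return np.maximum(var, np.maximum(VARIANCE_FLOOR_ABS, VARIANCE_FLOOR_REL * mu))


def _nonshared_area_arrays(mu1, var1, mu2, var2):
    """Vectorized 1 - OVL of two normal densities (variances already floored).

    The overlap is computed analytically: the densities cross where their
    log-densities agree, a quadratic in x, and the overlap is a sum of normal
    cdf masses over the intervals the crossing points delimit.
    """
    mu1, var1, mu2, var2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu1, var1, mu2, var2))
    )
    if not all(np.all(np.isfinite(a)) for a in (mu1, var1, mu2, var2)):
        raise ValueError("non-finite coverage parameters")
    sd1, sd2 = np.sqrt(var1), np.sqrt(var2)
    out = np.empty(mu1.shape, dtype=float)

    same = (mu1 == mu2) & (var1 == var2)
    out[same] = 0.0
    rest = ~same

    # equal variances: single crossing at the midpoint, OVL = 2 Phi(-|dmu|/(2 sd))
    eq = rest & np.isclose(var1, var2, rtol=1e-9, atol=0.0)
    if np.any(eq):
        ovl = 2.0 * ndtr(-np.abs(mu1[eq] - mu2[eq]) / (2.0 * sd1[eq]))
        out[eq] = 1.0 - ovl

    gen = rest & ~eq
    if np.any(gen):
        # order so that density "a" is the narrower one
        swap = var1 > var2
        mua = np.where(swap, mu2, mu1)[gen]
        mub = np.where(swap, mu1, mu2)[gen]
        va = np.where(swap, var2, var1)[gen]
        vb = np.where(swap, var1, var2)[gen]
        sa, sb = np.sqrt(va), np.sqrt(vb)
        # crossing points: quadratic a x^2 + b x + c = 0 from equating log-densities
        a = 0.5 / vb - 0.5 / va  # < 0 since va < vb
        b = mua / va - mub / vb
        c = mub**2 / (2.0 * vb) - mua**2 / (2.0 * va) + 0.5 * np.log(vb / va)
        disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
        r1 = (-b + disc) / (2.0 * a)
        r2 = (-b - disc) / (2.0 * a)
        lo, hi = np.minimum(r1, r2), np.maximum(r1, r2)
        # narrow density dominates between the crossings, wide one outside
        ovl = (
            ndtr((lo - mua) / sa)
            + (ndtr((hi - mub) / sb) - ndtr((lo - mub) / sb))
            + (1.0 - ndtr((hi - mua) / sa))
        )
        out[gen] = 1.0 - ovl

    return np.clip(out, 0.0, 1.0)


def normal_nonshared_area(mu1, var1, mu2, var2, floor_variances: bool = True) -> float:
    """Distance in [0, 1] between two normal depth distributions.

    Returns ``1 - integral of min(f1, f2)``: 0 for identical parameters, 1 in
    the limit of disjoint distributions.  Variances are floored at
    ``max(1e-6, 0.05 * mean)`` unless ``floor_variances`` is False.
    """
    if not all(np.isfinite(x) for x in (mu1, var1, mu2, var2)):
        raise ValueError("non-finite coverage parameters")
    if floor_variances:
        var1 = float(_floor_variance(mu1, var1))
        var2 = float(_floor_variance(mu2, var2))
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive (enable flooring)")
    return float(_nonshared_area_arrays(mu1, var1, mu2, var2))


def coverage_distance(p1: CoverageProfile, p2: CoverageProfile) -> float:
    """Mean per-sample non-shared area between two contigs' depth profiles."""
    if p1.num_samples != p2.num_samples:
        raise ValueError(
            f"sample count mismatch: {p1.contig_id!r} has {p1.num_samples}, "
            f"{p2.contig_id!r} has {p2.num_samples}"
        )
    v1 = _floor_variance(p1.means, p1.variances)
    v2 = _floor_variance(p2.means, p2.variances)
    return float(np.mean(_nonshared_area_arrays(p1.means, v1, p2.means, v2)))


def coverage_matrix_from_depth(means, variances) -> np.ndarray:
    """Symmetric N x N coverage-distance matrix from (N, S) mean/variance arrays."""
    means = np.asarray(means, dtype=float)
    variances = _floor_variance(means, np.asarray(variances, dtype=float))
    if means.ndim != 2:
        raise ValueError("means must be (N, S)")
    n, s = means.shape
    out = np.zeros((n, n), dtype=float)
    for k in range(s):
        mu = means[:, k]
        var = variances[:, k]
        out += _nonshared_area_arrays(
            mu[:, None], var[:, None], mu[None, :], var[None, :]
        )
    out /= s
    out = 0.5 * (out + out.T)  # exact symmetry against fp noise
    np.fill_diagonal(out, 0.0)
    return out


def build_coverage_matrix(profiles) -> np.ndarray:
    """Coverage-distance matrix for a list of :class:`CoverageProfile`."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no coverage profiles given")
    S = profiles[0].num_samples
    for p in profiles:
        if p.num_samples != S:
            raise ValueError(f"sample count mismatch for {p.contig_id!r}")
    means = np.stack([p.means for p in profiles])
    variances = np.stack([p.variances for p in profiles])
    return coverage_matrix_from_depth(means, variances)
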