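"""Profile summaries, distance-matrix correlation and two-group comparisons.

The correlation between two distance matrices is a Pearson r over the
vectorized strict upper triangles.  Two p-values are available: the plain
parametric one that treats the n(n-1)/2 entries as independent observations,
and a Mantel-style permutation p obtained by relabeling one matrix's
entities, which respects the dependence structure and is the recommended
mode.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import PhenotypeMatrix
from .ordination import DistanceMatrix

__all__ = [
    "ProfileSummary",
    "CorrelationResult",
    "GroupComparison",
    "summarize_profiles",
    "distance_correlation",
    "compare_groups",
    "rank_sum_test",
]


@dataclass(frozen=True)
class ProfileSummary:
    per_strain_counts: dict[str, int]  # resources used by each strain
    per_resource_counts: dict[str, int]  # strains using each resource
    universal_resources: tuple[str, ...]  # used by every strain
    unused_resources: tuple[str, ...]  # used by no strain
    group_means: dict[str, float] | None  # mean per-strain count per label


def summarize_profiles(
    m: PhenotypeMatrix, groups: dict[str, str] | None = None
) -> ProfileSummary:
    """Exact per-strain/per-resource usage counts and universal/unused lists.

    ``groups``, if given, must label every strain; per-label means of the
    per-strain counts are then reported.
    """
    row_sums = m.values.sum(axis=1)
    col_sums = m.values.sum(axis=0)
    per_strain = {s: int(c) for s, c in zip(m.strain_names, row_sums)}
    per_resource = {r: int(c) for r, c in zip(m.resource_names, col_sums)}
    universal = tuple(r for r, c in per_resource.items() if c == m.n_strains)
    unused = tuple(r for r, c in per_resource.items() if c == 0)

    group_means = None
    if groups is not None:
        unknown = set(groups) - set(m.strain_names)
        if unknown:
            raise ValueError(f"unknown strain(s) in groups map: {sorted(unknown)}")
        missing = set(m.strain_names) - set(groups)
        if missing:
            raise ValueError(f"groups map does not cover strain(s): {sorted(missing)}")
        by_label: dict[str, list[int]] = {}
        for s, label in groups.items():
            by_label.setdefault(label, []).append(per_strain[s])
        group_means = {label: float(np.mean(v)) for label, v in by_label.items()}
    return ProfileSummary(per_strain, per_resource, universal, unused, group_means)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_parametric: float  # treats upper-triangle entries as independent ("as in paper")
    p_permutation: float | None  # Mantel-style; None when permutations == 0
    n_pairs: int
    n_entities: int
    permutations: int


def _align(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[DistanceMatrix, DistanceMatrix]:
    if d1.names == d2.names:
        return d1, d2
    shared = [n for n in d1.names if n in set(d2.names)]
    if set(d1.names) != set(d2.names):
        warnings.warn(
            f"distance matrices share only {len(shared)} of "
            f"{len(d1.names)}/{len(d2.names)} entities; using the intersection"
        )
    if len(shared) < 3:
        raise ValueError("need at least 3 shared entities")

    def subset(d: DistanceMatrix) -> DistanceMatrix:
        idx = [d.names.index(n) for n in shared]
        return DistanceMatrix(tuple(shared), d.values[np.ix_(idx, idx)])

    return subset(d1), subset(d2)


def distance_correlation(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 0,
    seed: int | np.random.Generator | None = None,
) -> CorrelationResult:
    """Pearson correlation of two distance matrices over matched upper triangles.

    The parametric p comes from the t transform with n(n-1)/2 - 2 degrees of
    freedom.  With ``permutations > 0`` a two-sided Mantel permutation p is
    added, computed by jointly permuting rows and columns of ``d2``.
    """
    d1, d2 = _align(d1, d2)
    n = d1.n
    if n < 3:
        raise ValueError("need at least 3 entities")
    v1 = d1.upper_triangle()
    v2 = d2.upper_triangle()
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero variance in a distance triangle; correlation undefined")
    r, p_param = sps.pearsonr(v1, v2)

    p_perm = None
    if permutations > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        iu = np.triu_indices(n, k=1)
        z1 = (v1 - v1.mean()) / v1.std()
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            pv2 = d2.values[np.ix_(perm, perm)][iu]
            rb = float(np.mean(z1 * (pv2 - pv2.mean()) / pv2.std()))
            if abs(rb) >= abs(r) - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (permutations + 1)

    return CorrelationResult(
        rho=float(r),
        p_parametric=float(p_param),
        p_permutation=p_perm,
        n_pairs=len(v1),
        n_entities=n,
        permutations=permutations,
    )


# ---------------------------------------------------------------------------
# Two-group comparison (rank-sum with KS normality pre-check)
# ---------------------------------------------------------------------------

EXACT_LIMIT = 12  # combined sample size up to which the null is enumerated


def rank_sum_test(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p, method)`` where W is the sum of midranks of ``x``.  For
    combined n <= EXACT_LIMIT the p-value enumerates all C(n, n1) rank
    assignments (ties handled through midranks); otherwise a normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2

    if n <= EXACT_LIMIT:
        obs = abs(w - mu)
        total = math.comb(n, n1)
        hits = sum(
            1
            for comb in itertools.combinations(range(n), n1)
            if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9
        )
        return w, hits / total, "exact"

    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:  # all values identical
        return w, 1.0, "normal"
    z = (w - mu) / math.sqrt(var)
    p = min(1.0, 2 * sps.norm.sf(abs(z)))
    return w, p, "normal"


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    ks_stat: tuple[float, float]  # KS normality statistic per group
    ks_p: tuple[float, float]
    rank_sum: float  # sum of midranks of the first group
    p_value: float
    method: str  # "exact" | "normal"


def _group_values(data, labels: dict[str, str]) -> dict[str, np.ndarray]:
    """Values per label: within-group pairwise distances for a DistanceMatrix,
    plain values for a name -> value mapping."""
    by_label: dict[str, list[str]] = {}
    for name, label in labels.items():
        by_label.setdefault(label, []).append(name)
    if len(by_label) != 2:
        raise ValueError(f"exactly two groups required, got {len(by_label)}")
    out: dict[str, np.ndarray] = {}
    if isinstance(data, DistanceMatrix):
        idx = {n: i for i, n in enumerate(data.names)}
        for label, members in by_label.items():
            ii = [idx[m] for m in members]
            sub = data.values[np.ix_(ii, ii)]
            out[label] = sub[np.triu_indices(len(ii), k=1)]
    else:
        for label, members in by_label.items():
            out[label] = np.array([data[m] for m in members], dtype=float)
    for label, v in out.items():
        if v.size == 0:
            raise ValueError(f"group {label!r} has no values")
    return out


def _ks_normality(v: np.ndarray) -> tuple[float, float]:
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        return 1.0, 0.0  # degenerate: maximally non-normal
    stat, p = sps.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p)


def compare_groups(data, labels: dict[str, str]) -> GroupComparison:
    """Compare two labeled groups of values with a rank-sum test.

    ``data`` is either a :class:`DistanceMatrix` (groups are compared on
    their within-group pairwise distances) or a mapping name -> value.  A KS
    normality check is reported per group before the Wilcoxon rank-sum test.
    """
    grouped = _group_values(data, labels)
    (la, va), (lb, vb) = sorted(grouped.items())
    ks_a, ks_b = _ks_normality(va), _ks_normality(vb)
    w, p, method = rank_sum_test(va, vb)
    return GroupComparison(
        labels=(la, lb),
        n=(va.size, vb.size),
        ks_stat=(ks_a[0], ks_b[0]),
        ks_p=(ks_a[1], ks_b[1]),
        rank_sum=w,
        p_value=p,
        method=method,
    )
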