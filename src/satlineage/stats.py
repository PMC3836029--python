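"""Differentiation statistics: exact R x 2 tests, Bonferroni, private
alleles, and Weir-Cockerham FST with a permutation test.

The per-locus differentiation test compares allele counts (gene copies)
between two groups under the multivariate hypergeometric null with fixed
margins; the two-sided p-value is the total probability of tables no more
probable than the observed one (the table-probability criterion, i.e. the
classical Fisher exact test generalized to R alleles). Tables small enough
are enumerated exhaustively; larger ones fall back to Monte-Carlo sampling
with the add-one estimator, so a reported p can never understate
1 / (n_draws + 1).

FST is the Weir & Cockerham (1984) variance-components estimator theta:
per locus and allele, the among-group (a), among-individual-within-group (b)
and within-individual (c) components are computed from sample sizes, allele
frequencies and heterozygote frequencies; the multi-locus estimate is the
ratio of sums, theta = sum(a) / sum(a + b + c) over all loci and alleles.
The permutation test reallocates individuals between groups (genotypes
intact, group sizes preserved), matching the standard scheme for FST among
groups of individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotypes import (
    AlleleFrequencyTable,
    GenotypeTable,
    ValidationError,
)

__all__ = [
    "exact_test_rxc",
    "count_tables",
    "bonferroni",
    "private_allele_proportions",
    "weir_cockerham_fst",
    "fst_permutation_test",
    "FstResult",
    "PermutationResult",
    "MonomorphicDataError",
]

_LOG_TOL = 1e-7  # tolerance when comparing table log-probabilities


class MonomorphicDataError(ValueError):
    """Every locus is monomorphic: theta is undefined (0/0)."""


# ---------------------------------------------------------------------------
# Exact R x 2 allele-count test
# ---------------------------------------------------------------------------


def count_tables(row_margins: np.ndarray, c1: int) -> int:
    """Number of R x 2 tables with the given row margins and first-column sum.

    Dynamic programming over rows (polynomial-coefficient counting).
    """
    poly = np.zeros(c1 + 1, dtype=object)
    poly[0] = 1
    for r in row_margins:
        new = np.zeros(c1 + 1, dtype=object)
        for s in range(c1 + 1):
            if poly[s]:
                hi = min(int(r), c1 - s)
                new[s : s + hi + 1] += poly[s]
        poly = new
    return int(poly[c1])


def _validate_counts(counts) -> np.ndarray:
    mat = np.asarray(counts)
    if mat.ndim != 2 or mat.shape[1] != 2:
        raise ValidationError("exact test expects an R x 2 count table")
    if np.any(mat < 0) or not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat != np.floor(mat)) or np.any(mat < 0):
            raise ValidationError("counts must be nonnegative integers")
        mat = mat.astype(int)
    row_sums = mat.sum(axis=1)
    if np.any(row_sums == 0):
        warnings.warn("dropping zero-margin allele rows", stacklevel=3)
        mat = mat[row_sums > 0]
    if mat.size == 0 or mat.sum() == 0:
        raise ValidationError("table has no positive margins")
    return mat


def _log_table_prob(x: np.ndarray, row_margins: np.ndarray) -> float:
    """log P(column-1 counts = x | margins) under the hypergeometric null."""
    r = row_margins
    return float(
        np.sum(gammaln(r + 1) - gammaln(x + 1) - gammaln(r - x + 1))
    )


def exact_test_rxc(
    counts,
    mode: str = "auto",
    n_mc: int = 100_000,
    seed: int | None = None,
    max_tables: int = 100_000,
) -> float:
    """Two-sided exact test of allele-count homogeneity for R alleles x 2 groups.

    ``mode``: ``exhaustive`` enumerates every table with the observed margins;
    ``montecarlo`` samples ``n_mc`` tables from the null (seed required);
    ``auto`` enumerates when the table count is at most ``max_tables`` and
    falls back to Monte Carlo otherwise.
    """
    mat = _validate_counts(counts)
    row_margins = mat.sum(axis=1)
    c1 = int(mat[:, 0].sum())
    obs_logp = _log_table_prob(mat[:, 0], row_margins)

    if mode == "auto":
        mode = "exhaustive" if count_tables(row_margins, c1) <= max_tables else "montecarlo"
    if mode == "exhaustive":
        return _exact_exhaustive(row_margins, c1, obs_logp)
    if mode == "montecarlo":
        if seed is None:
            raise ValidationError("Monte-Carlo exact test requires a seed")
        return _exact_montecarlo(row_margins, c1, obs_logp, n_mc, seed)
    raise ValidationError(f"unknown exact-test mode {mode!r}")


def _exact_exhaustive(row_margins: np.ndarray, c1: int, obs_logp: float) -> float:
    """Depth-first enumeration of column-1 count vectors, with pruning."""
    r = row_margins.astype(int)
    R = len(r)
    suffix = np.concatenate([np.cumsum(r[::-1])[::-1], [0]])  # sum r[i:]
    log_binom = [
        gammaln(ri + 1) - gammaln(np.arange(ri + 1) + 1)
        - gammaln(ri - np.arange(ri + 1) + 1)
        for ri in r
    ]
    p_extreme = 0.0
    total = 0.0  # accumulated for a normalization sanity check

    stack = [(0, c1, 0.0)]  # (row index, remaining column-1 mass, logprob so far)
    while stack:
        i, rem, lp = stack.pop()
        if i == R:
            p_here = np.exp(lp)
            total += p_here
            if lp <= obs_logp + _LOG_TOL:
                p_extreme += p_here
            continue
        lo = max(0, rem - int(suffix[i + 1]))
        hi = min(int(r[i]), rem)
        for x in range(lo, hi + 1):
            stack.append((i + 1, rem - x, lp + float(log_binom[i][x])))

    n = int(r.sum())
    log_denom = float(gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    # `total` should equal exp(log_denom); normalize to be safe
    return min(1.0, p_extreme / np.exp(log_denom))


def _exact_montecarlo(
    row_margins: np.ndarray, c1: int, obs_logp: float, n_mc: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(row_margins.astype(int), c1, size=n_mc)
    r = row_margins[None, :]
    logp = np.sum(
        gammaln(r + 1) - gammaln(draws + 1) - gammaln(r - draws + 1), axis=1
    )
    hits = int(np.sum(logp <= obs_logp + _LOG_TOL))
    return (1 + hits) / (1 + n_mc)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValidationError("family size m must be >= number of p-values")
    out = []
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


# ---------------------------------------------------------------------------
# Private (lineage-specific) alleles
# ---------------------------------------------------------------------------


def private_allele_proportions(
    freqs: AlleleFrequencyTable,
    groups: tuple[str, str],
) -> dict[str, dict]:
    """Per-locus proportion of alleles observed in exactly one of two groups.

    The count-based proportion is (# distinct alleles seen in exactly one
    group) / (# distinct alleles seen overall). A frequency-weighted variant
    — the share of pooled gene copies carried by private alleles — is also
    returned, since either reading of "proportion of lineage-specific
    alleles" is defensible.
    """
    g1, g2 = groups
    out: dict[str, dict] = {}
    for locus in freqs.loci:
        if (locus, g1) in freqs.flagged or (locus, g2) in freqs.flagged:
            out[locus] = {"defined": False}
            continue
        s1 = freqs.observed_alleles(locus, g1)
        s2 = freqs.observed_alleles(locus, g2)
        union = s1 | s2
        private = (s1 - s2) | (s2 - s1)
        pooled = {
            a: freqs.counts[locus][g1].get(a, 0) + freqs.counts[locus][g2].get(a, 0)
            for a in union
        }
        total_copies = sum(pooled.values())
        out[locus] = {
            "defined": True,
            "n_alleles": len(union),
            "n_private": len(private),
            "n_private_per_group": {g1: len(s1 - s2), g2: len(s2 - s1)},
            "proportion": len(private) / len(union),
            "proportion_weighted": sum(pooled[a] for a in private) / total_copies,
        }
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------


@dataclass
class _LocusArrays:
    """Per-locus dosage/heterozygote arrays for fast theta recomputation."""

    dosage: np.ndarray   # individuals x alleles, allele copies carried (0/1/2)
    het: np.ndarray      # individuals x alleles, 1 if heterozygous carrier
    typed: np.ndarray    # individuals, bool


@dataclass
class FstResult:
    theta: float
    per_locus: dict[str, float]
    sum_a: float
    sum_abc: float
    groups: list[str]


@dataclass
class PermutationResult:
    theta_obs: float
    p_value: float
    n_perm: int
    seed: int
    n_greater_equal: int
    perm_mean: float = field(default=float("nan"))


def _locus_arrays(table: GenotypeTable) -> dict[str, tuple[list[int], _LocusArrays]]:
    n = len(table.individuals)
    out = {}
    for locus in table.locus_names:
        alleles = sorted(
            {a for ind in table.individuals
             for a in (ind.genotypes[locus] or ())}
        )
        idx = {a: k for k, a in enumerate(alleles)}
        dosage = np.zeros((n, len(alleles)))
        het = np.zeros((n, len(alleles)))
        typed = np.zeros(n, dtype=bool)
        for i, ind in enumerate(table.individuals):
            g = ind.genotypes[locus]
            if g is None:
                continue
            typed[i] = True
            a, b = g
            dosage[i, idx[a]] += 1
            dosage[i, idx[b]] += 1
            if a != b:
                het[i, idx[a]] = 1
                het[i, idx[b]] = 1
        out[locus] = (alleles, _LocusArrays(dosage, het, typed))
    return out


def _theta_components(
    arrays: dict[str, tuple[list[int], _LocusArrays]],
    membership: np.ndarray,  # groups x individuals, 0/1
) -> tuple[float, float, dict[str, tuple[float, float]]]:
    """Sum of W&C a and a+b+c over loci and alleles for one grouping."""
    sum_a = 0.0
    sum_abc = 0.0
    per_locus: dict[str, tuple[float, float]] = {}
    for locus, (alleles, la) in arrays.items():
        n_i = membership @ la.typed.astype(float)          # typed per group
        use = n_i >= 1
        r = int(use.sum())
        if r < 2 or la.dosage.shape[1] < 2:
            per_locus[locus] = (0.0, 0.0)
            continue
        n_i = n_i[use]
        counts = (membership[use] @ la.dosage)             # groups x alleles
        hets = (membership[use] @ la.het)
        p_i = counts / (2 * n_i[:, None])
        h_i = hets / n_i[:, None]

        nbar = n_i.mean()
        if nbar <= 1:
            per_locus[locus] = (0.0, 0.0)
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            per_locus[locus] = (0.0, 0.0)
            continue
        pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i[:, None] * (p_i - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        la_a = float(a.sum())
        la_abc = float((a + b + c).sum())
        per_locus[locus] = (la_a, la_abc)
        sum_a += la_a
        sum_abc += la_abc
    return sum_a, sum_abc, per_locus


def _membership(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    groups: list[str] = []
    for lab in labels:
        if lab not in groups:
            groups.append(lab)
    m = np.zeros((len(groups), len(labels)))
    for i, lab in enumerate(labels):
        m[groups.index(lab), i] = 1.0
    return m, groups


def _resolve_grouping(table: GenotypeTable, grouping) -> list[str]:
    if isinstance(grouping, str):
        return table.group_labels(grouping)
    labels = list(grouping)
    if len(labels) != len(table.individuals):
        raise ValidationError("grouping length does not match number of individuals")
    return labels


def weir_cockerham_fst(table: GenotypeTable, grouping="lineage") -> FstResult:
    """Multi-locus Weir-Cockerham theta (ratio of sums over loci and alleles)."""
    labels = _resolve_grouping(table, grouping)
    membership, groups = _membership(labels)
    if len(groups) < 2:
        raise ValidationError("FST requires at least 2 groups")
    for g, row in zip(groups, membership):
        if row.sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 individuals")
    arrays = _locus_arrays(table)
    sum_a, sum_abc, per_locus = _theta_components(arrays, membership)
    if sum_abc == 0.0:
        raise MonomorphicDataError(
            "theta undefined: no genetic variance at any locus"
        )
    per_locus_theta = {
        loc: (a / abc if abc != 0 else float("nan"))
        for loc, (a, abc) in per_locus.items()
    }
    return FstResult(
        theta=sum_a / sum_abc,
        per_locus=per_locus_theta,
        sum_a=sum_a,
        sum_abc=sum_abc,
        groups=groups,
    )


def fst_permutation_test(
    table: GenotypeTable,
    grouping="lineage",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for theta: individuals reallocated between groups.

    Group sizes are preserved; p = (1 + #{theta_perm >= theta_obs}) /
    (1 + n_perm) (add-one rule, so p can never be reported below its
    resolution).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    labels = _resolve_grouping(table, grouping)
    membership, groups = _membership(labels)
    if len(groups) < 2:
        raise ValidationError("FST requires at least 2 groups")
    arrays = _locus_arrays(table)
    sum_a, sum_abc, _ = _theta_components(arrays, membership)
    if sum_abc == 0.0:
        raise MonomorphicDataError("theta undefined: no genetic variance")
    theta_obs = sum_a / sum_abc

    rng = np.random.default_rng(seed)
    n = len(labels)
    ge = 0
    perm_sum = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        a, abc, _ = _theta_components(arrays, membership[:, perm])
        theta_p = a / abc if abc != 0 else 0.0
        perm_sum += theta_p
        if theta_p >= theta_obs - 1e-12:
            ge += 1
    return PermutationResult(
        theta_obs=theta_obs,
        p_value=(1 + ge) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
        n_greater_equal=ge,
        perm_mean=perm_sum / n_perm,
    )
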