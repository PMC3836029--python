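"""Pairwise allele-sharing distance between diploid individuals.

The per-locus distance between individuals *i* and *j* is 0 when their
unordered allele pairs are identical, 0.5 when they share a single allele,
and 1.0 when they have no allele in common; the pairwise distance is the mean
over loci. "Share a single allele" is read by copy number (multiset
intersection of size 1): {A,A} vs {A,B} -> 0.5 and {A,A} vs {A,A} -> 0.
For diploids an intersection of size 2 with unequal genotypes cannot occur,
so the three-way rule is exhaustive.

Missing genotypes are handled by pairwise deletion: the mean runs over loci
typed in both individuals, and the number of loci used per pair is recorded.
The distance is a semimetric (no triangle-inequality claim); neighbor joining
does not require metricity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import Genotype, GenotypeTable, Individual, ValidationError

__all__ = [
    "locus_distance",
    "pairwise_distance",
    "distance_matrix",
    "DistanceMatrix",
    "read_phylip",
]


def locus_distance(g_i: Genotype, g_j: Genotype) -> float:
    """Per-locus allele-sharing distance: 0, 0.5 or 1.0.

    Both genotypes must be non-missing; callers average over computable loci.
    """
    if g_i is None or g_j is None:
        raise ValidationError(
            "locus distance is not computable with a missing genotype; "
            "callers must average over commonly typed loci"
        )
    a, b = sorted(g_i)
    c, d = sorted(g_j)
    if (a, b) == (c, d):
        return 0.0
    # multiset intersection size for two sorted pairs
    shared = 0
    for allele in {a, b}:
        shared += min((a, b).count(allele), (c, d).count(allele))
    return 0.5 if shared == 1 else 1.0


def pairwise_distance(
    ind_i: Individual,
    ind_j: Individual,
    loci: list[str] | None = None,
) -> float:
    """Mean allele-sharing distance over loci typed in both individuals."""
    d, used = _pair(ind_i, ind_j, loci or sorted(ind_i.genotypes))
    return d


def _pair(ind_i: Individual, ind_j: Individual, loci) -> tuple[float, int]:
    total = 0.0
    used = 0
    for loc in loci:
        g_i = ind_i.genotypes.get(loc)
        g_j = ind_j.genotypes.get(loc)
        if g_i is None or g_j is None:
            continue
        total += locus_distance(g_i, g_j)
        used += 1
    if used == 0:
        raise ValidationError(
            f"individuals {ind_i.id!r} and {ind_j.id!r} share no typed locus; "
            "distance undefined"
        )
    return total / used, used


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal.

    Allele-sharing matrices built by :func:`distance_matrix` additionally lie
    in [0, 1], each entry being a mean of per-locus values from {0, 0.5, 1}.
    ``loci_used[i, j]`` records how many loci entered each pairwise mean
    (pairwise deletion makes this vary when data are missing).
    """

    ids: list[str]
    values: np.ndarray
    loci_used: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("matrix shape does not match number of ids")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if v.min() < 0:
            raise ValidationError("distances must be nonnegative")
        self.values = v

    def submatrix_mean(self, rows: list[int], cols: list[int]) -> float:
        """Mean over the rows x cols block, excluding diagonal cells."""
        block = self.values[np.ix_(rows, cols)]
        mask = np.ones_like(block, dtype=bool)
        common = set(rows) & set(cols)
        if common:
            ri = {r: k for k, r in enumerate(rows)}
            ci = {c: k for k, c in enumerate(cols)}
            for x in common:
                mask[ri[x], ci[x]] = False
        vals = block[mask]
        return float(vals.mean()) if vals.size else float("nan")

    def to_phylip(self, path: str | Path, precision: int = 6) -> None:
        """PHYLIP square (lower+full) distance matrix format."""
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, ind_id in enumerate(self.ids):
                row = " ".join(f"{x:.{precision}f}" for x in self.values[i])
                fh.write(f"{ind_id:<10s} {row}\n")

    def to_tsv(self, path: str | Path, precision: int = 6) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, ind_id in enumerate(self.ids):
                row = "\t".join(f"{x:.{precision}f}" for x in self.values[i])
                fh.write(f"{ind_id}\t{row}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (one taxon per line)."""
    lines = [l for l in Path(path).read_text(encoding="utf-8").splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(ids=ids, values=np.array(rows))


def distance_matrix(table: GenotypeTable) -> DistanceMatrix:
    """All-pairs allele-sharing distance matrix for a genotype table."""
    inds = table.individuals
    n = len(inds)
    if n < 3:
        raise ValidationError("distance matrix requires at least 3 individuals")
    loci = table.locus_names
    values = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    used[np.diag_indices(n)] = len(loci)
    for i in range(n):
        for j in range(i + 1, n):
            d, k = _pair(inds[i], inds[j], loci)
            values[i, j] = values[j, i] = d
            used[i, j] = used[j, i] = k
    return DistanceMatrix(ids=[ind.id for ind in inds], values=values, loci_used=used)
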