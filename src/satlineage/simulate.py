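"""Synthetic two-lineage microsatellite genotype generator.

Emulates the sampling design the downstream analysis assumes: two genetically
isolated lineages (sexual and asexual) sampled at two sites, ~20 females per
lineage per site, nine microsatellite loci, with lineage-private alleles at
every locus and geographic substructure in the sexual lineage only.

Generative model, per locus:

1. Draw a contiguous block of allele codes (fragment-length-like integers)
   and split it so that an expected ``divergence`` fraction of alleles is
   private to one lineage. Private-to-sexual alleles take the low codes,
   private-to-asexual the high codes, shared alleles the middle; the asexual
   pool (shared + asexual-private) is therefore contiguous, so stepwise
   mutation reflected at the pool boundary can never re-create a
   sexual-private allele. With ``divergence = 1`` the pools are disjoint and
   every between-lineage per-locus distance is exactly 1.
2. Sexual lineage: ancestral allele frequencies ~ symmetric
   Dirichlet(concentration); per-site frequencies are a Balding-Nichols
   perturbation Dirichlet(p * (1 - F) / F) targeting ``sexual_site_fst``
   between sites; each individual's two alleles are drawn independently
   (Hardy-Weinberg random mating within site).
3. Asexual lineage: ``n_clone_founders`` founder genotypes are drawn from a
   single asexual allele pool shared across sites; each sampled individual
   copies a uniformly random founder regardless of site (no site structure,
   by design), then each locus mutates with probability
   ``clone_mutation_rate`` by a reflected +/-1 step on one allele copy
   (repeat-unit stepwise mutation).

A single :class:`numpy.random.Generator` seeded from ``config.seed`` drives
everything; identical config + seed gives a bit-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .genotypes import GenotypeTable, Individual, LocusDef, ValidationError

__all__ = [
    "SimulationConfig",
    "simulate_two_lineages",
    "null_shuffle",
    "hwe_montecarlo_test",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the two-lineage generator.

    Defaults mirror the study design the pipeline targets: 9 loci, two sites,
    20 sexual + 20 asexual females per site. ``divergence`` is the expected
    proportion of each locus's alleles private to one lineage;
    ``sexual_site_fst`` the target between-site differentiation within the
    sexual lineage (the asexual lineage deliberately has none).
    """

    n_loci: int = 9
    alleles_per_locus: int = 8
    n_sexual_per_site: int = 20
    n_asexual_per_site: int = 20
    sites: tuple[str, ...] = ("Nanporo", "Kuriyama")
    divergence: float = 0.5
    sexual_site_fst: float = 0.02
    n_clone_founders: int = 3
    clone_mutation_rate: float = 0.01
    dirichlet_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_loci, self.n_sexual_per_site, self.n_asexual_per_site,
               self.n_clone_founders) < 1 or not self.sites:
            raise ValidationError("all counts must be positive and sites nonempty")
        for name in ("divergence", "sexual_site_fst", "clone_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be positive")
        if self.alleles_per_locus < 2 and self.divergence > 0:
            raise ValidationError(
                "alleles_per_locus < 2 cannot create private alleles "
                "with divergence > 0"
            )
        object.__setattr__(self, "sites", tuple(self.sites))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML key-value file whose keys are the field names."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValidationError(f"unknown simulation config keys: {sorted(extra)}")
        if "sites" in raw:
            raw["sites"] = tuple(raw["sites"])
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class _LocusModel:
    codes: np.ndarray            # all allele codes, ascending
    sexual_pool: np.ndarray      # codes available to the sexual lineage
    asexual_pool: np.ndarray     # contiguous block: shared + asexual-private
    site_freqs: dict[str, np.ndarray]   # over sexual_pool, one per site
    asexual_freqs: np.ndarray    # over asexual_pool


def _split_alleles(rng: np.random.Generator, cfg: SimulationConfig) -> tuple:
    """Partition one locus's codes into sexual-private / shared / asexual-private."""
    A = cfg.alleles_per_locus
    n_priv = rng.binomial(A, cfg.divergence)
    if cfg.divergence > 0 and n_priv == 0:
        n_priv = 1  # every locus carries at least one private allele
    n_asex_priv = rng.binomial(n_priv, 0.5) if n_priv else 0
    if n_priv == A:  # no shared alleles: both lineages need a nonempty pool
        n_asex_priv = min(max(n_asex_priv, 1), A - 1)
    n_sex_priv = n_priv - n_asex_priv
    return n_sex_priv, n_asex_priv


def _build_locus(rng: np.random.Generator, cfg: SimulationConfig) -> _LocusModel:
    A = cfg.alleles_per_locus
    start = int(rng.integers(100, 280))
    codes = np.arange(start, start + A)
    n_sex_priv, n_asex_priv = _split_alleles(rng, cfg)
    sexual_pool = codes[: A - n_asex_priv]
    asexual_pool = codes[n_sex_priv:]
    conc = cfg.dirichlet_concentration

    p = rng.dirichlet(np.full(len(sexual_pool), conc))
    F = cfg.sexual_site_fst
    site_freqs = {}
    for site in cfg.sites:
        if F > 0:
            site_freqs[site] = rng.dirichlet(np.maximum(p * (1 - F) / F, 1e-9))
        else:
            site_freqs[site] = p
    asexual_freqs = rng.dirichlet(np.full(len(asexual_pool), conc))
    return _LocusModel(codes, sexual_pool, asexual_pool, site_freqs, asexual_freqs)


def _draw_pair(rng, pool: np.ndarray, freqs: np.ndarray) -> tuple[int, int]:
    a, b = rng.choice(pool, size=2, replace=True, p=freqs)
    return int(a), int(b)


def _mutate(rng, allele: int, pool: np.ndarray) -> int:
    """Reflected +/-1 stepwise mutation, confined to the pool's code range."""
    lo, hi = int(pool[0]), int(pool[-1])
    step = int(rng.choice([-1, 1]))
    cand = allele + step
    if cand < lo or cand > hi:
        cand = allele - step
    if cand < lo or cand > hi:  # single-allele pool: mutation is a no-op
        return allele
    return cand


def simulate_two_lineages(config: SimulationConfig) -> GenotypeTable:
    """Generate a labeled two-lineage genotype table (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    loci = [_build_locus(rng, config) for _ in range(config.n_loci)]
    locus_names = [f"L{k + 1:02d}" for k in range(config.n_loci)]

    individuals: list[Individual] = []
    counter = 0

    # sexual lineage: HWE within site, frequencies differ between sites
    for site in config.sites:
        for _ in range(config.n_sexual_per_site):
            counter += 1
            genotypes = {
                name: _draw_pair(rng, lm.sexual_pool, lm.site_freqs[site])
                for name, lm in zip(locus_names, loci)
            }
            individuals.append(
                Individual(id=f"S{counter:03d}", lineage="sexual",
                           location=site, genotypes=genotypes)
            )

    # asexual lineage: founders shared across sites, then stepwise mutation
    founders = [
        {name: _draw_pair(rng, lm.asexual_pool, lm.asexual_freqs)
         for name, lm in zip(locus_names, loci)}
        for _ in range(config.n_clone_founders)
    ]
    counter = 0
    for site in config.sites:
        for _ in range(config.n_asexual_per_site):
            counter += 1
            founder = founders[int(rng.integers(config.n_clone_founders))]
            genotypes = {}
            for name, lm in zip(locus_names, loci):
                g = founder[name]
                if rng.random() < config.clone_mutation_rate:
                    which = int(rng.integers(2))
                    g = list(g)
                    g[which] = _mutate(rng, g[which], lm.asexual_pool)
                    g = tuple(g)
                genotypes[name] = g
            individuals.append(
                Individual(id=f"A{counter:03d}", lineage="asexual",
                           location=site, genotypes=genotypes)
            )

    return GenotypeTable(
        loci=[
            LocusDef(name, frozenset(int(c) for c in lm.codes))
            for name, lm in zip(locus_names, loci)
        ],
        individuals=individuals,
    )


def null_shuffle(table: GenotypeTable, seed: int) -> GenotypeTable:
    """Permute lineage labels uniformly at random; genotypes untouched.

    Destroys lineage structure while conserving the label multiset — the
    null-model fixture for type-I-error suites.
    """
    lineages = {ind.lineage for ind in table.individuals}
    if len(lineages) < 2:
        raise ValidationError("null shuffle requires at least 2 lineage labels")
    rng = np.random.default_rng(seed)
    labels = [ind.lineage for ind in table.individuals]
    perm = rng.permutation(len(labels))
    shuffled = [labels[k] for k in perm]
    individuals = [
        Individual(id=ind.id, lineage=lab, location=ind.location,
                   genotypes=dict(ind.genotypes))
        for ind, lab in zip(table.individuals, shuffled)
    ]
    return GenotypeTable(loci=list(table.loci), individuals=individuals)


def hwe_montecarlo_test(
    genotypes: list[tuple[int, int]],
    n_mc: int = 999,
    seed: int = 0,
) -> float:
    """Conditional Hardy-Weinberg test for one locus in one deme (QC utility).

    Null: conditional on the observed gene-copy multiset, the 2n copies are
    paired into individuals uniformly at random (random mating). The
    heterozygote count is the statistic; the two-sided p-value is
    Monte-Carlo-evaluated with the add-one rule, doubling the smaller tail
    (capped at 1). Used only to QC the synthetic sexual lineage.
    """
    pairs = [g for g in genotypes if g is not None]
    if len(pairs) < 2:
        raise ValidationError("HWE test needs at least 2 typed individuals")
    copies = np.array([a for g in pairs for a in g])
    n = len(pairs)
    obs_het = sum(1 for a, b in pairs if a != b)
    rng = np.random.default_rng(seed)
    het = np.empty(n_mc, dtype=int)
    for k in range(n_mc):
        perm = rng.permutation(copies).reshape(n, 2)
        het[k] = int((perm[:, 0] != perm[:, 1]).sum())
    hi = int((het >= obs_het).sum())
    lo = int((het <= obs_het).sum())
    p = 2.0 * (1 + min(hi, lo)) / (1 + n_mc)
    return min(p, 1.0)
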