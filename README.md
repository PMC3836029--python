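# satlineage

Population-genetic evidence for reproductive isolation between sympatric
sexual and asexual (thelytokous) lineages, from codominant microsatellite
genotypes. The motivating system is onion thrips (*Thrips tabaci*), where
both reproductive modes co-occur in the same fields and each female can be
assigned to a lineage by a wet-lab assay; the question is whether the two
lineages exchange genes. `satlineage` implements the complete downstream
analysis chain for that question, for anyone with a diploid multi-locus
genotype table and a per-individual lineage label:

1. **Allele-sharing distance** between individuals: at each locus
   d<sub>l</sub> = 0 if the two unordered allele pairs are identical, 0.5 if
   they share exactly one allele (counted by copy), 1.0 if they share none;
   the pairwise distance is the mean over loci, D = (1/L)·Σ d<sub>l</sub>.
2. **Neighbor-joining tree** (canonical Saitou–Nei) from the distance
   matrix, with Newick export and a **monophyly test**: a lineage is
   monophyletic iff some edge of the unrooted tree separates it from
   everything else. Genetically isolated lineages form mutually exclusive
   clades.
3. **Per-locus exact tests** of allele-frequency homogeneity between the
   lineages (Fisher's exact test generalized to R alleles × 2 groups,
   exhaustive or Monte-Carlo), with Bonferroni correction over loci.
4. **Private (lineage-specific) allele** proportions per locus — alleles
   observed in exactly one lineage.
5. **F<sub>ST</sub>** as the Weir–Cockerham (1984) variance-components
   estimator θ (multi-locus ratio of sums), with a permutation test that
   reallocates individuals between lineages (add-one p-value rule).

Because such field datasets are frequently not deposited, the package ships
a first-class **synthetic generator** that reproduces the statistical
structure this analysis assumes: two isolated lineages at two sites,
20 females per lineage per site, nine loci, lineage-private alleles,
Hardy–Weinberg random mating within sites for the sexual lineage, and
clonal founder genotypes with stepwise mutation (no site structure) for the
asexual lineage. Every stage is validated against it.

## Worked example

```bash
python analysis/01_simulate.py        # synthetic 80-female dataset
python analysis/02_distance_tree.py   # distances + NJ tree + monophyly
python analysis/03_differentiation.py # exact tests, private alleles, FST
python analysis/04_full_report.py     # full pipeline + shuffled-label null
```

Output of the chain (seed 1, divergence 0.8):

```
mean allele-sharing distance: within sexual 0.486, within asexual 0.337, between 0.946
sexual lineage monophyletic on the NJ tree: True
asexual lineage monophyletic on the NJ tree: True
...
loci significant after Bonferroni at alpha=0.05: 9/9
multi-locus Weir-Cockerham theta = 0.42763; permutation p = 0.0001 (minimum attainable 0.0001)
...
[shuffled labels] significant loci after Bonferroni: 0/9
[shuffled labels] theta = -0.00547; permutation p = 0.6502
[shuffled labels] monophyly: {'asexual': False, 'sexual': False}
```

Read: between-lineage distances (0.946) dwarf within-lineage ones, every
locus is significantly differentiated after correction, θ is large with the
smallest attainable permutation p, and each lineage is a clade on the NJ
tree — the full signature of two reproductively isolated gene pools living
in the same fields. Shuffling the lineage labels destroys every one of those
signals, so none of them is an artifact of the pipeline.

The same pipeline runs from the shell on your own data:

```bash
satlineage simulate --seed 1 --out sim_out
satlineage analyze sim_out/genotypes.tsv --n-perm 9999 --out results
satlineage analyze data.gen --format genepop --metadata data.meta.tsv
```

Inputs are a TSV dialect (`id`, `lineage`, `location`, then
`<locus>_1`/`<locus>_2` columns) or GenePop 4.x with a metadata sidecar TSV
(GenePop has no metadata fields). The `analyze` command writes `report.json`
(machine-readable, byte-reproducible given input + config + seed),
`report.txt`, `tree.nwk` and the distance matrix in PHYLIP and TSV form.

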