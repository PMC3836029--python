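#!/usr/bin/env python
"""Generate the synthetic two-lineage study dataset.

Emulates the sampling design of the field study the pipeline targets: two
sampling sites (Nanporo, Kuriyama), 20 sexual + 20 asexual females per site,
nine microsatellite loci, strong lineage isolation (divergence 0.8 -> private
alleles expected at every locus), mild site substructure in the sexual
lineage only. Writes TSV + GenePop + metadata sidecar under
results/synthetic/ and prints the realized per-locus private-allele
proportions.
"""

import json
from pathlib import Path

from satlineage import SimulationConfig, run_simulation

OUT = Path("results/synthetic")
CONFIG = SimulationConfig(divergence=0.8, seed=1)


def main() -> None:
    summary = run_simulation(CONFIG, OUT)
    print(f"wrote {summary['n_individuals']} individuals to {OUT}/")
    print("realized private-allele proportion per locus:")
    for locus, prop in summary["private_allele_proportion"].items():
        print(f"  {locus}: {prop:.3f}")
    n_with_private = sum(
        1 for p in summary["private_allele_proportion"].values() if p and p > 0
    )
    print(f"loci with at least one lineage-private allele: {n_with_private}/9")
    (OUT / "01_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
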