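"""End-to-end analysis: genotypes in, differentiation report out.

Stage order is fixed: load -> validate -> allele counts -> per-locus exact
tests (+ Bonferroni) -> private alleles -> FST + permutation -> distance
matrix -> NJ tree -> monophyly verdicts -> report. Any stage failure aborts
with a stage-named error; partial outputs are flushed per stage so failures
are diagnosable.

All randomness flows from the single config seed through stage-keyed
substreams (deterministic CRC32 derivation), so identical (input, config,
seed) yields a byte-identical JSON report.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .distance import distance_matrix
from .genotypes import (
    GenotypeTable,
    ValidationError,
    allele_counts,
    read_genepop,
    read_tsv,
    write_genepop,
    write_tsv,
)
from .nj import is_monophyletic, neighbor_joining, to_newick
from .simulate import SimulationConfig, simulate_two_lineages
from .stats import (
    bonferroni,
    exact_test_rxc,
    fst_permutation_test,
    private_allele_proportions,
)

__all__ = ["AnalysisConfig", "StageError", "run_analysis", "run_simulation",
           "stage_seed"]


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (kept below 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce a run; echoed into the report."""

    input_path: str
    input_format: str = "tsv"            # "tsv" | "genepop"
    metadata_path: str | None = None     # sidecar for genepop inputs
    n_perm: int = 10_000
    exact_mode: str = "auto"             # "auto" | "exhaustive" | "montecarlo"
    n_mc: int = 100_000
    max_tables: int = 100_000
    bonferroni_m: int | None = None      # default: number of testable loci
    out_dir: str = "results"
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def _load(config: AnalysisConfig) -> GenotypeTable:
    if config.input_format == "tsv":
        return read_tsv(config.input_path)
    if config.input_format == "genepop":
        return read_genepop(config.input_path, metadata=config.metadata_path)
    raise ValidationError(f"unknown input format {config.input_format!r}")


def _check_inputs(table: GenotypeTable) -> None:
    lineages = [l for l in table.lineages() if l != "unknown"]
    if len(lineages) < 2:
        raise ValidationError(
            "fewer than 2 known lineage labels present; lineage assignment is "
            "a wet-lab step — supply it via the metadata sidecar TSV "
            "(columns: id, lineage, location)"
        )
    if len(table.individuals) < 3:
        raise ValidationError("analysis requires at least 3 individuals")


def _differentiation(table: GenotypeTable, config: AnalysisConfig,
                     warnings_log: list[str]) -> dict:
    """Per-locus exact tests and private alleles, lineage vs lineage,
    globally and per sampling location."""
    out: dict = {}
    scopes: dict[str, GenotypeTable] = {"global": table}
    for loc in table.locations():
        sub = table.subset(lambda ind, loc=loc: ind.location == loc)
        if len({i.lineage for i in sub.individuals}) >= 2:
            scopes[loc] = sub
    for scope, sub in scopes.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            freqs = allele_counts(sub, group_by="lineage")
        for w in caught:
            warnings_log.append(f"differentiation[{scope}]: {w.message}")
        groups = [g for g in freqs.groups if g != "unknown"]
        if len(groups) != 2:
            continue
        raw: dict[str, float | None] = {}
        testable = []
        for locus in freqs.loci:
            if (locus, groups[0]) in freqs.flagged or (locus, groups[1]) in freqs.flagged:
                raw[locus] = None
                warnings_log.append(
                    f"differentiation[{scope}]: locus {locus} untyped in a "
                    "group; test skipped"
                )
                continue
            _, mat = freqs.count_matrix(locus, groups)
            raw[locus] = exact_test_rxc(
                mat,
                mode=config.exact_mode,
                n_mc=config.n_mc,
                seed=stage_seed(config.seed, f"exact:{scope}:{locus}"),
                max_tables=config.max_tables,
            )
            testable.append(locus)
        m = config.bonferroni_m or len(testable)
        adj = dict(zip(testable, bonferroni([raw[l] for l in testable], m)))
        privates = private_allele_proportions(freqs, (groups[0], groups[1]))
        out[scope] = {
            "groups": groups,
            "n_individuals": {
                g: sum(1 for i in sub.individuals if i.lineage == g)
                for g in groups
            },
            "gene_copies": {
                locus: {g: freqs.gene_copies(locus, g) for g in groups}
                for locus in freqs.loci
            },
            "exact_p": raw,
            "bonferroni_m": m,
            "exact_p_adjusted": {l: adj.get(l) for l in freqs.loci},
            "private_alleles": privates,
        }
    return out


def _distance_summary(dm, table: GenotypeTable) -> dict:
    by_lineage: dict[str, list[int]] = {}
    for k, ind in enumerate(table.individuals):
        by_lineage.setdefault(ind.lineage, []).append(k)
    summary: dict = {
        "overall": {
            "min": float(dm.values[np.triu_indices(len(dm.ids), 1)].min()),
            "max": float(dm.values.max()),
            "mean": float(dm.values[np.triu_indices(len(dm.ids), 1)].mean()),
        },
        "within": {},
        "between": {},
    }
    lineages = sorted(by_lineage)
    for g in lineages:
        summary["within"][g] = dm.submatrix_mean(by_lineage[g], by_lineage[g])
    for i, g1 in enumerate(lineages):
        for g2 in lineages[i + 1:]:
            summary["between"][f"{g1}|{g2}"] = dm.submatrix_mean(
                by_lineage[g1], by_lineage[g2]
            )
    return summary


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    report.json, report.txt, tree.nwk, distances.phy and distances.tsv."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    report: dict = {
        "software": {"name": "satlineage", "version": __version__},
        "config": config.to_dict(),
    }

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 — rewrap with stage name
            raise StageError(name, exc) from exc

    table = stage("load", _load, config)
    stage("validate", _check_inputs, table)
    report["n_individuals"] = len(table.individuals)
    report["n_loci"] = len(table.loci)
    report["lineage_counts"] = {
        g: sum(1 for i in table.individuals if i.lineage == g)
        for g in table.lineages()
    }

    report["differentiation"] = stage(
        "differentiation", _differentiation, table, config, warnings_log
    )
    _flush(report, out_dir)

    def _fst():
        perm = fst_permutation_test(
            table, grouping="lineage", n_perm=config.n_perm,
            seed=stage_seed(config.seed, "fst_permutation"),
        )
        return {
            "theta": perm.theta_obs,
            "permutation_p": perm.p_value,
            "n_perm": perm.n_perm,
            "permutation_seed": perm.seed,
            "min_attainable_p": 1.0 / (perm.n_perm + 1),
        }

    report["fst"] = stage("fst", _fst)
    _flush(report, out_dir)

    dm = stage("distance_matrix", distance_matrix, table)
    report["distance_summary"] = stage(
        "distance_summary", _distance_summary, dm, table
    )
    dm.to_phylip(out_dir / "distances.phy")
    dm.to_tsv(out_dir / "distances.tsv")

    def _tree():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            tree = neighbor_joining(dm)
        for w in caught:
            warnings_log.append(f"nj_tree: {w.message}")
        return tree

    tree = stage("nj_tree", _tree)
    newick = to_newick(tree)
    (out_dir / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
    report["newick"] = newick

    def _monophyly():
        verdicts: dict[str, dict[str, bool | None]] = {}
        lineages = [l for l in table.lineages() if l != "unknown"]
        for g in lineages:
            ids = {i.id for i in table.individuals if i.lineage == g}
            verdicts[g] = {"global": is_monophyletic(tree, ids)}
            for loc in table.locations():
                ids_loc = {
                    i.id for i in table.individuals
                    if i.lineage == g and i.location == loc
                }
                verdicts[g][loc] = (
                    is_monophyletic(tree, ids_loc) if ids_loc else None
                )
        return verdicts

    report["monophyly"] = stage("monophyly", _monophyly)
    report["warnings"] = warnings_log
    _flush(report, out_dir)
    (out_dir / "report.txt").write_text(_text_summary(report), encoding="utf-8")
    return report


def _flush(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _text_summary(report: dict) -> str:
    lines = [
        f"satlineage {report['software']['version']} analysis report",
        f"individuals: {report['n_individuals']}  loci: {report['n_loci']}",
        f"lineages: {report['lineage_counts']}",
        "",
    ]
    diff = report.get("differentiation", {})
    for scope, d in diff.items():
        lines.append(f"[{scope}] exact tests ({' vs '.join(d['groups'])}, "
                     f"Bonferroni m={d['bonferroni_m']}):")
        for locus, p in d["exact_p"].items():
            adj = d["exact_p_adjusted"].get(locus)
            priv = d["private_alleles"][locus]
            prop = priv.get("proportion") if priv.get("defined") else None
            lines.append(
                f"  {locus}: p={_fmt(p)} adj={_fmt(adj)} "
                f"private_prop={_fmt(prop)}"
            )
        lines.append("")
    if "fst" in report:
        f = report["fst"]
        lines.append(
            f"FST (Weir-Cockerham theta) = {f['theta']:.5f}; "
            f"permutation p = {f['permutation_p']:.6g} "
            f"({f['n_perm']} permutations)"
        )
    if "monophyly" in report:
        for g, v in report["monophyly"].items():
            lines.append(f"monophyly[{g}]: {v}")
    if report.get("warnings"):
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in report["warnings"])
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    return "NA" if x is None else f"{x:.4g}"


def run_simulation(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic table and write TSV + GenePop + metadata sidecar.

    Returns a summary with file paths and per-locus realized private-allele
    proportions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = simulate_two_lineages(config)
    tsv = out_dir / "genotypes.tsv"
    gen = out_dir / "genotypes.gen"
    meta = out_dir / "genotypes.meta.tsv"
    write_tsv(table, tsv)
    write_genepop(table, gen, metadata_path=meta)
    freqs = allele_counts(table, group_by="lineage")
    privates = private_allele_proportions(freqs, ("sexual", "asexual"))
    summary = {
        "config": {**asdict(config), "sites": list(config.sites)},
        "files": {"tsv": str(tsv), "genepop": str(gen), "metadata": str(meta)},
        "n_individuals": len(table.individuals),
        "private_allele_proportion": {
            loc: (p["proportion"] if p["defined"] else None)
            for loc, p in privates.items()
        },
    }
    (out_dir / "simulation.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
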