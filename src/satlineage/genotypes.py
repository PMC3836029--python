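"""Diploid codominant genotype tables with lineage/location metadata.

The universal input of the pipeline is a :class:`GenotypeTable`: an ordered set
of microsatellite loci and an ordered set of individuals, each carrying an
unordered diploid allele pair (or a missing marker) per locus, plus two
metadata labels — the reproductive lineage (``sexual`` / ``asexual`` /
``unknown``, assigned upstream by a wet-lab assay and entering here as plain
metadata) and the sampling location.

Two text formats are supported: GenePop 4.x (the field's interchange format;
2- or 3-digit diploid encoding, ``POP`` separators, ``00``/``000`` = missing)
and a simple TSV dialect with explicit metadata columns. GenePop has no
metadata fields, so lineage/location travel in a sidecar TSV keyed by
individual id.

Allele codes are opaque positive integers (fragment lengths in bp or arbitrary
codes); no binning or size correction is applied. Missing data is per-locus:
a half-called diploid genotype is rejected as ambiguous.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LINEAGES",
    "LocusDef",
    "Individual",
    "GenotypeTable",
    "AlleleFrequencyTable",
    "ParseError",
    "ValidationError",
    "EncodingError",
    "read_genepop",
    "read_tsv",
    "write_genepop",
    "write_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "allele_counts",
]

LINEAGES = ("sexual", "asexual", "unknown")

Genotype = tuple[int, int]  # stored sorted ascending; None = missing at locus


class ValidationError(ValueError):
    """A table or row violates the data-model invariants."""


class ParseError(ValueError):
    """A file cannot be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EncodingError(ValueError):
    """An allele code does not fit the chosen GenePop digit width."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: a name and an optional allowed allele set."""

    name: str
    allele_universe: frozenset[int] | None = None

    def __post_init__(self):
        if not self.name:
            raise ValidationError("locus name must be nonempty")
        if self.allele_universe is not None:
            universe = frozenset(int(a) for a in self.allele_universe)
            if any(a <= 0 for a in universe):
                raise ValidationError(
                    f"locus {self.name!r}: allele codes must be positive integers"
                )
            object.__setattr__(self, "allele_universe", universe)


def _normalize_genotype(g) -> Genotype | None:
    if g is None:
        return None
    a, b = g
    a, b = int(a), int(b)
    if a <= 0 or b <= 0:
        raise ValidationError(f"allele codes must be positive integers, got {g!r}")
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    """One genotyped female: id, lineage/location labels, per-locus genotypes.

    ``genotypes`` maps locus name -> unordered allele pair (stored sorted) or
    None for missing-at-locus.
    """

    id: str
    lineage: str = "unknown"
    location: str = ""
    genotypes: dict[str, Genotype | None] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise ValidationError("individual id must be nonempty")
        if self.lineage not in LINEAGES:
            raise ValidationError(
                f"individual {self.id!r}: unknown lineage {self.lineage!r}; "
                f"accepted tokens: {', '.join(LINEAGES)}"
            )
        self.genotypes = {
            loc: _normalize_genotype(g) for loc, g in self.genotypes.items()
        }


@dataclass
class GenotypeTable:
    """Ordered loci x ordered individuals, validated on construction."""

    loci: list[LocusDef]
    individuals: list[Individual]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValidationError("locus names must be unique")
        ids = [ind.id for ind in self.individuals]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValidationError(f"duplicate individual ids: {sorted(dup)}")
        universe = {l.name: l.allele_universe for l in self.loci}
        for ind in self.individuals:
            extra = set(ind.genotypes) - set(names)
            if extra:
                raise ValidationError(
                    f"individual {ind.id!r}: genotypes at undeclared loci {sorted(extra)}"
                )
            for name in names:
                g = ind.genotypes.get(name)
                ind.genotypes.setdefault(name, None)
                if g is None:
                    continue
                u = universe[name]
                if u is not None and not set(g) <= u:
                    raise ValidationError(
                        f"individual {ind.id!r}, locus {name!r}: alleles {g} "
                        f"outside declared allele universe"
                    )
            # keep genotype dict in locus order for stable serialization
            ind.genotypes = {name: ind.genotypes[name] for name in names}

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def lineages(self) -> list[str]:
        return sorted({ind.lineage for ind in self.individuals})

    def locations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.location)
        return list(seen)

    def subset(self, predicate) -> "GenotypeTable":
        return GenotypeTable(
            loci=list(self.loci),
            individuals=[ind for ind in self.individuals if predicate(ind)],
        )

    def group_labels(self, group_by: str) -> list[str]:
        """Per-individual group label for ``lineage``, ``location`` or both."""
        if group_by == "lineage":
            return [ind.lineage for ind in self.individuals]
        if group_by == "location":
            return [ind.location for ind in self.individuals]
        if group_by == "lineage+location":
            return [f"{ind.lineage}@{ind.location}" for ind in self.individuals]
        raise ValidationError(f"unknown grouping key {group_by!r}")


# ---------------------------------------------------------------------------
# Allele frequency table
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per (locus, group) allele counts over gene copies.

    ``counts[locus][group]`` maps allele code -> count of gene copies
    (2 per typed diploid individual); ``typed[locus][group]`` is the number of
    typed individuals. Groups with zero typed individuals at a locus are
    listed in ``flagged`` and skipped by downstream tests.
    """

    loci: list[str]
    groups: list[str]
    counts: dict[str, dict[str, dict[int, int]]]
    typed: dict[str, dict[str, int]]
    flagged: set[tuple[str, str]] = field(default_factory=set)

    def frequencies(self, locus: str, group: str) -> dict[int, float]:
        c = self.counts[locus][group]
        total = sum(c.values())
        if total == 0:
            return {}
        return {a: n / total for a, n in c.items()}

    def gene_copies(self, locus: str, group: str) -> int:
        return sum(self.counts[locus][group].values())

    def observed_alleles(self, locus: str, group: str | None = None) -> set[int]:
        if group is not None:
            return {a for a, n in self.counts[locus][group].items() if n > 0}
        out: set[int] = set()
        for g in self.groups:
            out |= self.observed_alleles(locus, g)
        return out

    def count_matrix(self, locus: str, groups: Sequence[str] | None = None):
        """Alleles x groups integer count table (sorted allele order)."""
        import numpy as np

        groups = list(groups) if groups is not None else self.groups
        alleles = sorted(
            set().union(*(self.counts[locus][g] for g in groups))
        )
        mat = np.array(
            [[self.counts[locus][g].get(a, 0) for g in groups] for a in alleles],
            dtype=int,
        )
        return alleles, mat


def allele_counts(
    table: GenotypeTable,
    group_by: str | Sequence[str] = "lineage",
) -> AlleleFrequencyTable:
    """Count gene copies per locus x group.

    ``group_by`` is a metadata key (``lineage``, ``location``,
    ``lineage+location``) or an explicit per-individual label sequence.
    Each typed diploid individual contributes two gene copies.
    """
    if isinstance(group_by, str):
        labels = table.group_labels(group_by)
    else:
        labels = list(group_by)
        if len(labels) != len(table.individuals):
            raise ValidationError(
                "explicit partition length does not match number of individuals"
            )
    groups: list[str] = []
    for lab in labels:
        if lab not in groups:
            groups.append(lab)
    loci = table.locus_names
    counts: dict[str, dict[str, dict[int, int]]] = {
        loc: {g: {} for g in groups} for loc in loci
    }
    typed: dict[str, dict[str, int]] = {loc: {g: 0 for g in groups} for loc in loci}
    for ind, lab in zip(table.individuals, labels):
        for loc in loci:
            g = ind.genotypes[loc]
            if g is None:
                continue
            typed[loc][lab] += 1
            bucket = counts[loc][lab]
            for a in g:
                bucket[a] = bucket.get(a, 0) + 1
    flagged = {
        (loc, grp) for loc in loci for grp in groups if typed[loc][grp] == 0
    }
    for loc, grp in sorted(flagged):
        warnings.warn(
            f"locus {loc!r}, group {grp!r}: no typed individuals; "
            "downstream tests will skip this cell",
            stacklevel=2,
        )
    return AlleleFrequencyTable(
        loci=loci, groups=groups, counts=counts, typed=typed, flagged=flagged
    )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "na", "NaN"}


def read_tsv(path: str | Path) -> GenotypeTable:
    """Read the TSV dialect: id, lineage, location, then <locus>_1, <locus>_2.

    UTF-8; comment lines start with ``#``; empty cell or ``NA`` = missing
    allele, and both alleles of a locus must be missing together.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        rows = [
            (i + 1, line.rstrip("\n").split("\t"))
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not rows:
        raise ParseError("empty file", line=1)
    header_line, header = rows[0]
    if header[:3] != ["id", "lineage", "location"]:
        raise ParseError(
            "header must start with: id, lineage, location", line=header_line
        )
    allele_cols = header[3:]
    if len(allele_cols) % 2 != 0:
        raise ParseError("odd number of allele columns", line=header_line)
    loci: list[str] = []
    for k in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[k], allele_cols[k + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise ParseError(
                f"allele columns must come in <locus>_1/<locus>_2 pairs, "
                f"got {c1!r}, {c2!r}",
                line=header_line,
            )
        loci.append(c1[:-2])

    individuals = []
    for lineno, row in rows[1:]:
        if len(row) != len(header):
            raise ParseError(
                f"expected {len(header)} columns, got {len(row)}", line=lineno
            )
        ind_id, lineage, location = (c.strip() for c in row[:3])
        genotypes: dict[str, Genotype | None] = {}
        for k, locus in enumerate(loci):
            a_raw = row[3 + 2 * k].strip()
            b_raw = row[4 + 2 * k].strip()
            a_missing = a_raw in _MISSING_TOKENS
            b_missing = b_raw in _MISSING_TOKENS
            if a_missing != b_missing:
                raise ValidationError(
                    f"line {lineno}: individual {ind_id!r}, locus {locus!r}: "
                    "exactly one allele cell missing (half-called genotypes "
                    "are rejected as ambiguous)"
                )
            if a_missing:
                genotypes[locus] = None
                continue
            try:
                genotypes[locus] = (int(a_raw), int(b_raw))
            except ValueError:
                raise ParseError(
                    f"non-integer allele code at locus {locus!r}", line=lineno
                ) from None
        individuals.append(
            Individual(id=ind_id, lineage=lineage, location=location,
                       genotypes=genotypes)
        )
    return GenotypeTable(loci=[LocusDef(n) for n in loci], individuals=individuals)


def write_tsv(table: GenotypeTable, path: str | Path) -> None:
    path = Path(path)
    loci = table.locus_names
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["id", "lineage", "location"]
        for loc in loci:
            header += [f"{loc}_1", f"{loc}_2"]
        w.writerow(header)
        for ind in table.individuals:
            row = [ind.id, ind.lineage, ind.location]
            for loc in loci:
                g = ind.genotypes[loc]
                row += ["NA", "NA"] if g is None else [str(g[0]), str(g[1])]
            w.writerow(row)


# ---------------------------------------------------------------------------
# Metadata sidecar (id -> lineage, location), used alongside GenePop files
# ---------------------------------------------------------------------------


def read_metadata_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Sidecar dialect: header ``id\\tlineage\\tlocation``; ``#`` comments."""
    path = Path(path)
    meta: dict[str, tuple[str, str]] = {}
    with path.open(encoding="utf-8") as fh:
        rows = [
            (i + 1, line.rstrip("\n").split("\t"))
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not rows or [c.strip() for c in rows[0][1][:3]] != ["id", "lineage", "location"]:
        raise ParseError("metadata sidecar header must be: id, lineage, location",
                         line=1)
    for lineno, row in rows[1:]:
        if len(row) < 3:
            raise ParseError("expected 3 columns", line=lineno)
        ind_id, lineage, location = (c.strip() for c in row[:3])
        if lineage not in LINEAGES:
            raise ValidationError(
                f"line {lineno}: unknown lineage {lineage!r}; "
                f"accepted tokens: {', '.join(LINEAGES)}"
            )
        if ind_id in meta:
            raise ValidationError(f"line {lineno}: duplicate id {ind_id!r}")
        meta[ind_id] = (lineage, location)
    return meta


def write_metadata_tsv(table: GenotypeTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("id\tlineage\tlocation\n")
        for ind in table.individuals:
            fh.write(f"{ind.id}\t{ind.lineage}\t{ind.location}\n")


# ---------------------------------------------------------------------------
# GenePop 4.x
# ---------------------------------------------------------------------------


def _decode_genepop_token(token: str, lineno: int) -> Genotype | None:
    if len(token) == 4:
        width = 2
    elif len(token) == 6:
        width = 3
    else:
        raise ParseError(
            f"allele token {token!r} is not a 4- or 6-digit diploid encoding",
            line=lineno,
        )
    if not token.isdigit():
        raise ParseError(f"non-numeric allele token {token!r}", line=lineno)
    a, b = int(token[:width]), int(token[width:])
    if a == 0 and b == 0:
        return None
    if a == 0 or b == 0:
        raise ParseError(
            f"half-missing genotype {token!r} (one allele coded 0)", line=lineno
        )
    return (a, b)


def read_genepop(
    path: str | Path,
    metadata: str | Path | Mapping[str, tuple[str, str]] | None = None,
) -> GenotypeTable:
    """Read a GenePop 4.x file.

    POP blocks become location labels ``pop1``, ``pop2``, ... and lineage is
    ``unknown``, unless a metadata sidecar (path or mapping id -> (lineage,
    location)) supplies labels.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty file", line=1)

    meta: Mapping[str, tuple[str, str]] | None
    if metadata is None or isinstance(metadata, Mapping):
        meta = metadata
    else:
        meta = read_metadata_tsv(metadata)

    locus_names: list[str] = []
    individuals: list[Individual] = []
    pop_index = 0
    in_pops = False
    for lineno, raw in enumerate(lines[1:], start=2):  # line 1 is the title
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            in_pops = True
            pop_index += 1
            continue
        if not in_pops:
            # locus declaration: one per line, or several comma-separated
            locus_names.extend(
                name.strip() for name in line.split(",") if name.strip()
            )
            continue
        if "," not in line:
            raise ParseError(
                "individual line must contain a comma after the id", line=lineno
            )
        ind_id, _, geno_part = line.partition(",")
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"individual {ind_id!r} has {len(tokens)} genotypes but the "
                f"header declares {len(locus_names)} loci",
                line=lineno,
            )
        genotypes = {
            loc: _decode_genepop_token(tok, lineno)
            for loc, tok in zip(locus_names, tokens)
        }
        lineage, location = "unknown", f"pop{pop_index}"
        if meta is not None and ind_id in meta:
            lineage, location = meta[ind_id]
        individuals.append(
            Individual(id=ind_id, lineage=lineage, location=location,
                       genotypes=genotypes)
        )
    if not locus_names:
        raise ParseError("no locus names declared before first POP", line=2)
    if pop_index == 0:
        raise ParseError("no POP block found", line=len(lines))
    return GenotypeTable(
        loci=[LocusDef(n) for n in locus_names], individuals=individuals
    )


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    digits: int = 3,
    title: str = "satlineage export",
    metadata_path: str | Path | None = None,
) -> None:
    """Write GenePop with one POP block per location (order of appearance).

    ``digits`` is the per-allele width (2 or 3); codes that do not fit raise
    :class:`EncodingError`. Lineage/location metadata optionally goes to a
    sidecar TSV (GenePop itself has no metadata fields).
    """
    if digits not in (2, 3):
        raise EncodingError("digit width must be 2 or 3")
    limit = 10**digits - 1
    path = Path(path)

    def encode(g: Genotype | None) -> str:
        if g is None:
            return "0" * (2 * digits)
        if g[0] > limit or g[1] > limit:
            raise EncodingError(
                f"allele code {max(g)} exceeds the {digits}-digit GenePop encoding"
            )
        return f"{g[0]:0{digits}d}{g[1]:0{digits}d}"

    blocks: dict[str, list[Individual]] = {}
    for ind in table.individuals:
        blocks.setdefault(ind.location, []).append(ind)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(title + "\n")
        for loc in table.locus_names:
            fh.write(loc + "\n")
        for inds in blocks.values():
            fh.write("POP\n")
            for ind in inds:
                codes = " ".join(encode(ind.genotypes[l]) for l in table.locus_names)
                fh.write(f"{ind.id} , {codes}\n")
    if metadata_path is not None:
        write_metadata_tsv(table, metadata_path)
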