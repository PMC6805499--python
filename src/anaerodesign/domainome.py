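"""Comparative core-domainome analysis.

Each genome is reduced to its set of InterPro domain accessions (presence is
genome-level boolean: at least one gene carries the domain; copy number is
ignored).  The core domainome of a group is the intersection over its
members; the group-exclusive core additionally subtracts the union of a
background group.  Comparing a facultative-anaerobe panel against an
obligate-aerobe panel yields the shortlist of anaerobe-only domains, which
are then binned into three functional categories: ATP generation, unknown
function, and other.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .model_core import ConfigurationError

log = logging.getLogger("anaerodesign")

ACCESSION_PATTERN = re.compile(r"^[A-Za-z]+\d+$")
CATEGORIES = ("atp_generation", "unknown_function", "other")

#: functional assignments for the accessions with known roles in the
#: anaerobe-exclusive shortlist: acetate kinase and the two
#: ribonucleotide-triphosphate-reductase domains drive ATP generation /
#: anaerobic dNTP supply; siderophore-transport, pilus-assembly and
#: iron-sulfur-cluster domains fall under "other".  Everything unmapped
#: defaults to unknown_function; users extend this with their own table.
DEFAULT_CATEGORY_MAP: Dict[str, str] = {
    "IPR000890": "atp_generation",
    "IPR012833": "atp_generation",
    "IPR012840": "atp_generation",
    "IPR003538": "other",
    "IPR008707": "other",
    "IPR013362": "other",
    "IPR013374": "other",
    "IPR025746": "other",
    "IPR007202": "other",
    "IPR018298": "other",
}

#: the genome panels compared in the source analysis (config mirrors these)
DEFAULT_GROUPS: Dict[str, Tuple[str, ...]] = {
    "anaerobe": ("PAO1", "M18", "DSM10701", "A1501", "ATCC13867", "F113"),
    "aerobe": ("KT2440", "F1", "S16", "W619", "GB1", "BIRD1"),
}


class AnnotationFormatError(ConfigurationError):
    """A malformed annotation row in strict mode."""


@dataclass
class GenomeDomainSet:
    genome_id: str
    group: str  # anaerobe | aerobe
    domains: Set[str] = field(default_factory=set)
    gene_count: int = 0

    def __post_init__(self) -> None:
        if self.group not in {"anaerobe", "aerobe"}:
            raise ConfigurationError(
                f"genome {self.genome_id!r}: group must be anaerobe or aerobe, got {self.group!r}"
            )
        bad = [d for d in self.domains if not ACCESSION_PATTERN.match(d)]
        if bad:
            raise ConfigurationError(f"genome {self.genome_id!r}: malformed accessions {bad[:5]}")


@dataclass
class CategoryCounts:
    counts: Dict[str, int]
    total: int
    assignments: Dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"accession": a, "category": c} for a, c in sorted(self.assignments.items())],
            columns=["accession", "category"],
        )


# -- annotation readers ------------------------------------------------------


def load_domain_annotations(
    path,
    dialect: str = "interproscan_tsv",
    genome_id: Optional[str] = None,
    group: str = "aerobe",
    strict: bool = False,
) -> GenomeDomainSet:
    """Read one genome's domain annotations.

    ``interproscan_tsv``: the standard 11-15 column output; the InterPro
    accession sits in column 12 and rows with an empty or "-" accession
    (signature hits without an InterPro mapping) are skipped and counted.
    ``simple_tsv``: three columns genome_id, gene_id, domain_id (an optional
    header line is recognised and skipped).
    """
    path = Path(path)
    if dialect not in {"interproscan_tsv", "simple_tsv"}:
        raise ConfigurationError(f"unknown annotation dialect {dialect!r}")
    domains: Set[str] = set()
    genes: Set[str] = set()
    skipped = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if dialect == "interproscan_tsv":
            if len(fields) < 11:
                if strict:
                    raise AnnotationFormatError(
                        f"{path}:{lineno}: expected >=11 tab-separated columns, got {len(fields)}"
                    )
                skipped += 1
                continue
            genes.add(fields[0])
            accession = fields[11].strip() if len(fields) > 11 else ""
            if not accession or accession == "-":
                skipped += 1
                continue
            domains.add(accession)
        else:  # simple_tsv
            if lineno == 1 and fields[0] == "genome_id":
                continue
            if len(fields) != 3:
                if strict:
                    raise AnnotationFormatError(
                        f"{path}:{lineno}: expected 3 columns (genome_id, gene_id, domain_id)"
                    )
                skipped += 1
                continue
            genes.add(fields[1])
            domains.add(fields[2].strip())
            if genome_id is None:
                genome_id = fields[0]
    if skipped:
        log.info("%s: skipped %d rows without a usable accession", path, skipped)
    return GenomeDomainSet(
        genome_id=genome_id or path.stem,
        group=group,
        domains=domains,
        gene_count=len(genes),
    )


# -- set algebra -------------------------------------------------------------


def core_domains(group: Sequence[GenomeDomainSet]) -> Set[str]:
    """Domains present in every genome of the group (intersection)."""
    if not group:
        raise ConfigurationError("core_domains: empty genome group")
    core = set(group[0].domains)
    for genome in group[1:]:
        core &= genome.domains
    return core


def exclusive_core(
    target: Sequence[GenomeDomainSet], background: Sequence[GenomeDomainSet]
) -> Set[str]:
    """Core of the target group minus the union of all background genomes.

    Postconditions (asserted): the result is contained in the target core
    and disjoint from every background genome.
    """
    if not background:
        raise ConfigurationError("exclusive_core: empty background group")
    core = core_domains(target)
    background_union: Set[str] = set()
    for genome in background:
        background_union |= genome.domains
    result = core - background_union
    assert result <= core
    assert all(not (result & g.domains) for g in background)
    return result


def categorize_domains(
    domains: Iterable[str], category_map: Optional[Mapping[str, str]] = None
) -> CategoryCounts:
    """Bin a shortlist into the three functional categories.

    Accessions missing from the map default to ``unknown_function`` (logged).
    A map naming a category outside the allowed three raises.
    """
    category_map = DEFAULT_CATEGORY_MAP if category_map is None else dict(category_map)
    bad = {c for c in category_map.values() if c not in CATEGORIES}
    if bad:
        raise ConfigurationError(f"categories outside {CATEGORIES}: {sorted(bad)}")
    assignments: Dict[str, str] = {}
    unmapped = 0
    for accession in sorted(set(domains)):
        category = category_map.get(accession)
        if category is None:
            category = "unknown_function"
            unmapped += 1
        assignments[accession] = category
    if unmapped:
        log.info("categorize_domains: %d accessions defaulted to unknown_function", unmapped)
    counts = {c: 0 for c in CATEGORIES}
    for category in assignments.values():
        counts[category] += 1
    return CategoryCounts(counts=counts, total=len(assignments), assignments=assignments)


# -- matrix / report writers -------------------------------------------------


def presence_absence_matrix(genomes: Sequence[GenomeDomainSet]) -> pd.DataFrame:
    """Genomes x domains boolean matrix (0/1), sorted both ways."""
    all_domains = sorted(set().union(*(g.domains for g in genomes))) if genomes else []
    data = {
        g.genome_id: [int(d in g.domains) for d in all_domains]
        for g in sorted(genomes, key=lambda g: g.genome_id)
    }
    return pd.DataFrame(data, index=all_domains).T


def write_presence_absence(genomes: Sequence[GenomeDomainSet], path) -> None:
    presence_absence_matrix(genomes).to_csv(path, sep="\t", index_label="genome_id")


def shortlist_report(
    shortlist: Iterable[str],
    genomes: Sequence[GenomeDomainSet],
    categories: CategoryCounts,
) -> pd.DataFrame:
    """Per-accession report: category plus per-genome presence flags."""
    genome_order = sorted(genomes, key=lambda g: g.genome_id)
    rows = []
    for accession in sorted(set(shortlist)):
        row = {"accession": accession, "category": categories.assignments.get(accession, "unknown_function")}
        for g in genome_order:
            row[g.genome_id] = int(accession in g.domains)
        rows.append(row)
    columns = ["accession", "category"] + [g.genome_id for g in genome_order]
    return pd.DataFrame(rows, columns=columns)
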