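"""Pipeline configuration, stage orchestration and the consolidated report.

The pipeline runs the two in-silico arms — GSM-based O2 essentiality
scanning plus design-grid evaluation, and comparative core-domainome
subtraction — and then combines them: each essential O2-dependent
bottleneck is paired with the intervention set(s) that bypass it, and the
energy-generation designs are cross-referenced with the shortlist domains
categorized as ATP generation.  Outputs are plain TSV/JSON files plus a run
log; re-running with the same config and seed reproduces every report
byte-identically (the log carries the only timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .model_core import (
    GROWTH_EPSILON,
    ConfigurationError,
    MediumSpec,
    MetabolicModel,
    PRESET_NAMES,
    apply_medium,
    load_model,
    preset_medium,
)
from .fba_engine import fba, growth_predicts
from .o2_essentiality import ScanRecord, essential_ids, o2_essentiality_scan, records_to_frame
from .interventions import (
    DesignGrid,
    InterventionSet,
    builtin_designs,
    evaluate_designs,
    load_design_library,
)
from .domainome import (
    CategoryCounts,
    DEFAULT_CATEGORY_MAP,
    GenomeDomainSet,
    categorize_domains,
    exclusive_core,
    load_domain_annotations,
    shortlist_report,
)

log = logging.getLogger("anaerodesign")

STAGES = ("load", "media_sweep", "scan", "designs", "domainome", "combine")

#: keyword themes used to pair an essential O2 bottleneck with the design
#: set(s) whose reactions bypass it
BOTTLENECK_THEMES: Dict[str, Tuple[str, ...]] = {
    "heme": ("heme", "protoporphyrinogen", "hemg", "hemy", "hemj", "pppgo"),
    "nad_precursor": ("aspartate", "nadb", "aspo", "nad_synth", "nad-precursor", "iminoaspartate"),
    "pyrimidine": ("orotate", "dihydroorotate", "dhodh", "oro_synth", "pyrd"),
    "dntp": ("ribonucleotide", "rnr", "dntp", "nrd", "rntr"),
}
ENERGY_KEYWORDS = ("acetate kinase", "nitrate", "nitrite", "electrode", "fermentative", "substrate-level")


@dataclass
class GenomeEntry:
    genome_id: str
    path: str
    group: str


@dataclass
class PipelineConfig:
    model_path: str
    output_dir: str
    model_format: Optional[str] = None
    objective_override: Optional[str] = None
    media: Dict[str, dict] = field(default_factory=dict)  # custom medium definitions
    base_medium: str = "minimal_glucose"
    scan_enabled: bool = True
    scan_overlay: str = "oxic"
    epsilon: float = GROWTH_EPSILON
    include_exchange: bool = False
    include_transport: bool = False
    designs_enabled: bool = True
    design_library: str = "builtin"
    combos: List[List[str]] = field(default_factory=list)
    conditions: List[List[str]] = field(default_factory=list)
    reference_condition: Optional[List[str]] = None
    domainome_enabled: bool = False
    genomes: List[GenomeEntry] = field(default_factory=list)
    annotation_dialect: str = "simple_tsv"
    category_map_path: Optional[str] = None
    seed: int = 1
    strict: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genomes = [GenomeEntry(**g) for g in raw.pop("genomes", [])]
        cfg = cls(**{**raw, "genomes": genomes})
        return cfg.validate(base=Path(path).parent)

    def validate(self, base: Optional[Path] = None) -> "PipelineConfig":
        base = base or Path(".")

        def resolve(p: Optional[str]) -> Optional[str]:
            if p is None:
                return None
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        self.model_path = resolve(self.model_path)
        self.output_dir = resolve(self.output_dir)
        self.category_map_path = resolve(self.category_map_path)
        if self.design_library != "builtin":
            self.design_library = resolve(self.design_library)
            if not Path(self.design_library).exists():
                raise ConfigurationError(f"design library not found: {self.design_library}")
        for g in self.genomes:
            g.path = resolve(g.path)
            if not Path(g.path).exists():
                raise ConfigurationError(f"annotation table not found: {g.path}")
        if not Path(self.model_path).exists():
            raise ConfigurationError(f"model file not found: {self.model_path}")
        if self.domainome_enabled and not self.genomes:
            raise ConfigurationError("domainome stage enabled but no genomes configured")
        return self


# -- medium resolution -------------------------------------------------------


def _resolve_medium(name: str, model: MetabolicModel, custom: Mapping[str, dict]) -> MediumSpec:
    if name in custom:
        spec = custom[name]
        return MediumSpec(
            name=name,
            uptake_limits={k: float(v) for k, v in spec.get("uptake_limits", {}).items()},
            default_uptake=spec.get("default_uptake", 0.0),
        )
    if name in PRESET_NAMES:
        return preset_medium(name, model)
    raise ConfigurationError(f"unknown medium {name!r} (not a custom medium or preset)")


def _condition_medium(names: Sequence[str], model: MetabolicModel, custom: Mapping[str, dict]) -> MediumSpec:
    """Merge a base medium with overlays into one concrete MediumSpec."""
    merged: Dict[str, float] = {}
    default: Optional[float] = None
    for name in names:
        medium = _resolve_medium(name, model, custom)
        merged.update(medium.uptake_limits)
        if medium.default_uptake is not None:
            default = medium.default_uptake
    return MediumSpec(name="+".join(names), uptake_limits=merged, default_uptake=default)


# -- the combine step --------------------------------------------------------


def _theme_of(text: str) -> Optional[str]:
    lowered = text.lower()
    for theme, keywords in BOTTLENECK_THEMES.items():
        if any(k in lowered for k in keywords):
            return theme
    return None


def consolidate(
    scan_records: Sequence[ScanRecord],
    library: Mapping[str, InterventionSet],
    categories: Optional[CategoryCounts],
    grid: Optional[DesignGrid],
) -> dict:
    """Cross-reference scan essentials, bypass designs and domain evidence."""
    bottlenecks = []
    for record in scan_records:
        if not record.essential:
            continue
        theme = _theme_of(f"{record.reaction_id} {record.reaction_name}")
        proposals = []
        for iset in library.values():
            matches = [
                r.id
                for r in iset.reactions
                if _theme_of(f"{r.id} {r.name}") == theme and theme is not None
            ]
            if matches:
                proposals.append(
                    {
                        "design": iset.name,
                        "reactions": matches,
                        "note": "endogenous alternative possible"
                        if "endogenous" in iset.provenance.lower()
                        else "",
                    }
                )
        bottlenecks.append(
            {
                "reaction_id": record.reaction_id,
                "name": record.reaction_name,
                "theme": theme or "unmatched",
                "proposed_designs": proposals,
            }
        )

    energy_designs = [
        iset.name
        for iset in library.values()
        if any(k in (iset.provenance + " " + iset.name).lower() for k in ENERGY_KEYWORDS)
    ]
    atp_domains = (
        sorted(a for a, c in categories.assignments.items() if c == "atp_generation")
        if categories is not None
        else []
    )
    payload = {
        "bottlenecks": bottlenecks,
        "energy": {
            "proposed_designs": sorted(energy_designs),
            "shortlist_atp_generation_domains": atp_domains,
        },
    }
    if grid is not None:
        payload["growth_outcomes"] = [
            {
                "design": row,
                "condition": col,
                "mu": grid.cells[(row, col)].mu,
                "growth_class": grid.cells[(row, col)].growth_class,
            }
            for row in grid.rows
            for col in grid.columns
        ]
    return payload


# -- orchestration -----------------------------------------------------------


@dataclass
class PipelineResult:
    output_dir: Path
    completed_stages: List[str]
    scan_records: List[ScanRecord] = field(default_factory=list)
    grid: Optional[DesignGrid] = None
    shortlist: Optional[set] = None
    categories: Optional[CategoryCounts] = None
    consolidated: Optional[dict] = None


def _load_category_map(path: Optional[str]) -> Optional[Dict[str, str]]:
    if path is None:
        return None
    frame = pd.read_csv(path, sep="\t")
    merged = dict(DEFAULT_CATEGORY_MAP)
    merged.update(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
    return merged


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the enabled stages in order, writing reports as it goes.

    A stage failure aborts with a stage-named error; partial outputs are
    retained and MANIFEST lists the stages that completed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    completed: List[str] = []
    result = PipelineResult(output_dir=out, completed_stages=completed)

    def manifest() -> None:
        (out / "MANIFEST").write_text("\n".join(completed) + "\n")

    import scipy

    log.info("anaerodesign %s (scipy %s, LP backend: HiGHS)", __version__, scipy.__version__)
    log.info("effective config: %s", json.dumps(dataclasses.asdict(config), default=str, sort_keys=True))

    try:
        stage = "load"
        model = load_model(
            config.model_path,
            format=config.model_format,
            objective_override=config.objective_override,
        )
        completed.append(stage)

        stage = "media_sweep"
        base = _resolve_medium(config.base_medium, model, config.media)
        overlays = [
            _resolve_medium(n, model, config.media)
            for n in ("oxic", "anoxic")
            if n in config.media or n in PRESET_NAMES
        ]
        sweep = growth_predicts(model, base, overlays)
        sweep.to_csv(out / "media_sweep.tsv", sep="\t", index=False)
        completed.append(stage)

        library: Mapping[str, InterventionSet] = {}
        if config.designs_enabled or config.scan_enabled:
            library = (
                builtin_designs()
                if config.design_library == "builtin"
                else load_design_library(config.design_library)
            )

        if config.scan_enabled:
            stage = "scan"
            scan_medium = _condition_medium(
                [config.base_medium, config.scan_overlay], model, config.media
            )
            result.scan_records = o2_essentiality_scan(
                model,
                scan_medium,
                epsilon=config.epsilon,
                include_exchange=config.include_exchange,
                include_transport=config.include_transport,
            )
            records_to_frame(result.scan_records).to_csv(out / "scan.tsv", sep="\t", index=False)
            completed.append(stage)

        if config.designs_enabled:
            stage = "designs"
            conditions = [
                _condition_medium(names, model, config.media) for names in config.conditions
            ]
            reference = (
                _condition_medium(config.reference_condition, model, config.media)
                if config.reference_condition
                else None
            )
            result.grid = evaluate_designs(
                model,
                config.combos,
                conditions,
                library=library,
                reference_medium=reference,
                epsilon=config.epsilon,
            )
            result.grid.to_tsv(out / "design_grid.tsv")
            completed.append(stage)

        if config.domainome_enabled:
            stage = "domainome"
            genomes = [
                load_domain_annotations(
                    g.path,
                    dialect=config.annotation_dialect,
                    genome_id=g.genome_id,
                    group=g.group,
                    strict=config.strict,
                )
                for g in config.genomes
            ]
            target = [g for g in genomes if g.group == "anaerobe"]
            background = [g for g in genomes if g.group == "aerobe"]
            result.shortlist = exclusive_core(target, background)
            result.categories = categorize_domains(
                result.shortlist, _load_category_map(config.category_map_path)
            )
            shortlist_report(result.shortlist, genomes, result.categories).to_csv(
                out / "shortlist.tsv", sep="\t", index=False
            )
            completed.append(stage)

        stage = "combine"
        result.consolidated = consolidate(
            result.scan_records, library, result.categories, result.grid
        )
        (out / "consolidated_design.json").write_text(
            json.dumps(result.consolidated, indent=1, sort_keys=True) + "\n"
        )
        completed.append(stage)
    except Exception as exc:
        manifest()
        log.removeHandler(handler)
        handler.close()
        raise ConfigurationError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest()
    log.removeHandler(handler)
    handler.close()
    return result
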