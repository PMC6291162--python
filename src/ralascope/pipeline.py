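"""End-to-end orchestration: cohort -> region -> statistics -> report.

The pipeline executes whichever stages have inputs configured, skipping
absent ones with a logged reason, and emits a single JSON-serializable
report. Every statistic carries its inputs and conventions (tail
definitions, test sidedness) so a report is interpretable standalone.
Reruns on identical inputs and seed produce identical reports apart from
the timestamp field.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .assay_norm import compare_groups, normalize_glisa, normalize_gtpase, read_assay_csv
from .burden_stats import enrichment_test, observed_denovo_count
from .cohort_io import (
    CohortTable,
    GeneModel,
    collapse_families,
    phenotype_fraction,
    read_cohort,
    truncation_lengths,
)
from .paralog_map import global_align, homolog_report, read_fasta, read_known_positions
from .regional_constraint import (
    build_depletion_table,
    read_population_variants,
    recurrence_summary,
)
from .structure_contacts import (
    contact_residues,
    read_region_list,
    read_structure,
    region_fraction,
)

__all__ = ["RunConfig", "StageError", "run_all", "load_config", "round_sig"]

log = logging.getLogger("ralascope")

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A stage hard-failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and constants for one pipeline run (all paths optional)."""

    gene_symbol: str = "RALA"
    protein_length: int = 206
    denovo_rate: float = 6.16e-6
    cohort_variants: str | None = None
    cohort_phenotypes: str | None = None
    sites: str | None = None
    n_probands: int | None = None
    structure: str | None = None
    ligand: str = "GDP"
    threshold: float = 1.5
    residue_offset: int = 0
    region_list: str | None = None
    population_variants: str | None = None
    query_fasta: str | None = None
    target_fastas: list[str] = field(default_factory=list)
    known_positions: str | None = None
    gtpase_csv: str | None = None
    glisa_csv: str | None = None
    assay_reference: str = "WT"
    phenotype_flags: list[str] = field(default_factory=list)
    seed: int = 0
    out_dir: str | None = None


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (paper-style rendering)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def _read_sites(path: str | Path) -> tuple[int, set[str]]:
    """Read a site table (site, n_probands, in_denominator); returns the
    screened proband total and the set of screened site names."""
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    total, screened = 0, set()
    for row in csv.DictReader(lines, delimiter="\t"):
        if row["in_denominator"].strip().lower() in {"yes", "true", "1"}:
            screened.add(row["site"])
            total += int(row["n_probands"])
    return total, screened


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and return the report dictionary."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": asdict(config),
        "skipped": {},
        "stages": {},
    }
    gene = GeneModel(config.gene_symbol, config.protein_length, config.denovo_rate)

    cohort = _stage_cohort(config, report)
    region = _stage_region(config, gene, report)
    _stage_burden(config, gene, cohort, report)
    _stage_depletion(config, region, report)
    _stage_recurrence(config, cohort, report)
    _stage_paralog(config, cohort, report)
    _stage_assay(config, report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
        )
    return report


def _skip(report: dict, stage: str, reason: str) -> None:
    log.info("skipping stage %s: %s", stage, reason)
    report["skipped"][stage] = reason


def _stage_cohort(config: RunConfig, report: dict) -> CohortTable | None:
    if not config.cohort_variants:
        _skip(report, "cohort", "no cohort_variants path configured")
        return None
    try:
        cohort = read_cohort(config.cohort_variants, config.cohort_phenotypes)
        families = collapse_families(cohort)
        summary: dict = {
            "n_probands": len(cohort.probands),
            "n_families": len(families),
            "phenotype_fractions": {},
        }
        flags = config.phenotype_flags
        if not flags and cohort.probands and cohort.probands[0]["phenotypes"]:
            flags = list(cohort.probands[0]["phenotypes"])
        for flag in flags:
            num, den, pct = phenotype_fraction(cohort, flag)
            summary["phenotype_fractions"][flag] = {
                "numerator": num, "denominator": den, "percent": pct,
            }
        truncations = [
            truncation_lengths(v.codon_index, config.protein_length)
            for v in cohort.variants
            if v.consequence == "nonsense"
        ]
        if truncations:
            summary["nonsense_truncations"] = truncations
        report["stages"]["cohort"] = summary
        return cohort
    except Exception as exc:
        raise StageError("cohort", str(exc)) from exc


def _stage_region(config: RunConfig, gene: GeneModel, report: dict):
    try:
        if config.region_list:
            region = read_region_list(config.region_list, gene.protein_length)
        elif config.structure:
            model = read_structure(config.structure)
            region = contact_residues(
                model, config.ligand, config.threshold,
                protein_length=gene.protein_length,
                residue_offset=config.residue_offset,
            )
        else:
            _skip(report, "region", "neither region_list nor structure configured")
            return None
        report["stages"]["region"] = {
            "n_residues": len(region.residues),
            "residues": region.sorted_residues,
            "fraction_percent": region_fraction(region),
            "source": region.source,
        }
        return region
    except Exception as exc:
        raise StageError("region", str(exc)) from exc


def _stage_burden(config: RunConfig, gene: GeneModel, cohort, report: dict) -> None:
    if cohort is None:
        _skip(report, "burden", "cohort stage unavailable")
        return
    if config.sites:
        n_probands, screened = _read_sites(config.sites)
    elif config.n_probands:
        n_probands, screened = config.n_probands, None
    else:
        _skip(report, "burden", "no site table or n_probands configured")
        return
    try:
        observed = observed_denovo_count(cohort, screened_sites=screened)
        result = enrichment_test(observed, n_probands, gene.denovo_rate_per_chromosome)
        payload = result.to_dict()
        payload["rendered"] = {
            "expected_denovo_3sf": round_sig(result.expected_denovo),
            "p_binomial_3sf": round_sig(result.p_binomial_upper),
            "p_poisson_3sf": round_sig(result.p_poisson_upper),
        }
        payload["conventions"] = (
            "one-sided upper tail including the observed count; "
            "alleles = 2 x screened probands"
        )
        report["stages"]["burden"] = payload
    except Exception as exc:
        raise StageError("burden", str(exc)) from exc


def _stage_depletion(config: RunConfig, region, report: dict) -> None:
    if region is None:
        _skip(report, "depletion", "region stage unavailable")
        return
    if not config.population_variants:
        _skip(report, "depletion", "no population_variants path configured")
        return
    try:
        variants = read_population_variants(config.population_variants)
        table = build_depletion_table(region, variants)
        payload = table.to_dict()
        payload["rendered"] = {"p_fisher_2sf": round_sig(table.p_fisher_two_sided, 2)}
        payload["conventions"] = (
            "two-sided = minimum-likelihood hypergeometric summation; "
            "one-sided = lower tail on in-region variant residues"
        )
        report["stages"]["depletion"] = payload
    except Exception as exc:
        raise StageError("depletion", str(exc)) from exc


def _stage_recurrence(config: RunConfig, cohort, report: dict) -> None:
    if cohort is None:
        _skip(report, "recurrence", "cohort stage unavailable")
        return
    try:
        report["stages"]["recurrence"] = recurrence_summary(cohort).to_dict()
    except Exception as exc:
        raise StageError("recurrence", str(exc)) from exc


def _stage_paralog(config: RunConfig, cohort, report: dict) -> None:
    if not config.query_fasta or not config.target_fastas:
        _skip(report, "paralog", "query/target FASTA files not configured")
        return
    if cohort is None:
        _skip(report, "paralog", "cohort stage unavailable")
        return
    try:
        query = read_fasta(config.query_fasta)[0]
        maps = [
            global_align(query, read_fasta(t)[0]) for t in config.target_fastas
        ]
        known = (
            read_known_positions(config.known_positions)
            if config.known_positions else []
        )
        rows = homolog_report(cohort.variants, maps, known)
        report["stages"]["paralog"] = {
            "alignments": [
                {"query": m.id_a, "target": m.id_b,
                 "percent_identity": round(m.percent_identity, 1),
                 "score": m.score}
                for m in maps
            ],
            "rows": rows,
        }
    except Exception as exc:
        raise StageError("paralog", str(exc)) from exc


def _stage_assay(config: RunConfig, report: dict) -> None:
    if not config.gtpase_csv and not config.glisa_csv:
        _skip(report, "assay", "no assay CSVs configured")
        return
    try:
        payload = {}
        if config.gtpase_csv:
            assay = read_assay_csv(config.gtpase_csv)
            normalized = normalize_gtpase(assay)
            payload["gtpase"] = {
                "normalized": normalized,
                "vs_reference": compare_groups(normalized, config.assay_reference),
                "vs_ntc": compare_groups(
                    [r for r in normalized], "NTC"
                ),
            }
        if config.glisa_csv:
            assay = read_assay_csv(config.glisa_csv)
            normalized = normalize_glisa(assay)
            payload["glisa"] = {
                "normalized": normalized,
                "vs_reference": compare_groups(normalized, config.assay_reference),
                "vs_ntc": compare_groups(normalized, "NTC"),
            }
        report["stages"]["assay"] = payload
    except Exception as exc:
        raise StageError("assay", str(exc)) from exc
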