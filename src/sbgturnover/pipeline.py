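"""End-to-end orchestration: inputs -> reports, reproducibly.

``run_pipeline`` executes the full analysis in order — orthogroup summary,
per-gene bias calls, order consensus, family classification with class
counts, turnover tables and shares for both contexts, and (when trees are
supplied) gene-tree/species-tree congruence plus the terminal-branch
acceleration screen. Every report is a deterministic function of the
inputs and configuration; a manifest records the configuration hash, seed
and the row count of every artifact, so a rerun from the same manifest
reproduces every report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import dendropy
import yaml

from . import families as fam
from .bias import (
    BiasCall,
    CallParams,
    OrderConsensusRow,
    build_consensus_table,
    call_table,
)
from .io_formats import (
    Orthogroup,
    SpeciesMeta,
    read_chromosome_map,
    read_expression,
    read_newick,
    read_orthogroups,
    read_species_meta,
)
from .phylo import rf_distance, terminal_branch_screen

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "PipelineResult",
    "validate_inputs",
    "run_pipeline",
    "load_config",
]


@dataclass
class PipelineConfig:
    orthogroups: str
    expression: str
    species_meta: str
    out_dir: str
    chromosome_map: str | None = None
    species_tree: str | None = None
    gene_trees: list[str] = field(default_factory=list)
    min_fpkm_floor: float = 1.0
    fold_threshold: float = 1.0
    pseudocount: float = 0.01
    consensus_rule: Literal["majority", "unanimity"] = "majority"
    min_orders: int = 4
    min_species_per_order: int = 1
    min_total_species: int | None = None
    attribution: Literal["strict", "lenient"] = "strict"
    ratio_threshold: float = 3.0
    z_threshold: float = 2.0
    flag_rule: Literal["and", "or"] = "and"
    seed: int = 0

    def call_params(self) -> CallParams:
        return CallParams(self.min_fpkm_floor, self.fold_threshold, self.pseudocount)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def empty(self) -> bool:
        return not self.errors and not self.warnings


def _cross_validate(
    orthogroups: Sequence[Orthogroup],
    expression_genes: set[str],
    species_meta: Mapping[str, SpeciesMeta],
) -> ValidationReport:
    rep = ValidationReport()
    for og in orthogroups:
        for sp, genes in og.membership.items():
            if sp not in species_meta:
                rep.errors.append(
                    f"orthogroup {og.og_id}: species {sp} has no metadata entry"
                )
            for g in genes:
                if g not in expression_genes:
                    rep.warnings.append(
                        f"gene {g} ({og.og_id}) has no expression row; "
                        "left uncalled"
                    )
    return rep


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Cross-check the configured inputs without running the analysis."""
    for path in [config.orthogroups, config.expression, config.species_meta]:
        if not Path(path).exists():
            return ValidationReport(errors=[f"missing input file: {path}"])
    orthogroups = read_orthogroups(config.orthogroups)
    expression = read_expression(config.expression)
    meta = read_species_meta(config.species_meta)
    return _cross_validate(orthogroups, {r.gene_id for r in expression}, meta)


@dataclass
class PipelineResult:
    summary: fam.OrthogroupSummary
    calls: dict[str, BiasCall]
    consensus: list[OrderConsensusRow]
    classifications: list[fam.FamilyClassification]
    class_counts: dict[str, int]
    turnover_female: fam.TurnoverTable
    turnover_male: fam.TurnoverTable
    single_copy_ids: list[str]
    out_dir: Path
    validation: ValidationReport
    congruence: list[dict] = field(default_factory=list)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> int:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return len(rows)


def _relabel_gene_tree(
    tree: dendropy.Tree, gene_to_species: Mapping[str, str]
) -> dendropy.Tree | None:
    """Map gene-id leaves to species ids; None when not a bijection."""
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = gene_to_species.get(leaf.taxon.label, leaf.taxon.label)
        if label in seen:
            return None
        seen.add(label)
        leaf.taxon.label = label
    return tree


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole analysis and write all reports under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_of: dict[str, int] = {}

    orthogroups = read_orthogroups(config.orthogroups)
    expression = read_expression(config.expression)
    meta = read_species_meta(config.species_meta)
    validation = _cross_validate(
        orthogroups, {r.gene_id for r in expression}, meta
    )
    if not validation.ok:
        raise ValueError(
            "input validation failed:\n  " + "\n  ".join(validation.errors)
        )

    # stage 1: occupancy summary
    summary = fam.summarize_orthogroups(
        orthogroups, meta, min_orders=config.min_orders
    )
    (out_dir / "summary.json").write_text(
        json.dumps(dataclasses.asdict(summary), indent=2) + "\n", encoding="utf-8"
    )

    # stage 2: bias calls
    calls = call_table(expression, config.call_params())
    counts_of["bias_calls.tsv"] = _write_tsv(
        out_dir / "bias_calls.tsv",
        ["gene_id", "species_id", "direction", "fold_change", "passed_floor"],
        [
            (c.gene_id, c.species_id, c.direction, f"{c.fold_change:.6g}",
             int(c.passed_floor))
            for c in calls.values()
        ],
    )

    # stage 3: consensus over the qualifying single-copy families
    single_ids = fam.single_copy_families(
        orthogroups,
        meta,
        min_orders=config.min_orders,
        min_species_per_order=config.min_species_per_order,
        min_total_species=config.min_total_species,
    )
    single_set = set(single_ids)
    single_ogs = [og for og in orthogroups if og.og_id in single_set]
    consensus = build_consensus_table(
        single_ogs, calls, meta, config.consensus_rule
    )
    cons_rows = []
    for row in consensus:
        for order, direction in row.directions.items():
            nm, nf, nu = row.counts[order]
            cons_rows.append((row.og_id, order, direction, nm, nf, nu))
    counts_of["consensus.tsv"] = _write_tsv(
        out_dir / "consensus.tsv",
        ["og_id", "order", "direction", "n_male", "n_female", "n_unbiased"],
        cons_rows,
    )

    # stage 4: classification
    classifications = fam.classify_families(consensus, meta)
    counts_of["classifications.tsv"] = _write_tsv(
        out_dir / "classifications.tsv",
        ["og_id", "label", "deviating_order", "deviating_species"],
        [
            (c.og_id, c.label, c.deviating_order or "",
             ",".join(c.deviating_species))
            for c in classifications
        ],
    )
    class_counts = {label: 0 for label in fam.CLASS_LABELS}
    for c in classifications:
        class_counts[c.label] += 1
    n_total = len(classifications)
    n_consistent = (
        class_counts["consistent_male"] + class_counts["consistent_female"]
    )
    class_json = {
        "n_single_copy_families": n_total,
        **class_counts,
        "n_not_consistent": n_total - n_consistent,
    }
    (out_dir / "class_counts.json").write_text(
        json.dumps(class_json, indent=2) + "\n", encoding="utf-8"
    )

    # stage 5: turnover tables + shares for both contexts
    tables = {}
    for context in ("female_biased", "male_biased"):
        table = fam.count_turnovers(
            classifications, context, meta, config.attribution
        )
        tables[context] = table
        shares = fam.turnover_shares(table) if table.total > 0 else {}
        counts_of[f"turnover_{context}.tsv"] = _write_tsv(
            out_dir / f"turnover_{context}.tsv",
            ["species_id", "count", "share_pct"],
            [
                (sp, n, shares.get(sp, ""))
                for sp, n in sorted(
                    table.counts.items(), key=lambda kv: (-kv[1], kv[0])
                )
            ],
        )
    stats: dict[str, object] = {
        "total_female_biased_context": tables["female_biased"].total,
        "total_male_biased_context": tables["male_biased"].total,
        "attribution": config.attribution,
        "unattributed_female": tables["female_biased"].remainder,
        "unattributed_male": tables["male_biased"].remainder,
    }
    if tables["female_biased"].total > 0 and tables["male_biased"].total > 0:
        stats["female_over_male_excess_pct"] = fam.turnover_excess(
            tables["female_biased"].total, tables["male_biased"].total
        )
    (out_dir / "turnover_stats.json").write_text(
        json.dumps(stats, indent=2) + "\n", encoding="utf-8"
    )

    # stage 6: chromosome cross-tab when a map is supplied
    if config.chromosome_map:
        chrom = read_chromosome_map(config.chromosome_map)
        crosstab = fam.chromosome_bias_crosstab(calls, chrom, meta)
        payload = {
            system: {d: tab.loc[d].to_dict() for d in tab.index}
            for system, tab in crosstab.items()
        }
        (out_dir / "chromosome_crosstab.json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )

    # stage 7: congruence + acceleration when trees are supplied
    congruence: list[dict] = []
    accel_rows: list[tuple] = []
    if config.species_tree and config.gene_trees:
        gene_to_species = {
            g: sp
            for og in orthogroups
            for sp, genes in og.membership.items()
            for g in genes
        }
        for gt_path in config.gene_trees:
            name = Path(gt_path).stem
            gene_tree = _relabel_gene_tree(
                read_newick(Path(gt_path)), gene_to_species
            )
            if gene_tree is None:
                validation.warnings.append(
                    f"gene tree {name}: leaves do not map 1:1 onto species; "
                    "skipped"
                )
                continue
            species_tree = read_newick(Path(config.species_tree))
            gt_leaves = {l.taxon.label for l in gene_tree.leaf_node_iter()}
            species_tree.retain_taxa_with_labels(sorted(gt_leaves))
            if len(gt_leaves) >= 4:
                rep = rf_distance(gene_tree, species_tree)
                congruence.append(
                    {
                        "tree": name,
                        "rf": rep.rf,
                        "max_rf": rep.max_rf,
                        "normalized_rf": rep.normalized_rf,
                        "discordant_splits": [
                            list(s) for s in rep.discordant_splits
                        ],
                    }
                )
                screen = terminal_branch_screen(
                    gene_tree,
                    config.ratio_threshold,
                    config.z_threshold,
                    config.flag_rule,
                )
                for r in screen.rows:
                    accel_rows.append(
                        (name, r.leaf, f"{r.terminal_length:.6g}",
                         f"{r.ratio:.6g}", f"{r.robust_z:.6g}", int(r.flagged))
                    )
            else:
                validation.warnings.append(
                    f"gene tree {name}: fewer than 4 mapped leaves; skipped"
                )
        (out_dir / "congruence.json").write_text(
            json.dumps(congruence, indent=2) + "\n", encoding="utf-8"
        )
        counts_of["acceleration.tsv"] = _write_tsv(
            out_dir / "acceleration.tsv",
            ["tree", "leaf", "terminal_length", "ratio", "robust_z", "flagged"],
            accel_rows,
        )

    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "row_counts": counts_of,
        "n_orthogroups": len(orthogroups),
        "n_expression_records": len(expression),
        "n_single_copy_families": len(single_ids),
        "warnings": validation.warnings,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )

    return PipelineResult(
        summary=summary,
        calls=calls,
        consensus=consensus,
        classifications=classifications,
        class_counts=class_json,
        turnover_female=tables["female_biased"],
        turnover_male=tables["male_biased"],
        single_copy_ids=single_ids,
        out_dir=out_dir,
        validation=validation,
        congruence=congruence,
    )
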