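"""Per-gene sex-bias calling and order-level consensus.

A gene is called male-biased when its male-sample FPKM exceeds the
female-sample FPKM (and vice versa), subject to an expression floor and a
configurable fold-change threshold on the pseudocounted ratio. Upstream
expression databases apply their own differential-expression testing; the
default here is therefore sign-with-floor (``fold_threshold = 1.0``), which
is the weakest rule consistent with published per-gene annotations, and the
threshold is exposed for stricter re-analysis.

Order consensus aggregates the species-level calls of one insect order into
a single direction per gene family, under either a strict-plurality
(majority) or a unanimity rule.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .io_formats import ExpressionRecord, Orthogroup, SpeciesMeta

__all__ = [
    "Direction",
    "BiasCall",
    "CallParams",
    "OrderConsensusRow",
    "TISSUE_PRIORITY",
    "call_bias",
    "call_table",
    "select_primary_tissue",
    "order_consensus",
    "build_consensus_table",
]

Direction = Literal["male", "female", "unbiased"]
ConsensusDirection = Literal["male", "female", "unbiased", "no_data"]

#: When a gene is profiled in several tissues, the first listed tissue wins.
TISSUE_PRIORITY: tuple[str, ...] = ("whole body", "gonad", "carcass", "head")


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the bias caller.

    min_fpkm_floor
        Both sexes below this FPKM -> the gene is unexpressed for calling
        purposes (``unbiased`` with ``passed_floor=False``).
    fold_threshold
        Minimum pseudocounted ratio (larger sex over smaller) for a biased
        call; 1.0 means pure sign.
    pseudocount
        Added to both FPKMs in the ratio, stabilising zero denominators.
    """

    min_fpkm_floor: float = 1.0
    fold_threshold: float = 1.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.min_fpkm_floor < 0:
            raise ValueError("min_fpkm_floor must be >= 0")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class BiasCall:
    gene_id: str
    species_id: str
    direction: Direction
    fold_change: float
    passed_floor: bool


def call_bias(
    m_fpkm: float,
    f_fpkm: float,
    params: CallParams = CallParams(),
    gene_id: str = "",
    species_id: str = "",
) -> BiasCall:
    """Call one gene's bias direction from its male/female FPKM pair."""
    if m_fpkm < 0 or f_fpkm < 0 or math.isnan(m_fpkm) or math.isnan(f_fpkm):
        raise ValueError(f"invalid FPKM pair ({m_fpkm}, {f_fpkm})")
    eps = params.pseudocount
    hi, lo = max(m_fpkm, f_fpkm), min(m_fpkm, f_fpkm)
    fold = (hi + eps) / (lo + eps)
    if hi < params.min_fpkm_floor:
        return BiasCall(gene_id, species_id, "unbiased", fold, False)
    direction: Direction = "unbiased"
    if m_fpkm > f_fpkm and fold >= params.fold_threshold:
        direction = "male"
    elif f_fpkm > m_fpkm and fold >= params.fold_threshold:
        direction = "female"
    return BiasCall(gene_id, species_id, direction, fold, True)


def select_primary_tissue(
    records: Sequence[ExpressionRecord],
    priority: Sequence[str] = TISSUE_PRIORITY,
) -> list[ExpressionRecord]:
    """Keep one record per gene, preferring tissues earlier in ``priority``.

    Ties (same gene in two unknown tissues, or twice in one tissue) resolve
    to the earlier file row, so the output is deterministic in input order.
    """
    rank = {t: i for i, t in enumerate(priority)}
    best: dict[str, tuple[int, int, ExpressionRecord]] = {}
    for pos, rec in enumerate(records):
        key = (rank.get(rec.tissue, len(priority)), pos, rec)
        if rec.gene_id not in best or key < best[rec.gene_id]:
            best[rec.gene_id] = key
    # preserve first-occurrence order of genes
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.gene_id)
    return [best[g][2] for g in seen]


def call_table(
    records: Sequence[ExpressionRecord],
    params: CallParams = CallParams(),
    tissue_priority: Sequence[str] = TISSUE_PRIORITY,
) -> dict[str, BiasCall]:
    """Call every gene of an expression table; returns gene_id -> call."""
    primary = select_primary_tissue(records, tissue_priority)
    return {
        r.gene_id: call_bias(r.m_fpkm, r.f_fpkm, params, r.gene_id, r.species_id)
        for r in primary
    }


@dataclass
class OrderConsensusRow:
    """Per-family consensus directions, one per insect order.

    ``species_directions`` keeps the underlying species-level direction for
    every species with at least one called gene, so downstream
    classification can name the deviating species.
    """

    og_id: str
    directions: dict[str, ConsensusDirection]
    counts: dict[str, tuple[int, int, int]]  # order -> (n_male, n_female, n_unbiased)
    species_directions: dict[str, Direction] = field(default_factory=dict)


def _plurality(directions: Iterable[Direction]) -> Direction:
    c = Counter(directions)
    if c["male"] > c["female"]:
        return "male"
    if c["female"] > c["male"]:
        return "female"
    return "unbiased"


def order_consensus(
    species_directions: Mapping[str, Direction],
    species_meta: Mapping[str, SpeciesMeta],
    order_name: str,
    rule: Literal["majority", "unanimity"] = "majority",
) -> tuple[ConsensusDirection, tuple[int, int, int]]:
    """Collapse one order's species-level directions into one direction.

    majority: strict plurality among male/female calls; unbiased calls are
    counted but never win; a male/female tie -> unbiased.
    unanimity: every calling species must agree (an unbiased call breaks
    unanimity). No calls at all -> ``no_data``.
    """
    if rule not in ("majority", "unanimity"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    for sp in species_directions:
        meta = species_meta.get(sp)
        if meta is None:
            raise KeyError(f"species {sp} absent from metadata")
        if meta.order_name != order_name:
            raise ValueError(
                f"species {sp} belongs to {meta.order_name}, not {order_name}"
            )
    if not species_directions:
        return "no_data", (0, 0, 0)
    dirs = list(species_directions.values())
    counts = (dirs.count("male"), dirs.count("female"), dirs.count("unbiased"))
    if rule == "majority":
        return _plurality(dirs), counts
    first = dirs[0]
    if first != "unbiased" and all(d == first for d in dirs):
        return first, counts
    return "unbiased", counts


def build_consensus_table(
    orthogroups: Sequence[Orthogroup],
    calls: Mapping[str, BiasCall],
    species_meta: Mapping[str, SpeciesMeta],
    rule: Literal["majority", "unanimity"] = "majority",
) -> list[OrderConsensusRow]:
    """One consensus row per family, deterministic in content not order.

    Genes without a call are skipped (the pipeline's validation reports
    them); a gene whose species has no metadata is a hard error. Species
    carrying several genes of one family get a species-level direction by
    the same strict-plurality rule before entering the order consensus.
    """
    orders: dict[str, None] = {}
    for meta in species_meta.values():
        orders.setdefault(meta.order_name)
    rows: list[OrderConsensusRow] = []
    for og in sorted(orthogroups, key=lambda o: o.og_id):
        species_dirs: dict[str, Direction] = {}
        for sp, genes in og.membership.items():
            if sp not in species_meta:
                missing = next(g for g in genes)
                raise KeyError(
                    f"gene {missing} belongs to species {sp}, which has no "
                    "metadata entry"
                )
            gene_dirs = [calls[g].direction for g in genes if g in calls]
            if gene_dirs:
                species_dirs[sp] = _plurality(gene_dirs)
        directions: dict[str, ConsensusDirection] = {}
        counts: dict[str, tuple[int, int, int]] = {}
        for order in orders:
            within = {
                sp: d
                for sp, d in species_dirs.items()
                if species_meta[sp].order_name == order
            }
            directions[order], counts[order] = order_consensus(
                within, species_meta, order, rule
            )
        rows.append(
            OrderConsensusRow(og.og_id, directions, counts, species_dirs)
        )
    return rows
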