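"""Orthogroup summaries, consistency/reversal classification and turnover.

The central objects are single-copy orthologous gene families scored, per
insect order, with a sex-bias direction. A family is *consistent* when all
four orders agree on the direction, and *non-consistent* when exactly three
orders agree and the fourth is reversed — the signature of a lineage-level
turnover of sex-biased expression. Turnover counts attribute each
non-consistent family to the species carrying the reversed call, yielding
per-species turnover tables and the derived percentage statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Sequence

import pandas as pd

from .bias import BiasCall, OrderConsensusRow
from .io_formats import CHROMOSOME_CLASSES, Orthogroup, SpeciesMeta

__all__ = [
    "OrthogroupSummary",
    "FamilyClassification",
    "TurnoverTable",
    "CLASS_LABELS",
    "summarize_orthogroups",
    "single_copy_families",
    "classify_family",
    "classify_families",
    "count_turnovers",
    "turnover_shares",
    "turnover_excess",
    "chromosome_bias_crosstab",
]

ClassLabel = Literal[
    "consistent_male",
    "consistent_female",
    "non_consistent_male",
    "non_consistent_female",
    "mixed",
    "unclassified",
]

CLASS_LABELS: tuple[str, ...] = (
    "consistent_male",
    "consistent_female",
    "non_consistent_male",
    "non_consistent_female",
    "mixed",
    "unclassified",
)


@dataclass(frozen=True)
class OrthogroupSummary:
    n_orthogroups: int
    n_species_specific: int
    n_genes_in_species_specific: int
    n_shared_by_all: int
    n_single_copy_qualifying: int


@dataclass(frozen=True)
class FamilyClassification:
    og_id: str
    label: ClassLabel
    deviating_order: str | None = None
    deviating_species: tuple[str, ...] = ()


@dataclass
class TurnoverTable:
    """Per-species turnover counts for one bias context.

    ``context`` names the majority direction: ``female_biased`` counts
    reversals within non-consistent female-biased families (the deviating
    species is male-biased there), and symmetrically for ``male_biased``.
    Families with zero or several deviating species are excluded from
    strict counts and listed in ``remainder``.
    """

    context: Literal["female_biased", "male_biased"]
    counts: dict[str, int]
    total: int
    attribution: Literal["strict", "lenient"] = "strict"
    remainder: list[str] = field(default_factory=list)


def summarize_orthogroups(
    orthogroups: Sequence[Orthogroup],
    species_meta: Mapping[str, SpeciesMeta],
    *,
    min_orders: int = 4,
) -> OrthogroupSummary:
    """Headline occupancy counts over an orthogroup table.

    species-specific = members from exactly one species (any gene count);
    shared-by-all = at least one member in every species of the metadata.
    """
    all_species = set(species_meta)
    n_specific = 0
    n_genes_specific = 0
    n_shared = 0
    for og in orthogroups:
        present = set(og.membership)
        if len(present) == 1:
            n_specific += 1
            n_genes_specific += og.n_genes()
        if present >= all_species:
            n_shared += 1
    qualifying = single_copy_families(
        orthogroups, species_meta, min_orders=min_orders
    )
    return OrthogroupSummary(
        n_orthogroups=len(orthogroups),
        n_species_specific=n_specific,
        n_genes_in_species_specific=n_genes_specific,
        n_shared_by_all=n_shared,
        n_single_copy_qualifying=len(qualifying),
    )


def single_copy_families(
    orthogroups: Sequence[Orthogroup],
    species_meta: Mapping[str, SpeciesMeta],
    *,
    min_orders: int = 4,
    min_species_per_order: int = 1,
    min_total_species: int | None = None,
) -> list[str]:
    """Orthogroups in which every present species carries exactly one gene.

    With the default presence criterion a family must span at least
    ``min_orders`` insect orders with ``min_species_per_order`` species
    each. Passing ``min_total_species`` switches to a total-occupancy
    criterion (>= k species, any orders), the rule used for larger
    tree-building sets.
    """
    orders_available = {m.order_name for m in species_meta.values()}
    if min_total_species is None and min_orders > len(orders_available):
        raise ValueError(
            f"min_orders={min_orders} exceeds the {len(orders_available)} "
            "orders in the metadata"
        )
    out: list[str] = []
    for og in orthogroups:
        if not og.is_single_copy():
            continue
        present = list(og.membership)
        if any(sp not in species_meta for sp in present):
            raise KeyError(
                f"orthogroup {og.og_id} contains species without metadata"
            )
        if min_total_species is not None:
            if len(present) >= min_total_species:
                out.append(og.og_id)
            continue
        per_order = Counter(species_meta[sp].order_name for sp in present)
        if sum(1 for n in per_order.values() if n >= min_species_per_order) >= min_orders:
            out.append(og.og_id)
    return out


def classify_family(
    row: OrderConsensusRow,
    species_meta: Mapping[str, SpeciesMeta] | None = None,
) -> FamilyClassification:
    """Assign one family its consistency class from its order consensus.

    All orders male -> consistent_male (female symmetric); exactly three
    one way and one reversed -> non_consistent_* with the reversed order
    recorded; any order unbiased or without data -> unclassified; anything
    else (e.g. a 2-2 split) -> mixed. The deviating species are the species
    of the reversed order whose own call matches the reversed direction.
    """
    dirs = row.directions
    values = list(dirs.values())
    if any(v in ("no_data", "unbiased") for v in values):
        return FamilyClassification(row.og_id, "unclassified")
    n_male = values.count("male")
    n_female = values.count("female")
    n_orders = len(values)
    if n_male == n_orders:
        return FamilyClassification(row.og_id, "consistent_male")
    if n_female == n_orders:
        return FamilyClassification(row.og_id, "consistent_female")
    if n_male == n_orders - 1 and n_female == 1:
        label: ClassLabel = "non_consistent_male"
        dev_dir = "female"
    elif n_female == n_orders - 1 and n_male == 1:
        label = "non_consistent_female"
        dev_dir = "male"
    else:
        return FamilyClassification(row.og_id, "mixed")
    dev_order = next(o for o, d in dirs.items() if d == dev_dir)
    # without metadata the deviating calls cannot be scoped to the order
    deviating = tuple(
        sorted(
            sp
            for sp, d in row.species_directions.items()
            if d == dev_dir
            and (species_meta is None or species_meta[sp].order_name == dev_order)
        )
    )
    return FamilyClassification(row.og_id, label, dev_order, deviating)


def classify_families(
    rows: Sequence[OrderConsensusRow],
    species_meta: Mapping[str, SpeciesMeta],
) -> list[FamilyClassification]:
    return [classify_family(r, species_meta) for r in rows]


def count_turnovers(
    classifications: Sequence[FamilyClassification],
    context: Literal["female_biased", "male_biased"],
    species_meta: Mapping[str, SpeciesMeta],
    attribution: Literal["strict", "lenient"] = "strict",
) -> TurnoverTable:
    """Per-species counts of expression reversals for one context.

    strict: a family counts once, for its single deviating species;
    families with zero or several deviating species go to ``remainder``.
    lenient: every deviating species of every family counts.
    """
    if context == "female_biased":
        wanted = "non_consistent_female"
    elif context == "male_biased":
        wanted = "non_consistent_male"
    else:
        raise ValueError(f"unknown context {context!r}")
    if attribution not in ("strict", "lenient"):
        raise ValueError(f"unknown attribution mode {attribution!r}")
    counts: dict[str, int] = {sp: 0 for sp in species_meta}
    remainder: list[str] = []
    total = 0
    for fc in classifications:
        if fc.label != wanted:
            continue
        if attribution == "strict":
            if len(fc.deviating_species) == 1:
                counts[fc.deviating_species[0]] += 1
                total += 1
            else:
                remainder.append(fc.og_id)
        else:
            for sp in fc.deviating_species:
                counts[sp] += 1
                total += 1
            if not fc.deviating_species:
                remainder.append(fc.og_id)
    return TurnoverTable(context, counts, total, attribution, remainder)


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def turnover_shares(table: TurnoverTable) -> dict[str, float]:
    """Each species' percentage of the table total, to one decimal."""
    if table.total <= 0:
        raise ZeroDivisionError("turnover table total is zero")
    return {
        sp: _round_half_up(100.0 * n / table.total, 1)
        for sp, n in table.counts.items()
    }


def turnover_excess(n_a: int, n_b: int) -> int:
    """How much more frequent class a is than class b, as a whole percent."""
    if n_b <= 0:
        raise ZeroDivisionError("reference class total is zero")
    return int(_round_half_up(100.0 * (n_a - n_b) / n_b, 0))


def chromosome_bias_crosstab(
    calls: Mapping[str, BiasCall] | Sequence[BiasCall],
    chromosome_map: Mapping[str, str],
    species_meta: Mapping[str, SpeciesMeta],
) -> dict[str, pd.DataFrame]:
    """Counts of genes by (direction, chromosome class), per sex system.

    Genes absent from the map fall into class ``unknown``. Counts only —
    no statistical test is attached.
    """
    call_list = list(calls.values()) if isinstance(calls, Mapping) else list(calls)
    rows = []
    for c in call_list:
        meta = species_meta.get(c.species_id)
        if meta is None:
            raise KeyError(f"species {c.species_id} absent from metadata")
        cls = chromosome_map.get(c.gene_id, "unknown")
        if cls not in CHROMOSOME_CLASSES:
            raise ValueError(f"gene {c.gene_id}: bad chromosome class {cls!r}")
        rows.append((meta.sex_system, c.direction, cls))
    out: dict[str, pd.DataFrame] = {}
    directions = ["male", "female", "unbiased"]
    classes = sorted(CHROMOSOME_CLASSES)
    for system in sorted({r[0] for r in rows}):
        tab = pd.DataFrame(0, index=directions, columns=classes, dtype=int)
        for sys_, d, cls in rows:
            if sys_ == system:
                tab.loc[d, cls] += 1
        out[system] = tab
    return out
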