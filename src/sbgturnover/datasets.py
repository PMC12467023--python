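"""Small packaged benchmark datasets, generated programmatically.

These fixtures encode the canonical cross-order configuration the
classifier is specified against: 181 single-copy gene families spanning all
four insect orders, of which 12 are consistently male-biased, none
consistently female-biased, 27 non-consistent male-biased, and 44
non-consistent female-biased with the deviating (male-biased) species
distributed 18/7/7/5/3/3/1 over the seven species of the published turnover
table; the remaining 98 families split evenly between mixed (2-2) and
unclassified (one order unbiased) patterns.

Every family carries one species per order, with the deviating species
standing as its own order's representative — the configuration under which
a single reversed species flips its order's consensus. FPKM pairs are
chosen so every intended call is unambiguous at default calling parameters
(40 vs 10 for a biased gene, 20 vs 20 for an unbiased one).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ExpressionRecord, Orthogroup, SpeciesMeta
from .synth import default_species_meta

__all__ = [
    "BenchmarkDataset",
    "TURNOVER_DISTRIBUTION",
    "turnover_benchmark",
    "classification_benchmark",
]

#: Deviating-species distribution of the 44 non-consistent female-biased
#: families: (species_id, number of families attributed to it).
TURNOVER_DISTRIBUTION: tuple[tuple[str, int], ...] = (
    ("Tcast", 18),
    ("Bmori", 7),
    ("Agamb", 7),
    ("Dpse", 5),
    ("Aalbi", 3),
    ("Apisu", 3),
    ("Astep", 1),
)

_DEFAULT_REP = {
    "Hemiptera": "Apisu",
    "Coleoptera": "Tcast",
    "Lepidoptera": "Bmori",
    "Diptera": "Dmel",
}

_BIASED_HI, _BIASED_LO = 40.0, 10.0
_FLAT = 20.0


@dataclass
class BenchmarkDataset:
    orthogroups: list[Orthogroup]
    expression: list[ExpressionRecord]
    species_meta: dict[str, SpeciesMeta]
    #: og_id -> (expected label, expected deviating species or None)
    expected: dict[str, tuple[str, str | None]]


def _family(
    og_id: str,
    meta: dict[str, SpeciesMeta],
    order_directions: dict[str, str],  # order -> male / female / unbiased
    deviating_species: str | None = None,
) -> tuple[Orthogroup, list[ExpressionRecord]]:
    reps = dict(_DEFAULT_REP)
    if deviating_species is not None:
        reps[meta[deviating_species].order_name] = deviating_species
    membership: dict[str, list[str]] = {}
    records: list[ExpressionRecord] = []
    for order, sp in reps.items():
        gene = f"{og_id}_{sp}"
        membership[sp] = [gene]
        direction = order_directions[order]
        if direction == "male":
            m, f = _BIASED_HI, _BIASED_LO
        elif direction == "female":
            m, f = _BIASED_LO, _BIASED_HI
        else:
            m = f = _FLAT
        records.append(ExpressionRecord(gene, sp, "whole body", m, f))
    return Orthogroup(og_id, membership), records


def classification_benchmark() -> BenchmarkDataset:
    """The full 181-family classification benchmark described above."""
    meta = default_species_meta()
    ogs: list[Orthogroup] = []
    expr: list[ExpressionRecord] = []
    expected: dict[str, tuple[str, str | None]] = {}

    def add(og, records, label, dev=None):
        ogs.append(og)
        expr.extend(records)
        expected[og.og_id] = (label, dev)

    all_male = {o: "male" for o in _DEFAULT_REP}
    all_female = {o: "female" for o in _DEFAULT_REP}
    for i in range(12):
        add(*_family(f"BCM{i + 1:03d}", meta, all_male), "consistent_male")

    cycle = [sp for sp, _ in TURNOVER_DISTRIBUTION]
    for i in range(27):
        dev = cycle[i % len(cycle)]
        dirs = dict(all_male)
        dirs[meta[dev].order_name] = "female"
        add(
            *_family(f"BNM{i + 1:03d}", meta, dirs, dev),
            "non_consistent_male",
            dev,
        )

    k = 0
    for dev, n in TURNOVER_DISTRIBUTION:
        for _ in range(n):
            k += 1
            dirs = dict(all_female)
            dirs[meta[dev].order_name] = "male"
            add(
                *_family(f"BNF{k:03d}", meta, dirs, dev),
                "non_consistent_female",
                dev,
            )

    mixed = {"Hemiptera": "male", "Coleoptera": "male",
             "Lepidoptera": "female", "Diptera": "female"}
    for i in range(49):
        add(*_family(f"BMX{i + 1:03d}", meta, mixed), "mixed")

    flat_dip = dict(all_female)
    flat_dip["Diptera"] = "unbiased"
    for i in range(49):
        add(*_family(f"BUN{i + 1:03d}", meta, flat_dip), "unclassified")

    return BenchmarkDataset(ogs, expr, meta, expected)


def turnover_benchmark() -> BenchmarkDataset:
    """Just the 44 non-consistent female-biased families (turnover table)."""
    full = classification_benchmark()
    keep = {og for og, (label, _) in full.expected.items()
            if label == "non_consistent_female"}
    ogs = [og for og in full.orthogroups if og.og_id in keep]
    genes = {g for og in ogs for g in og.genes}
    expr = [r for r in full.expression if r.gene_id in genes]
    expected = {k: v for k, v in full.expected.items() if k in keep}
    return BenchmarkDataset(ogs, expr, full.species_meta, expected)
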