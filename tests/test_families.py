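"""Occupancy summaries, consistency classification, turnover counting."""

import pytest

from sbgturnover.bias import BiasCall, OrderConsensusRow
from sbgturnover.families import (
    FamilyClassification,
    chromosome_bias_crosstab,
    classify_family,
    count_turnovers,
    single_copy_families,
    summarize_orthogroups,
    turnover_excess,
    turnover_shares,
)
from sbgturnover.io_formats import Orthogroup, SpeciesMeta
from sbgturnover.synth import default_species_meta

META = default_species_meta()
ORDERS = ("Hemiptera", "Coleoptera", "Lepidoptera", "Diptera")


def row(og_id, directions, species_directions=None):
    return OrderConsensusRow(
        og_id,
        dict(zip(ORDERS, directions)),
        {o: (0, 0, 0) for o in ORDERS},
        species_directions or {},
    )


# ------------------------------------------------------------- summaries


def test_species_specific_counts_families_and_genes():
    ogs = [
        Orthogroup("OG1", {"Apisu": ["g1", "g2"]}),
        Orthogroup("OG2", {"Apisu": ["g3"], "Tcast": ["g4"]}),
    ]
    s = summarize_orthogroups(ogs, META)
    assert s.n_species_specific == 1
    assert s.n_genes_in_species_specific == 2
    assert s.n_shared_by_all == 0


def test_shared_by_all_requires_every_species():
    full = Orthogroup("OG1", {sp: [f"g_{sp}"] for sp in META})
    partial = Orthogroup("OG2", {sp: [f"h_{sp}"] for sp in list(META)[:-1]})
    s = summarize_orthogroups([full, partial], META)
    assert s.n_shared_by_all == 1


# ------------------------------------------------------ single-copy rules


def test_multi_copy_family_excluded():
    og = Orthogroup("OG1", {
        "Apisu": ["a"], "Tcast": ["b", "b2"], "Bmori": ["c"], "Dmel": ["d"],
    })
    assert single_copy_families([og], META) == []


def test_one_species_per_order_qualifies_at_defaults():
    og = Orthogroup("OG1", {
        "Apisu": ["a"], "Tcast": ["b"], "Bmori": ["c"], "Dmel": ["d"],
    })
    assert single_copy_families([og], META) == ["OG1"]


def test_total_species_criterion_switches_presence_rule():
    dipterans = ["Aaegy", "Aalbi", "Agamb", "Astep", "Dmel"]
    og = Orthogroup("OG1", {sp: [f"g_{sp}"] for sp in dipterans})
    assert single_copy_families([og], META) == []
    assert single_copy_families([og], META, min_total_species=5) == ["OG1"]
    assert single_copy_families([og], META, min_total_species=6) == []


# --------------------------------------------------------- classification


@pytest.mark.parametrize(
    "directions,label",
    [
        (("male",) * 4, "consistent_male"),
        (("female",) * 4, "consistent_female"),
        (("female", "female", "male", "male"), "mixed"),
        (("female", "female", "female", "no_data"), "unclassified"),
        (("female", "female", "female", "unbiased"), "unclassified"),
    ],
)
def test_classify_family_patterns(directions, label):
    assert classify_family(row("OG1", directions), META).label == label


def test_non_consistent_female_names_the_deviating_order_and_species():
    # female in Hemiptera/Lepidoptera/Diptera, male in Coleoptera
    r = row(
        "OG1",
        ("female", "male", "female", "female"),
        {"Apisu": "female", "Tcast": "male", "Bmori": "female", "Dmel": "female"},
    )
    fc = classify_family(r, META)
    assert fc.label == "non_consistent_female"
    assert fc.deviating_order == "Coleoptera"
    assert fc.deviating_species == ("Tcast",)


def test_deviating_species_scoped_to_deviating_order():
    # a male call outside the deviating order must not be attributed
    r = row(
        "OG1",
        ("female", "male", "female", "female"),
        {"Tcast": "male", "Dmel": "male", "Apisu": "female", "Bmori": "female",
         "Dpse": "female", "Dsim": "female"},
    )
    fc = classify_family(r, META)
    assert fc.deviating_species == ("Tcast",)


def test_classification_is_a_partition(benchmark_full):
    from sbgturnover.bias import build_consensus_table, call_table
    from sbgturnover.families import CLASS_LABELS, classify_families

    ds = benchmark_full
    calls = call_table(ds.expression)
    rows = build_consensus_table(ds.orthogroups, calls, ds.species_meta)
    classes = classify_families(rows, ds.species_meta)
    assert len(classes) == len(ds.orthogroups)
    counts = {label: 0 for label in CLASS_LABELS}
    for c in classes:
        counts[c.label] += 1
    assert sum(counts.values()) == len(ds.orthogroups)


# --------------------------------------------------------------- turnover


def fc(og, label, dev_order=None, dev_species=()):
    return FamilyClassification(og, label, dev_order, tuple(dev_species))


def test_strict_counts_single_deviators_and_reports_remainder():
    classes = [
        fc("A", "non_consistent_female", "Coleoptera", ["Tcast"]),
        fc("B", "non_consistent_female", "Diptera", ["Agamb", "Astep"]),
        fc("C", "non_consistent_male", "Diptera", ["Dmel"]),
        fc("D", "mixed"),
    ]
    table = count_turnovers(classes, "female_biased", META, "strict")
    assert table.counts["Tcast"] == 1
    assert table.total == 1
    assert table.remainder == ["B"]
    lenient = count_turnovers(classes, "female_biased", META, "lenient")
    assert lenient.total == 3
    assert lenient.counts["Agamb"] == lenient.counts["Astep"] == 1


def test_empty_classifications_give_all_zero_table():
    table = count_turnovers([], "male_biased", META)
    assert table.total == 0
    assert set(table.counts.values()) == {0}


def test_unknown_context_is_hard_error():
    with pytest.raises(ValueError):
        count_turnovers([], "sideways", META)


def test_shares_round_half_up_to_one_decimal():
    classes = [
        fc(f"F{i}", "non_consistent_female", "Coleoptera", ["Tcast"])
        for i in range(18)
    ] + [
        fc(f"G{i}", "non_consistent_female", "Lepidoptera", ["Bmori"])
        for i in range(26)
    ]
    table = count_turnovers(classes, "female_biased", META)
    shares = turnover_shares(table)
    assert shares["Tcast"] == 40.9
    assert shares["Apisu"] == 0.0


def test_excess_statistic_rounds_to_whole_percent():
    assert turnover_excess(44, 27) == 63
    assert turnover_excess(10, 10) == 0
    with pytest.raises(ZeroDivisionError):
        turnover_excess(5, 0)


def test_shares_need_nonzero_total():
    with pytest.raises(ZeroDivisionError):
        turnover_shares(count_turnovers([], "female_biased", META))


# --------------------------------------------------- chromosome cross-tab


def test_crosstab_reproduces_x_linked_female_bias_pattern():
    calls = [
        BiasCall("AALB006416", "Aalbi", "female", 1.2, True),
        BiasCall("AgaP_AGAP000308", "Agamb", "female", 3.0, True),
        BiasCall("Aste1435_g", "Astep", "female", 2.7, True),
        BiasCall("LOC4815668", "Dpse", "female", 3.9, True),
        BiasCall("LOC663373", "Tcast", "male", 40.0, True),
    ]
    chrom = {
        "AALB006416": "X",
        "AgaP_AGAP000308": "X",
        "Aste1435_g": "X",
        "LOC4815668": "X",
        "LOC663373": "autosome",
    }
    tabs = chromosome_bias_crosstab(calls, chrom, META)
    xy = tabs["XY"]
    assert xy.loc["female", "X"] == 4
    assert xy.loc["male", "autosome"] == 1
    assert int(xy.to_numpy().sum()) == 5


def test_crosstab_unmapped_genes_fall_in_unknown_and_order_invariance():
    calls = [
        BiasCall("g1", "Dmel", "male", 2.0, True),
        BiasCall("g2", "Bmori", "female", 2.0, True),
    ]
    tabs = chromosome_bias_crosstab(calls, {}, META)
    assert tabs["XY"].loc["male", "unknown"] == 1
    assert tabs["ZW"].loc["female", "unknown"] == 1
    rev = chromosome_bias_crosstab(list(reversed(calls)), {}, META)
    for k in tabs:
        assert tabs[k].equals(rev[k])


# ------------------------------------------------------------ equivariance


def test_relabeling_species_permutes_outputs_identically():
    mapping = {"Tcast": "Zcast", "Bmori": "Zmori"}
    meta2 = {}
    for sp, m in META.items():
        sp2 = mapping.get(sp, sp)
        meta2[sp2] = SpeciesMeta(sp2, m.order_name, m.sex_system, m.display_name)
    classes = [
        fc("A", "non_consistent_female", "Coleoptera", ["Tcast"]),
        fc("B", "non_consistent_female", "Lepidoptera", ["Bmori"]),
    ]
    relabeled = [
        fc("A", "non_consistent_female", "Coleoptera", ["Zcast"]),
        fc("B", "non_consistent_female", "Lepidoptera", ["Zmori"]),
    ]
    t1 = count_turnovers(classes, "female_biased", META)
    t2 = count_turnovers(relabeled, "female_biased", meta2)
    assert {mapping.get(k, k): v for k, v in t1.counts.items()} == t2.counts
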