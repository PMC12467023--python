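"""Ground-truth-labeled synthetic datasets for the turnover analysis.

The generator emulates the data regime of a cross-order insect study: 13
species from four orders (one aphid, one beetle, two lepidopterans, nine
dipterans), gene families with variable species occupancy, and a latent
male/female bias state evolving along the species tree as a symmetric
two-state Markov chain. Reversals therefore accumulate on long branches —
the beetle's long terminal branch makes it the natural reversal hotspot,
mirroring the empirical pattern the analysis is built to detect. Expression
values are lognormal around a baseline, with the biased sex multiplied by a
fold-change; sequence alignments evolve under Jukes–Cantor, optionally with
one accelerated focal terminal branch.

Every operation is a pure function of (config, seed): a fixed seed yields
byte-identical datasets. The single RNG stream is consumed in a documented
order (membership, then per-family bias states, then expression, then
alignments) so partial regeneration stays reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import (
    ExpressionRecord,
    Orthogroup,
    SpeciesMeta,
    read_newick,
    write_expression,
    write_newick,
    write_orthogroups,
    write_species_meta,
)

__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_SPECIES_TREE",
    "SimConfig",
    "FamilyTruth",
    "SyntheticTruth",
    "default_species_meta",
    "default_species_tree",
    "simulate_bias_states",
    "emit_expression",
    "simulate_membership",
    "simulate_alignment",
    "write_dataset",
]

#: The 13-species roster: (species_id, order, sex system, display name).
DEFAULT_SPECIES: tuple[tuple[str, str, str, str], ...] = (
    ("Apisu", "Hemiptera", "XO", "Acyrthosiphon pisum"),
    ("Tcast", "Coleoptera", "XY", "Tribolium castaneum"),
    ("Bmori", "Lepidoptera", "ZW", "Bombyx mori"),
    ("Dplex", "Lepidoptera", "ZW", "Danaus plexippus"),
    ("Aaegy", "Diptera", "XY", "Aedes aegypti"),
    ("Aalbi", "Diptera", "XY", "Anopheles albimanus"),
    ("Agamb", "Diptera", "XY", "Anopheles gambiae"),
    ("Astep", "Diptera", "XY", "Anopheles stephensi"),
    ("Dmel", "Diptera", "XY", "Drosophila melanogaster"),
    ("Dpse", "Diptera", "XY", "Drosophila pseudoobscura"),
    ("Dsim", "Diptera", "XY", "Drosophila simulans"),
    ("Dvir", "Diptera", "XY", "Drosophila virilis"),
    ("Dyak", "Diptera", "XY", "Drosophila yakuba"),
)

#: Default species tree (substitutions/site): hemipteran outermost, then the
#: beetle on a long terminal branch, two lepidopterans, and nine dipterans
#: split into mosquitoes and drosophilids.
DEFAULT_SPECIES_TREE = (
    "(Apisu:0.60,(Tcast:0.50,((Bmori:0.18,Dplex:0.20):0.22,"
    "((Aaegy:0.12,(Aalbi:0.06,(Agamb:0.05,Astep:0.06):0.02):0.05):0.18,"
    "(Dvir:0.14,(Dpse:0.10,(Dmel:0.04,(Dsim:0.03,Dyak:0.05):0.02):0.05):0.03)"
    ":0.12):0.10):0.08):0.05);"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_species_meta() -> dict[str, SpeciesMeta]:
    return {
        sid: SpeciesMeta(sid, order, system, name)
        for sid, order, system, name in DEFAULT_SPECIES
    }


def default_species_tree() -> dendropy.Tree:
    return read_newick(DEFAULT_SPECIES_TREE)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    bias_rate_mu is the per-unit-branch-length rate of the symmetric
    male<->female switch; along a branch of length t the latent state flips
    with probability (1 - exp(-2*mu*t))/2. FPKM magnitudes follow the
    lognormal 2**N(fpkm_log2_baseline, fpkm_log2_sd) for the unbiased sex,
    times bias_effect_fold for the biased sex.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 500
    bias_rate_mu: float = 0.3
    root_state_probs: tuple[float, float] = (0.5, 0.5)  # (P(male), P(female))
    fpkm_log2_baseline: float = 4.5
    fpkm_log2_sd: float = 0.8
    bias_effect_fold: float = 4.0
    presence_prob: float = 0.35
    extra_copy_prob: float = 0.1
    seq_length: int = 500
    acceleration_factor: float = 1.0
    focal_species: str | None = "Tcast"
    seed: int = 0
    max_alignment_families: int | None = 25

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if self.bias_rate_mu < 0:
            raise ValueError("bias_rate_mu must be non-negative")
        pm, pf = self.root_state_probs
        if pm < 0 or pf < 0 or abs(pm + pf - 1.0) > 1e-12:
            raise ValueError("root_state_probs must be non-negative and sum to 1")
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0, 1]")
        if not 0 <= self.extra_copy_prob <= 1:
            raise ValueError("extra_copy_prob must be in [0, 1]")
        if self.fpkm_log2_sd < 0:
            raise ValueError("fpkm_log2_sd must be non-negative")
        if self.bias_effect_fold <= 1:
            raise ValueError("bias_effect_fold must exceed 1")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if self.acceleration_factor < 1:
            raise ValueError("acceleration_factor must be >= 1")

    def tree(self) -> dendropy.Tree:
        return read_newick(self.species_tree)

    def species_ids(self) -> list[str]:
        return [s[0] for s in DEFAULT_SPECIES]


@dataclass
class FamilyTruth:
    og_id: str
    tip_states: dict[str, str]  # species -> planted direction, all species
    n_transitions: int
    accelerated_taxa: tuple[str, ...] = ()


@dataclass
class SyntheticTruth:
    families: list[FamilyTruth]
    gene_directions: dict[str, str] = field(default_factory=dict)

    def family(self, og_id: str) -> FamilyTruth:
        return next(f for f in self.families if f.og_id == og_id)


def simulate_bias_states(
    tree: dendropy.Tree,
    mu: float,
    root_probs: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[dict[str, str], int]:
    """Evolve the binary bias state down the tree; return tip states and the
    realized number of state switches (branches whose endpoints differ)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    state_of: dict[int, int] = {}  # node id -> 0 male / 1 female
    root = tree.seed_node
    state_of[id(root)] = int(rng.random() < root_probs[1])
    n_flips = 0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        p_flip = 0.5 * (1.0 - math.exp(-2.0 * mu * t))
        parent_state = state_of[id(node.parent_node)]
        flip = rng.random() < p_flip
        state_of[id(node)] = parent_state ^ int(flip)
        n_flips += int(flip)
    tips = {
        leaf.taxon.label: ("male", "female")[state_of[id(leaf)]]
        for leaf in tree.leaf_node_iter()
    }
    return tips, n_flips


def emit_expression(
    tip_states: Mapping[str, str],
    membership: Mapping[str, Sequence[str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[ExpressionRecord]:
    """Lognormal FPKM pairs for every present gene, biased sex scaled up.

    Each sex receives an independent lognormal draw around the baseline,
    with the biased sex's log2 mean shifted up by log2(fold); measurement
    noise can therefore flip the observed direction once the noise scale
    approaches the effect size.
    """
    records: list[ExpressionRecord] = []
    shift = math.log2(config.bias_effect_fold)
    for sp, genes in membership.items():
        state = tip_states[sp]
        for gene in genes:
            mu_m = config.fpkm_log2_baseline + (shift if state == "male" else 0.0)
            mu_f = config.fpkm_log2_baseline + (shift if state == "female" else 0.0)
            m = 2.0 ** rng.normal(mu_m, config.fpkm_log2_sd)
            f = 2.0 ** rng.normal(mu_f, config.fpkm_log2_sd)
            records.append(ExpressionRecord(gene, sp, "whole body", m, f))
    return records


def simulate_membership(
    config: SimConfig, rng: np.random.Generator
) -> list[Orthogroup]:
    """Bernoulli presence per (family, species); present species carry one
    gene or two with probability ``extra_copy_prob``; empty families are
    redrawn."""
    species = config.species_ids()
    out: list[Orthogroup] = []
    for i in range(config.n_families):
        og_id = f"OG{i + 1:05d}"
        while True:
            present = rng.random(len(species)) < config.presence_prob
            if present.any():
                break
        membership: dict[str, list[str]] = {}
        for sp, here in zip(species, present):
            if not here:
                continue
            genes = [f"{og_id}_{sp}"]
            if rng.random() < config.extra_copy_prob:
                genes.append(f"{og_id}_{sp}_b")
            membership[sp] = genes
        out.append(Orthogroup(og_id, membership))
    return out


def simulate_alignment(
    tree: dendropy.Tree,
    seq_length: int,
    rng: np.random.Generator,
    acceleration_factor: float = 1.0,
    focal_species: str | None = None,
) -> dict[str, str]:
    """Jukes–Cantor site evolution from a uniform root sequence.

    ``acceleration_factor`` multiplies only the focal species' terminal
    branch, planting the long-branch signal the acceleration screen hunts.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=seq_length, dtype=np.uint8)
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        if (
            node.is_leaf()
            and focal_species is not None
            and node.taxon.label == focal_species
        ):
            t *= acceleration_factor
        p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
        parent_seq = seqs[id(node.parent_node)]
        child = parent_seq.copy()
        hit = rng.random(seq_length) < p_change
        n_hit = int(hit.sum())
        if n_hit:
            # uniform over the three other bases
            child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit)) % 4
        seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = _BASES[child].tobytes().decode("ascii")
    return out


def write_alignment_tsv(alignment: Mapping[str, str], path: Path) -> None:
    lines = ["taxon\tsequence"]
    for taxon, seq in alignment.items():
        lines.append(f"{taxon}\t{seq}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_alignment_tsv(path: Path) -> dict[str, str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out: dict[str, str] = {}
    for line in lines[1:]:
        taxon, seq = line.split("\t")
        out[taxon] = seq
    return out


def write_dataset(config: SimConfig, out_dir: str | Path) -> SyntheticTruth:
    """Emit a complete labeled dataset under ``out_dir``.

    Files: ``orthogroups.tsv``, ``expression.tsv``, ``species_meta.tsv``,
    ``species_tree.nwk``, ``alignments/<og>.tsv`` (for up to
    ``max_alignment_families`` families with >= 2 present species, pruned to
    the present species), and ``truth.tsv`` with the planted per-species
    states, transition counts and acceleration flags. Identical seeds yield
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = config.tree()
    meta = default_species_meta()

    orthogroups = simulate_membership(config, rng)
    families: list[FamilyTruth] = []
    gene_directions: dict[str, str] = {}
    all_records: list[ExpressionRecord] = []
    for og in orthogroups:
        tips, n_flips = simulate_bias_states(
            tree, config.bias_rate_mu, config.root_state_probs, rng
        )
        accelerated: tuple[str, ...] = ()
        if config.acceleration_factor > 1 and config.focal_species:
            accelerated = (config.focal_species,)
        families.append(FamilyTruth(og.og_id, tips, n_flips, accelerated))
        for sp, genes in og.membership.items():
            for g in genes:
                gene_directions[g] = tips[sp]
    # expression after all states: one stream position per family in order
    for og, fam in zip(orthogroups, families):
        all_records.extend(
            emit_expression(fam.tip_states, og.membership, config, rng)
        )

    write_orthogroups(orthogroups, out_dir / "orthogroups.tsv",
                      species_order=config.species_ids())
    write_expression(all_records, out_dir / "expression.tsv")
    write_species_meta(meta, out_dir / "species_meta.tsv")
    (out_dir / "species_tree.nwk").write_text(write_newick(tree), encoding="utf-8")

    aln_dir = out_dir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    cap = config.max_alignment_families
    n_written = 0
    for og in orthogroups:
        if cap is not None and n_written >= cap:
            break
        if len(og.membership) < 2:
            continue
        sub = tree.clone(depth=1)
        keep = set(og.membership)
        sub.retain_taxa_with_labels(sorted(keep))
        aln = simulate_alignment(
            sub,
            config.seq_length,
            rng,
            acceleration_factor=config.acceleration_factor,
            focal_species=config.focal_species,
        )
        write_alignment_tsv(aln, aln_dir / f"{og.og_id}.tsv")
        n_written += 1

    truth_lines = ["og_id\tspecies_id\tplanted_state\tn_transitions\taccelerated"]
    for fam in families:
        for sp in config.species_ids():
            acc = int(sp in fam.accelerated_taxa)
            truth_lines.append(
                f"{fam.og_id}\t{sp}\t{fam.tip_states[sp]}\t{fam.n_transitions}\t{acc}"
            )
    (out_dir / "truth.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    return SyntheticTruth(families, gene_directions)


def read_truth(path: str | Path) -> SyntheticTruth:
    """Re-load a truth table written by :func:`write_dataset`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    fams: dict[str, FamilyTruth] = {}
    for line in lines[1:]:
        og_id, sp, state, n_tr, acc = line.split("\t")
        fam = fams.get(og_id)
        if fam is None:
            fam = FamilyTruth(og_id, {}, int(n_tr))
            fams[og_id] = fam
        fam.tip_states[sp] = state
        if acc == "1":
            fam.accelerated_taxa = tuple(sorted({*fam.accelerated_taxa, sp}))
    return SyntheticTruth(list(fams.values()))
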