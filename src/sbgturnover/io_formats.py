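"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are tab-separated UTF-8 with a mandatory header row:

* orthogroup membership in the OrthoFinder ``Orthogroups.tsv`` dialect
  (one row per orthogroup, one column per species, comma-separated gene
  lists, empty cell = species absent);
* sexed expression tables with columns
  ``gene_id, species_id, tissue, m_fpkm, f_fpkm`` (FPKM units, male and
  female samples respectively);
* species metadata with columns
  ``species_id, order_name, sex_system, display_name``;
* an optional gene-to-chromosome-class map with columns
  ``gene_id, chromosome_class``.

Trees travel as plain Newick (unquoted labels, decimal branch lengths, no
comments/NHX), parsed into :class:`dendropy.Tree` objects. Every reader
validates loudly and every writer round-trips through its reader.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import dendropy

__all__ = [
    "SpeciesMeta",
    "ExpressionRecord",
    "Orthogroup",
    "SEX_SYSTEMS",
    "CHROMOSOME_CLASSES",
    "read_orthogroups",
    "write_orthogroups",
    "read_expression",
    "write_expression",
    "read_species_meta",
    "write_species_meta",
    "read_chromosome_map",
    "write_chromosome_map",
    "read_newick",
    "write_newick",
]

SEX_SYSTEMS = frozenset({"XY", "ZW", "XO", "unknown"})
CHROMOSOME_CLASSES = frozenset({"X", "Z", "autosome", "unknown"})


class FormatError(ValueError):
    """A file violated its format contract; message names the offence."""


@dataclass(frozen=True)
class SpeciesMeta:
    """One species of the study roster.

    ``sex_system`` records the chromosomal sex-determination system (XY for
    most Diptera and Coleoptera, ZW for Lepidoptera, XO for aphids).
    """

    species_id: str
    order_name: str
    sex_system: str = "unknown"
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.species_id or any(c.isspace() for c in self.species_id):
            raise FormatError(f"invalid species_id {self.species_id!r}")
        if not self.order_name:
            raise FormatError(f"species {self.species_id}: empty order_name")
        if self.sex_system not in SEX_SYSTEMS:
            raise FormatError(
                f"species {self.species_id}: sex_system {self.sex_system!r} "
                f"not one of {sorted(SEX_SYSTEMS)}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Sexed expression of one gene: FPKM in male and female samples."""

    gene_id: str
    species_id: str
    tissue: str
    m_fpkm: float
    f_fpkm: float

    def __post_init__(self) -> None:
        if self.m_fpkm < 0 or self.f_fpkm < 0:
            raise FormatError(
                f"gene {self.gene_id}: negative FPKM "
                f"({self.m_fpkm}, {self.f_fpkm})"
            )
        if math.isnan(self.m_fpkm) or math.isnan(self.f_fpkm):
            raise FormatError(f"gene {self.gene_id}: NaN FPKM")


@dataclass
class Orthogroup:
    """A clustered gene family: map species_id -> ordered gene-id list.

    Species with no members are absent from the map, never empty lists.
    """

    og_id: str
    membership: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(self.membership.values()):
            raise FormatError(f"orthogroup {self.og_id}: no member genes")
        for sp, genes in self.membership.items():
            if not genes:
                raise FormatError(
                    f"orthogroup {self.og_id}: species {sp} has an empty "
                    "gene list (absent species must be omitted)"
                )

    @property
    def species(self) -> list[str]:
        return list(self.membership)

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.membership.values() for g in genes]

    def n_genes(self) -> int:
        return sum(len(v) for v in self.membership.values())

    def is_single_copy(self) -> bool:
        return all(len(v) == 1 for v in self.membership.values())


# ---------------------------------------------------------------------------
# orthogroup tables


def read_orthogroups(path: Union[str, Path]) -> list[Orthogroup]:
    """Parse an OrthoFinder-style Orthogroups TSV.

    Cells are split on commas with optional trailing whitespace; an empty
    cell means the species is absent. Duplicate orthogroup ids, duplicate
    gene ids across rows and ragged rows are hard errors.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.split("\t")
        if len(columns) < 2:
            raise FormatError(f"{path}: header has no species columns")
        species_cols = columns[1:]
        seen_ogs: set[str] = set()
        seen_genes: set[str] = set()
        out: list[Orthogroup] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(columns):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(cells)} fields, "
                    f"expected {len(columns)})"
                )
            og_id = cells[0]
            if og_id in seen_ogs:
                raise FormatError(f"{path}:{lineno}: duplicate orthogroup id {og_id}")
            seen_ogs.add(og_id)
            membership: dict[str, list[str]] = {}
            for sp, cell in zip(species_cols, cells[1:]):
                cell = cell.strip()
                if not cell:
                    continue
                genes = [g.strip() for g in cell.split(",")]
                for g in genes:
                    if not g:
                        raise FormatError(
                            f"{path}:{lineno}: empty gene id in column {sp}"
                        )
                    if g in seen_genes:
                        raise FormatError(
                            f"{path}:{lineno}: gene {g} appears in more than "
                            "one orthogroup"
                        )
                    seen_genes.add(g)
                membership[sp] = genes
            out.append(Orthogroup(og_id=og_id, membership=membership))
    return out


def write_orthogroups(
    orthogroups: Sequence[Orthogroup],
    path: Union[str, Path],
    species_order: Sequence[str] | None = None,
) -> None:
    """Write the OrthoFinder dialect; column order is ``species_order`` or
    first-seen order across the input."""
    if species_order is None:
        seen: dict[str, None] = {}
        for og in orthogroups:
            for sp in og.membership:
                seen.setdefault(sp)
        species_order = list(seen)
    lines = ["Orthogroup\t" + "\t".join(species_order)]
    for og in orthogroups:
        cells = [", ".join(og.membership.get(sp, [])) for sp in species_order]
        lines.append(og.og_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# expression tables

_EXPR_HEADER = ["gene_id", "species_id", "tissue", "m_fpkm", "f_fpkm"]


def read_expression(path: Union[str, Path]) -> list[ExpressionRecord]:
    """Read a sexed expression TSV, preserving file order.

    Unknown species are permitted here (cross-validated later against the
    species metadata); negative or non-numeric FPKM is a hard error.
    """
    path = Path(path)
    records: list[ExpressionRecord] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EXPR_HEADER:
            raise FormatError(
                f"{path}: expected header {_EXPR_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields")
            gene_id, species_id, tissue, m_s, f_s = cells
            try:
                m = float(m_s)
                f = float(f_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric FPKM ({m_s!r}, {f_s!r})"
                ) from exc
            try:
                records.append(
                    ExpressionRecord(gene_id, species_id, tissue, m, f)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_expression(
    records: Iterable[ExpressionRecord], path: Union[str, Path]
) -> None:
    lines = ["\t".join(_EXPR_HEADER)]
    for r in records:
        lines.append(
            f"{r.gene_id}\t{r.species_id}\t{r.tissue}\t{r.m_fpkm:.6g}\t{r.f_fpkm:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# species metadata and chromosome maps

_META_HEADER = ["species_id", "order_name", "sex_system", "display_name"]


def read_species_meta(path: Union[str, Path]) -> dict[str, SpeciesMeta]:
    """Read species metadata into an insertion-ordered dict keyed by id."""
    path = Path(path)
    out: dict[str, SpeciesMeta] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _META_HEADER:
            raise FormatError(f"{path}: expected header {_META_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            meta = SpeciesMeta(*cells)
            if meta.species_id in out:
                raise FormatError(
                    f"{path}:{lineno}: duplicate species_id {meta.species_id}"
                )
            out[meta.species_id] = meta
    return out


def write_species_meta(
    meta: Mapping[str, SpeciesMeta] | Iterable[SpeciesMeta],
    path: Union[str, Path],
) -> None:
    items = meta.values() if isinstance(meta, Mapping) else meta
    lines = ["\t".join(_META_HEADER)]
    for m in items:
        lines.append(
            f"{m.species_id}\t{m.order_name}\t{m.sex_system}\t{m.display_name}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_CHROM_HEADER = ["gene_id", "chromosome_class"]


def read_chromosome_map(path: Union[str, Path]) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CHROM_HEADER:
            raise FormatError(f"{path}: expected header {_CHROM_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            gene_id, cls = cells
            if cls not in CHROMOSOME_CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: chromosome_class {cls!r} not one of "
                    f"{sorted(CHROMOSOME_CLASSES)}"
                )
            if gene_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            out[gene_id] = cls
    return out


def write_chromosome_map(mapping: Mapping[str, str], path: Union[str, Path]) -> None:
    lines = ["\t".join(_CHROM_HEADER)]
    for gene_id, cls in mapping.items():
        lines.append(f"{gene_id}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Newick


def _validate_newick_text(text: str) -> str:
    """Balance/termination checks with character offsets, ahead of parsing."""
    depth = 0
    semi_at: int | None = None
    for i, ch in enumerate(text):
        if semi_at is not None and not ch.isspace():
            raise FormatError(
                f"newick: trailing garbage after ';' at offset {i}"
            )
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"newick: unbalanced ')' at offset {i}"
                )
        elif ch == ";":
            if depth != 0:
                raise FormatError(
                    f"newick: ';' at offset {i} inside {depth} open "
                    "parenthesis(es)"
                )
            semi_at = i
    if semi_at is None:
        raise FormatError("newick: missing terminating ';'")
    if depth != 0:
        raise FormatError("newick: unbalanced '(' (unclosed group)")
    return text


def read_newick(source: Union[str, Path]) -> dendropy.Tree:
    """Parse one Newick tree from a path or a literal string.

    Missing branch lengths default to 0; duplicate leaf labels are a hard
    error. Internal node labels are tolerated and kept.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source and os.path.exists(source)
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    _validate_newick_text(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"newick: duplicate leaf labels ({exc})") from exc
    except Exception as exc:
        raise FormatError(f"newick: parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"newick: duplicate leaf labels {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            node.edge.length = 0.0
        elif node.edge.length < 0:
            raise FormatError(
                f"newick: negative branch length on edge above "
                f"{node.taxon.label if node.taxon else 'internal node'}"
            )
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to one Newick line; branch lengths to 10 significant digits."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
        suppress_internal_node_labels=True,
    )
    return text.strip() + "\n"


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf labels in tree traversal order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
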