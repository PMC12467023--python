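"""Desk-scale tree building and comparison.

Distances come from the Jukes–Cantor correction of pairwise mismatch
fractions, trees from canonical neighbor-joining (exact on additive
matrices), congruence from the Robinson–Foulds bipartition metric, and
lineage-specific acceleration from a terminal-branch outlier screen
(ratio to the median of the other terminals, plus a robust z-score on log
lengths). The report formats are tool-agnostic: externally inferred Newick
trees (e.g. maximum-likelihood output) drop straight into ``rf_distance``
and ``terminal_branch_screen``; support values on input trees are carried
but ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import dendropy
import numpy as np
import pandas as pd

from .io_formats import read_newick

__all__ = [
    "CongruenceReport",
    "AccelerationRow",
    "AccelerationReport",
    "jc_distance",
    "jc_distance_matrix",
    "nj_tree",
    "bipartitions",
    "rf_distance",
    "terminal_branch_screen",
]


# ---------------------------------------------------------------------------
# Jukes–Cantor distances


def jc_distance(p: float) -> float:
    """JC69 distance for mismatch fraction p: d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise ValueError(f"mismatch fraction {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(
    alignment: Mapping[str, str],
    on_saturation: Literal["error", "cap"] = "error",
    saturation_cap: float = 5.0,
) -> pd.DataFrame:
    """Symmetric JC distance matrix over an ungapped alignment.

    A pair with mismatch fraction >= 0.75 has no finite JC distance
    (saturation); by default this is a hard error, or the pair is assigned
    ``saturation_cap`` when ``on_saturation='cap'``.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    (L,) = lengths
    if L == 0:
        raise ValueError("zero-length alignment")
    arr = np.vstack(
        [np.frombuffer(alignment[t].encode("ascii"), dtype=np.uint8) for t in taxa]
    )
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.count_nonzero(arr[i] != arr[j])) / L
            if p >= 0.75:
                if on_saturation == "error":
                    raise ValueError(
                        f"pair ({taxa[i]}, {taxa[j]}) saturated: p = {p:.4f}"
                    )
                dij = saturation_cap
            else:
                dij = jc_distance(p)
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=taxa, columns=taxa)


# ---------------------------------------------------------------------------
# neighbor-joining


def _check_matrix(dm: pd.DataFrame) -> None:
    if dm.shape[0] != dm.shape[1] or list(dm.index) != list(dm.columns):
        raise ValueError("distance matrix must be square with matching labels")
    vals = dm.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("distance matrix contains NaN")
    if (vals < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(vals), 0):
        raise ValueError("distance matrix diagonal must be zero")


def nj_tree(dm: pd.DataFrame) -> dendropy.Tree:
    """Canonical neighbor-joining on a labeled distance matrix.

    Joins minimize the Q criterion, breaking ties by the lexicographically
    smallest pair of cluster labels (a cluster is labeled by its smallest
    leaf). Negative branch-length estimates are clamped to zero with the
    deficit moved to the sibling branch, so the output has no negative
    lengths. Returns an unrooted (trifurcating-root) dendropy tree.
    """
    _check_matrix(dm)
    n0 = dm.shape[0]
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.to_numpy(dtype=float).copy()
    # each active node: (tie-break key = smallest contained leaf, newick part)
    keys: list[str] = list(dm.index)
    parts: list[str] = [str(t) for t in dm.index]
    active = list(range(n0))

    def fmt(sub: str, length: float) -> str:
        return f"{sub}:{length:.10g}"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    pair = tuple(sorted((keys[active[a]], keys[active[b]])))
                    if best is None or pair < best:
                        best, bi, bj = pair, a, b
        i, j = active[bi], active[bj]
        dij = sub[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        # distances from the new node u to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for b in range(m):
            k = active[b]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        u = d.shape[0] - 1
        ordered = (i, j) if keys[i] <= keys[j] else (j, i)
        lens = {i: li, j: lj}
        parts.append(
            f"({fmt(parts[ordered[0]], lens[ordered[0]])},"
            f"{fmt(parts[ordered[1]], lens[ordered[1]])})"
        )
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    trio = sorted(((keys[a], a, la), (keys[b], b, lb), (keys[c], c, lc)))
    newick = (
        "("
        + ",".join(fmt(parts[idx], max(l, 0.0)) for _, idx, l in trio)
        + ");"
    )
    tree = read_newick(newick)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Robinson–Foulds


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial leaf bipartitions of an (unrooted) tree.

    Each split is canonicalized as the side not containing the
    lexicographically smallest leaf.
    """
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = labels[0]
    n = len(labels)
    all_set = frozenset(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


@dataclass
class CongruenceReport:
    rf: int
    max_rf: int
    normalized_rf: float
    discordant_splits: list[tuple[str, ...]]


def rf_distance(
    tree_a: dendropy.Tree, tree_b: dendropy.Tree
) -> CongruenceReport:
    """Robinson–Foulds distance on unrooted topologies with identical leaf
    sets; lists the splits present in exactly one tree."""
    la = {l.taxon.label for l in tree_a.leaf_node_iter()}
    lb = {l.taxon.label for l in tree_b.leaf_node_iter()}
    if la != lb:
        raise ValueError(
            "leaf sets differ: only in first "
            f"{sorted(la - lb)}, only in second {sorted(lb - la)}"
        )
    sa, sb = bipartitions(tree_a), bipartitions(tree_b)
    disc = sa ^ sb
    n = len(la)
    max_rf = max(2 * (n - 3), 0)
    rf = len(disc)
    return CongruenceReport(
        rf=rf,
        max_rf=max_rf,
        normalized_rf=(rf / max_rf) if max_rf else 0.0,
        discordant_splits=sorted(tuple(sorted(s)) for s in disc),
    )


# ---------------------------------------------------------------------------
# terminal-branch acceleration screen


@dataclass
class AccelerationRow:
    leaf: str
    terminal_length: float
    ratio: float
    robust_z: float  # NaN when the MAD of the other log-lengths is 0
    flagged: bool


@dataclass
class AccelerationReport:
    rows: list[AccelerationRow]
    ratio_threshold: float
    z_threshold: float
    rule: Literal["and", "or"]

    @property
    def flagged(self) -> list[str]:
        return [r.leaf for r in self.rows if r.flagged]


def terminal_branch_screen(
    tree: dendropy.Tree,
    ratio_threshold: float = 3.0,
    z_threshold: float = 2.0,
    rule: Literal["and", "or"] = "and",
) -> AccelerationReport:
    """Flag leaves whose terminal branch is an outlier among the terminals.

    For each leaf: ratio = terminal length over the median of the other
    terminal lengths; robust z = (log length - median of other log
    lengths) / (1.4826 * MAD of other log lengths). Under the default
    ``and`` rule a leaf is flagged when both statistics exceed their
    thresholds; a degenerate z (MAD 0 or nonpositive lengths) defers to the
    ratio rule alone. Rows come back sorted by ratio, largest first.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 4:
        raise ValueError("need at least 4 leaves")
    lengths = {l.taxon.label: float(l.edge.length or 0.0) for l in leaves}
    vals = np.array(list(lengths.values()))
    if np.median(vals) <= 0:
        raise ValueError("median terminal branch length is not positive")
    rows: list[AccelerationRow] = []
    for leaf, L in lengths.items():
        others = np.array([v for k, v in lengths.items() if k != leaf])
        med = float(np.median(others))
        if med > 0:
            ratio = L / med
        else:
            ratio = math.inf if L > 0 else 0.0
        pos = others[others > 0]
        z = math.nan
        if L > 0 and len(pos) >= 2:
            logs = np.log(pos)
            mad = float(np.median(np.abs(logs - np.median(logs))))
            if mad > 0:
                z = (math.log(L) - float(np.median(logs))) / (1.4826 * mad)
        ratio_hit = ratio >= ratio_threshold
        z_hit = (not math.isnan(z)) and z >= z_threshold
        if math.isnan(z):
            flagged = ratio_hit
        elif rule == "and":
            flagged = ratio_hit and z_hit
        elif rule == "or":
            flagged = ratio_hit or z_hit
        else:
            raise ValueError(f"unknown rule {rule!r}")
        rows.append(AccelerationRow(leaf, L, ratio, z, flagged))
    rows.sort(key=lambda r: (-r.ratio, r.leaf))
    return AccelerationReport(rows, ratio_threshold, z_threshold, rule)
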