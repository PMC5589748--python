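"""Desk-scale phylogenetic placement of receptor proteins.

The production-scale analysis behind a receptor catalogue uses iterative
alignment and maximum-likelihood trees; for a reproducible desk-scale
pipeline this module builds a neighbor-joining tree from simple identity
distances and propagates clade labels from reference leaves.  An externally
computed tree (newick) can be supplied instead, in which case only the label
propagation is used.

Clade vocabulary: 33 numbered clades plus the obligate co-receptor clade
(Orco) — 34 labels in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import parse_newick

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX",
          "XX", "XXI", "XXII", "XXIII", "XXIV", "XXV", "XXVI", "XXVII",
          "XXVIII", "XXIX", "XXX", "XXXI", "XXXII", "XXXIII"]
CLADE_LABELS = _ROMAN + ["Orco"]

PHYLO_MIN_LEN = 200
MIN_SHARED_COLUMNS = 30


@dataclass
class MsaBlock:
    """A protein alignment: equal-length rows with '-' gaps."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class CladeAssignment:
    or_id: str
    clade: str
    support: float


def length_filter_for_phylogeny(proteins, min_len: int = PHYLO_MIN_LEN):
    """Retain proteins of at least ``min_len`` residues (gaps not counted)."""
    return [p for p in proteins if len(p.seq.replace("-", "")) >= min_len]


def gap_trim(msa: MsaBlock, max_gap_fraction: float):
    """Drop columns whose gap fraction exceeds the threshold.

    Returns ``(trimmed_msa, kept_columns)`` where ``kept_columns[i]`` is the
    original index of trimmed column i.
    """
    n = len(msa.rows)
    kept = []
    for c in range(msa.column_count):
        gaps = sum(1 for r in msa.rows if r[c] == "-")
        if gaps / n <= max_gap_fraction:
            kept.append(c)
    if not kept:
        raise ValueError("gap trimming removed every column")
    rows = ["".join(r[c] for c in kept) for r in msa.rows]
    return MsaBlock(taxa=list(msa.taxa), rows=rows), kept


def protein_distance(msa: MsaBlock):
    """Pairwise distance = 1 − identity over mutually non-gap columns.

    Returns ``(D, shared)`` where ``shared[i, j]`` counts the columns used;
    pairs with no shared columns get infinite distance, and pairs under
    ``MIN_SHARED_COLUMNS`` shared columns should be treated as unreliable.
    """
    n = len(msa.rows)
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    gap = ord("-")
    D = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrs[i] != gap) & (arrs[j] != gap)
            ns = int(ok.sum())
            shared[i, j] = shared[j, i] = ns
            if ns == 0:
                D[i, j] = D[j, i] = np.inf
            else:
                ident = float((arrs[i][ok] == arrs[j][ok]).mean())
                D[i, j] = D[j, i] = 1.0 - ident
    return D, shared


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: np.ndarray, taxa: list[str]):
    """Neighbor-joining tree with deterministic tie-breaking.

    ``D`` must be symmetric with zero diagonal and finite entries.  Negative
    branch lengths are clamped to zero with the deficit moved to the sister
    edge.  Returns a dendropy Tree with a trifurcating root (unrooted).
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or \
            not np.allclose(np.diag(D), 0) or not np.isfinite(D).all():
        raise ValueError("distance matrix must be symmetric, finite, zero-diagonal")
    n = D.shape[0]
    if n != len(taxa):
        raise ValueError("taxa count does not match matrix size")
    if n == 1:
        return parse_newick(f"({taxa[0]}:0);")
    if n == 2:
        d = D[0, 1] / 2
        return parse_newick(f"({taxa[0]}:{d:.10g},{taxa[1]}:{d:.10g});")

    # cluster label = lexicographically smallest member leaf (for tie-breaks)
    nodes = [f"{t}" for t in taxa]          # newick fragment per live cluster
    names = list(taxa)                      # canonical name per live cluster
    dist = D.copy()
    active = list(range(n))

    def _join(i, j, li, lj):
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((names[i], names[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _q, _key, i, j = best
        li = dist[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        frag = _join(i, j, li, lj)
        new = len(nodes)
        nodes.append(frag)
        names.append(min(names[i], names[j]))
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dist[new, k] = dist[k, new] = \
                (dist[i, k] + dist[j, k] - dist[i, j]) / 2
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = (dist[i, j] + dist[i, k] - dist[j, k]) / 2
    lj = (dist[i, j] + dist[j, k] - dist[i, k]) / 2
    lk = (dist[i, k] + dist[j, k] - dist[i, j]) / 2
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    newick = (f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},"
              f"{nodes[k]}:{lk:.10g});")
    return parse_newick(newick)


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------

def assign_clades(tree, reference_labels: dict[str, str]) -> list[CladeAssignment]:
    """Propagate reference clade labels to unlabeled leaves.

    Each unlabeled leaf takes the clade of the smallest enclosing subtree
    whose labeled leaves are unanimous (at least two of them; support 1.0).
    Where no such subtree exists the nearest labeled leaf by path length
    decides, with support 0.5; with no labeled leaf in the tree at all the
    leaf is "unassigned".  Reference leaves keep their labels.
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [r for r in reference_labels if r not in leaves]
    if missing:
        raise ValueError(f"reference leaves absent from tree: {missing[:5]}")

    # labeled-leaf tally per internal node, bottom-up
    tally: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = reference_labels.get(node.taxon.label)
            tally[node] = {} if lab is None else {lab: 1}
        else:
            d: dict[str, int] = {}
            for ch in node.child_nodes():
                for lab, c in tally[ch].items():
                    d[lab] = d.get(lab, 0) + c
            tally[node] = d

    pdm = tree.phylogenetic_distance_matrix() if reference_labels else None
    out: list[CladeAssignment] = []
    for name in sorted(leaves):
        if name in reference_labels:
            out.append(CladeAssignment(name, reference_labels[name], 1.0))
            continue
        leaf = leaves[name]
        assigned = None
        node = leaf.parent_node
        blocked = False
        while node is not None and not blocked:
            t = tally[node]
            if len(t) > 1:
                blocked = True
            elif len(t) == 1:
                lab, c = next(iter(t.items()))
                if c >= 2:
                    assigned = CladeAssignment(name, lab, 1.0)
                    break
            node = node.parent_node
        if assigned is None:
            best = None
            for ref in sorted(reference_labels):
                d = pdm.patristic_distance(leaf.taxon, leaves[ref].taxon)
                cand = (d, reference_labels[ref], ref)
                if best is None or cand < best:
                    best = cand
            if best is None:
                assigned = CladeAssignment(name, "unassigned", 0.0)
            else:
                assigned = CladeAssignment(name, best[1], 0.5)
        out.append(assigned)
    return out
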