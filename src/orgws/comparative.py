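"""Cross-species comparison: reciprocal best hits, collinear blocks, tandem
arrays, and the receptor-count vs genome-size correlation.

Collinearity follows the MCScanX parameterisation: homology edges filtered at
E ≤ 1e-5, chains of ≥ MATCH_SIZE (5) anchor pairs with monotone gene ranks on
both scaffolds (descending on one for inverted blocks), scored as
``match_score`` per anchor plus ``gap_penalty`` per skipped rank unit.  The
full MCScanX scoring has tool-specific details; this simplification keeps the
stated parameters and is exactly testable against exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MATCH_SCORE = 50
GAP_PENALTY = -1
MATCH_SIZE = 5
E_CUTOFF = 1e-5


@dataclass(frozen=True)
class HomologyEdge:
    gene_a: str
    gene_b: str
    score: float = 0.0
    evalue: float = 0.0


@dataclass
class CollinearBlock:
    scaffold_a: str
    scaffold_b: str
    anchors: list[tuple[str, str]]
    orientation: str               # same | inverted
    dp_score: float


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def reciprocal_best_hits(score_matrix: np.ndarray, ids_a: list[str],
                         ids_b: list[str]):
    """Classify best-hit relations between two protein sets.

    ``score_matrix[i, j]`` scores A protein i against B protein j (higher is
    better).  Returns ``(rbh_pairs, one_to_many, many_to_many)``:

    - ``rbh_pairs``: list of (a, b) where each is the *unique* best of the other;
    - ``one_to_many``: dict mapping the shared gene to its partner list, for
      best-hit components where one side collects several partners;
    - ``many_to_many``: list of components (sets of genes) not in the first
      two classes.
    """
    S = np.asarray(score_matrix, dtype=float)
    n_a, n_b = S.shape
    best_of_a = {}
    for i in range(n_a):
        row = S[i]
        m = row.max()
        js = np.flatnonzero(row == m)
        best_of_a[i] = set(js.tolist())
    best_of_b = {}
    for j in range(n_b):
        col = S[:, j]
        m = col.max()
        best_of_b[j] = set(np.flatnonzero(col == m).tolist())

    rbh = []
    for i in range(n_a):
        if len(best_of_a[i]) == 1:
            j = next(iter(best_of_a[i]))
            if best_of_b[j] == {i}:
                rbh.append((ids_a[i], ids_b[j]))
    rbh_a = {a for a, _ in rbh}
    rbh_b = {b for _, b in rbh}

    # best-hit digraph over the remaining edges; connected components classify
    edges = set()
    for i in range(n_a):
        for j in best_of_a[i]:
            edges.add((ids_a[i], ids_b[j]))
    for j in range(n_b):
        for i in best_of_b[j]:
            edges.add((ids_a[i], ids_b[j]))
    edges = {(a, b) for a, b in edges
             if not (a in rbh_a or b in rbh_b)}
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    one_to_many: dict[str, list[str]] = {}
    many_to_many: list[set[str]] = []
    for node in sorted(adj):
        if node in seen:
            continue
        comp = set()
        stack = [node]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj.get(x, ()))
        seen |= comp
        comp_a = sorted(x for x in comp if x in set(ids_a))
        comp_b = sorted(x for x in comp if x in set(ids_b))
        if len(comp_a) == 1 and len(comp_b) >= 1:
            one_to_many[comp_a[0]] = comp_b
        elif len(comp_b) == 1 and len(comp_a) >= 1:
            one_to_many[comp_b[0]] = comp_a
        else:
            many_to_many.append(comp)
    return rbh, one_to_many, many_to_many


# ---------------------------------------------------------------------------
# collinear blocks
# ---------------------------------------------------------------------------

def _chain_anchors(anchors: list[tuple[int, int, str, str]], inverted: bool,
                   match_score: float, gap_penalty: float):
    """Best chain by DP over anchors (rank_a asc; rank_b asc or desc)."""
    if not anchors:
        return 0.0, []
    anc = sorted(anchors)
    n = len(anc)
    best = [match_score] * n
    back = [-1] * n
    for i in range(n):
        ra_i, rb_i = anc[i][0], anc[i][1]
        for j in range(i):
            ra_j, rb_j = anc[j][0], anc[j][1]
            if ra_i <= ra_j:
                continue
            if (rb_i <= rb_j) if not inverted else (rb_i >= rb_j):
                continue
            gaps = (ra_i - ra_j - 1) + abs(rb_i - rb_j) - 1
            cand = best[j] + match_score + gap_penalty * gaps
            if cand > best[i]:
                best[i] = cand
                back[i] = j
    i = int(np.argmax(best))
    chain = []
    while i != -1:
        chain.append(anc[i])
        i = back[i]
    chain.reverse()
    return float(max(best)), chain


def collinear_blocks(gene_orders: dict[str, list[str]], edges, *,
                     match_score: float = MATCH_SCORE,
                     gap_penalty: float = GAP_PENALTY,
                     match_size: int = MATCH_SIZE,
                     e_cutoff: float = E_CUTOFF) -> list[CollinearBlock]:
    """Collinear blocks between (and within) scaffolds.

    ``gene_orders`` maps scaffold id to its ranked gene list (rank = position
    in list; ranks must be unique).  Blocks are extracted greedily best-first
    per scaffold pair and orientation; anchors used by one block are excluded
    from later blocks.
    """
    rank: dict[str, tuple[str, int]] = {}
    for scaf, genes in gene_orders.items():
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene in order of {scaf}")
        for r, g in enumerate(genes):
            if g in rank:
                raise ValueError(f"gene {g} appears on two scaffolds")
            rank[g] = (scaf, r)

    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for e in edges:
        if e.evalue > e_cutoff or e.gene_a == e.gene_b:
            continue
        if e.gene_a not in rank or e.gene_b not in rank:
            continue
        (sa, ra), (sb, rb) = rank[e.gene_a], rank[e.gene_b]
        ga, gb = e.gene_a, e.gene_b
        if (sb, rb) < (sa, ra):
            sa, ra, sb, rb = sb, rb, sa, ra
            ga, gb = gb, ga
        by_pair.setdefault((sa, sb), []).append((ra, rb, ga, gb))

    blocks: list[CollinearBlock] = []
    for (sa, sb), anchors in sorted(by_pair.items()):
        pool = sorted(set(anchors))
        for orientation in ("same", "inverted"):
            while True:
                score, chain = _chain_anchors(pool, orientation == "inverted",
                                              match_score, gap_penalty)
                if len(chain) < match_size or score <= 0:
                    break
                blocks.append(CollinearBlock(
                    scaffold_a=sa, scaffold_b=sb,
                    anchors=[(g1, g2) for _, _, g1, g2 in chain],
                    orientation=orientation, dp_score=score))
                used = set(chain)
                pool = [a for a in pool if a not in used]
    return blocks


# ---------------------------------------------------------------------------
# tandem arrays
# ---------------------------------------------------------------------------

def tandem_arrays(gene_order: list[str], edges, *, max_gene_gap: int = 1,
                  e_cutoff: float = E_CUTOFF) -> list[list[str]]:
    """Maximal runs of nearby homologous genes on one scaffold.

    Two genes belong to the same array when they are homologous (an edge at
    E ≤ cutoff, in either orientation) and separated by at most
    ``max_gene_gap`` intervening genes; arrays of size ≥ 2 are reported in
    scaffold order.
    """
    pos = {g: i for i, g in enumerate(gene_order)}
    hom: dict[str, set[str]] = {}
    for e in edges:
        if e.evalue > e_cutoff or e.gene_a == e.gene_b:
            continue
        if e.gene_a in pos and e.gene_b in pos:
            hom.setdefault(e.gene_a, set()).add(e.gene_b)
            hom.setdefault(e.gene_b, set()).add(e.gene_a)
    arrays: list[list[str]] = []
    current: list[str] = []
    for g in gene_order:
        if current and any(
                0 < pos[g] - pos[p] <= max_gene_gap + 1 and g in hom.get(p, ())
                for p in current):
            current.append(g)
        elif current and pos[g] - pos[current[-1]] <= max_gene_gap:
            continue                    # intervening gene; the run stays open
        else:
            if len(current) >= 2:
                arrays.append(current)
            current = [g] if g in hom else []
    if len(current) >= 2:
        arrays.append(current)
    return arrays


# ---------------------------------------------------------------------------
# receptor count vs genome size
# ---------------------------------------------------------------------------

def count_correlation(table, groups: list[str] | None = None):
    """Pearson correlation of receptor count against genome size (Mb).

    ``table`` is a pandas DataFrame with columns ``species``, ``n_or``,
    ``genome_mb`` and ``group``; ``groups`` restricts the rows.  Returns
    ``(r, n_rows)``; ``r`` is NaN when undefined (fewer than 3 rows or zero
    variance).
    """
    df = table
    if groups is not None:
        df = df[df["group"].isin(groups)]
    if len(df) < 3 or df["n_or"].nunique() == 1 or df["genome_mb"].nunique() == 1:
        return float("nan"), len(df)
    r, _p = stats.pearsonr(df["n_or"].to_numpy(dtype=float),
                           df["genome_mb"].to_numpy(dtype=float))
    return float(r), len(df)


def demo_count_table():
    """A small demonstration table (illustrative values, not authoritative).

    Receptor counts and genome sizes for a correlation demo; real analyses
    should supply a table compiled from the literature.
    """
    import pandas as pd
    rows = [
        ("fly_a", 62, 144, "diptera"), ("fly_b", 74, 191, "diptera"),
        ("mosquito_a", 79, 278, "diptera"), ("moth_a", 70, 393, "lepidoptera"),
        ("moth_b", 57, 246, "lepidoptera"), ("bug_a", 106, 720, "hemiptera"),
        ("louse_a", 10, 108, "pthiraptera"), ("roach_a", 134, 3300, "blattodea"),
        ("bee_a", 177, 236, "hymenoptera"), ("bee_b", 112, 290, "hymenoptera"),
        ("ant_a", 352, 296, "hymenoptera"),
    ]
    return pd.DataFrame(rows, columns=["species", "n_or", "genome_mb", "group"])
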