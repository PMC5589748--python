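"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* (full
matrices, exhaustive enumeration, direct counting) rather than against the
package's optimised implementations.
"""

from itertools import combinations

import numpy as np
from Bio.Seq import Seq


def sw_best_score(q: str, t: str, matrix, lookup, gap_open: int,
                  gap_extend: int) -> int:
    """Affine-gap Smith–Waterman best local score, full-matrix reference.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    n, m = len(q), len(t)
    NEG = -10 ** 9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend,
                          H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend,
                          H[i - 1, j] + gap_open + gap_extend)
            s = matrix[lookup[q[i - 1]], lookup[t[j - 1]]]
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, int(H[i, j]))
    return best


def translated_best_score(q: str, dna: str, matrix, lookup, gap_open, gap_extend):
    """Best SW score of a protein against all six frames of a DNA string."""
    best = 0
    for strand_seq in (dna, str(Seq(dna).reverse_complement())):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            best = max(best, sw_best_score(q, prot, matrix, lookup,
                                           gap_open, gap_extend))
    return best


def best_chain_exhaustive(hsps, junction_fn):
    """Best-scoring admissible chain by enumeration over ordered subsets.

    ``junction_fn(a, b)`` returns the junction bonus/penalty or None when the
    join a->b is inadmissible.  HSPs are considered in genomic order; every
    subset whose consecutive joins are admissible is scored as the sum of HSP
    scores plus junction terms.
    """
    order = sorted(range(len(hsps)), key=lambda k: (hsps[k].g_start,
                                                    hsps[k].g_end,
                                                    hsps[k].q_start))
    best = 0.0
    for r in range(1, len(order) + 1):
        for subset in combinations(order, r):
            total = hsps[subset[0]].score
            ok = True
            for a, b in zip(subset, subset[1:]):
                term = junction_fn(hsps[a], hsps[b])
                if term is None:
                    ok = False
                    break
                total += hsps[b].score + term
            if ok:
                best = max(best, float(total))
    return best


def overlap_components(intervals):
    """Transitive closure of pairwise interval overlap (>= 1 unit)."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if min(a[1], b[1]) - max(a[0], b[0]) >= 1:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(frozenset(c) for c in comps.values())


def majority_consensus(preds):
    out = []
    for col in zip(*preds):
        out.append("M" if sum(c == "M" for c in col) >= 2 else "-")
    return "".join(out)


def pearson_direct(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def best_monotone_chain(anchors, inverted, match_score, gap_penalty):
    """Exhaustive best chain over anchors (rank_a, rank_b) pairs."""
    best = (0.0, ())
    idx = sorted(range(len(anchors)), key=lambda k: anchors[k])
    for r in range(1, len(idx) + 1):
        for subset in combinations(idx, r):
            ok = True
            for a, b in zip(subset, subset[1:]):
                ra1, rb1 = anchors[a][:2]
                ra2, rb2 = anchors[b][:2]
                if ra2 <= ra1:
                    ok = False
                    break
                if (rb2 <= rb1) if not inverted else (rb2 >= rb1):
                    ok = False
                    break
            if not ok:
                continue
            score = match_score
            for a, b in zip(subset, subset[1:]):
                gaps = (anchors[b][0] - anchors[a][0] - 1) + \
                    abs(anchors[b][1] - anchors[a][1]) - 1
                score += match_score + gap_penalty * gaps
            if score > best[0]:
                best = (score, subset)
    return best


def random_additive_tree(rng, n_taxa):
    """Random binary tree with branch lengths; returns (newick, D, taxa)."""
    import dendropy
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = {t: t for t in taxa}
    frags = {t: t for t in taxa}
    live = list(taxa)
    while len(live) > 2:
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        a, b = live[i], live[j]
        la, lb = rng.uniform(0.1, 2.0, size=2)
        new = f"({frags[a]}:{la:.6f},{frags[b]}:{lb:.6f})"
        key = a + b
        frags[key] = new
        live = [x for x in live if x not in (a, b)] + [key]
    la, lb = rng.uniform(0.1, 2.0, size=2)
    newick = f"({frags[live[0]]}:{la:.6f},{frags[live[1]]}:{lb:.6f});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    tmap = {t.label: t for t in tree.taxon_namespace}
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = pdm.patristic_distance(tmap[taxa[i]],
                                                       tmap[taxa[j]])
    return newick, D, taxa
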