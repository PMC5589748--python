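"""Spliced protein-to-genome search: translated Smith–Waterman, HSP chaining,
locus selection and locus refinement.

This is a self-contained, exact stand-in for a spliced aligner such as
Exonerate: the query protein is aligned against all six translation frames of a
scaffold with affine-gap local alignment; high-scoring segment pairs (HSPs) are
harvested as non-overlapping local optima by iterative target masking; a sparse
dynamic program then chains colinear HSPs across introns (canonical ``GT..AG``
junctions earn a splice bonus) or across short non-intron gaps (frame-shifted
joins pay a penalty — this is how pseudogene lesions stay inside one locus);
overlapping models are pooled into loci and the best model per locus is kept,
with a relaxed completion pass (PAM250, longer introns, softer gaps) for models
that look incomplete.

Coordinates inside this module are *strand space*: positions on the forward
strand for ``+`` models and on the reverse complement for ``-`` models.
``fwd_interval`` converts back to forward scaffold coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from ._seq import aa_string, encode_aa, encode_nt, load_matrix, revcomp, translate_codes

MIN_INTRON = 40

# Admissible slack when joining HSPs.  Local alignments fray at exon and
# lesion boundaries (AT-rich DNA translates to hydrophobic-leaning peptide, so
# tails drift into introns with weakly positive score); junctions therefore
# tolerate bounded overlap, paid for per overlapped residue, and the exact
# boundary is resolved later against splice signals.
_JOIN_G_OVERLAP = 60       # nt of genomic overlap at a non-intron join
_JOIN_Q_OVERLAP = 30       # residues of query overlap at any join
_JOIN_Q_GAP = 10           # residues of query skipped at a join
_OVERLAP_PENALTY = 2       # per query residue claimed by both HSPs


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters for one search pass.

    ``gap_open`` is charged once per gap in addition to ``gap_extend`` per
    gapped position (a length-k gap costs ``gap_open + k*gap_extend``).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    splice_bonus: int = 10
    frameshift_penalty: int = -20

    def matrix(self) -> np.ndarray:
        return load_matrix(self.matrix_name)


STRICT_SCHEME = ScoringScheme("BLOSUM62", -11, -1)
RELAXED_SCHEME = ScoringScheme("PAM250", -7, -1)


@dataclass
class HSP:
    """A gapped translated local alignment segment (strand-space coordinates)."""

    query_id: str
    scaffold_id: str
    strand: str
    frame: int
    q_start: int
    q_end: int
    g_start: int           # nt, strand space, codon-aligned
    g_end: int
    score: int
    aligned_pairs: list[tuple[int, int]]   # (query residue, codon start nt)
    scaffold_len: int

    def fwd_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.g_start, self.g_end
        return self.scaffold_len - self.g_end, self.scaffold_len - self.g_start


@dataclass
class ChainedModel:
    """An ordered chain of HSPs forming one candidate gene model."""

    query_id: str
    scaffold_id: str
    strand: str
    hsps: list[HSP]
    total_score: float
    junctions: list[dict] = field(default_factory=list)  # between consecutive HSPs
    scaffold_len: int = 0

    @property
    def g_span(self) -> tuple[int, int]:
        return self.hsps[0].g_start, self.hsps[-1].g_end

    def fwd_span(self) -> tuple[int, int]:
        s, e = self.g_span
        if self.strand == "+":
            return s, e
        return self.scaffold_len - e, self.scaffold_len - s

    @property
    def q_coverage(self) -> tuple[int, int]:
        return self.hsps[0].q_start, self.hsps[-1].q_end


@dataclass
class Locus:
    """A pooled group of overlapping models on one scaffold/strand."""

    scaffold_id: str
    strand: str
    span: tuple[int, int]          # forward coordinates
    best: ChainedModel
    models: list[ChainedModel]


# ---------------------------------------------------------------------------
# Smith–Waterman kernels (numba)
# ---------------------------------------------------------------------------
# H and E are full int16 matrices laid out (target, query) so one DP "column"
# (all query rows at one target position) is contiguous in memory.  Masking an
# HSP's target footprint then only requires recomputing target positions until
# the DP state reconverges.  Masked positions are hard barriers: no alignment
# may pass through them.

@njit(cache=True)
def _sw_columns(prof, tcodes, masked, go, ge, H, E, colmax, j0, allow_stop, stop_after):
    qlen = prof.shape[1]
    tlen = tcodes.shape[0]
    NEG = -30000
    for j in range(j0, tlen):
        changed = False
        cmax = 0
        f = NEG
        if masked[j]:
            for i in range(qlen):
                if H[j, i] != 0 or E[j, i] != NEG:
                    changed = True
                H[j, i] = 0
                E[j, i] = NEG
            colmax[j] = 0
        else:
            tc = tcodes[j]
            for i in range(qlen):
                if j > 0:
                    e = E[j - 1, i] + ge
                    t2 = H[j - 1, i] + go + ge
                    if t2 > e:
                        e = t2
                    if e < NEG:
                        e = NEG
                    hd = H[j - 1, i - 1] if i > 0 else 0
                else:
                    e = NEG
                    hd = 0
                if i > 0:
                    t3 = H[j, i - 1] + go + ge
                    fnew = f + ge
                    if t3 > fnew:
                        fnew = t3
                    if fnew < NEG:
                        fnew = NEG
                    f = fnew
                else:
                    f = NEG
                h = hd + prof[tc, i]
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0:
                    h = 0
                if H[j, i] != h or E[j, i] != e:
                    changed = True
                H[j, i] = h
                E[j, i] = e
                if h > cmax:
                    cmax = h
            colmax[j] = cmax
        if allow_stop and j >= stop_after and not changed:
            return j
    return tlen


@njit(cache=True)
def _col_argmax(H, j):
    best = -1
    bi = 0
    for i in range(H.shape[1]):
        if H[j, i] > best:
            best = H[j, i]
            bi = i
    return bi


def _f_column(H, j, go, ge):
    """Recompute the vertical-gap scores F at target position j from H."""
    qlen = H.shape[1]
    NEG = -30000
    F = np.full(qlen, NEG, dtype=np.int32)
    f = NEG
    for i in range(1, qlen):
        f = max(f + ge, int(H[j, i - 1]) + go + ge, NEG)
        F[i] = f
    return F


def _traceback(prof, tcodes, go, ge, H, E, i, j):
    """Walk back from H[j, i]; returns (pairs, q0, q1, t0, t1)."""
    NEG = -30000
    pairs: list[tuple[int, int]] = []
    tmin = tmax = j
    state = "H"
    fcols: dict[int, np.ndarray] = {}
    while True:
        if state == "H":
            h = int(H[j, i])
            if h == 0:
                break
            s = int(prof[tcodes[j], i])
            hd = int(H[j - 1, i - 1]) if i > 0 and j > 0 else 0
            if h == hd + s:
                pairs.append((i, j))
                tmin = min(tmin, j)
                if i == 0 or j == 0:
                    break
                i, j = i - 1, j - 1
                continue
            if h == int(E[j, i]):
                state = "E"
                continue
            if j not in fcols:
                fcols[j] = _f_column(H, j, go, ge)
            if h == int(fcols[j][i]):
                state = "F"
                continue
            raise AssertionError("traceback: inconsistent DP state")
        elif state == "E":
            # gap consuming target position j
            e = int(E[j, i])
            tmin = min(tmin, j)
            prev_e = int(E[j - 1, i]) if j > 0 else NEG
            if j > 0 and e == prev_e + ge:
                j -= 1
                continue
            j -= 1
            state = "H"
        else:  # F: gap consuming query row i
            if j not in fcols:
                fcols[j] = _f_column(H, j, go, ge)
            fv = int(fcols[j][i])
            prev_f = int(fcols[j][i - 1]) if i > 0 else NEG
            if i > 0 and fv == prev_f + ge:
                i -= 1
                continue
            i -= 1
            state = "H"
    pairs.reverse()
    q0, q1 = pairs[0][0], pairs[-1][0] + 1
    return pairs, q0, q1, tmin, tmax + 1


def local_align_hsps(qcodes: np.ndarray, tcodes: np.ndarray, matrix: np.ndarray,
                     gap_open: int, gap_extend: int, min_score: int,
                     max_hsps: int = 200):
    """All non-overlapping local optima of query vs target, by iterative masking.

    Returns a list of ``(score, pairs, q0, q1, t0, t1)`` tuples, best first.
    Each subsequent HSP is the optimal local alignment after the previous
    HSPs' target footprints have been masked out.
    """
    qlen, tlen = len(qcodes), len(tcodes)
    if qlen == 0 or tlen == 0:
        return []
    # prof[sym, i] = score of target symbol `sym` against query residue i
    prof = np.ascontiguousarray(matrix[:, qcodes.astype(np.intp)])
    H = np.zeros((tlen, qlen), dtype=np.int16)
    E = np.full((tlen, qlen), -30000, dtype=np.int16)
    colmax = np.zeros(tlen, dtype=np.int16)
    masked = np.zeros(tlen, dtype=np.bool_)
    _sw_columns(prof, tcodes, masked, gap_open, gap_extend, H, E, colmax,
                0, False, tlen)
    out = []
    for _ in range(max_hsps):
        j = int(np.argmax(colmax))
        score = int(colmax[j])
        if score < min_score:
            break
        i = int(_col_argmax(H, j))
        pairs, q0, q1, t0, t1 = _traceback(prof, tcodes, gap_open, gap_extend,
                                           H, E, i, j)
        out.append((score, pairs, q0, q1, t0, t1))
        masked[t0:t1] = True
        _sw_columns(prof, tcodes, masked, gap_open, gap_extend, H, E, colmax,
                    t0, True, t1)
    return out


def local_protein_score(a: str, b: str, scheme: ScoringScheme = STRICT_SCHEME):
    """Best local alignment of two proteins: ``(score, identity)``.

    Identity is the number of matching aligned residues of the best HSP
    normalised by the *shorter* protein length, so a short chance alignment
    between unrelated proteins cannot look highly identical; 0.0 if nothing
    scores above 0.
    """
    ca, cb = encode_aa(a), encode_aa(b)
    if len(ca) == 0 or len(cb) == 0:
        return 0, 0.0
    hits = local_align_hsps(ca, cb, scheme.matrix(), scheme.gap_open,
                            scheme.gap_extend, min_score=1, max_hsps=1)
    if not hits:
        return 0, 0.0
    score, pairs, *_ = hits[0]
    matches = sum(1 for qi, tj in pairs if ca[qi] == cb[tj])
    return score, matches / min(len(ca), len(cb))


# ---------------------------------------------------------------------------
# translated search
# ---------------------------------------------------------------------------

def translated_local_align(query, scaffold, scheme: ScoringScheme = STRICT_SCHEME,
                           hsp_min_score: int = 40, strands: str = "both") -> list[HSP]:
    """Align a query protein against all six frames of a scaffold.

    ``query``/``scaffold`` carry ``.id`` and ``.seq``.  Returns HSPs with
    strand-space coordinates; within one (strand, frame) the HSPs are
    non-overlapping local optima obtained by iterative masking.
    """
    qseq = query.seq.upper()
    bad = set(qseq) - set("ARNDCQEGHILKMFPSTWYVBZX*")
    if bad:
        raise ValueError(f"query {query.id}: illegal residues {sorted(bad)}")
    if scaffold.length < 3:
        return []
    qcodes = encode_aa(qseq)
    matrix = scheme.matrix()
    out: list[HSP] = []
    strand_list = ["+", "-"] if strands == "both" else [strands]
    for strand in strand_list:
        seq_s = scaffold.seq if strand == "+" else revcomp(scaffold.seq)
        nt = encode_nt(seq_s)
        for frame in range(3):
            tcodes = translate_codes(nt, frame)
            if len(tcodes) == 0:
                continue
            hits = local_align_hsps(qcodes, tcodes, matrix, scheme.gap_open,
                                    scheme.gap_extend, hsp_min_score)
            for score, pairs, q0, q1, t0, t1 in hits:
                out.append(HSP(
                    query_id=query.id, scaffold_id=scaffold.id, strand=strand,
                    frame=frame, q_start=q0, q_end=q1,
                    g_start=frame + 3 * t0, g_end=frame + 3 * t1,
                    score=score,
                    aligned_pairs=[(qi, frame + 3 * tj) for qi, tj in pairs],
                    scaffold_len=scaffold.length))
    out.sort(key=lambda h: (-h.score, h.strand, h.frame, h.g_start))
    return out


# ---------------------------------------------------------------------------
# HSP splitting and chaining
# ---------------------------------------------------------------------------

def _segment_score(pairs, qcodes, seq_nt, matrix, scheme) -> int:
    """Score of a pair-chain segment: diagonal scores plus affine gap costs."""
    total = 0
    for k, (qi, g) in enumerate(pairs):
        aa = translate_codes(seq_nt[g:g + 3])[0]
        total += int(matrix[qcodes[qi], aa])
        if k > 0:
            dq = qi - pairs[k - 1][0]
            dg = (g - pairs[k - 1][1]) // 3
            gap = abs(dg - dq) + (min(dq, dg) - 1)
            if gap > 0:
                total += scheme.gap_open + scheme.gap_extend * gap
    return total


def trim_frayed_pairs(pairs, qcodes, nt, min_drop: int = 3):
    """Cut back both ends of a pair chain where identity falls to background.

    Local alignments drift past exon and lesion boundaries with weak positive
    BLOSUM score but near-random identity; left untrimmed, those tails shadow
    the neighbouring exon's HSP and break chain colinearity.  Each residue
    contributes +1 (exact match) or −1 (mismatch); an end is cut at the
    minimum of the running sum from that end when the minimum reaches
    ``−min_drop``.  Genuinely homologous sequence (identity well above 50%)
    is never cut.  Returns the trimmed pair list (at least one pair kept).
    """
    if len(pairs) < 4:
        return pairs
    vals = []
    for k, (qi, g) in enumerate(pairs):
        v = 2 * int(qcodes[qi] == translate_codes(nt[g:g + 3])[0]) - 1
        if k > 0:
            # gapped tails align only where they match; charge the skips
            dq = qi - pairs[k - 1][0]
            dg = (g - pairs[k - 1][1]) // 3
            v -= (dq - 1) + (dg - 1)
        vals.append(v)

    def cut(vs):
        run = best = 0
        best_k = 0
        for k, v in enumerate(vs):
            run += v
            if run < best:
                best = run
                best_k = k + 1
        return best_k if best <= -min_drop else 0

    head = cut(vals)
    tail_vals = []
    for k in range(len(pairs) - 1, -1, -1):
        qi, g = pairs[k]
        v = 2 * int(qcodes[qi] == translate_codes(nt[g:g + 3])[0]) - 1
        if k < len(pairs) - 1:
            dq = pairs[k + 1][0] - qi
            dg = (pairs[k + 1][1] - g) // 3
            v -= (dq - 1) + (dg - 1)
        tail_vals.append(v)
    tail = cut(tail_vals)
    if head + tail >= len(pairs):
        return pairs
    return pairs[head:len(pairs) - tail]


def _drawdown_split(pairs, qcodes, nt, drop: int = 8):
    """Split a pair chain at internal near-random-identity stretches.

    An in-frame intron read through by the aligner shows up as a long run of
    mismatches *inside* one HSP (no alignment gap, so the skip-based split
    cannot see it).  Using the same +1/−1 match score, any stretch whose
    drawdown from the running peak reaches ``drop`` is excised and the two
    flanks are processed recursively.  Returns a list of pair chains.
    """
    if len(pairs) < 8:
        return [pairs]
    vals = [2 * int(qcodes[qi] == translate_codes(nt[g:g + 3])[0]) - 1
            for qi, g in pairs]
    run = peak = 0
    peak_i = -1
    best = (0, -1, -1)          # (drawdown, peak index, trough index)
    for i, v in enumerate(vals):
        run += v
        if run > peak:
            peak = run
            peak_i = i
        dd = peak - run
        if dd > best[0]:
            best = (dd, peak_i, i)
    if best[0] < drop:
        return [pairs]
    left = pairs[:best[1] + 1]
    right = pairs[best[2] + 1:]
    out = []
    if len(left) >= 2:
        out.extend(_drawdown_split(left, qcodes, nt, drop))
    if len(right) >= 2:
        out.extend(_drawdown_split(right, qcodes, nt, drop))
    return out or [pairs]


def split_hsps_at_introns(hsps: list[HSP], qseq: str, seq_s: str,
                          scheme: ScoringScheme,
                          min_intron: int = MIN_INTRON,
                          trim: bool = True) -> list[HSP]:
    """Chaining preprocessing: split gapped HSPs at intron-sized skips and
    trim frayed ends.

    A long target-side gap inside one SW alignment is an intron in disguise
    (an in-frame intron can be bridged by the aligner as a query gap); the
    chainer needs it as two HSPs so the junction can be modelled as a splice.
    Each resulting segment is end-trimmed with :func:`trim_frayed_pairs` and
    re-scored.
    """
    qcodes = encode_aa(qseq)
    nt = encode_nt(seq_s)
    matrix = scheme.matrix()
    out: list[HSP] = []
    for h in hsps:
        cut_points = [0]
        for k in range(1, len(h.aligned_pairs)):
            dg = h.aligned_pairs[k][1] - h.aligned_pairs[k - 1][1]
            dq = h.aligned_pairs[k][0] - h.aligned_pairs[k - 1][0]
            if dg - 3 * dq >= min_intron or dg >= min_intron + 3:
                cut_points.append(k)
        cut_points.append(len(h.aligned_pairs))
        for a, b in zip(cut_points, cut_points[1:]):
            pieces = [h.aligned_pairs[a:b]]
            if trim:
                pieces = _drawdown_split(pieces[0], qcodes, nt)
                pieces = [trim_frayed_pairs(p, qcodes, nt) for p in pieces]
            for seg in pieces:
                if not seg:
                    continue
                untouched = len(cut_points) == 2 and seg is h.aligned_pairs
                out.append(h if untouched else replace(
                    h, q_start=seg[0][0], q_end=seg[-1][0] + 1,
                    g_start=seg[0][1], g_end=seg[-1][1] + 3,
                    score=_segment_score(seg, qcodes, nt, matrix, scheme),
                    aligned_pairs=seg))
    return out


def junction_term(prev: HSP, nxt: HSP, seq_s: str | None, scheme: ScoringScheme,
                  max_intron: int, min_intron: int = MIN_INTRON):
    """Score contribution and classification of joining ``prev`` -> ``nxt``.

    Returns ``None`` if the junction is inadmissible, else a dict with
    ``kind`` ("intron" | "contiguous" | "frameshift"), ``bonus`` and the gap
    geometry.  ``seq_s`` may be None when splice-site inspection is impossible
    (no sequence at hand); introns then earn no bonus.
    """
    g_gap = nxt.g_start - prev.g_end
    q_gap = nxt.q_start - prev.q_end
    if nxt.g_end <= prev.g_end or nxt.q_end <= prev.q_end:
        return None
    overlap_cost = _OVERLAP_PENALTY * max(0, -q_gap)
    if min_intron <= g_gap <= max_intron and \
            -_JOIN_Q_OVERLAP <= q_gap <= _JOIN_Q_GAP:
        bonus = -overlap_cost
        if seq_s is not None:
            donor = seq_s[prev.g_end:prev.g_end + 2]
            acceptor = seq_s[nxt.g_start - 2:nxt.g_start]
            if donor == "GT" and acceptor == "AG":
                bonus += scheme.splice_bonus
        return {"kind": "intron", "bonus": bonus, "g_gap": g_gap, "q_gap": q_gap}
    if (-_JOIN_G_OVERLAP < g_gap < min_intron
            and -_JOIN_Q_OVERLAP <= q_gap <= _JOIN_Q_GAP):
        delta = g_gap - 3 * q_gap
        if delta % 3 == 0:
            return {"kind": "contiguous", "bonus": -overlap_cost,
                    "g_gap": g_gap, "q_gap": q_gap}
        return {"kind": "frameshift",
                "bonus": scheme.frameshift_penalty - overlap_cost,
                "g_gap": g_gap, "q_gap": q_gap}
    return None


def chain_hsps(hsps: list[HSP], max_intron: int = 2000,
               min_intron: int = MIN_INTRON,
               scheme: ScoringScheme = STRICT_SCHEME,
               seq_s: str | None = None) -> list[ChainedModel]:
    """Maximum-score colinear chains of HSPs (one query/scaffold/strand).

    Sparse DP over HSPs sorted by genomic position; each HSP ends up in at
    most one chain (chains are peeled off best-first).  Junctions follow
    :func:`junction_term`.  Returns chains sorted by descending score.
    """
    if not hsps:
        return []
    ids = {(h.query_id, h.scaffold_id, h.strand) for h in hsps}
    if len(ids) > 1:
        raise ValueError("chain_hsps: HSPs must share query, scaffold and strand")
    order = sorted(range(len(hsps)), key=lambda k: (hsps[k].g_start, hsps[k].g_end,
                                                    hsps[k].q_start))
    remaining = set(order)
    chains: list[ChainedModel] = []
    while remaining:
        idx = [k for k in order if k in remaining]
        best_tot = {k: float(hsps[k].score) for k in idx}
        back: dict[int, int | None] = {k: None for k in idx}
        jterm: dict[int, dict | None] = {k: None for k in idx}
        for pos, k in enumerate(idx):
            for prev in idx[:pos]:
                term = junction_term(hsps[prev], hsps[k], seq_s, scheme,
                                     max_intron, min_intron)
                if term is None:
                    continue
                cand = best_tot[prev] + term["bonus"] + hsps[k].score
                if cand > best_tot[k]:
                    best_tot[k] = cand
                    back[k] = prev
                    jterm[k] = term
        end = max(idx, key=lambda k: (best_tot[k], -hsps[k].g_start))
        members: list[int] = []
        junctions: list[dict] = []
        k: int | None = end
        while k is not None:
            members.append(k)
            if jterm[k] is not None:
                junctions.append(jterm[k])
            k = back[k]
        members.reverse()
        junctions.reverse()
        h0 = hsps[members[0]]
        chains.append(ChainedModel(
            query_id=h0.query_id, scaffold_id=h0.scaffold_id, strand=h0.strand,
            hsps=[hsps[m] for m in members], total_score=best_tot[end],
            junctions=junctions, scaffold_len=h0.scaffold_len))
        remaining -= set(members)
    chains.sort(key=lambda c: (-c.total_score, c.g_span))
    return chains


# ---------------------------------------------------------------------------
# locus selection
# ---------------------------------------------------------------------------

def select_best_per_locus(models: list[ChainedModel]) -> list[Locus]:
    """Pool overlapping models (same scaffold/strand) and keep the best one.

    Pooling is the transitive closure of pairwise span overlap (≥ 1 nt, forward
    coordinates).  Ties: higher score, then longer span, then leftmost start,
    then lexicographic query id.
    """
    groups: dict[tuple[str, str], list[ChainedModel]] = {}
    for m in models:
        groups.setdefault((m.scaffold_id, m.strand), []).append(m)
    loci: list[Locus] = []
    for (scaf, strand), ms in sorted(groups.items()):
        ms_sorted = sorted(ms, key=lambda m: m.fwd_span())
        cluster: list[ChainedModel] = []
        cluster_end = -1
        def flush():
            if not cluster:
                return
            best = min(cluster, key=lambda m: (
                -m.total_score,
                -(m.fwd_span()[1] - m.fwd_span()[0]),
                m.fwd_span()[0],
                m.query_id))
            span = (min(m.fwd_span()[0] for m in cluster),
                    max(m.fwd_span()[1] for m in cluster))
            loci.append(Locus(scaffold_id=scaf, strand=strand, span=span,
                              best=best, models=list(cluster)))
        for m in ms_sorted:
            s, e = m.fwd_span()
            if cluster and s < cluster_end:
                cluster.append(m)
                cluster_end = max(cluster_end, e)
            else:
                flush()
                cluster = [m]
                cluster_end = e
        flush()
    loci.sort(key=lambda l: (l.scaffold_id, l.span, l.strand))
    return loci


# ---------------------------------------------------------------------------
# refinement (completion pass)
# ---------------------------------------------------------------------------

def hsp_identity(hsp: HSP, qcodes: np.ndarray, nt: np.ndarray) -> float:
    """Fraction of aligned pairs whose residues match exactly."""
    match = 0
    for qi, g in hsp.aligned_pairs:
        match += int(qcodes[qi] == translate_codes(nt[g:g + 3])[0])
    return match / len(hsp.aligned_pairs) if hsp.aligned_pairs else 0.0


def model_identity(model: ChainedModel, qseq: str, seq_s: str) -> float:
    """Per-residue identity of a model over its aligned pairs."""
    qcodes = encode_aa(qseq)
    nt = encode_nt(seq_s)
    match = total = 0
    for h in model.hsps:
        for qi, g in h.aligned_pairs:
            aa = translate_codes(nt[g:g + 3])[0]
            match += int(qcodes[qi] == aa)
            total += 1
    return match / total if total else 0.0


def looks_complete(model: ChainedModel, qlen: int) -> bool:
    q0, q1 = model.q_coverage
    if q0 > 5 or q1 < qlen - 5:
        return False
    for a, b in zip(model.hsps, model.hsps[1:]):
        if b.q_start - a.q_end >= 15:
            return False
    return True


def refine_locus(locus: Locus, scaffolds: dict[str, "object"],
                 queries: dict[str, str],
                 scheme: ScoringScheme = RELAXED_SCHEME,
                 max_intron: int = 10000, pad: int = 20000,
                 hsp_min_score: int = 40,
                 min_identity: float = 0.3) -> Locus:
    """Completion pass: re-search the locus window with relaxed parameters.

    The refined model replaces the original only if it scores higher under the
    relaxed scheme than the original's relaxed re-score, or extends query
    coverage without dropping identity below ``min_identity``.  Models that
    already look complete are returned unchanged.
    """
    model = locus.best
    qseq = queries[model.query_id]
    scaffold = scaffolds[model.scaffold_id]
    if looks_complete(model, len(qseq)):
        return locus
    L = scaffold.length
    fs, fe = model.fwd_span()
    ws, we = max(0, fs - pad), min(L, fe + pad)
    window_fwd = scaffold.seq[ws:we]

    class _Win:
        id = scaffold.id
        seq = window_fwd if model.strand == "+" else revcomp(window_fwd)
        length = we - ws

    class _Q:
        id = model.query_id
        seq = qseq

    hsps = translated_local_align(_Q, _Win, scheme, hsp_min_score,
                                  strands=model.strand)
    # restrict to the searched strand's own orientation, shift into scaffold
    # strand space: window strand-space offset
    off = ws if model.strand == "+" else L - we
    shifted: list[HSP] = []
    for h in hsps:
        if h.strand != model.strand:
            continue
        shifted.append(replace(
            h, g_start=h.g_start + off, g_end=h.g_end + off,
            aligned_pairs=[(qi, g + off) for qi, g in h.aligned_pairs],
            scaffold_len=L))
    seq_s = scaffold.seq if model.strand == "+" else revcomp(scaffold.seq)
    shifted = split_hsps_at_introns(shifted, qseq, seq_s, scheme)
    # the completion pass looks for weak exons of the *same* gene; distant
    # paralogs in the window (family members align too) are excluded by an
    # identity floor so chains cannot become cross-gene chimeras
    qcodes_f = encode_aa(qseq)
    nt_f = encode_nt(seq_s)
    shifted = [h for h in shifted
               if len(h.aligned_pairs) >= 8
               and hsp_identity(h, qcodes_f, nt_f) >= 0.5]
    cands = chain_hsps(shifted, max_intron=max_intron, scheme=scheme, seq_s=seq_s)
    # only consider candidates overlapping the original locus
    cands = [c for c in cands
             if c.fwd_span()[0] < fe and c.fwd_span()[1] > fs]
    if not cands:
        return locus
    cand = cands[0]
    old_q0, old_q1 = model.q_coverage
    new_q0, new_q1 = cand.q_coverage
    # a completion pass must never give up existing coverage
    keeps_coverage = new_q0 <= old_q0 + 5 and new_q1 >= old_q1 - 5
    extends = new_q0 <= old_q0 and new_q1 >= old_q1 and \
        (new_q1 - new_q0) > (old_q1 - old_q0)
    better = cand.total_score > rescore_model(model, qseq, seq_s, scheme) \
        and keeps_coverage
    if better or (extends and model_identity(cand, qseq, seq_s) >= min_identity):
        return Locus(scaffold_id=locus.scaffold_id, strand=locus.strand,
                     span=(min(locus.span[0], cand.fwd_span()[0]),
                           max(locus.span[1], cand.fwd_span()[1])),
                     best=cand, models=locus.models + [cand])
    return locus


def rescore_model(model: ChainedModel, qseq: str, seq_s: str,
                  scheme: ScoringScheme) -> float:
    """Re-score an existing chain under a different scoring scheme."""
    qcodes = encode_aa(qseq)
    nt = encode_nt(seq_s)
    matrix = scheme.matrix()
    total = 0.0
    for h in model.hsps:
        total += _segment_score(h.aligned_pairs, qcodes, nt, matrix, scheme)
    for j in model.junctions:
        total += j["bonus"] if j["kind"] == "intron" else \
            (0 if j["kind"] == "contiguous" else scheme.frameshift_penalty)
    return total


# ---------------------------------------------------------------------------
# whole-genome survey
# ---------------------------------------------------------------------------

def survey_genome(scaffolds, queries, scheme: ScoringScheme = STRICT_SCHEME,
                  max_intron: int = 2000, hsp_min_score: int = 40,
                  min_chain_score: int = 120, refine: bool = True,
                  relaxed_scheme: ScoringScheme = RELAXED_SCHEME,
                  max_intron_relaxed: int = 10000,
                  min_model_identity: float = 0.45) -> list[Locus]:
    """Run the full search: align every query to every scaffold, chain, pool
    into loci, and run the completion pass on incomplete models.

    ``min_chain_score`` suppresses background-level chains (a single spurious
    HSP passes ``hsp_min_score`` far too often on megabase genomes); real
    models score far above it.
    """
    scaffold_map = {s.id: s for s in scaffolds}
    query_map = {q.id: q.seq for q in queries}
    models: list[ChainedModel] = []
    rc_cache: dict[str, str] = {}
    for scaffold in scaffolds:
        rc_cache[scaffold.id] = revcomp(scaffold.seq)
        for query in queries:
            hsps = translated_local_align(query, scaffold, scheme, hsp_min_score)
            by_strand: dict[str, list[HSP]] = {"+": [], "-": []}
            for h in hsps:
                by_strand[h.strand].append(h)
            for strand, group in by_strand.items():
                if not group:
                    continue
                seq_s = scaffold.seq if strand == "+" else rc_cache[scaffold.id]
                group = split_hsps_at_introns(group, query.seq, seq_s, scheme)
                for chain in chain_hsps(group, max_intron=max_intron,
                                        scheme=scheme, seq_s=seq_s):
                    if chain.total_score < min_chain_score:
                        continue
                    # background-identity chains (cross-family shadows and
                    # drift) are excluded before pooling: a low-identity
                    # model spanning two tandem copies must not weld their
                    # loci together
                    if model_identity(chain, query.seq, seq_s) < min_model_identity:
                        continue
                    models.append(chain)
    loci = select_best_per_locus(models)
    loci = suppress_shadow_loci(loci)
    if refine:
        loci = [refine_locus(l, scaffold_map, query_map, relaxed_scheme,
                             max_intron=max_intron_relaxed,
                             hsp_min_score=hsp_min_score)
                for l in loci]
        # refinement can grow spans; re-pool so overlapping refined models
        # collapse back to one locus each
        loci = suppress_shadow_loci(select_best_per_locus(
            [l.best for l in loci]))
    return loci


def suppress_shadow_loci(loci: list[Locus], frac: float = 0.5) -> list[Locus]:
    """Drop a locus dominated by a higher-scoring opposite-strand locus.

    Reverse-complemented coding sequence keeps enough compositional bias to
    align family queries weakly; such shadows overlap a real gene's span on
    the other strand and never outscore it.  A locus is removed when an
    opposite-strand locus with a higher-scoring model overlaps it by at least
    ``frac`` of the smaller span.
    """
    keep = []
    for lo in loci:
        dominated = False
        for other in loci:
            if other is lo or other.scaffold_id != lo.scaffold_id \
                    or other.strand == lo.strand:
                continue
            ov = min(lo.span[1], other.span[1]) - max(lo.span[0], other.span[0])
            smaller = min(lo.span[1] - lo.span[0],
                          other.span[1] - other.span[0])
            if ov >= frac * smaller and \
                    other.best.total_score > lo.best.total_score:
                dominated = True
                break
        if not dominated:
            keep.append(lo)
    return keep
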