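"""From chained alignments to curated gene models.

The chainer delivers colinear HSP chains whose boundaries fray by a few
codons (local alignment drifts into introns, and frays around lesions).  This
module resolves every junction against the genomic sequence — choosing the
donor/acceptor pair (``GT..AG``) or the contiguous/frameshift join that best
explains the query — then builds the CDS and protein, classifies integrity
(complete / partial; pseudogene orthogonally), renders hypothetical proteins
(``X`` at stop/frameshift lesions, ``Z`` runs for missing internal residues),
assigns orthology-based names against a reference set, and produces the
survey summary table.

Naming scheme: reciprocal best pairs inherit the reference number
(``DnOr5``); one-directional best hits are suffixed ``like``; several new
proteins sharing one best reference get ``_i`` in descending similarity;
partial models append ``N``/``C``/``F``/``N_C``/``N_F``/``F_C`` (the letter
names the portion that is present); pseudogenes append ``P`` last; proteins
under 35% identity to every reference receive fresh numbers from 180.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from ._seq import AA_ALPHABET, aa_string, encode_aa, encode_nt, translate_codes
from .io_formats import GffRecord, internal_to_gff
from .spliced_search import (MIN_INTRON, STRICT_SCHEME, ChainedModel, Locus,
                             ScoringScheme, local_protein_score)

NEW_NUMBER_START = 180
NEW_NUMBER_IDENTITY = 0.35
FRAGMENT_GAP = 15          # residues of internal query coverage gap
COMPLETE_LEN = 370         # longer proteins count as complete regardless


@dataclass
class GeneModel:
    """A curated gene model (forward-coordinate exons, ascending)."""

    name: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    protein: str                    # may contain * (stop), X, Z
    best_query_id: str
    integrity: str = "complete"     # complete | partial
    terminus_flags: dict = field(default_factory=dict)
    pseudo: bool = False
    lesions: list[tuple[str, int]] = field(default_factory=list)
    score: float = 0.0

    @property
    def protein_for_analysis(self) -> str:
        """Hypothetical protein: lesions rendered as X (used downstream)."""
        return self.protein.replace("*", "X")


# ---------------------------------------------------------------------------
# junction resolution
# ---------------------------------------------------------------------------

@dataclass
class _Seg:
    pairs: list[tuple[int, int]]    # (query residue, codon start), strand space

    @property
    def g_start(self) -> int:
        return self.pairs[0][1]

    @property
    def g_end(self) -> int:
        return self.pairs[-1][1] + 3

    @property
    def q_start(self) -> int:
        return self.pairs[0][0]

    @property
    def q_end(self) -> int:
        return self.pairs[-1][0] + 1


def _pair_scores(pairs, qcodes, nt, matrix):
    out = []
    for qi, g in pairs:
        aa = translate_codes(nt[g:g + 3])[0]
        out.append(int(matrix[qcodes[qi], aa]))
    return out


def _resolve_junction(A: _Seg, B: _Seg, seq_s: str, nt, qcodes, matrix,
                      scheme: ScoringScheme, min_intron: int = MIN_INTRON):
    """Choose the best boundary pair between two segments and trim/extend them.

    Returns a junction record ``{kind, donor, acceptor, q_gap}`` with
    strand-space coordinates; mutates A and B in place.
    """
    L = len(seq_s)
    q_overlap = max(0, A.q_end - B.q_start)
    win = 3 * (q_overlap + 5) + 9

    # --- A side: prefix score as a function of the donor position d ----------
    a_scores = _pair_scores(A.pairs, qcodes, nt, matrix)
    a_prefix = np.concatenate([[0], np.cumsum(a_scores)])
    a_gpos = [g for _, g in A.pairs]

    def a_side(d):
        """(score, q_end) of A trimmed/extended to end at d."""
        n_keep = bisect_right(a_gpos, d - 3)
        lo = bisect_left(a_gpos, A.g_end - win - 3)
        s = float(a_prefix[n_keep] - a_prefix[lo])
        if n_keep == 0:
            return -1e9, A.q_start
        q_end = A.pairs[n_keep - 1][0] + 1
        g_end = A.pairs[n_keep - 1][1] + 3
        if n_keep == len(A.pairs):        # extrapolate past the last pair
            qlen = len(qcodes)
            g, qi = g_end, q_end
            while g + 3 <= d and qi < qlen and g + 3 <= L:
                s += int(matrix[qcodes[qi], translate_codes(nt[g:g + 3])[0]])
                g += 3
                qi += 1
            q_end = qi
        return s, q_end

    b_scores = _pair_scores(B.pairs, qcodes, nt, matrix)
    b_suffix = np.concatenate([np.cumsum(b_scores[::-1])[::-1], [0]])
    b_gpos = [g for _, g in B.pairs]

    def b_side(a):
        """(score, q_start) of B trimmed/extended to start at a."""
        n_skip = bisect_left(b_gpos, a)
        hi = bisect_right(b_gpos, B.g_start + win)
        s = float(b_suffix[n_skip] - b_suffix[hi])
        if n_skip == len(B.pairs):
            return -1e9, B.q_end
        q_start = B.pairs[n_skip][0]
        g_start = B.pairs[n_skip][1]
        if n_skip == 0:                   # extrapolate before the first pair
            g, qi = g_start - 3, q_start - 1
            while g >= a and qi >= 0:
                s += int(matrix[qcodes[qi], translate_codes(nt[g:g + 3])[0]])
                g -= 3
                qi -= 1
            q_start = qi + 1
        return s, q_start

    def gap_term(q_end, q_start):
        # a query residue claimed by both sides would be scored twice; the
        # penalty must exceed a typical exact-match score to neutralise that
        gq = q_start - q_end
        return -6.0 * (-gq) if gq < 0 else -1.0 * gq

    candidates = []
    # intron candidates: donor GT, acceptor AG, intron >= min_intron.  The
    # inward windows must cover boundary drift even when only one side
    # frayed (90 nt base width plus the query-overlap span); the outward
    # windows must cover residues lost to over-trimming (the unaccounted
    # query gap), recovered by extrapolation during scoring.
    q_missing = max(0, B.q_start - A.q_end)
    d_lo = max(A.g_start + 3, A.g_end - 3 * q_overlap - 90)
    d_hi = min(L - 2, A.g_end + 3 * q_missing + 7)
    a_lo = max(2, B.g_start - 3 * q_missing - 6)
    a_hi = min(L, B.g_end - 3, B.g_start + 3 * q_overlap + 91)
    donors = [d for d in range(d_lo, d_hi) if seq_s[d:d + 2] == "GT"]
    acceptors = [a for a in range(a_lo, a_hi) if seq_s[a - 2:a] == "AG"]
    for d in donors:
        sa, qe = a_side(d)
        for a in acceptors:
            if a - d < min_intron:
                continue
            sb, qs = b_side(a)
            s = sa + sb + gap_term(qe, qs) + scheme.splice_bonus
            candidates.append((s, -(abs(d - A.g_end) + abs(a - B.g_start)),
                               d, a, "intron", qe, qs))
    # contiguous / frameshift candidates (grid-aligned, small genomic gap)
    if B.g_start - A.g_end < min_intron:
        for kd in range(0, q_overlap + 3):
            d = A.g_end - 3 * kd
            if d <= A.g_start:
                break
            sa, qe = a_side(d)
            for ka in range(0, q_overlap + 3):
                a = B.g_start + 3 * ka
                if a >= B.g_end:
                    break
                if a < d or a - d >= min_intron:
                    continue
                sb, qs = b_side(a)
                kind = "contiguous" if (a - d) % 3 == 0 else "frameshift"
                s = sa + sb + gap_term(qe, qs) + \
                    (scheme.frameshift_penalty if kind == "frameshift" else 0)
                candidates.append((s, -(3 * kd + 3 * ka), d, a, kind, qe, qs))
    if not candidates:
        # fallback: keep boundaries, drop B pairs overlapping A in the query
        B.pairs = [p for p in B.pairs if p[0] >= A.q_end]
        return {"kind": "intron", "donor": A.g_end, "acceptor": B.g_start,
                "q_gap": max(0, (B.q_start if B.pairs else A.q_end) - A.q_end),
                "canonical": False}
    s, _tie, d, a, kind, qe, qs = max(candidates)
    _apply_boundary(A, d, qcodes, nt, L, side="end")
    _apply_boundary(B, a, qcodes, nt, L, side="start")
    return {"kind": kind, "donor": d, "acceptor": a,
            "q_gap": max(0, qs - qe), "canonical": kind == "intron"}


def _apply_boundary(seg: _Seg, pos: int, qcodes, nt, L, side: str) -> None:
    qlen = len(qcodes)
    if side == "end":
        keep = [p for p in seg.pairs if p[1] + 3 <= pos]
        if keep and keep[-1] == seg.pairs[-1]:
            qi, g = keep[-1][0] + 1, keep[-1][1] + 3
            while g + 3 <= pos and qi < qlen and g + 3 <= L:
                keep.append((qi, g))
                qi += 1
                g += 3
        seg.pairs = keep or seg.pairs[:1]
    else:
        keep = [p for p in seg.pairs if p[1] >= pos]
        if keep and keep[0] == seg.pairs[0]:
            qi, g = keep[0][0] - 1, keep[0][1] - 3
            ext = []
            while g >= pos and qi >= 0:
                ext.append((qi, g))
                qi -= 1
                g -= 3
            keep = ext[::-1] + keep
        seg.pairs = keep or seg.pairs[-1:]


def _trim_terminal_fray(seg: _Seg, qcodes, nt, head: bool,
                        min_drop: int = 3) -> None:
    """Trim a frayed model terminus.

    Local alignment drifts past the true gene boundary into non-coding
    sequence with weak positive BLOSUM score but near-random identity; the
    terminus is cut at the minimum of a running +1/−1 (match/mismatch) sum
    from that end, when the drop reaches ``min_drop``.  Internal boundaries
    are handled by junction resolution instead.
    """
    pairs = seg.pairs if head else seg.pairs[::-1]
    sign = 1 if head else -1
    run = best = 0
    k = 0
    for i, (qi, g) in enumerate(pairs):
        v = 2 * int(qcodes[qi] == translate_codes(nt[g:g + 3])[0]) - 1
        if i > 0:
            dq = sign * (qi - pairs[i - 1][0])
            dg = sign * (g - pairs[i - 1][1]) // 3
            v -= (dq - 1) + (dg - 1)
        run += v
        if run < best:
            best = run
            k = i + 1
    if best > -min_drop:
        k = 0
    if 0 < k < len(seg.pairs) - 1:
        seg.pairs = seg.pairs[k:] if head else seg.pairs[:-k]


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_cds(model: ChainedModel, scaffold, query_seq: str,
              scheme: ScoringScheme = STRICT_SCHEME):
    """Materialise a chain: resolve junctions, extend termini, build CDS.

    Returns ``(cds_seq, protein, terminus_flags, exons_fwd, junctions)``.
    ``protein`` contains ``*`` at in-frame stops, ``X`` at frameshift
    breakpoints and ``Z`` runs where internal query residues are uncovered.
    The stop codon, when found immediately downstream, is included in the
    final exon (and CDS) but not in the protein.
    """
    from ._seq import revcomp
    seq_s = scaffold.seq if model.strand == "+" else revcomp(scaffold.seq)
    nt = encode_nt(seq_s)
    qcodes = encode_aa(query_seq)
    qlen = len(qcodes)
    matrix = scheme.matrix()
    L = len(seq_s)

    segs = [_Seg(pairs=list(h.aligned_pairs)) for h in model.hsps]
    _trim_terminal_fray(segs[0], qcodes, nt, head=True)
    _trim_terminal_fray(segs[-1], qcodes, nt, head=False)
    junctions = []
    for A, B in zip(segs, segs[1:]):
        junctions.append(_resolve_junction(A, B, seq_s, nt, qcodes, matrix, scheme))

    # terminal completion: pull the alignment to the query ends when close
    first, last = segs[0], segs[-1]
    if 0 < first.q_start <= 5:
        qi, g = first.q_start - 1, first.g_start - 3
        ext = []
        while qi >= 0 and g >= 0:
            ext.append((qi, g))
            qi -= 1
            g -= 3
        first.pairs = ext[::-1] + first.pairs
    if 0 < qlen - last.q_end <= 5:
        qi, g = last.q_end, last.g_end
        while qi < qlen and g + 3 <= L:
            last.pairs.append((qi, g))
            qi += 1
            g += 3

    # stop codon immediately after the final exon joins the CDS
    has_stop = False
    stop_ext = 0
    g = last.g_end
    if g + 3 <= L and aa_string(translate_codes(nt[g:g + 3])) == "*":
        has_stop = True
        stop_ext = 3

    # group segments into exons (introns separate; lesion joins merge)
    exon_bounds: list[tuple[int, int]] = []
    protein_parts: list[str] = []
    lesions: list[tuple[str, int]] = []
    cur_start = segs[0].g_start
    plen = 0
    for idx, seg in enumerate(segs):
        trans = aa_string(translate_codes(nt[seg.g_start:seg.g_end]))
        if idx > 0:
            j = junctions[idx - 1]
            if j["kind"] == "intron":
                exon_bounds.append((cur_start, segs[idx - 1].g_end))
                cur_start = seg.g_start
                if j["q_gap"] > 0:
                    protein_parts.append("Z" * j["q_gap"])
                    plen += j["q_gap"]
            elif j["kind"] == "frameshift":
                protein_parts.append("X")
                lesions.append(("frameshift", plen))
                plen += 1
            else:  # contiguous: translate any in-frame inserted codons
                gap_nt = seg.g_start - segs[idx - 1].g_end
                if gap_nt > 0:
                    extra = aa_string(translate_codes(
                        nt[segs[idx - 1].g_end:seg.g_start]))
                    protein_parts.append(extra)
                    plen += len(extra)
        protein_parts.append(trans)
        plen += len(trans)
    exon_bounds.append((cur_start, segs[-1].g_end + stop_ext))

    protein = "".join(protein_parts)
    for m in re.finditer(r"\*", protein):
        lesions.append(("inframe_stop", m.start()))
    lesions.sort(key=lambda x: x[1])

    cds_seq = "".join(seq_s[s:e] for s, e in exon_bounds)
    q0, q1 = segs[0].q_start, segs[-1].q_end
    fragmented = any(j["kind"] == "intron" and j["q_gap"] >= FRAGMENT_GAP
                     for j in junctions)
    flags = {
        "has_start_codon": cds_seq.startswith("ATG"),
        "has_stop_codon": has_stop,
        "n_terminus_present": q0 <= 5,
        "c_terminus_present": q1 >= qlen - 5,
        "fragmented": fragmented,
    }
    if model.strand == "+":
        exons_fwd = sorted(exon_bounds)
    else:
        exons_fwd = sorted((L - e, L - s) for s, e in exon_bounds)
    return cds_seq, protein, flags, exons_fwd, lesions


def classify_integrity(gm: GeneModel) -> GeneModel:
    """Set pseudo/integrity from the built protein, flags and lesions.

    Pseudogene status (in-frame stop or frameshift) is orthogonal to the
    complete/partial classification; proteins longer than 370 aa count as
    complete even with a terminus missing.
    """
    f = gm.terminus_flags
    gm.pseudo = bool(gm.lesions)
    prot_len = len(gm.protein.replace("Z", ""))
    intact = (f.get("n_terminus_present") and f.get("c_terminus_present")
              and not f.get("fragmented"))
    gm.integrity = "complete" if (intact or prot_len > COMPLETE_LEN) else "partial"
    return gm


def build_gene_model(locus: Locus, scaffold, query_seq: str,
                     scheme: ScoringScheme = STRICT_SCHEME) -> GeneModel:
    model = locus.best
    cds, protein, flags, exons, lesions = build_cds(model, scaffold, query_seq,
                                                    scheme)
    gm = GeneModel(
        name="", scaffold_id=model.scaffold_id, strand=model.strand,
        exons=exons, cds_seq=cds, protein=protein,
        best_query_id=model.query_id, terminus_flags=flags, lesions=lesions,
        score=model.total_score)
    return classify_integrity(gm)


def make_hypothetical_protein(gm: GeneModel) -> str:
    """Render the pseudogene protein: X at each stop/frameshift lesion.

    Z runs (missing internal residues) are already present from construction.
    Returns the protein unchanged when there are no lesions.
    """
    if not gm.lesions:
        return gm.protein
    return gm.protein.replace("*", "X")


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def _ref_number(ref_id: str) -> str:
    m = re.search(r"(\d+)$", ref_id)
    return m.group(1) if m else ref_id


def partial_suffix(flags: dict) -> str:
    n, c = flags.get("n_terminus_present"), flags.get("c_terminus_present")
    frag = flags.get("fragmented")
    if n and c:
        return "N_C" if frag else ""
    if n:
        return "N_F" if frag else "N"
    if c:
        return "F_C" if frag else "C"
    return "F"


def assign_names(models: list[GeneModel], references: dict[str, str],
                 prefix: str = "Or") -> list[GeneModel]:
    """Deterministic orthology naming against a reference protein set.

    Similarity is the local-alignment score (BLOSUM62) between the model's
    analysis protein and each reference; ties break by identity, then by
    reference name.  The result is independent of the input order.
    """
    order = sorted(range(len(models)),
                   key=lambda i: (models[i].scaffold_id, models[i].exons[0][0]
                                  if models[i].exons else 0, models[i].strand))
    ref_ids = sorted(references)
    scores = np.zeros((len(models), len(ref_ids)))
    idents = np.zeros_like(scores)
    for i, gm in enumerate(models):
        prot = gm.protein_for_analysis.replace("Z", "")
        for j, rid in enumerate(ref_ids):
            s, ident = local_protein_score(prot, references[rid])
            scores[i, j] = s
            idents[i, j] = ident

    best_ref: dict[int, int] = {}
    for i in range(len(models)):
        j = max(range(len(ref_ids)),
                key=lambda j: (scores[i, j], idents[i, j], -j))
        best_ref[i] = j
    ref_best: dict[int, int] = {}
    for j in range(len(ref_ids)):
        if not len(models):
            break
        i = max(range(len(models)),
                key=lambda i: (scores[i, j], idents[i, j],
                               -order.index(i)))
        ref_best[j] = i

    groups: dict[int, list[int]] = {}
    fresh: list[int] = []
    for i in range(len(models)):
        j = best_ref[i]
        if idents[i, j] < NEW_NUMBER_IDENTITY:
            fresh.append(i)
        else:
            groups.setdefault(j, []).append(i)

    base: dict[int, str] = {}
    for j, members in sorted(groups.items()):
        members.sort(key=lambda i: (-scores[i, j], -idents[i, j], order.index(i)))
        num = _ref_number(ref_ids[j])
        for rank, i in enumerate(members, start=1):
            reciprocal = ref_best.get(j) == i
            stem = num + ("" if reciprocal else "like")
            if len(members) > 1:
                stem += f"_{rank}"
            base[i] = stem
    next_new = NEW_NUMBER_START
    for i in sorted(fresh, key=lambda i: order.index(i)):
        base[i] = str(next_new)
        next_new += 1

    used: set[str] = set()
    for i, gm in enumerate(models):
        name = prefix + base[i]
        if gm.integrity == "partial":
            name += partial_suffix(gm.terminus_flags)
        if gm.pseudo:
            name += "P"
        if name in used:
            raise RuntimeError(f"duplicate gene name {name!r}")
        used.add(name)
        gm.name = name
    return models


# ---------------------------------------------------------------------------
# survey summary
# ---------------------------------------------------------------------------

@dataclass
class SurveySummary:
    total: int = 0
    complete: int = 0
    partial: int = 0
    pseudogenes: int = 0
    novel: int = 0
    differing: int = 0
    identical: int = 0

    def as_dict(self) -> dict:
        return dict(total=self.total, complete=self.complete,
                    partial=self.partial, pseudogenes=self.pseudogenes,
                    novel=self.novel, differing=self.differing,
                    identical=self.identical)


def summarize_survey(models: list[GeneModel],
                     reference_gff: list[GffRecord] | None = None) -> SurveySummary:
    """Table-1 style accounting; novelty is judged against a reference
    annotation by same-strand overlap and exon-set equality."""
    s = SurveySummary(total=len(models))
    for gm in models:
        if gm.integrity == "complete":
            s.complete += 1
        else:
            s.partial += 1
        if gm.pseudo:
            s.pseudogenes += 1
    ref_genes: list[tuple[str, str, list[tuple[int, int]]]] = []
    if reference_gff:
        from .io_formats import group_gff_genes
        for gid, b in group_gff_genes(reference_gff).items():
            exons = sorted(r.interval for r in (b["cds"] or b["exon"]))
            if exons:
                ref_genes.append((b["scaffold_id"], b["strand"], exons))
    for gm in models:
        span = (gm.exons[0][0], gm.exons[-1][1])
        overlapping = [
            rg for rg in ref_genes
            if rg[0] == gm.scaffold_id and rg[1] == gm.strand
            and rg[2][0][0] < span[1] and rg[2][-1][1] > span[0]]
        if not overlapping:
            s.novel += 1
        elif any(rg[2] == sorted(gm.exons) for rg in overlapping):
            s.identical += 1
        else:
            s.differing += 1
    return s


def models_to_gff(models: list[GeneModel], source: str = "orgws") -> list[GffRecord]:
    records = []
    for gm in models:
        span = internal_to_gff(gm.exons[0][0], gm.exons[-1][1])
        attrs = {"ID": gm.name, "Name": gm.name,
                 "best_query": gm.best_query_id,
                 "integrity": gm.integrity,
                 "pseudo": str(gm.pseudo).lower()}
        records.append(GffRecord(gm.scaffold_id, source, "gene", span[0], span[1],
                                 f"{gm.score:g}", gm.strand, ".", attrs))
        exons = sorted(gm.exons, reverse=(gm.strand == "-"))
        phase = 0
        for s, e in exons:
            s1, e1 = internal_to_gff(s, e)
            records.append(GffRecord(gm.scaffold_id, source, "CDS", s1, e1, ".",
                                     gm.strand, str(phase),
                                     {"ID": gm.name + ".cds", "Parent": gm.name}))
            phase = (3 - ((e - s) - phase) % 3) % 3
    return records
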