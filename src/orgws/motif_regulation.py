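"""Upstream cis-regulatory analysis.

Stages: strand-aware extraction of 300-nt windows upstream of the translation
start (records of ≤ 100 nt are dropped); de-novo motif discovery under the
ZOOPS model (zero or one site per sequence, both strands) by expectation
maximisation from word seeds, up to 10 motifs of width 6–10, each accepted at
E ≤ 1e-5 and masked before the next is sought; a stricter reporting filter
(E < 1e-10 and more than 40 occurrences); PSSM scanning with exact p-values
(dynamic-programming convolution of the integer-rescaled score distribution
under the background); per-species / per-clade distribution tables; and
enrichment counting of degenerate literal words such as [A/G]CGCAAGCG[C/T].

Motif significance.  The E-value is an analytic surrogate for a motif-suite
E-value: twice the log-likelihood ratio of the site alignment against the
background is referred to a chi-square with 3·width degrees of freedom, and
the resulting tail probability is Bonferroni-corrected by the (log) number of
possible site assignments (which sequences carry a site, at which position and
strand) and by the number of EM seeds tried.  Computed throughout in log
space, it preserves ordering and honours the stated thresholds; it is not the
E-value any particular external tool would print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import revcomp
from .io_formats import Scaffold, group_gff_genes, logger

UPSTREAM_WINDOW = 300
UPSTREAM_MIN_LEN = 101      # keep records strictly longer than 100 nt
DISCOVERY_EVALUE = 1e-5
REPORT_EVALUE = 1e-10
REPORT_MIN_OCC = 41         # strictly more than 40 occurrences
PSEUDOCOUNT = 0.01
SCALE = 1e-3                # integer rescaling granularity for exact p-values

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PSSM:
    probs: np.ndarray               # (width, 4), rows sum to 1
    background: np.ndarray          # (4,)
    nsites: int = 0
    evalue: float = float("inf")
    log10_evalue: float = float("inf")
    motif_id: str = "motif"

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        p = np.clip(self.probs, 1e-9, 1.0)
        b = np.clip(self.background, 1e-9, 1.0)
        return np.log2(p) - np.log2(b)[None, :]

    def int_scores(self, scale: float = SCALE) -> np.ndarray:
        """Per-column integer-rescaled log-odds (the exact-p-value currency)."""
        return np.round(self.log_odds() / scale).astype(np.int64)


@dataclass
class UpstreamRecord:
    gene_id: str
    species: str = ""
    clade: str | None = None
    seq: str = ""


@dataclass
class MotifOccurrence:
    motif_id: str
    gene_id: str
    position: int
    strand: str
    score: float
    pvalue: float = 1.0


# ---------------------------------------------------------------------------
# upstream extraction
# ---------------------------------------------------------------------------

def extract_upstream(gff_records, scaffolds: list[Scaffold],
                     window: int = UPSTREAM_WINDOW,
                     min_len: int = UPSTREAM_MIN_LEN,
                     species: str = "") -> list[UpstreamRecord]:
    """300-nt windows upstream of each gene's translation start, coding strand.

    The anchor is the first base of the first CDS (the ATG); records shorter
    than ``min_len`` (scaffold edge) are dropped and logged.  Genes without
    CDS features are skipped with a warning.
    """
    smap = {s.id: s.seq for s in scaffolds}
    out: list[UpstreamRecord] = []
    for gid, b in sorted(group_gff_genes(gff_records).items()):
        cds = b["cds"] or b["exon"]
        if not cds:
            logger.warning("gene %s has no CDS; skipped", gid)
            continue
        seq = smap.get(b["scaffold_id"])
        if seq is None:
            logger.warning("gene %s on unknown scaffold %s", gid, b["scaffold_id"])
            continue
        L = len(seq)
        first = cds[0]              # transcription order from group_gff_genes
        s0, e0 = first.interval
        if b["strand"] == "+":
            region = seq[max(0, s0 - window):s0]
        else:
            region = revcomp(seq[e0:min(L, e0 + window)])
        if len(region) < min_len:
            logger.info("gene %s upstream region %d nt (< %d); dropped",
                        gid, len(region), min_len)
            continue
        out.append(UpstreamRecord(gene_id=gid, species=species, seq=region))
    return out


# ---------------------------------------------------------------------------
# ZOOPS EM discovery
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


@dataclass
class _Windows:
    """All candidate site windows of one width over a sequence set."""

    X: np.ndarray          # (n_windows, w) base codes, no N
    seq_idx: np.ndarray    # window -> sequence index
    pos: np.ndarray        # start offset in the sequence
    strand: np.ndarray     # '+'/'-'
    n_seqs: int
    m_per_seq: np.ndarray  # candidate windows per sequence


def _build_windows(seqs: list[str], w: int) -> _Windows:
    Xs, si, po, st = [], [], [], []
    for i, s in enumerate(seqs):
        for strand, text in (("+", s), ("-", revcomp(s))):
            codes = _encode(text)
            n = len(codes) - w + 1
            if n <= 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, w)
            ok = (win < 4).all(axis=1)
            idx = np.flatnonzero(ok)
            Xs.append(win[idx])
            si.append(np.full(len(idx), i))
            if strand == "+":
                po.append(idx)
            else:
                po.append(len(s) - w - idx)
            st.append(np.full(len(idx), strand, dtype="U1"))
    if not Xs:
        raise ValueError(f"no candidate windows of width {w}")
    X = np.concatenate(Xs)
    seq_idx = np.concatenate(si)
    m = np.bincount(seq_idx, minlength=len(seqs))
    return _Windows(X=X, seq_idx=seq_idx, pos=np.concatenate(po),
                    strand=np.concatenate(st), n_seqs=len(seqs), m_per_seq=m)


def _em_run(win: _Windows, theta0: np.ndarray, bg: np.ndarray, gamma0: float,
            n_iter: int, tol: float = 1e-6):
    """EM under the ZOOPS model; returns (theta, gamma, resp, objective trace).

    The tracked objective is the data log-likelihood plus the Dirichlet
    pseudocount prior on theta; it is non-decreasing by EM construction.
    """
    w = theta0.shape[0]
    X = win.X
    lbg_col = np.log(np.clip(bg, 1e-12, 1))[X].sum(axis=1)
    theta = theta0.copy()
    gamma = gamma0
    trace: list[float] = []
    resp = None
    m_safe = np.maximum(win.m_per_seq, 1)
    for it in range(n_iter):
        lth = np.log(np.clip(theta, 1e-12, 1))
        lo = lth[np.arange(w)[None, :], X].sum(axis=1) - lbg_col
        u = (gamma / m_safe[win.seq_idx]) * np.exp(lo)
        denom = (1.0 - gamma) + np.bincount(win.seq_idx, weights=u,
                                            minlength=win.n_seqs)
        resp = u / denom[win.seq_idx]
        obj = float(np.log(np.clip(denom, 1e-300, None)).sum()) + \
            PSEUDOCOUNT * float(np.log(np.clip(theta, 1e-12, 1)).sum())
        if trace and obj < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise AssertionError("EM objective decreased")
        converged = bool(trace) and abs(obj - trace[-1]) <= \
            tol * max(1.0, abs(trace[-1]))
        trace.append(obj)
        # M-step
        counts = np.zeros((w, 4))
        for k in range(w):
            counts[k] = np.bincount(X[:, k], weights=resp, minlength=4)[:4]
        q = resp.sum()
        theta = (counts + PSEUDOCOUNT) / (q + 4 * PSEUDOCOUNT)
        z1 = 1.0 - (1.0 - gamma) / denom          # P(site | seq)
        gamma = float(np.clip(z1.mean(), 1.0 / (2 * win.n_seqs), 0.99))
        if converged:
            break
    return theta, gamma, resp, trace


def _map_sites(win: _Windows, resp: np.ndarray):
    """MAP site per sequence: best window where P(site) > 0.5."""
    z1 = np.bincount(win.seq_idx, weights=resp, minlength=win.n_seqs)
    best = {}
    order = np.argsort(-resp, kind="stable")
    for idx in order:
        i = int(win.seq_idx[idx])
        if i not in best:
            best[i] = int(idx)
    return {i: j for i, j in best.items() if z1[i] > 0.5}


def motif_log10_evalue(site_matrix: np.ndarray, bg: np.ndarray,
                       m_per_seq: np.ndarray, n_seqs: int,
                       n_tests: int) -> tuple[float, int]:
    """Log10 surrogate E-value of an aligned site set (see module docstring).

    ``site_matrix`` must be ordered best site first.  The E-value is
    minimised over the number of sites kept (every prefix of the ordering),
    the same device MEME uses to choose ``nsites``: an over-inclusive EM
    solution that absorbed background sequences is still judged on its
    strong core.  Each site pays the log of the number of candidate
    positions (both strands); the prefix choice and the seed/width
    multiplicity are added as further Bonferroni terms.  Returns
    ``(log10_evalue, n_sites_used)``.
    """
    q, w = site_matrix.shape
    if q < 2:
        return float("inf"), 0
    mean_m = max(float(np.mean(np.maximum(m_per_seq, 1))), 1.0)
    counts = np.zeros((w, 4))
    best = (float("inf"), 0)
    for qq in range(1, q + 1):
        for k in range(w):
            counts[k, site_matrix[qq - 1, k]] += 1
        if qq < 3:
            continue
        llr = 0.0
        for k in range(w):
            c = counts[k]
            f = c / qq
            nz = c > 0
            llr += float((c[nz] * (np.log(f[nz]) - np.log(bg[nz]))).sum())
        log_p = stats.chi2.logsf(2.0 * llr, df=3 * w)
        penalty = qq * math.log(mean_m) + math.log(max(n_tests, 1)) + \
            math.log(q)
        log10_e = float((log_p + penalty) / math.log(10))
        if log10_e < best[0]:
            best = (log10_e, qq)
    return best


def discover_motifs_zoops(seqs, n_motifs: int = 10, w_min: int = 6,
                          w_max: int = 10,
                          evalue_cutoff: float = DISCOVERY_EVALUE,
                          seed: int = 0, n_starts: int = 12,
                          short_iters: int = 10, long_iters: int = 80):
    """Iterative ZOOPS motif discovery with masking.

    ``seqs`` is a list of :class:`UpstreamRecord` or raw strings.  For each
    motif in turn: over every width, EM is run from ``n_starts`` word seeds
    (a short burn-in, then full convergence for the best start); the best
    width's motif is kept if its E-value passes ``evalue_cutoff``, its MAP
    occurrences are masked with N, and the search repeats.  Deterministic
    given ``seed``.  Returns ``(pssms, occurrences)``.
    """
    records = [s if isinstance(s, UpstreamRecord)
               else UpstreamRecord(gene_id=f"seq{i}", seq=s)
               for i, s in enumerate(seqs)]
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    work = [r.seq.upper() for r in records]
    if all(len(s) < w_min for s in work):
        raise ValueError("all sequences shorter than the minimum motif width")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20230601]))
    bg_counts = np.zeros(4)
    for s in work:
        c = _encode(s)
        bg_counts += np.bincount(c[c < 4], minlength=4)[:4]
    bg = (bg_counts + 1.0) / (bg_counts.sum() + 4.0)

    pssms: list[PSSM] = []
    occurrences: list[MotifOccurrence] = []
    n_tests_per_width = n_starts
    for motif_no in range(1, n_motifs + 1):
        best_cand = None
        for w in range(w_min, w_max + 1):
            try:
                win = _build_windows(work, w)
            except ValueError:
                continue
            if len(win.X) < 2:
                continue
            seed_idx = rng.choice(len(win.X),
                                  size=min(n_starts, len(win.X)),
                                  replace=False)
            runs = []
            for sidx in seed_idx:
                theta0 = np.full((w, 4), 0.15)
                theta0[np.arange(w), win.X[sidx]] = 0.55
                try:
                    theta, gamma, resp, trace = _em_run(
                        win, theta0, bg, 0.5, short_iters)
                except AssertionError:
                    continue
                runs.append((trace[-1], int(sidx), theta, gamma))
            if not runs:
                continue
            runs.sort(key=lambda r: (-r[0], r[1]))
            _obj, _sidx, theta, gamma = runs[0]
            theta, gamma, resp, trace = _em_run(win, theta, bg, gamma,
                                                long_iters)
            sites = _map_sites(win, resp)
            if len(sites) < 3:
                continue
            # order sites best-first by their log-odds under the fitted motif
            lth = np.log(np.clip(theta, 1e-12, 1))
            lbg = np.log(np.clip(bg, 1e-12, 1))

            def site_lo(j):
                x = win.X[j]
                return float((lth[np.arange(w), x] - lbg[x]).sum())

            ordered = sorted(sites.items(), key=lambda kv: -site_lo(kv[1]))
            site_matrix = np.stack([win.X[j] for _, j in ordered])
            log10_e, n_used = motif_log10_evalue(
                site_matrix, bg, win.m_per_seq, win.n_seqs,
                n_tests_per_width * (w_max - w_min + 1))
            cand = (log10_e, w, theta, win, ordered[:n_used])
            if best_cand is None or cand[0] < best_cand[0]:
                best_cand = cand
        if best_cand is None:
            break
        log10_e, w, theta, win, kept = best_cand
        if log10_e > math.log10(evalue_cutoff):
            break
        pssm = PSSM(probs=theta, background=bg.copy(), nsites=len(kept),
                    evalue=float(10.0 ** max(log10_e, -300.0)),
                    log10_evalue=log10_e, motif_id=f"motif_{motif_no}")
        pssms.append(pssm)
        lo = pssm.log_odds()
        for i, j in sorted(kept):
            x = win.X[j]
            score = float(lo[np.arange(w), x].sum())
            occurrences.append(MotifOccurrence(
                motif_id=pssm.motif_id, gene_id=records[i].gene_id,
                position=int(win.pos[j]), strand=str(win.strand[j]),
                score=score))
            # mask the occurrence (forward coordinates of the site)
            p = int(win.pos[j])
            work[i] = work[i][:p] + "N" * w + work[i][p + w:]
    return pssms, occurrences


def report_filter(pssms, occurrences=None,
                  evalue: float = REPORT_EVALUE,
                  min_occ: int = REPORT_MIN_OCC) -> list[PSSM]:
    """The reporting rule: E-value better than 1e-10 AND more than 40 sites."""
    counts = {}
    if occurrences is not None:
        for o in occurrences:
            counts[o.motif_id] = counts.get(o.motif_id, 0) + 1
    out = []
    for p in pssms:
        n = counts.get(p.motif_id, p.nsites) if occurrences is not None else p.nsites
        if p.evalue < evalue and n >= min_occ:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# PSSM scanning with exact p-values
# ---------------------------------------------------------------------------

def pssm_score_pvalues(pssm: PSSM, scale: float = SCALE):
    """Exact tail distribution of the integer-rescaled score under background.

    Returns ``(offset, tail)`` where ``tail[s - offset]`` is the probability
    that a random background word scores >= s (integer units).
    """
    S = pssm.int_scores(scale)
    bg = pssm.background
    # iterative convolution over columns of the integer score distribution
    cur = {0: 1.0}
    for k in range(pssm.width):
        nxt: dict[int, float] = {}
        for s, p in cur.items():
            for b in range(4):
                s2 = s + int(S[k, b])
                nxt[s2] = nxt.get(s2, 0.0) + p * float(bg[b])
        cur = nxt
    scores = np.array(sorted(cur))
    probs = np.array([cur[s] for s in scores])
    tail = probs[::-1].cumsum()[::-1]
    return scores, tail


def scan_pssm(pssm: PSSM, seqs, pvalue_cutoff: float = 1e-4,
              both_strands: bool = True,
              scale: float = SCALE) -> list[MotifOccurrence]:
    """FIMO-style scan: every position/strand scored; exact p-values.

    Overlapping hits are allowed (scan mode).  Sequences shorter than the
    motif width are skipped.
    """
    records = [s if isinstance(s, UpstreamRecord)
               else UpstreamRecord(gene_id=f"seq{i}", seq=s)
               for i, s in enumerate(seqs)]
    S = pssm.int_scores(scale)
    w = pssm.width
    scores_axis, tail = pssm_score_pvalues(pssm, scale)
    out: list[MotifOccurrence] = []
    for rec in records:
        s = rec.seq.upper()
        if len(s) < w:
            continue
        strands = [("+", s)] + ([("-", revcomp(s))] if both_strands else [])
        for strand, text in strands:
            codes = _encode(text)
            win = np.lib.stride_tricks.sliding_window_view(codes, w)
            ok = (win < 4).all(axis=1)
            ints = np.where(
                ok, S[np.arange(w)[None, :], np.clip(win, 0, 3)].sum(axis=1),
                np.iinfo(np.int64).min)
            idx_p = np.searchsorted(scores_axis, ints, side="left")
            for j in np.flatnonzero(ok):
                p = float(tail[idx_p[j]]) if idx_p[j] < len(tail) else 0.0
                if p <= pvalue_cutoff:
                    pos = j if strand == "+" else len(s) - w - j
                    out.append(MotifOccurrence(
                        motif_id=pssm.motif_id, gene_id=rec.gene_id,
                        position=int(pos), strand=strand,
                        score=float(ints[j] * scale), pvalue=p))
    return out


# ---------------------------------------------------------------------------
# distribution tables and word enrichment
# ---------------------------------------------------------------------------

def distribution_table(occurrences, species_map: dict[str, str],
                       denominators: dict[str, int],
                       clade_map: dict[str, str] | None = None,
                       by: str = "species"):
    """Percentage of receptors (per species or per clade) carrying each motif.

    A gene counts once per motif regardless of occurrence multiplicity.
    Cells are ``100 * carriers / denominator`` rounded to 2 decimals; a zero
    denominator yields NaN.
    """
    import pandas as pd
    key_of = species_map if by == "species" else (clade_map or {})
    carriers: dict[tuple[str, str], set[str]] = {}
    motifs = sorted({o.motif_id for o in occurrences})
    for o in occurrences:
        k = key_of.get(o.gene_id)
        if k is None:
            continue
        carriers.setdefault((k, o.motif_id), set()).add(o.gene_id)
    keys = sorted(denominators)
    data = {}
    for m in motifs:
        col = []
        for k in keys:
            den = denominators.get(k, 0)
            if den <= 0:
                col.append(float("nan"))
            else:
                col.append(round(100.0 * len(carriers.get((k, m), ())) / den, 2))
        data[m] = col
    return pd.DataFrame(data, index=keys)


def expand_pattern(pattern: str) -> list[str]:
    """Expand a degenerate word like ``[A/G]CGCAAGCG[C/T]`` to literal words."""
    words = [""]
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            alts = [a for a in pattern[i + 1:j].split("/") if a]
            if not alts or any(b not in _BASES for a in alts for b in a):
                raise ValueError(f"unsupported pattern group {pattern[i:j+1]!r}")
            words = [w + a for w in words for a in alts]
            i = j + 1
        elif c in _BASES:
            words = [w + c for w in words]
            i += 1
        else:
            raise ValueError(f"unsupported pattern symbol {c!r}")
    return words


def word_enrichment(pattern: str, upstream_or, upstream_all):
    """Count sequences containing any expansion of ``pattern`` (coding strand).

    Returns a dict with the per-set sequence counts, totals and the ratio of
    per-set frequencies (NaN when undefined).
    """
    words = expand_pattern(pattern)

    def count(records):
        n = 0
        for r in records:
            s = (r.seq if isinstance(r, UpstreamRecord) else r).upper()
            if any(wd in s for wd in words):
                n += 1
        return n

    n_or, n_all = count(upstream_or), count(upstream_all)
    t_or, t_all = len(upstream_or), len(upstream_all)
    if n_all == 0 or t_or == 0 or t_all == 0:
        ratio = float("nan")
    else:
        ratio = (n_or / t_or) / (n_all / t_all)
    return {"pattern": pattern, "n_words": len(words),
            "or_count": n_or, "or_total": t_or,
            "all_count": n_all, "all_total": t_all,
            "enrichment_ratio": ratio}
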