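import numpy as np
import pytest

from orgws._seq import AA_INDEX, encode_aa, load_matrix, revcomp, translate
from orgws.io_formats import Scaffold
from orgws.spliced_search import (HSP, MIN_INTRON, STRICT_SCHEME, ChainedModel,
                                  Locus, chain_hsps, junction_term,
                                  local_align_hsps, refine_locus,
                                  select_best_per_locus,
                                  split_hsps_at_introns,
                                  translated_local_align)

import oracles

MAT = load_matrix("BLOSUM62")
LOOKUP = {a: i for a, i in AA_INDEX.items()}
AA20 = "ARNDCQEGHILKMFPSTWYV"


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA20), size=n))


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTranslatedAlign:
    def test_perfect_orf_self_match(self, rng):
        prot = _random_protein(rng, 60)
        from orgws.synthetic_data import back_translate
        orf = back_translate(prot, rng)
        dna = _random_dna(rng, 90) + orf + _random_dna(rng, 90)
        query = Scaffold("q", prot)
        hsps = translated_local_align(query, Scaffold("s", dna),
                                      STRICT_SCHEME, 40)
        top = hsps[0]
        diag = sum(int(MAT[AA_INDEX[a], AA_INDEX[a]]) for a in prot)
        assert top.score == diag
        assert top.q_start == 0 and top.q_end == len(prot)
        assert top.strand == "+"
        assert top.fwd_interval() == (90, 90 + 3 * len(prot))

    def test_strand_symmetry(self, rng):
        prot = _random_protein(rng, 50)
        from orgws.synthetic_data import back_translate
        dna = _random_dna(rng, 60) + back_translate(prot, rng) + _random_dna(rng, 60)
        query = Scaffold("q", prot)
        fwd = translated_local_align(query, Scaffold("s", dna), STRICT_SCHEME, 40)
        rev = translated_local_align(query, Scaffold("s", revcomp(dna)),
                                     STRICT_SCHEME, 40)
        L = len(dna)
        f = {(h.score, h.fwd_interval(), h.strand) for h in fwd}
        r = {(h.score, (L - h.fwd_interval()[1], L - h.fwd_interval()[0]),
              {"+": "-", "-": "+"}[h.strand]) for h in rev}
        assert f == r

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError):
            translated_local_align(Scaffold("q", "MKL#"), Scaffold("s", "ACGTACGT"),
                                   STRICT_SCHEME, 10)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_bruteforce_sw(self, trial):
        """Top HSP score equals a full-matrix six-frame SW oracle."""
        rng = np.random.default_rng(1000 + trial)
        q = _random_protein(rng, int(rng.integers(10, 41)))
        dna = _random_dna(rng, int(rng.integers(60, 601)))
        hsps = translated_local_align(Scaffold("q", q), Scaffold("s", dna),
                                      STRICT_SCHEME, 1)
        got = hsps[0].score if hsps else 0
        want = oracles.translated_best_score(
            q, dna, MAT, LOOKUP, STRICT_SCHEME.gap_open, STRICT_SCHEME.gap_extend)
        assert got == want


class TestIterativeMasking:
    def test_non_overlapping_local_optima(self, rng):
        prot = _random_protein(rng, 30)
        from orgws.synthetic_data import back_translate
        orf = back_translate(prot, rng)
        dna = (_random_dna(rng, 50) + orf + _random_dna(rng, 50) + orf
               + _random_dna(rng, 50))
        hsps = translated_local_align(Scaffold("q", prot), Scaffold("s", dna),
                                      STRICT_SCHEME, 40)
        plus = [h for h in hsps if h.strand == "+"]
        assert len(plus) >= 2
        ivals = sorted((h.g_start, h.g_end) for h in plus if h.frame == plus[0].frame)
        for (a, b), (c, d) in zip(ivals, ivals[1:]):
            assert b <= c      # masked footprints cannot overlap


def _mk_hsp(q0, q1, g0, g1, score):
    return HSP(query_id="q", scaffold_id="s", strand="+", frame=0,
               q_start=q0, q_end=q1, g_start=g0, g_end=g1, score=score,
               aligned_pairs=[], scaffold_len=100000)


class TestChaining:
    def test_two_exons_with_splice_bonus(self):
        seq = "X" * 300
        seq = seq[:100] + "GT" + "A" * 496 + "AG" + seq[100:]
        seq_s = "C" * 100 + "GT" + "A" * 496 + "AG" + "C" * 100
        h1 = _mk_hsp(0, 20, 40, 100, 90)
        h2 = _mk_hsp(20, 40, 600, 660, 80)
        chains = chain_hsps([h1, h2], max_intron=2000, scheme=STRICT_SCHEME,
                            seq_s=seq_s)
        assert len(chains) == 1
        assert chains[0].total_score == 90 + 80 + STRICT_SCHEME.splice_bonus
        assert chains[0].junctions[0]["kind"] == "intron"

    def test_max_intron_splits_chain(self):
        h1 = _mk_hsp(0, 20, 0, 60, 90)
        h2 = _mk_hsp(20, 40, 5060, 5120, 80)
        chains = chain_hsps([h1, h2], max_intron=2000, scheme=STRICT_SCHEME)
        assert len(chains) == 2
        assert all(len(c.hsps) == 1 for c in chains)

    def test_frameshift_junction_admitted(self):
        h1 = _mk_hsp(0, 20, 0, 60, 90)
        h2 = _mk_hsp(20, 40, 61, 121, 80)
        chains = chain_hsps([h1, h2], max_intron=2000, scheme=STRICT_SCHEME)
        assert len(chains) == 1
        assert chains[0].junctions[0]["kind"] == "frameshift"
        assert chains[0].total_score == 90 + 80 + STRICT_SCHEME.frameshift_penalty

    def test_mixed_groups_rejected(self):
        h1 = _mk_hsp(0, 20, 0, 60, 90)
        h2 = HSP("q2", "s", "+", 0, 0, 10, 0, 30, 50, [], 100000)
        with pytest.raises(ValueError):
            chain_hsps([h1, h2])

    @pytest.mark.parametrize("trial", range(40))
    def test_chain_dp_equals_exhaustive(self, trial):
        """Best chain score equals enumeration of all admissible subsets."""
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(2, 7))
        hsps = []
        for _ in range(n):
            q0 = int(rng.integers(0, 80))
            q1 = q0 + int(rng.integers(5, 40))
            g0 = int(rng.integers(0, 4000))
            g1 = g0 + 3 * (q1 - q0)
            hsps.append(_mk_hsp(q0, q1, g0, g1, int(rng.integers(20, 120))))
        chains = chain_hsps(hsps, max_intron=2000, scheme=STRICT_SCHEME)
        got = max(c.total_score for c in chains)

        def junction(a, b):
            term = junction_term(a, b, None, STRICT_SCHEME, 2000, MIN_INTRON)
            return None if term is None else term["bonus"]

        want = oracles.best_chain_exhaustive(hsps, junction)
        assert got == want

    def test_each_hsp_in_at_most_one_chain(self, rng):
        hsps = [_mk_hsp(i * 10, i * 10 + 8, i * 500, i * 500 + 24, 50)
                for i in range(5)]
        chains = chain_hsps(hsps, max_intron=2000, scheme=STRICT_SCHEME)
        seen = []
        for c in chains:
            seen.extend(id(h) for h in c.hsps)
        assert len(seen) == len(set(seen)) == 5


def _mk_model(g0, g1, score, qid="q", strand="+"):
    h = HSP(query_id=qid, scaffold_id="s", strand=strand, frame=0,
            q_start=0, q_end=(g1 - g0) // 3, g_start=g0, g_end=g1,
            score=score, aligned_pairs=[], scaffold_len=100000)
    return ChainedModel(query_id=qid, scaffold_id="s", strand=strand,
                        hsps=[h], total_score=score, scaffold_len=100000)


class TestLocusSelection:
    def test_best_model_kept(self):
        loci = select_best_per_locus([_mk_model(100, 400, 120, "a"),
                                      _mk_model(200, 500, 95, "b")])
        assert len(loci) == 1
        assert loci[0].best.query_id == "a"

    def test_disjoint_models_separate(self):
        loci = select_best_per_locus([_mk_model(100, 400, 120),
                                      _mk_model(500, 900, 95)])
        assert len(loci) == 2

    @pytest.mark.parametrize("trial", range(30))
    def test_partition_equals_transitive_closure(self, trial):
        rng = np.random.default_rng(3000 + trial)
        models = []
        for _ in range(10):
            g0 = int(rng.integers(0, 5000))
            g1 = g0 + int(rng.integers(30, 900))
            models.append(_mk_model(g0, g1, int(rng.integers(50, 500)),
                                    qid=f"q{rng.integers(0, 5)}"))
        loci = select_best_per_locus(models)
        got = sorted((frozenset(id(m) for m in l.models) for l in loci),
                     key=sorted)
        comps = oracles.overlap_components([m.fwd_span() for m in models])
        want = sorted((frozenset(id(models[i]) for i in c) for c in comps),
                      key=sorted)
        assert got == want

    def test_tie_break_documented(self):
        a = _mk_model(100, 400, 100, "b")
        b = _mk_model(100, 460, 100, "a")
        loci = select_best_per_locus([a, b])
        assert loci[0].best is b          # longer span wins at equal score


class TestRefinement:
    def test_complete_model_unchanged(self, small_genome):
        from orgws.spliced_search import survey_genome
        scaffolds = small_genome["scaffolds"]
        queries = small_genome["queries"]
        loci = survey_genome(scaffolds[:1], queries, refine=False)
        smap = {s.id: s for s in scaffolds}
        qmap = {q.id: q.seq for q in queries}
        for l in loci:
            from orgws.spliced_search import looks_complete
            if looks_complete(l.best, len(qmap[l.best.query_id])):
                refined = refine_locus(l, smap, qmap)
                assert refined.best is l.best

    def test_scaffold_edge_window_clipped(self, small_genome):
        truth = small_genome["truth"]
        edge = next(g for g in truth.genes if g.gene_class.startswith("partial"))
        smap = {s.id: s for s in small_genome["scaffolds"]}
        qmap = {q.id: q.seq for q in small_genome["queries"]}
        from orgws.spliced_search import survey_genome
        loci = survey_genome([smap[edge.scaffold]],
                             small_genome["queries"], refine=False)
        target = [l for l in loci
                  if l.span[0] < max(e for _, e in edge.exons)
                  and l.span[1] > min(s for s, _ in edge.exons)]
        assert target
        refined = refine_locus(target[0], smap, qmap)   # must not raise
        assert refined.span[0] >= 0


def test_split_hsps_at_introns(rng):
    prot = _random_protein(rng, 40)
    from orgws.synthetic_data import back_translate
    half = back_translate(prot[:20], rng)
    rest = back_translate(prot[20:], rng)
    seq_s = "C" * 30 + half + "GT" + "A" * 100 + "AG" + rest + "C" * 30
    pairs = [(i, 30 + 3 * i) for i in range(20)] + \
            [(20 + i, 30 + 60 + 104 + 3 * i) for i in range(20)]
    h = HSP("q", "s", "+", 0, 0, 40, 30, 30 + 60 + 104 + 60, 100, pairs,
            len(seq_s))
    out = split_hsps_at_introns([h], prot, seq_s, STRICT_SCHEME)
    assert len(out) == 2
    assert out[0].g_end == 90 and out[1].g_start == 194
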