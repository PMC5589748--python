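import itertools

import numpy as np
import pytest

from orgws._seq import revcomp
from orgws.io_formats import GffRecord, Scaffold
from orgws.motif_regulation import (PSSM, UpstreamRecord, _build_windows,
                                    _em_run, discover_motifs_zoops,
                                    distribution_table, expand_pattern,
                                    extract_upstream, pssm_score_pvalues,
                                    report_filter, scan_pssm, word_enrichment)


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def consensus_hamming(planted: str, consensus: str) -> int:
    """Best-offset Hamming distance of a planted word to a (possibly wider,
    possibly reverse-complement) recovered consensus."""
    best = len(planted)
    for cons in (consensus, revcomp(consensus)):
        if len(cons) < len(planted):
            continue
        for off in range(len(cons) - len(planted) + 1):
            d = sum(a != b for a, b in zip(planted, cons[off:off + len(planted)]))
            best = min(best, d)
    return best


def _pssm(word, background=None, conc=0.91):
    probs = np.full((len(word), 4), (1 - conc) / 3)
    for k, b in enumerate(word):
        probs[k, "ACGT".index(b)] = conc
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PSSM(probs=probs, background=bg, motif_id="m1")


class TestExtractUpstream:
    def _gff(self, strand, cds_start, cds_end):
        return [
            GffRecord("s1", "x", "gene", cds_start, cds_end, ".", strand, ".",
                      {"ID": "g1"}),
            GffRecord("s1", "x", "CDS", cds_start, cds_end, ".", strand, "0",
                      {"ID": "c1", "Parent": "g1"}),
        ]

    def test_plus_strand_window(self, rng):
        seq = _rand_dna(rng, 2000)
        recs = extract_upstream(self._gff("+", 1000, 1600),
                                [Scaffold("s1", seq)])
        assert len(recs) == 1
        assert recs[0].seq == seq[699:999]
        assert len(recs[0].seq) == 300

    def test_minus_strand_window(self, rng):
        seq = _rand_dna(rng, 10_000)
        recs = extract_upstream(self._gff("-", 100, 500),
                                [Scaffold("s1", seq)])
        assert recs[0].seq == revcomp(seq[500:800])

    def test_short_region_dropped(self, rng):
        seq = _rand_dna(rng, 1000)
        recs = extract_upstream(self._gff("+", 50, 500),
                                [Scaffold("s1", seq)])
        assert recs == []                       # 49 nt <= 100

    def test_101nt_region_retained(self, rng):
        seq = _rand_dna(rng, 1000)
        recs = extract_upstream(self._gff("+", 102, 500),
                                [Scaffold("s1", seq)])
        assert len(recs) == 1 and len(recs[0].seq) == 101


class TestZoopsEm:
    def test_objective_monotone(self, rng):
        seqs = [_rand_dna(rng, 120) for _ in range(12)]
        win = _build_windows(seqs, 6)
        theta0 = np.random.default_rng(0).dirichlet(np.ones(4), size=6)
        bg = np.full(4, 0.25)
        _, _, _, trace = _em_run(win, theta0, bg, 0.5, 40)
        for a, b in zip(trace, trace[1:]):
            assert b >= a - 1e-6 * max(1.0, abs(a))

    def test_planted_motif_recovered(self, rng):
        planted = "TTGACGTCAT"[:8]
        pssm = _pssm(planted)
        seqs = []
        for i in range(50):
            s = _rand_dna(rng, 300)
            if i < 40:
                site = "".join("ACGT"[rng.choice(4, p=pssm.probs[k])]
                               for k in range(8))
                p = int(rng.integers(0, 293))
                s = s[:p] + site + s[p + 8:]
            seqs.append(s)
        pssms, occ = discover_motifs_zoops(seqs, seed=1)
        assert pssms
        top = pssms[0]
        assert consensus_hamming(planted, top.consensus) <= 1
        assert top.nsites >= 30

    def test_null_yields_nothing(self, rng):
        seqs = [_rand_dna(rng, 300) for _ in range(50)]
        pssms, _ = discover_motifs_zoops(seqs, seed=2)
        assert pssms == []

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs_zoops(["ACGTACGT"], seed=0)

    def test_masking_blocks_reuse(self, rng):
        planted = "ACGTACGT"
        seqs = []
        for i in range(30):
            s = _rand_dna(rng, 200)
            p = int(rng.integers(0, 192))
            seqs.append(s[:p] + planted + s[p + 8:])
        pssms, occ = discover_motifs_zoops(seqs, n_motifs=3, seed=3)
        by_motif = {}
        for o in occ:
            by_motif.setdefault(o.motif_id, []).append(o)
        widths = {p.motif_id: p.width for p in pssms}
        for (m1, m2) in itertools.combinations(by_motif, 2):
            for a in by_motif[m1]:
                for b in by_motif[m2]:
                    if a.gene_id != b.gene_id:
                        continue
                    assert (a.position + widths[m1] <= b.position or
                            b.position + widths[m2] <= a.position)


class TestReportFilter:
    def _p(self, e, n):
        p = _pssm("ACGTAC")
        p.evalue = e
        p.nsites = n
        return p

    def test_thresholds(self):
        assert report_filter([self._p(1e-12, 45)]) != []
        assert report_filter([self._p(1e-12, 40)]) == []   # needs > 40
        assert report_filter([self._p(1e-9, 100)]) == []   # needs < 1e-10


class TestScanPssm:
    @pytest.mark.parametrize("trial", range(10))
    def test_pvalues_equal_enumeration(self, trial):
        rng = np.random.default_rng(7000 + trial)
        w = int(rng.integers(3, 6))
        probs = rng.dirichlet(np.ones(4) * 2, size=w)
        bg = rng.dirichlet(np.ones(4) * 5)
        pssm = PSSM(probs=probs, background=bg, motif_id="m")
        scores, tail = pssm_score_pvalues(pssm)
        S = pssm.int_scores()
        word_p = {}
        for word in itertools.product(range(4), repeat=w):
            s = sum(int(S[k, b]) for k, b in enumerate(word))
            word_p[s] = word_p.get(s, 0.0) + float(np.prod(bg[list(word)]))
        for s in word_p:
            want = sum(p for sc, p in word_p.items() if sc >= s)
            got = tail[np.searchsorted(scores, s)]
            assert got == pytest.approx(want, abs=1e-12)

    def test_best_word_has_min_pvalue(self):
        pssm = _pssm("ACGT")
        scores, tail = pssm_score_pvalues(pssm)
        occ = scan_pssm(pssm, ["ACGT"], pvalue_cutoff=1.0, both_strands=False)
        assert occ[0].pvalue == pytest.approx(tail[-1])

    def test_reverse_complement_symmetry(self, rng):
        pssm = _pssm("ACGTTC")
        seq = _rand_dna(rng, 80)
        fwd = scan_pssm(pssm, [seq], pvalue_cutoff=0.05)
        rev = scan_pssm(pssm, [revcomp(seq)], pvalue_cutoff=0.05)
        f = {(o.position, o.strand, round(o.score, 6)) for o in fwd}
        r = {(len(seq) - o.position - pssm.width,
              {"+": "-", "-": "+"}[o.strand], round(o.score, 6)) for o in rev}
        assert f == r

    def test_short_sequence_skipped(self):
        assert scan_pssm(_pssm("ACGTTC"), ["ACG"], pvalue_cutoff=1.0) == []


class TestDistributionTable:
    def _occ(self, gene, motif):
        from orgws.motif_regulation import MotifOccurrence
        return MotifOccurrence(motif, gene, 0, "+", 1.0)

    def test_simple_percentages(self):
        occ = [self._occ("g1", "m1")]
        t = distribution_table(occ, {"g1": "spA"}, {"spA": 4})
        assert t.loc["spA", "m1"] == 25.00

    def test_all_carry(self):
        occ = [self._occ(f"g{i}", "m1") for i in range(4)]
        t = distribution_table(occ, {f"g{i}": "spA" for i in range(4)},
                               {"spA": 4})
        assert t.loc["spA", "m1"] == 100.00

    def test_zero_denominator_nan(self):
        t = distribution_table([self._occ("g1", "m1")], {"g1": "spA"},
                               {"spA": 0})
        assert np.isnan(t.loc["spA", "m1"])

    def test_gene_counts_once(self):
        occ = [self._occ("g1", "m1"), self._occ("g1", "m1")]
        t = distribution_table(occ, {"g1": "spA"}, {"spA": 2})
        assert t.loc["spA", "m1"] == 50.00

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_recount(self, trial):
        rng = np.random.default_rng(8100 + trial)
        genes = [f"g{i}" for i in range(20)]
        species = {g: f"sp{rng.integers(3)}" for g in genes}
        denom = {f"sp{k}": int(rng.integers(1, 10)) for k in range(3)}
        occ = [self._occ(g, f"m{rng.integers(2)}")
               for g in rng.choice(genes, size=15)]
        t = distribution_table(occ, species, denom)
        for sp in denom:
            for m in {o.motif_id for o in occ}:
                carriers = {o.gene_id for o in occ
                            if o.motif_id == m and species[o.gene_id] == sp}
                want = round(100 * len(carriers) / denom[sp], 2)
                assert t.loc[sp, m] == want


class TestWordEnrichment:
    def test_pattern_expansion(self):
        words = expand_pattern("[A/G]CGCAAGCG[C/T]")
        assert len(words) == 4
        assert set(words) == {"ACGCAAGCGC", "ACGCAAGCGT",
                              "GCGCAAGCGC", "GCGCAAGCGT"}
        assert all(len(w) == 10 for w in words)

    def test_unsupported_symbol(self):
        with pytest.raises(ValueError):
            expand_pattern("AC?T")

    def test_absent_word_nan_ratio(self):
        out = word_enrichment("ACGT", ["CCCC"], ["GGGG"])
        assert out["or_count"] == 0 and out["all_count"] == 0
        assert np.isnan(out["enrichment_ratio"])

    def test_planted_word_counted_exactly(self, rng):
        word = "ACGCAAGCGC"
        ors, others = [], []
        k = 7
        for i in range(20):
            s = _rand_dna(rng, 300).replace(word, "A" * 10)
            if i < k:
                s = s[:100] + word + s[110:]
            ors.append(UpstreamRecord(gene_id=f"or{i}", seq=s))
        for i in range(30):
            others.append(UpstreamRecord(
                gene_id=f"x{i}",
                seq=_rand_dna(rng, 300).replace(word, "A" * 10)))
        out = word_enrichment("[A/G]CGCAAGCG[C/T]", ors, others)
        assert out["or_count"] == k
        assert out["all_count"] == 0
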