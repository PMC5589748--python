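import numpy as np
import pytest

from orgws._seq import revcomp
from orgws.gene_models import (GeneModel, assign_names, build_cds,
                               build_gene_model, classify_integrity,
                               make_hypothetical_protein, partial_suffix,
                               summarize_survey, models_to_gff)
from orgws.io_formats import Scaffold
from orgws.spliced_search import (STRICT_SCHEME, survey_genome)
from orgws.synthetic_data import GenomeSpec, back_translate, generate_genome


def _survey_models(genome_bundle):
    scaffolds = genome_bundle["scaffolds"]
    queries = genome_bundle["queries"]
    loci = survey_genome(scaffolds, queries)
    smap = {s.id: s for s in scaffolds}
    qmap = {q.id: q.seq for q in queries}
    return [build_gene_model(l, smap[l.best.scaffold_id],
                             qmap[l.best.query_id]) for l in loci]


@pytest.fixture(scope="module")
def small_models(request):
    bundle = request.getfixturevalue("small_genome")
    return _survey_models(bundle)


class TestBuildCds:
    def test_forward_single_exon_gene(self, rng):
        prot = "M" + "".join(rng.choice(list("ARNDQEGHKST"), size=59))
        cds = back_translate(prot, rng) + "TAA"
        dna = "C" * 120 + cds + "C" * 120
        query = Scaffold("q", prot)
        loci = survey_genome([Scaffold("s", dna)], [query],
                             min_chain_score=60, refine=False)
        assert len(loci) == 1
        cds_seq, protein, flags, exons, lesions = build_cds(
            loci[0].best, Scaffold("s", dna), prot)
        assert protein == prot
        assert cds_seq == cds                      # includes the stop codon
        assert flags["has_start_codon"] and flags["has_stop_codon"]
        assert flags["n_terminus_present"] and flags["c_terminus_present"]
        assert exons == [(120, 120 + len(cds))]
        assert lesions == []

    def test_minus_strand_gene(self, rng):
        prot = "M" + "".join(rng.choice(list("ARNDQEGHKST"), size=59))
        cds = back_translate(prot, rng) + "TGA"
        dna = "C" * 100 + revcomp(cds) + "C" * 100
        loci = survey_genome([Scaffold("s", dna)], [Scaffold("q", prot)],
                             min_chain_score=60, refine=False)
        model = loci[0].best
        assert model.strand == "-"
        cds_seq, protein, flags, exons, _ = build_cds(
            model, Scaffold("s", dna), prot)
        assert protein == prot
        assert exons == [(100, 100 + len(cds))]

    def test_internal_stop_reported(self, rng):
        prot = "M" + "".join(rng.choice(list("ARNDQEGHKST"), size=79))
        cds = back_translate(prot, rng)
        cds = cds[:120] + "TAA" + cds[123:] + "TAA"   # stop at codon 40
        dna = "C" * 90 + cds + "C" * 90
        loci = survey_genome([Scaffold("s", dna)], [Scaffold("q", prot)],
                             min_chain_score=60, refine=False)
        _, protein, _, _, lesions = build_cds(loci[0].best,
                                              Scaffold("s", dna), prot)
        assert ("inframe_stop", 40) in lesions
        assert protein[40] == "*"


class TestClassifyIntegrity:
    def _gm(self, protein, flags, lesions=()):
        return GeneModel(name="", scaffold_id="s", strand="+", exons=[(0, 3)],
                         cds_seq="", protein=protein, best_query_id="q",
                         terminus_flags=dict(flags), lesions=list(lesions))

    def test_stop_makes_pseudo_not_partial(self):
        gm = self._gm("M" + "A" * 100 + "*" + "A" * 300,
                      {"n_terminus_present": True, "c_terminus_present": True,
                       "fragmented": False}, [("inframe_stop", 101)])
        classify_integrity(gm)
        assert gm.pseudo and gm.integrity == "complete"

    def test_long_protein_complete_despite_missing_terminus(self):
        gm = self._gm("A" * 371, {"n_terminus_present": False,
                                  "c_terminus_present": True,
                                  "fragmented": False})
        classify_integrity(gm)
        assert gm.integrity == "complete"
        gm2 = self._gm("A" * 370, {"n_terminus_present": False,
                                   "c_terminus_present": True,
                                   "fragmented": False})
        classify_integrity(gm2)
        assert gm2.integrity == "partial"

    def test_planted_lesions_recovered(self, small_genome, small_models):
        truth = {g.id: g for g in small_genome["truth"].genes}
        pseudo_truth = [g for g in truth.values() if g.gene_class == "pseudogene"]
        assert pseudo_truth
        pseudo_models = [m for m in small_models if m.pseudo]
        assert len(pseudo_models) == len(pseudo_truth)
        for g in pseudo_truth:
            span = (min(s for s, _ in g.exons), max(e for _, e in g.exons))
            m = next(m for m in pseudo_models if m.scaffold_id == g.scaffold
                     and m.exons[0][0] < span[1] and m.exons[-1][1] > span[0])
            kinds = {k for k, _ in m.lesions}
            assert {k for k, _ in g.lesions} <= kinds


class TestHypotheticalProtein:
    def test_stop_rendered_as_x(self):
        gm = GeneModel(name="", scaffold_id="s", strand="+", exons=[],
                       cds_seq="", protein="MAA*KL", best_query_id="q",
                       lesions=[("inframe_stop", 3)])
        assert make_hypothetical_protein(gm) == "MAAXKL"
        assert make_hypothetical_protein(gm)[3] == "X"

    def test_no_lesions_identity(self):
        gm = GeneModel(name="", scaffold_id="s", strand="+", exons=[],
                       cds_seq="", protein="MAAKL", best_query_id="q")
        assert make_hypothetical_protein(gm) is gm.protein


class TestNaming:
    def _model(self, protein, i, pseudo=False, integrity="complete",
               flags=None):
        return GeneModel(
            name="", scaffold_id="s", strand="+", exons=[(i * 100, i * 100 + 9)],
            cds_seq="", protein=protein, best_query_id="q",
            integrity=integrity, pseudo=pseudo,
            terminus_flags=flags or {"n_terminus_present": True,
                                     "c_terminus_present": True,
                                     "fragmented": False},
            lesions=[("inframe_stop", 1)] if pseudo else [])

    def test_reciprocal_best_named_plain(self, rng):
        refs = {f"Or{k}": "M" + "".join(rng.choice(list("ARNDQEGHKSTLIVF"),
                                                   size=120))
                for k in (5, 9)}
        models = [self._model(refs["Or5"], 0), self._model(refs["Or9"], 1)]
        assign_names(models, refs, prefix="DnOr")
        assert sorted(m.name for m in models) == ["DnOr5", "DnOr9"]

    def test_shared_best_gets_suffixes(self, rng):
        ref = "M" + "".join(rng.choice(list("ARNDQEGHKSTLIVF"), size=150))
        refs = {"Or5": ref}
        near = ref[:60] + "A" * 4 + ref[64:]
        models = [self._model(ref, 0), self._model(near, 1)]
        assign_names(models, refs, prefix="DnOr")
        names = sorted(m.name for m in models)
        assert names == ["DnOr5_1", "DnOr5like_2"]

    def test_suffix_order_partial_then_pseudo(self, rng):
        ref = "M" + "".join(rng.choice(list("ARNDQEGHKSTLIVF"), size=150))
        m = self._model(ref, 0, pseudo=True, integrity="partial",
                        flags={"n_terminus_present": True,
                               "c_terminus_present": False,
                               "fragmented": False})
        assign_names([m], {"Or7": ref}, prefix="HlOr")
        assert m.name == "HlOr7NP"     # partiality before pseudogene marker

    def test_distant_protein_gets_fresh_number(self, rng):
        ref = "M" + "".join(rng.choice(list("LIVFA"), size=150))
        other = "M" + "".join(rng.choice(list("DEKRNQ"), size=150))
        models = [self._model(other, 0)]
        assign_names(models, {"Or3": ref}, prefix="DnOr")
        assert models[0].name == "DnOr180"

    def test_permutation_invariance(self, rng):
        refs = {f"Or{k}": "M" + "".join(rng.choice(list("ARNDQEGHKSTLIVF"),
                                                   size=130))
                for k in range(1, 5)}
        prots = [refs[f"Or{k}"][:100] + refs[f"Or{k}"][100:][::-1]
                 for k in range(1, 5)]
        base = [self._model(p, i) for i, p in enumerate(prots)]
        assign_names(base, refs, prefix="DnOr")
        want = sorted(m.name for m in base)
        for perm_seed in range(20):
            order = np.random.default_rng(perm_seed).permutation(4)
            models = [self._model(prots[i], i) for i in order]
            assign_names(models, refs, prefix="DnOr")
            assert sorted(m.name for m in models) == want

    def test_partial_suffix_vocabulary(self):
        cases = [
            ((True, True, False), ""), ((True, False, False), "N"),
            ((False, True, False), "C"), ((False, False, False), "F"),
            ((True, True, True), "N_C"), ((True, False, True), "N_F"),
            ((False, True, True), "F_C"),
        ]
        for (n, c, f), want in cases:
            flags = {"n_terminus_present": n, "c_terminus_present": c,
                     "fragmented": f}
            assert partial_suffix(flags) == want


class TestSummary:
    def test_no_reference_all_novel(self, small_models):
        s = summarize_survey(small_models, None)
        assert s.novel == s.total == len(small_models)
        assert s.complete + s.partial == s.total

    def test_zero_divergence_identical_to_truth(self):
        spec = GenomeSpec(n_scaffolds=1, scaffold_length=60_000, n_genes=4,
                          n_pseudogenes=0, n_partials=0, divergence=0.0,
                          tandem_cluster_spec=[], seed=21)
        scaffolds, truth, queries, gff = generate_genome(spec)
        loci = survey_genome(scaffolds, queries)
        smap = {s.id: s for s in scaffolds}
        qmap = {q.id: q.seq for q in queries}
        models = [build_gene_model(l, smap[l.best.scaffold_id],
                                   qmap[l.best.query_id]) for l in loci]
        assign_names(models, qmap, prefix="DnOr")
        s = summarize_survey(models, gff)
        assert s.total == 4
        assert s.novel == 0 and s.identical == 4 and s.differing == 0
        # at zero divergence every protein equals its template and names are
        # the bare template numbers
        for m in models:
            assert m.protein == qmap[m.best_query_id]
            num = m.best_query_id.removeprefix("Or")
            assert m.name == f"DnOr{num}"

    def test_models_to_gff_valid(self, small_models, tmp_path):
        from orgws.io_formats import write_gff3, read_gff3
        recs = models_to_gff(small_models)
        p = tmp_path / "m.gff3"
        write_gff3(recs, p)
        assert len(read_gff3(p)) == len(recs)
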