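"""End-to-end orchestration of the gene-family survey.

``run_survey`` executes the stages in order — query curation, spliced search,
gene-model construction and naming, topology/domain validation, tandem-array
detection, upstream motif discovery — writing every artifact under an output
directory with a manifest of content hashes and a machine-readable report.
The run is deterministic for a fixed config, seed and inputs.

Where the study design calls for external predictor evidence (membrane
topology, domain hits) and none is supplied, the built-in emulators provide
it, keyed to the derived seed, so the pipeline remains self-contained.
Manual curation is represented by an optional override map (gene id ->
accepted exon set) applied after model construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import io_formats as io
from .gene_models import (assign_names, build_gene_model, models_to_gff,
                          summarize_survey)
from .motif_regulation import (discover_motifs_zoops, distribution_table,
                               extract_upstream, report_filter)
from .query_curation import curate_queries
from .spliced_search import RELAXED_SCHEME, STRICT_SCHEME, survey_genome
from .synthetic_data import emit_domain_hits, emit_topology_table
from .validation import validate_models
from .comparative import HomologyEdge, tandem_arrays


@dataclass
class PipelineConfig:
    """Every numeric parameter of the survey, with the study's defaults."""

    query_min_len: int = 100
    query_max_len: int = 600
    domain_evalue: float = 0.01
    max_intron_strict: int = 2000
    max_intron_relaxed: int = 10000
    matrix_strict: str = "BLOSUM62"
    matrix_relaxed: str = "PAM250"
    matrix_fallback: str = "BLOSUM45"
    hsp_min_score: int = 40
    min_chain_score: int = 120
    complete_len_threshold: int = 370
    phylo_min_len: int = 200
    upstream_window: int = 300
    upstream_min_len: int = 101
    meme_n_motifs: int = 10
    meme_w_min: int = 6
    meme_w_max: int = 10
    meme_evalue: float = 1e-5
    report_evalue: float = 1e-10
    report_min_occ: int = 41
    synteny_match_size: int = 5
    synteny_evalue: float = 1e-5
    topology_flip_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"config field {name} must be non-negative")


@dataclass
class RunReport:
    summary: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    tandem: list = field(default_factory=list)
    motifs: list = field(default_factory=list)
    motif_table: dict = field(default_factory=dict)
    models: list = field(default_factory=list)
    stages: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True,
                          allow_nan=False, default=str)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_survey(config: PipelineConfig, genome, queries, *,
               domain_hits=None, topology_rows=None, reference_gff=None,
               curation_overrides: dict | None = None,
               name_prefix: str = "Or", out_dir: str | Path | None = None,
               run_motifs: bool = True):
    """Run the full survey; returns ``(report, models, manifest)``.

    ``genome``/``queries`` are lists of sequence records.  ``domain_hits``
    (for query curation) and ``topology_rows`` (for validation) are optional
    external-evidence tables; absent, the emulators supply them.
    """
    config.validate()
    manifest: dict[str, str] = {}
    report = RunReport()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name, writer):
        if out is None:
            return
        path = out / name
        writer(path)
        manifest[name] = _hash_file(path)

    # stage 1: query curation ------------------------------------------------
    if domain_hits is None:
        domain_hits = emit_domain_hits({q.id: q.seq for q in queries},
                                       seed=config.seed + 11)
    curated, rejects = curate_queries(
        queries, domain_hits, config.query_min_len, config.query_max_len,
        evalue_cutoff=config.domain_evalue)
    report.stages.append({"stage": "curate", "n_in": len(queries),
                          "n_out": len(curated), "n_rejected": len(rejects)})

    # stage 2: spliced search ------------------------------------------------
    strict = STRICT_SCHEME.__class__(matrix_name=config.matrix_strict,
                                     gap_open=STRICT_SCHEME.gap_open,
                                     gap_extend=STRICT_SCHEME.gap_extend)
    relaxed = RELAXED_SCHEME.__class__(matrix_name=config.matrix_relaxed,
                                       gap_open=RELAXED_SCHEME.gap_open,
                                       gap_extend=RELAXED_SCHEME.gap_extend)
    loci = survey_genome(genome, curated, scheme=strict,
                         max_intron=config.max_intron_strict,
                         hsp_min_score=config.hsp_min_score,
                         min_chain_score=config.min_chain_score,
                         relaxed_scheme=relaxed,
                         max_intron_relaxed=config.max_intron_relaxed)
    report.stages.append({"stage": "survey", "n_loci": len(loci)})

    # stage 3: gene models, overrides, naming --------------------------------
    smap = {s.id: s for s in genome}
    qmap = {q.id: q.seq for q in curated}
    models = [build_gene_model(l, smap[l.best.scaffold_id],
                               qmap[l.best.query_id], strict)
              for l in loci]
    if curation_overrides:
        for gm in models:
            key = f"{gm.scaffold_id}:{gm.exons[0][0]}" if gm.exons else ""
            if key in curation_overrides:
                gm.exons = [tuple(x) for x in curation_overrides[key]]
    assign_names(models, {q.id: q.seq for q in queries}, prefix=name_prefix)
    summary = summarize_survey(models, reference_gff)
    report.summary = summary.as_dict()
    report.models = [{
        "name": gm.name, "scaffold": gm.scaffold_id, "strand": gm.strand,
        "exons": [list(e) for e in gm.exons], "integrity": gm.integrity,
        "pseudo": gm.pseudo, "lesions": [list(l) for l in gm.lesions],
        "best_query": gm.best_query_id, "protein_length": len(gm.protein),
    } for gm in models]
    report.stages.append({"stage": "models", "n_models": len(models)})

    # stage 4: validation ----------------------------------------------------
    proteins = {gm.name: gm.protein_for_analysis.replace("Z", "")
                for gm in models}
    model_domain_hits = emit_domain_hits(proteins, seed=config.seed + 13)
    if topology_rows is None:
        topology_rows = emit_topology_table(
            proteins, flip_rate=config.topology_flip_rate,
            seed=config.seed + 17)
    topo_map = io.topology_table_to_map(topology_rows)
    vreport = validate_models(proteins, topo_map, model_domain_hits,
                              evalue=config.domain_evalue)
    report.validation = vreport.summary()
    report.stages.append({"stage": "validate", "n": vreport.n})

    # stage 5: tandem arrays -------------------------------------------------
    from .spliced_search import local_protein_score
    tandems = []
    by_scaffold: dict[str, list] = {}
    for gm in models:
        by_scaffold.setdefault(gm.scaffold_id, []).append(gm)
    for scaf, ms in sorted(by_scaffold.items()):
        ms.sort(key=lambda m: m.exons[0][0])
        order = [m.name for m in ms]
        edges = []
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                a = ms[i].protein_for_analysis.replace("Z", "")
                b = ms[j].protein_for_analysis.replace("Z", "")
                _s, ident = local_protein_score(a, b)
                if ident >= 0.5:
                    edges.append(HomologyEdge(ms[i].name, ms[j].name,
                                              evalue=1e-20))
        for arr in tandem_arrays(order, edges,
                                 e_cutoff=config.synteny_evalue):
            tandems.append(arr)
    report.tandem = tandems
    report.stages.append({"stage": "tandem", "n_arrays": len(tandems)})

    # stage 6: upstream motifs -----------------------------------------------
    if run_motifs:
        model_gff = models_to_gff(models)
        upstream = extract_upstream(model_gff, genome,
                                    window=config.upstream_window,
                                    min_len=config.upstream_min_len)
        if len(upstream) >= 2:
            pssms, occurrences = discover_motifs_zoops(
                upstream, n_motifs=config.meme_n_motifs,
                w_min=config.meme_w_min, w_max=config.meme_w_max,
                evalue_cutoff=config.meme_evalue, seed=config.seed + 23)
            reported = report_filter(pssms, occurrences,
                                     evalue=config.report_evalue,
                                     min_occ=config.report_min_occ)
            report.motifs = [{
                "id": p.motif_id, "width": p.width, "consensus": p.consensus,
                "nsites": p.nsites, "log10_evalue": round(p.log10_evalue, 3),
                "reported": p.motif_id in {r.motif_id for r in reported},
            } for p in pssms]
            species_map = {o.gene_id: "survey" for o in occurrences}
            table = distribution_table(occurrences, species_map,
                                       {"survey": len(upstream)})
            report.motif_table = {c: table[c].tolist() for c in table.columns}
        report.stages.append({"stage": "motifs",
                              "n_upstream": len(upstream),
                              "n_motifs": len(report.motifs)})

    # artifacts ---------------------------------------------------------------
    emit("models.gff3", lambda p: io.write_gff3(models_to_gff(models), p))
    emit("proteins.fasta", lambda p: io.write_fasta(
        [io.Scaffold(id=gm.name, seq=gm.protein_for_analysis) for gm in models], p))
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        manifest["report.json"] = _hash_file(out / "report.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return report, models, manifest
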