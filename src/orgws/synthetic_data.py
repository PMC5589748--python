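"""Synthetic genomes with planted, ledgered truth.

The generator emulates the statistical structure a gene-family survey relies
on: multi-exon genes (``GT..AG`` introns at codon boundaries) derived from
template proteins at a controlled substitution divergence, tandem gene
clusters sharing a template, pseudogenizing lesions (in-frame stops and
1–2 nt frameshifts), scaffold-edge-truncated partial genes, upstream promoter
windows carrying motif sites sampled from planted PSSMs, and noisy
per-residue membrane-topology predictions.  Every planted feature is recorded
in a :class:`TruthSet` so downstream stages can be scored exactly.

Template proteins are synthetic 350–450 aa sequences with a fixed seven-helix
hydrophobicity layout (hydrophobic helices, hydrophilic loops), so topology
prediction and 7tm-style domain emulation are meaningful without copying any
real sequence.  Divergence is substitution-only and preserves the
helix/loop layout; the only indels are the explicit pseudogenizing lesions.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children (templates, structure, placement,
motifs, predictors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seq import revcomp, translate
from .io_formats import GffRecord, Scaffold, internal_to_gff, logger

HELIX_AA = "AILMFV"          # Kyte–Doolittle strongly hydrophobic (core)
HELIX_POOL = list("AILMFVCWYGST")   # helix draw: mostly hydrophobic, some noise
HELIX_P = np.array([.13, .15, .15, .08, .12, .15, .04, .04, .04, .03, .03, .04])
LOOP_AA = "DEKRNQSTGPH"      # hydrophilic / neutral
LOOP_POOL = list(LOOP_AA)
LOOP_P = np.array([.1, .12, .12, .1, .09, .09, .1, .1, .07, .06, .05])
HELIX_LEN = 21
STOPS = ("TAA", "TAG", "TGA")

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}


class SpecError(ValueError):
    """Raised when a GenomeSpec is internally inconsistent or over capacity."""


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome."""

    n_scaffolds: int = 5
    scaffold_length: int = 200_000
    gc: float = 0.38
    n_genes: int = 25
    exon_count_range: tuple[int, int] = (3, 9)
    intron_length_range: tuple[int, int] = (60, 1500)
    divergence: float = 0.15
    n_pseudogenes: int = 3
    n_partials: int = 4
    tandem_cluster_spec: list[tuple[int, int]] = field(default_factory=lambda: [(4, 2000)])
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.divergence <= 0.6):
            raise SpecError("divergence must be in [0, 0.6]")
        if self.n_pseudogenes + self.n_partials > self.n_genes:
            raise SpecError("n_pseudogenes + n_partials exceeds n_genes")
        if self.intron_length_range[0] < 40:
            raise SpecError("introns must be at least 40 nt")
        if not (0.0 < self.gc < 1.0):
            raise SpecError("gc must be a fraction in (0, 1)")
        if sum(size for size, _ in self.tandem_cluster_spec) > \
                self.n_genes - self.n_pseudogenes - self.n_partials:
            raise SpecError("tandem clusters exceed available complete genes")
        # capacity sanity check on the *typical* footprint; assembly itself
        # raises if an unlucky draw still overflows a scaffold
        mean_exons = sum(self.exon_count_range) / 2
        mean_intron = sum(self.intron_length_range) / 2
        typical = 450 * 3 + (mean_exons - 1) * mean_intron + 3500
        if self.n_genes * typical > self.n_scaffolds * self.scaffold_length:
            raise SpecError("total gene footprint exceeds scaffold capacity")


@dataclass
class GeneTruth:
    """Ground truth for one planted gene (forward 0-based half-open exons)."""

    id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    template_query_id: str
    gene_class: str                  # complete | pseudogene | partial_N | partial_C | partial_F
    clade: str
    protein: str                     # encoded protein (pre-lesion for pseudogenes)
    lesions: list[tuple[str, int]] = field(default_factory=list)
    expected_suffix: str = ""        # P / N / C / F / "" per the naming scheme
    cds_start_fwd: int = -1          # forward coordinate of first coding base
    upstream_ok: bool = True


@dataclass
class TruthSet:
    genes: list[GeneTruth] = field(default_factory=list)
    motif_placements: list[tuple[str, str, int, str]] = field(default_factory=list)
    # (gene_id, motif_id, offset from upstream-window start, planted word)
    planted_pssms: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": [asdict(g) for g in self.genes],
            "motif_placements": list(self.motif_placements),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# template proteins and topology
# ---------------------------------------------------------------------------

def make_template_protein(rng: np.random.Generator,
                          length: int | None = None) -> tuple[str, str]:
    """A 7-helix template protein and its true topology string."""
    if length is None:
        length = int(rng.integers(350, 451))
    n_helix = 7
    loop_total = length - 1 - n_helix * HELIX_LEN
    # 8 loops (N-term, 6 inter-helix, C-term), each at least 12 residues
    base = 12
    slack = loop_total - 8 * base
    extras = rng.multinomial(max(slack, 0), np.full(8, 1 / 8))
    loops = [base + int(e) for e in extras]
    seq = ["M"]
    topo = ["i"]
    side = "i"
    for k in range(n_helix):
        n_loop = loops[k] - (1 if k == 0 else 0)
        seq.extend(rng.choice(LOOP_POOL, size=n_loop, p=LOOP_P))
        topo.extend(side * n_loop)
        seq.extend(rng.choice(HELIX_POOL, size=HELIX_LEN, p=HELIX_P))
        topo.extend("M" * HELIX_LEN)
        side = "o" if side == "i" else "i"
    seq.extend(rng.choice(LOOP_POOL, size=loops[7], p=LOOP_P))
    topo.extend(side * loops[7])
    return "".join(seq[:length]), "".join(topo[:length])


def infer_topology(protein: str) -> str:
    """Hydropathy-derived per-residue topology (the emulator's 'truth').

    Residues in smoothed hydrophobic stretches are labelled M; the remaining
    segments alternate i/o starting inside, as in the template layout.
    """
    kd = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
          "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
          "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
          "Y": -1.3, "V": 4.2, "X": 0.0, "Z": -1.0, "B": -3.5, "*": 0.0}
    vals = np.array([kd.get(c, 0.0) for c in protein])
    if len(vals) < 7:
        return "i" * len(protein)
    kernel = np.ones(7) / 7
    smooth = np.convolve(vals, kernel, mode="same")
    labels = np.where(smooth > 1.0, "M", "?")
    out = []
    side = "i"
    prev_m = False
    for lab in labels:
        if lab == "M":
            out.append("M")
            prev_m = True
        else:
            if prev_m:
                side = "o" if side == "i" else "i"
            out.append(side)
            prev_m = False
    return "".join(out)


def mutate_protein(protein: str, topology: str, divergence: float,
                   rng: np.random.Generator) -> str:
    """Substitution-only divergence preserving the helix/loop layout and the
    initial methionine."""
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < divergence:
            pool, p = (HELIX_POOL, HELIX_P) if topology[i] == "M" else (LOOP_POOL, LOOP_P)
            new = out[i]
            while new == out[i]:
                new = str(rng.choice(pool, p=p))
            out[i] = new
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        opts = _CODONS[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# gene cassettes
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _choose_exon_cuts(n_codons: int, n_exons: int, rng: np.random.Generator,
                      min_exon_codons: int = 20) -> list[int]:
    """Codon indices (phase-0 cut points) splitting the CDS into exons."""
    while n_exons > 1 and n_codons < min_exon_codons * n_exons:
        n_exons -= 1
    if n_exons == 1:
        return []
    slack = n_codons - min_exon_codons * n_exons
    extras = np.sort(rng.integers(0, slack + 1, size=n_exons - 1))
    return [min_exon_codons * (i + 1) + int(extras[i]) for i in range(n_exons - 1)]


@dataclass
class _Cassette:
    """A gene in coding orientation: sequence plus exon intervals within it."""

    seq: str
    exons: list[tuple[int, int]]     # coding-orientation, 0-based half-open
    protein: str
    lesions: list[tuple[str, int]] = field(default_factory=list)


def build_cassette(protein: str, spec: GenomeSpec,
                   rng: np.random.Generator) -> _Cassette:
    cds = back_translate(protein, rng) + STOPS[int(rng.integers(3))]
    n_codons = len(cds) // 3
    n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
    cuts = [3 * c for c in _choose_exon_cuts(n_codons, n_exons, rng)]
    return _assemble_cassette(cds, cuts, spec, rng, protein)


def _assemble_cassette(cds: str, cuts: list[int], spec: GenomeSpec,
                       rng: np.random.Generator, protein: str) -> _Cassette:
    parts = []
    exons = []
    pos = 0
    prev = 0
    for cut in cuts + [len(cds)]:
        exon = cds[prev:cut]
        exons.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if cut < len(cds):
            ilen = int(rng.integers(spec.intron_length_range[0],
                                    spec.intron_length_range[1] + 1))
            intron = "GT" + random_dna(rng, ilen - 4, spec.gc) + "AG"
            parts.append(intron)
            pos += ilen
        prev = cut
    return _Cassette(seq="".join(parts), exons=exons, protein=protein)


def pseudogenize(cds: str, cuts: list[int], mode: str,
                 rng: np.random.Generator) -> tuple[str, list[int], tuple[str, int]]:
    """Apply one pseudogenizing lesion to a CDS (before intron insertion).

    Returns the mutated CDS, shifted cut points, and the truth lesion
    ``(type, position)`` — codon index for ``inframe_stop``, CDS nt offset for
    ``frameshift``.
    """
    n_codons = len(cds) // 3 - 1          # exclude the stop codon
    if n_codons < 2:
        raise SpecError("cannot pseudogenize a 1-codon gene")
    if mode == "inframe_stop":
        bounds = [0] + cuts + [len(cds)]
        # keep the lesion well inside one exon and away from the termini
        candidates = [c for c in range(10, n_codons - 10)
                      if all(3 * c - b >= 15 and e - 3 * c >= 18
                             for b, e in zip(bounds, bounds[1:])
                             if b <= 3 * c < e)]
        codon = int(rng.choice(candidates))
        stop = STOPS[int(rng.integers(3))]
        new = cds[:3 * codon] + stop + cds[3 * codon + 3:]
        return new, list(cuts), ("inframe_stop", codon)
    if mode == "frameshift":
        bounds = [0] + cuts + [len(cds)]
        spans = [(b, e) for b, e in zip(bounds, bounds[1:])]
        b, e = max(spans, key=lambda s: s[1] - s[0])
        offset = int(rng.integers(b + 60, e - 60))
        if rng.random() < 0.5:
            new = cds[:offset] + cds[offset + 1:]          # 1 nt deletion
            shift = -1
        else:
            ins = "ACGT"[int(rng.integers(4))] * int(rng.integers(1, 3))
            new = cds[:offset] + ins + cds[offset:]
            shift = len(ins)
        new_cuts = [c + shift if c > offset else c for c in cuts]
        return new, new_cuts, ("frameshift", offset)
    raise ValueError(f"unknown pseudogene mode {mode!r}")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _truncate_for_partial(cassette: _Cassette, keep: str,
                          rng: np.random.Generator) -> tuple[_Cassette, int]:
    """Cut a cassette inside an intron so only one terminus survives.

    ``keep`` is "N" (keep the 5' exons) or "C" (keep the 3' exons).  The kept
    portion stays between ~100 and ~340 residues so the model is
    unambiguously partial.  Returns the clipped cassette and the number of
    retained codons.
    """
    exon_codons = np.array([(e - s) // 3 for s, e in cassette.exons])
    cum = np.cumsum(exon_codons)
    total = int(cum[-1])
    ok = [j for j in range(1, len(cassette.exons))
          if 100 <= (cum[j - 1] if keep == "N" else total - cum[j - 1]) <= 340]
    if not ok:
        ok = [max(1, len(cassette.exons) // 2)]
    j = int(rng.choice(ok))           # cut inside intron j-1..j
    intron_start = cassette.exons[j - 1][1]
    intron_end = cassette.exons[j][0]
    cut = (intron_start + intron_end) // 2
    if keep == "N":
        seq = cassette.seq[:cut]
        exons = cassette.exons[:j]
        kept = int(cum[j - 1])
    else:
        seq = cassette.seq[cut:]
        exons = [(s - cut, e - cut) for s, e in cassette.exons[j:]]
        kept = total - int(cum[j - 1])
    return _Cassette(seq=seq, exons=exons, protein=cassette.protein,
                     lesions=cassette.lesions), kept


def generate_genome(spec: GenomeSpec):
    """Build the genome: returns ``(scaffolds, truth, queries, gff_records)``.

    Deterministic given ``spec.seed``; the truth GFF matches planted exon
    coordinates exactly (CDS features include the stop codon).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_templates, rng_struct, rng_place, rng_seq = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    n_cluster = sum(size for size, _ in spec.tandem_cluster_spec)
    n_templates = spec.n_genes - n_cluster + len(spec.tandem_cluster_spec)
    templates = []
    for i in range(n_templates):
        prot, topo = make_template_protein(rng_templates)
        templates.append((f"Or{i + 1}", prot, topo))

    # gene plan: (template_idx, role, cluster_id)
    plan: list[tuple[int, str, int]] = []
    t = 0
    for ci, (size, _spacing) in enumerate(spec.tandem_cluster_spec):
        for _ in range(size):
            plan.append((t, "complete", ci))
        t += 1
    n_rest = spec.n_genes - n_cluster
    roles = (["pseudogene"] * spec.n_pseudogenes + ["partial"] * spec.n_partials
             + ["complete"] * (n_rest - spec.n_pseudogenes - spec.n_partials))
    for k in range(n_rest):
        plan.append((t + k, roles[k], -1))

    # build cassettes
    built: list[dict] = []
    n_stop_pseudo = (spec.n_pseudogenes + 1) // 2
    pseudo_seen = 0
    partial_seen = 0
    for gi, (ti, role, cluster) in enumerate(plan):
        tid, tprot, ttopo = templates[ti]
        mutated = mutate_protein(tprot, ttopo, spec.divergence, rng_struct)
        cds = back_translate(mutated, rng_struct) + STOPS[int(rng_struct.integers(3))]
        n_codons = len(cds) // 3
        n_exons = int(rng_struct.integers(spec.exon_count_range[0],
                                          spec.exon_count_range[1] + 1))
        cuts = [3 * c for c in _choose_exon_cuts(n_codons, n_exons, rng_struct)]
        lesions: list[tuple[str, int]] = []
        gene_class = "complete"
        suffix = ""
        if role == "pseudogene":
            mode = "inframe_stop" if pseudo_seen < n_stop_pseudo else "frameshift"
            pseudo_seen += 1
            cds, cuts, lesion = pseudogenize(cds, cuts, mode, rng_struct)
            lesions.append(lesion)
            gene_class = "pseudogene"
            suffix = "P"
        cassette = _assemble_cassette(cds, cuts, spec, rng_struct, mutated)
        cassette.lesions = lesions
        keep = None
        if role == "partial":
            keep = "N" if partial_seen % 2 == 0 else "C"
            partial_seen += 1
            cassette, _kept = _truncate_for_partial(cassette, keep, rng_struct)
            gene_class = f"partial_{keep}"
            suffix = keep
        built.append({"id": f"g{gi + 1:03d}", "template": tid, "cassette": cassette,
                      "class": gene_class, "suffix": suffix, "cluster": cluster,
                      "keep": keep, "protein": mutated})

    # assign genes to scaffolds
    per_scaffold: list[list[dict]] = [[] for _ in range(spec.n_scaffolds)]
    clusters: dict[int, list[dict]] = {}
    singles: list[dict] = []
    for g in built:
        if g["cluster"] >= 0:
            clusters.setdefault(g["cluster"], []).append(g)
        else:
            singles.append(g)
    order = list(clusters.values()) + [[g] for g in singles]
    lengths = [0] * spec.n_scaffolds
    for group in order:
        footprint = sum(len(g["cassette"].seq) for g in group) + 3000 * len(group)
        sc = int(np.argmin(lengths))
        per_scaffold[sc].extend(group)
        lengths[sc] += footprint

    margin = 2500
    cluster_spacing = {ci: sp for ci, (_sz, sp) in
                       enumerate(spec.tandem_cluster_spec)}
    scaffolds: list[Scaffold] = []
    truth = TruthSet()
    for si in range(spec.n_scaffolds):
        name = f"scaffold_{si + 1}"
        genes = per_scaffold[si]
        left_edge = [g for g in genes if g["keep"] == "C"][:1]
        right_edge = [g for g in genes if g["keep"] == "N"][:1]
        interior = [g for g in genes if g not in left_edge + right_edge]
        pieces: list[str] = []
        pos = 0

        def emit_gene(g, at_pos):
            cassette = g["cassette"]
            strand = "+" if (g["keep"] is not None or g["cluster"] >= 0
                             or rng_place.random() < 0.5) else "-"
            if strand == "+":
                seq = cassette.seq
                exons = [(at_pos + s, at_pos + e) for s, e in cassette.exons]
                cds_start = at_pos + cassette.exons[0][0] \
                    if g["keep"] != "C" else -1
            else:
                seq = revcomp(cassette.seq)
                L = len(cassette.seq)
                exons = sorted((at_pos + L - e, at_pos + L - s)
                               for s, e in cassette.exons)
                cds_start = at_pos + L - cassette.exons[0][0]
            truth.genes.append(GeneTruth(
                id=g["id"], scaffold=name, strand=strand, exons=exons,
                template_query_id=g["template"], gene_class=g["class"],
                clade=g["template"], protein=g["protein"],
                lesions=list(g["cassette"].lesions),
                expected_suffix=g["suffix"], cds_start_fwd=cds_start,
                upstream_ok=(g["keep"] != "C")))
            return seq

        if left_edge:
            seq0 = emit_gene(left_edge[0], 0)
            pieces.append(seq0)
            pos = len(seq0)
        prev_cluster = -2
        for g in interior:
            if g["cluster"] >= 0 and g["cluster"] == prev_cluster:
                gap = cluster_spacing[g["cluster"]]   # fixed tandem spacing
            else:
                gap = margin + int(rng_place.integers(0, 2000))
            pieces.append(random_dna(rng_seq, gap, spec.gc))
            pos += gap
            gseq = emit_gene(g, pos)
            pieces.append(gseq)
            pos += len(gseq)
            prev_cluster = g["cluster"]
        seq_so_far = sum(map(len, pieces))
        if right_edge:
            cassette = right_edge[0]["cassette"]
            tail_gap = spec.scaffold_length - seq_so_far - len(cassette.seq)
            if tail_gap < margin:
                raise SpecError("scaffold capacity overflow placing edge gene")
            pieces.append(random_dna(rng_seq, tail_gap, spec.gc))
            pieces.append(emit_gene(right_edge[0],
                                    spec.scaffold_length - len(cassette.seq)))
        else:
            tail_gap = spec.scaffold_length - seq_so_far
            if tail_gap < 0:
                raise SpecError("scaffold capacity overflow")
            pieces.append(random_dna(rng_seq, tail_gap, spec.gc))
        scaffolds.append(Scaffold(id=name, seq="".join(pieces)))
        assert scaffolds[-1].length == spec.scaffold_length

    queries = [Scaffold(id=tid, seq=prot) for tid, prot, _ in templates]
    gff = truth_gff(truth)
    return scaffolds, truth, queries, gff


def truth_gff(truth: TruthSet) -> list[GffRecord]:
    records: list[GffRecord] = []
    for g in truth.genes:
        gs = min(s for s, _ in g.exons)
        ge = max(e for _, e in g.exons)
        s1, e1 = internal_to_gff(gs, ge)
        records.append(GffRecord(g.scaffold, "orgws_sim", "gene", s1, e1, ".",
                                 g.strand, ".", {"ID": g.id, "Name": g.id}))
        records.append(GffRecord(g.scaffold, "orgws_sim", "mRNA", s1, e1, ".",
                                 g.strand, ".", {"ID": g.id + ".t1", "Parent": g.id}))
        exons = sorted(g.exons, reverse=(g.strand == "-"))
        phase = 0
        for s, e in exons:
            s1, e1 = internal_to_gff(s, e)
            records.append(GffRecord(g.scaffold, "orgws_sim", "CDS", s1, e1, ".",
                                     g.strand, str(phase),
                                     {"ID": g.id + ".cds", "Parent": g.id + ".t1"}))
            phase = (3 - ((e - s) - phase) % 3) % 3
    return records


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def sample_site(pssm, rng: np.random.Generator) -> str:
    return "".join("ACGT"[rng.choice(4, p=row / row.sum())] for row in pssm.probs)


def plant_upstream_motifs(scaffolds: list[Scaffold], truth: TruthSet, pssms,
                          clade_rates: dict, seed: int,
                          window: int = 300, max_retry: int = 10):
    """Write PSSM-sampled sites into 300-nt upstream windows, on the coding
    strand, at clade-dependent rates.

    ``clade_rates`` maps clade -> {motif_id: probability} (or a scalar applied
    to every motif).  Placements are recorded in ``truth.motif_placements``.
    Returns the updated scaffolds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seqs = {s.id: list(s.seq) for s in scaffolds}
    truth.planted_pssms = list(pssms)
    for gene in truth.genes:
        if not gene.upstream_ok or gene.cds_start_fwd < 0:
            continue
        rates = clade_rates.get(gene.clade, clade_rates.get("default", {}))
        used: list[tuple[int, int]] = []
        for pssm in pssms:
            p = rates if isinstance(rates, (int, float)) else rates.get(pssm.motif_id, 0.0)
            if rng.random() >= p:
                continue
            w = pssm.width
            word = sample_site(pssm, rng)
            placed = False
            for _ in range(max_retry):
                off = int(rng.integers(0, window - w + 1))
                if any(off < e and off + w > s for s, e in used):
                    continue
                _write_upstream(seqs[gene.scaffold], gene, off, word, window)
                used.append((off, off + w))
                truth.motif_placements.append((gene.id, pssm.motif_id, off, word))
                placed = True
                break
            if not placed:
                logger.warning("motif %s: no free slot upstream of %s",
                               pssm.motif_id, gene.id)
    return [Scaffold(id=s.id, seq="".join(seqs[s.id])) for s in scaffolds]


def _write_upstream(seq: list[str], gene: GeneTruth, off: int, word: str,
                    window: int) -> None:
    """``off`` is the 0-based offset from the window start; the window is the
    ``window`` nt immediately 5' of the translation start, coding strand."""
    if gene.strand == "+":
        start = gene.cds_start_fwd - window + off
        seq[start:start + len(word)] = list(word)
    else:
        rc = revcomp(word)
        end = gene.cds_start_fwd + window - off
        seq[end - len(word):end] = list(rc)


# ---------------------------------------------------------------------------
# predictor emulation
# ---------------------------------------------------------------------------

def emit_predictor_topologies(protein: str, true_topology: str,
                              flip_rate: float, n_predictors: int = 3,
                              seed: int = 0) -> list[str]:
    """Three noisy per-residue topology strings (emulated TMH predictors).

    Each predictor flips residue states independently at ``flip_rate`` (to one
    of the other two states), then short runs (< 3) are reverted to truth —
    real predictors do not emit 1–2 residue segments.
    """
    if not (0.0 <= flip_rate <= 0.5):
        raise SpecError("flip_rate must be in [0, 0.5]")
    if len(true_topology) != len(protein):
        raise ValueError("topology/protein length mismatch")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    states = "Mio"
    preds = []
    n = len(true_topology)
    for _ in range(n_predictors):
        arr = list(true_topology)
        flips = rng.random(n) < flip_rate
        for i in np.nonzero(flips)[0]:
            others = [s for s in states if s != arr[i]]
            arr[i] = others[int(rng.integers(2))]
        # revert runs shorter than 3
        i = 0
        while i < n:
            j = i
            while j < n and arr[j] == arr[i]:
                j += 1
            if j - i < 3:
                arr[i:j] = list(true_topology[i:j])
            i = j
        preds.append("".join(arr))
    return preds


def emit_domain_hits(proteins: dict[str, str], seed: int = 0,
                     domain: str = "7tm_6") -> list:
    """Emulated domain-search evidence: proteins whose hydropathy profile
    shows ≥2 helices get a (length-graded) significant E-value; others do not.
    """
    from .io_formats import HitRecord
    from .validation import count_tmh

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for pid, seq in sorted(proteins.items()):
        n_helix = count_tmh(infer_topology(seq))
        if n_helix >= 2:
            exponent = 1.5 * n_helix + rng.uniform(0.0, 3.0)
            ev = 10.0 ** (-exponent)
        else:
            ev = float(rng.uniform(0.05, 10.0))
        rows.append(HitRecord(query_id=pid, target_id=domain, evalue=ev,
                              bitscore=max(0.0, 30.0 * n_helix), domain_name=domain))
    return rows


def emit_topology_table(proteins: dict[str, str], flip_rate: float = 0.05,
                        seed: int = 0) -> list[tuple[str, str, str]]:
    """Topology-dialect rows for three emulated predictors per protein."""
    rows = []
    ss = np.random.SeedSequence(seed)
    child = {pid: int(s.generate_state(1)[0] % (2 ** 31))
             for pid, s in zip(sorted(proteins), ss.spawn(len(proteins)))}
    for pid in sorted(proteins):
        topo = infer_topology(proteins[pid])
        preds = emit_predictor_topologies(proteins[pid], topo, flip_rate,
                                          seed=child[pid])
        for k, p in enumerate(preds):
            rows.append((pid, f"predictor_{k + 1}", p))
    return rows
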