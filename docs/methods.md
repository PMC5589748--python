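# Methods

This note documents the models and procedures implemented in `orgws`, the
parameters that matter, the synthetic data they are tested on, and the
numerical choices made where the design was genuinely open.

## Spliced protein-to-genome search

**Alignment model.** Each query protein is aligned against all six
translation frames of each scaffold with exact affine-gap Smith–Waterman
(a length-k gap costs `gap_open + k·gap_extend`). The strict pass uses
BLOSUM62 with −11/−1; the completion pass uses PAM250 with −7/−1 and a
10 kb intron cap, run only on models whose query coverage looks incomplete.
Codons containing N translate to X, which is forced to score −1 against
everything: assembly gaps are mismatches and never create signal. The DP is
a numba kernel with matrices laid out (target, query); all non-overlapping
local optima at or above `hsp_min_score` (default 40) are harvested by
iterative masking — each accepted alignment's target footprint becomes a
hard barrier and only the affected DP columns are recomputed until the state
reconverges, so secondary optima remain exact.

**HSP hygiene.** Local alignments systematically fray past exon and lesion
boundaries: AT-rich non-coding DNA translates to hydrophobic-leaning
peptide, which scores weakly positive against membrane-protein queries.
Before chaining, each HSP is split wherever its alignment skips ≥ 40 nt of
genome (an intron bridged as a query gap), and each end is trimmed at the
minimum of a running +1/−1 match/mismatch sum (cut when the drop reaches 3).
This trim removes near-random-identity tails of any length while never
cutting genuinely homologous sequence, and it is what keeps neighbouring
exons' HSPs colinear. `translated_local_align` itself is untouched — its
top HSP score is exactly the Smith–Waterman optimum, which is how the
brute-force oracle tests check it.

**Chaining.** Colinear HSPs (same query, scaffold, strand) are chained by
sparse DP. A junction is admissible as an *intron* when the genomic gap is
in [40, max_intron] (2000 strict / 10000 relaxed), as a *contiguous or
frameshift* join when the genomic gap is below 40 nt (down to 60 nt of
overlap); query-side slack allows up to 10 skipped and up to 120 overlapped
residues, overlap costing 2 per residue. Canonical `GT..AG` introns earn a
+10 splice bonus; joins whose genomic-minus-query offset is not a multiple
of three pay the frameshift penalty (−20). Admitting small non-intron gaps
is what keeps a frameshifted pseudogene a single locus instead of two.
Chains are peeled best-first, each HSP used at most once.

**Locus selection.** Chains below `min_chain_score` (default 120) are
discarded first — for BLOSUM62 −11/−1 statistics on a megabase genome the
expected number of spurious chains above 120 is ≪ 1, while the weakest real
model (a ~100-residue partial) scores several hundred. Chains whose exact
per-residue identity is below 0.45 are also discarded: reverse-complement
"shadows" of real genes and cross-family matches between paralogs reach
high scores but plateau near 30% identity, and such a model spanning two
tandem copies would otherwise weld their loci together. Surviving models on
one scaffold and strand are pooled by transitive span overlap (≥ 1 nt) and
the best model per locus kept (ties: longer span, leftmost, query id). A
locus mostly covered by a higher-scoring opposite-strand locus is dropped as
a strand shadow. After the completion pass the pooling is repeated, since
refinement can grow spans.

## Gene-model construction

Chain junction boundaries are resolved against the genomic sequence. For
each adjacent segment pair, candidate donor/acceptor positions are
enumerated in windows of 90 nt plus three times the query overlap around the
current boundaries: intron candidates require `GT..AG` and ≥ 40 nt;
contiguous/frameshift candidates keep the genomic gap below 40 nt.
Candidates are scored by re-translating the boundary region against the
query (using the chain's own aligned pairs, extrapolated codon-by-codon
beyond them), plus the splice bonus or frameshift penalty; a query residue
claimed by both sides costs 6 (more than a typical exact match, so
double-counting can never win), a skipped residue costs 1. Ties prefer the
smallest boundary movement. Model termini are trimmed with the same
running-sum rule as HSP ends; when the alignment ends within 5 residues of
a query terminus the exon is extended to the query end, and a stop codon
immediately after the final exon is included in the CDS.

Translation is segment-wise on each segment's own codon grid, so a
frameshift resumes downstream translation in the corrected frame with an
`X` at the breakpoint; missing internal residues at intron junctions become
`Z` runs; in-frame stops appear as `*` and are rendered `X` in the
hypothetical protein. A model is *pseudo* iff it has a stop or frameshift
lesion. It is *complete* iff both termini are present (alignment within 5
residues of each query end) and no internal junction skips ≥ 15 residues —
or the protein exceeds 370 aa, which counts as complete regardless.
Pseudogene status is orthogonal to complete/partial.

**Naming.** Similarity to the reference set is the local-alignment score
(BLOSUM62), with identity normalised by the shorter protein so short chance
alignments cannot look identical. Reciprocal best pairs take the reference
number; one-directional best hits append `like`; when several new proteins
share a best reference they are numbered `_1, _2, …` in descending
similarity (the reciprocal member, if any, without `like`). Partial models
append the letter of the portion *present* (`N`, `C`; `F` when neither
terminus is present; `N_C`, `N_F`, `F_C` for fragmented combinations), and
pseudogenes append `P` last. Proteins under 35% identity to every reference
receive fresh numbers starting at 180. Naming is a pure function of the
similarity matrix: permuting the input order never changes a name.

## Validation

The topology consensus labels a residue M when at least two of three
per-residue predictions do; a helix is a maximal consensus-M run of ≥ 10
residues (below the ~17-residue physical helix but robust to boundary
noise; configurable). A protein passes when it has a 7tm_6 hit at E ≤ 0.01
and ≥ 6 consensus helices. Predictor outputs are ingested as per-residue
strings; the predictors themselves are out of scope.

## Comparative analyses

Reciprocal best hits partition best-hit edges into 1:1, 1:many and
many:many classes by connected components. Collinearity uses the MCScanX
parameterisation — edges at E ≤ 1e-5, blocks of ≥ 5 anchors, score
`50·anchors − rank gaps` — as a deliberate simplification of the tool's full
scoring (the capped-extension details are tool-specific); blocks are peeled
best-first per scaffold pair and orientation from one shared anchor pool.
Tandem arrays are maximal runs of homologous genes with at most one
intervening gene. The count-vs-genome-size correlation is a plain Pearson r;
the bundled species table is an illustrative demo, not a curated compilation.

## Clade placement

Production-scale repertoire phylogenetics (iterative alignment,
maximum-likelihood trees, bootstraps) is out of scope; clade *placement* is
the consumable output, and at desk scale it is served by neighbor-joining on
identity distances (1 − identity over mutually non-gap columns; pairs with
< 30 shared columns are flagged). NJ uses deterministic lexicographic
tie-breaking and clamps negative branch lengths to zero, moving the deficit
to the sister edge. Labels propagate from reference leaves: an unlabeled
leaf takes the clade of the smallest enclosing subtree whose ≥ 2 labeled
leaves are unanimous (support 1.0), else the nearest labeled leaf by path
length decides (support 0.5). An externally computed tree can be supplied
for assignment-only use. The unanimous-subtree rule is one formalisation of
clade membership that is otherwise drawn by eye against published trees.

## Upstream motif analysis

Upstream windows are the 300 nt 5' of the translation start (the first CDS
base — gene models here are CDS-defined, so the ATG, not the transcription
start, is the anchor), on the coding strand; records of ≤ 100 nt are
dropped. Discovery fits the ZOOPS model (zero or one site per sequence,
either strand) by EM from word seeds: per width 6–10, 12 data-sampled seeds
get a short burn-in and the best start runs to convergence; the best width's
motif is kept at E ≤ 1e-5, its MAP occurrences masked with N, and the
search repeats up to 10 motifs. The tracked objective (data log-likelihood
plus the Dirichlet pseudocount prior, pseudocount 0.01) is checked
non-decreasing at every iteration. The background is the 0-order nucleotide
composition of the input set.

**Significance surrogate.** The motif E-value refers twice the
log-likelihood ratio of the site alignment to a chi-square with 3·width
degrees of freedom and Bonferroni-corrects, in log space, for the selection
the fit actually performed: each site pays the log-count of candidate
positions (both strands), plus terms for the seeds × widths tried and for
the site-count choice. Sites are ranked best-first and the E-value is
minimised over the number kept — MEME's own device for choosing `nsites` —
so an EM solution that absorbed background sequences is still judged on its
strong core; the kept subset is what is reported and masked. The binomial
which-sequences term was deliberately left out: the ZOOPS mixture already
prices sequence membership through γ, and with it the statistic double-pays
and loses the planted signal at realistic site strengths, while without it
the null (EM on i.i.d. sequences) stays comfortably non-significant — both
checked by simulation. A Monte-Carlo shuffled null was considered and
rejected: a few hundred shuffles cannot resolve p-values anywhere near the
1e-5/1e-10 thresholds, and EM's selection bias would go uncorrected. The
surrogate preserves ordering, honours the thresholds, and is fully
seedable; it is not the E-value any particular external tool prints. The reporting filter
keeps motifs with E < 1e-10 *and* more than 40 occurrences (a conjunction;
the source procedure does not state an order).

PSSM scanning computes log-odds scores rescaled to integers at 1e-3
granularity; the p-value of a score is the exact tail probability of the
integer score distribution under the background, obtained by convolution
over columns, so scan p-values equal exhaustive word enumeration exactly.
Distribution tables count a gene once per motif and divide by the supplied
per-group denominators (per-species counts used in the phylogeny, when
reproducing that style of table).

## Synthetic data: what it emulates and what it does not

Template proteins are synthetic 350–450 aa sequences with a fixed
seven-helix layout: helices drawn from a hydrophobic-weighted pool, loops
from a hydrophilic pool, so hydropathy-based topology inference and the
domain emulator behave like their real counterparts without copying any
real sequence. Genes are back-translated with uniform synonymous codons and
split into 3–9 exons at codon boundaries (phase-0 introns only — this keeps
the truth alignment and the exon-recovery oracle unambiguous, at the cost
of not exercising phase-1/2 junctions; the junction-resolution code itself
supports split codons). Introns are 60–1500 nt with forced `GT..AG`.
Divergence is substitution-only (the stated expected substitution fraction,
layout-preserving); the only indels are the explicit pseudogene lesions
(a sense codon replaced by a stop, or a 1–2 nt frameshift). Partial genes
are made by truncating the *scaffold* mid-intron so that 100–340 residues
survive — unambiguously partial, with the cause the assembly, not the gene.
Tandem clusters share one template at the same divergence and fixed
spacing. Background DNA is i.i.d. at the specified GC (0.38 by default,
AT-rich as in bee genomes). Motif sites are sampled from planted PSSMs and
written at uniform offsets within the upstream window at clade-dependent
rates. Topology predictors are emulated as truth plus independent
per-residue flips (runs < 3 reverted); domain search is emulated from the
hydropathy helix count.

Not emulated: codon-usage bias, repeats and segmental duplications,
assembly errors, alternative isoforms, phase-1/2 introns, non-canonical
splice sites, real predictor error structure. Passing tests therefore show
the pipeline's logic is correct under the stated statistical structure, not
that it handles every artefact of a real assembly.

**Reference study conditions.** The default `GenomeSpec` is the fixed test
bed used throughout: 5 scaffolds × 200 kb, 25 genes (3 pseudogenes — two
stop, one frameshift — 4 edge partials, one tandem cluster of 4 at 2 kb
spacing), divergence 0.15. All randomness flows from one integer seed via
named `SeedSequence` children.

## Numerical choices and degenerate inputs

- DP matrices are int16; H stays in [0, ~7650], E/F are bounded below by
  `gap_open + gap_extend` because H ≥ 0, so no clamping is needed beyond a
  −30000 sentinel at masked barriers.
- `hsp_min_score` 40 is a deliberate low harvest threshold; specificity is
  enforced at chain level (score ≥ 120, identity ≥ 0.45), not per HSP.
- Chain and naming tie-breaks are documented and total, so every output is
  independent of input order.
- Empty inputs: empty hit tables parse to empty lists; a gene without CDS is
  skipped with a warning; an all-gap alignment column set raises; a distance
  matrix must be finite and symmetric or `nj_tree` refuses.
- Motif discovery raises when fewer than two sequences or none as long as
  the minimum width; sequences shorter than a motif width are skipped in
  scanning.

## Known limitations

- The aligner is exact but O(query × genome) per frame; surveys beyond tens
  of megabases would need heuristic seeding, which is deliberately not
  implemented.
- Frameshift detection relies on frame-split HSP chains; a frameshift within
  ~20 codons of an exon end can be absorbed by boundary resolution and
  missed.
- At divergences well above ~0.3 the identity-based trims and the 0.45
  model-identity floor begin to erode genuine signal; the generator's
  calibrated range is 0–0.25.
- The motif E-value is a surrogate (see above); absolute values are not
  comparable across tools, only across motifs within a run.
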