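# Methods

This note documents the models, conventions and design choices behind
`exonweave`, in the spirit of a methods appendix: enough detail to judge
what the package computes, under which assumptions, and what its tests do
and do not demonstrate.

## Coordinates, strands and canonical forms

All internal intervals are 0-based half-open in genome coordinates; GFF3,
GTF, GenBank and the compact alignment dialect convert to 1-based
inclusive at exactly one place, the I/O boundary in `formats`.  Minus-strand
features are stored in genome coordinates and reversed on demand.  Gene
models are canonicalized to *stop-codon-included* CDS at read time (GTF
`stop_codon` features are merged into the terminal CDS), because dialects
disagree on stop-codon placement and exact-coordinate comparison must not
be confounded by convention.  Completeness is inferred per transcript in a
fixed preference order: explicit `start_codon`/`stop_codon` features when
the file carries any, else a `completeness` attribute, else complete.

## Intron evidence scoring

A spliced protein-to-genome alignment chain contributes one candidate
intron per pair of consecutive aligned blocks.  Two scores are computed
per distinct intron `(seq, strand, interval)`:

**Intron border alignment (IBA).**  Let the columns flanking the junction
on one side be classified as identical (credit 1), positive substitution
(credit `substitution_credit`, default 0.5) or mismatch (credit 0), one
column per aligned codon.  The side score is the weighted mean of credits
over at most `window` (default 15) columns, the k-th column from the
junction weighted `decay^k` (default `decay` = 0.8, i.e. the column right
at the splice site carries ~3× the weight of the fifth column).  IBA is
the mean of the two side scores, multiplied by `event_penalty` (default
0.5) for every frameshift or in-frame-stop event within the scored window
on either side, clamped to [0, 1].  A side with no aligned columns scores
0.  The exponential-decay form is this package's concrete definition of
"conservation weighted toward the splice sites"; the weighting profile,
window and credits are all configurable because no single published
parameterization is canonical.

**Intron mapping coverage (IMC).**  The number of *distinct* donor protein
identifiers whose chains contain the identical intron.  A protein aligned
twice to the same locus counts once; the same interval on opposite strands
is two keys.  Distinct-protein counting (rather than alignment counting)
makes the score robust to redundant alignments of one donor.

**Classification.**  Per intron, IBA is the maximum over supporting
junctions (chains parsed from plain aligner GFF carry no residue detail
and contribute to IMC only).  Evidence is kept if IBA ≥ `iba_min_keep`
(0.1) **or** IMC ≥ `imc_min_keep` (2); kept evidence is high-confidence
if IBA ≥ `iba_min_high` (0.25) **or** IMC ≥ `imc_min_high` (2), else low.
The OR-combination means a weakly conserved intron is still trusted when
two independent donors map it identically, and a single well-conserved
donor suffices without corroboration.  High-confidence hints carry source
tag `M` (enforced by the predictor's extrinsic configuration), low
confidence `P`; whether a predictor treats `M` as a hard constraint or a
strong prior is left to its own configuration.  `CDSpart` hints are each
aligned block shrunk by 9 bp per side (floor 1 bp) — the shrink hedges
against imprecise block termini — and `start`/`stop` hints are emitted
over the chain-terminal codons when the alignment covers the protein's
first/last residue; exonic and terminal hints are emitted as
low-confidence.

## Training-gene construction

Candidates are chains whose every intron is high-confidence, whose CDS
length is a multiple of 3 and which record neither frameshifts nor
in-frame stops ("valid ORF" — the event-based test avoids re-translating
the genome and is exact whenever the aligner reports those events
faithfully).  A locus is a connected component of candidates overlapping
by CDS span on the same strand — deterministic and cheap; splice-graph
clustering would merge fewer borderline pairs but needs tunables.  Per
locus one winner survives: maximal alignment score, ties broken by longer
CDS, then lexicographic protein id.  Single-exon candidates are admitted
by default (`min_exons` = 1) since single-exon genes are real, but the
CLI exposes `--no-mono-training` because homology pipelines tend to
overpredict them.

Flank size is `clamp(round(0.5 × mean gene span), 500, 10000)` bp, one
value for all genes: flanks should scale with gene (hence intergenic)
dimensions, but beyond ~10 kb more flank mostly imports neighbouring genes.
In the iterative second round, predictions with *full evidence support*
(every intron exactly hinted, ≥ `coverage_threshold` = 0.8 of CDS bases
covered by `CDSpart` hints, complete model) become the new training set,
and all predictions — supported or not — delimit the flanking windows:
windows shrink to the near boundary of any intruding gene and never below
the training gene's own span.  The 0.8 coverage default reflects the
9 bp-per-side hint shrink, which caps attainable coverage below 1 for
short exons.

## Chunked prediction and merging

`max_intron_size(G) = ⌊3.6·√G⌋` bp (G = genome size in bp) caps intron
search in the aligner and sets the safety scale for chunking: the planner
warns when the overlap is below twice this cap.  Sequences longer than
`chunk_size` (default 5 Mb) are tiled with stride `chunk_size − overlap`
(overlap default 1 Mb); the final window is clamped to the sequence end
and its start pulled back to keep the full chunk size, so border genes see
maximal context.  Sequences up to `chunk_size` are greedily packed into
batches of total length ≤ `batch_target` (default 5 Mb) in input order.

Every window owns a responsibility interval; overlaps are split at their
centre, so the responsibility intervals of a sequence partition it — a
property-tested invariant.  Merging keeps a transcript with the copy from
the chunk whose responsibility contains its midpoint, provided that
window fully contains it; otherwise the lowest-indexed fully-containing
chunk wins; a transcript contained in no window survives once, flagged
truncated.  Exact duplicate structures collapse to one.  The rule is
deterministic and order-independent, and merging is idempotent.  Final
outputs are renumbered by genomic position so reruns are byte-identical.

## Accuracy evaluation

Matching is CDS-only and coordinate-exact.  Exon true positives are
counted over distinct exon coordinates (not per-transcript occurrences);
transcript matches pair identical ordered CDS exon lists one-to-one; a
gene matches when at least one of its transcripts does, counted on the
reference side for sensitivity and the prediction side for specificity.
F1 = 2·Sn·Sp/(Sn+Sp), defined 0 when both are 0.  The mono:mult ratio
considers only the first isoform (lexicographically smallest transcript
id) of each gene and is reported as the token `Inf` when no multi-exon
first isoform exists.  Cross-annotation summaries use the unweighted
arithmetic mean over species, rounded to two decimals; the package ships
a 14-species published benchmark F1 table that the summary routine
reproduces exactly at gene and exon level (the published transcript-level
average cell differs from the unweighted mean of its own row by 0.07,
which we attribute to a typo in the source table).

## Synthetic fixtures: what they emulate and what they don't

The generator plants `n_genes` genes (2–4 exons, exon lengths 60–240 bp in
codon multiples, introns 60–240 bp with canonical `GT..AG`, intergenic
gaps 1200–2000 bp, random strand) in uniform random DNA, with `ATG` start
and a single terminal `TAA` included in the CDS; donor proteomes are
derived by substituting each residue with probability `protein_divergence`
(within-similarity-group replacements half the time, so realized columns
split into identical/positive/mismatch); induced alignment chains
reproduce the true exon blocks exactly, with frameshift/in-frame-stop
events injected per block at the configured rates.  Divergence and
corruption draw from separate seeded RNG streams, so a divergence grid
sees identical corruption events and recovery curves isolate the
divergence effect.

The geometry is deliberately coupled to the mock predictor: its cluster
join distance (500 bp) exceeds the largest intron and stays below the
smallest intergenic gap, so planted neighbours never fuse; its edge margin
(1000 bp) stays below the minimal gene-to-border distance; chunked and
unchunked runs are provably identical whenever the chunk overlap exceeds
twice the edge margin plus the largest gene span.

Not emulated: repeat content, GC structure, alternative splicing,
paralogous (spurious) alignments, aligner block errors, and phylogenetic
substitution processes.  Consequently, passing recovery tests demonstrates
the correctness of scoring, selection and merging logic under controlled
noise — not the field accuracy of any full pipeline on real genomes.  In
particular, with three donor proteomes every planted intron has IMC = 3
and classifies high-confidence at any divergence, so intron recovery is
divergence-flat by construction; divergence sensitivity shows up in IBA
values and in single-donor settings.

## Orchestration

Stage order: align → hints → traingenes → train1 → chunks → predict1 →
support → train2 (plus optional optimizer unless `skip_optimize`) →
predict2 → summary.  External tools are invoked through command templates
with `{genome}`/`{proteins}`/`{chunk}`/`{hints}`/`{out}` placeholders;
without templates the pipeline dry-runs on built-in mocks.  Each stage
reads its inputs from files written by earlier stages and drops a
`<stage>.done` marker, so the work directory alone determines resume
behaviour.  GenBank records carry a fixed LOCUS date and all writers sort
deterministically, making complete reruns byte-identical.

## Problem sizes and numerical choices

The test suite and the acceptance script run on fixture scales chosen to
exercise every code path while keeping the default run fast: tiny
scenarios of 5–8 genes for I/O and pipeline tests, 50 genes / 3 donors /
400 kb for the divergence-grid recovery experiment, 200 genes over two
1 Mb sequences (chunks of 500 kb, 100 kb overlap) for chunked-equivalence,
1000 random configurations for the responsibility-partition property and
200 random instances for the IMC brute-force oracle.  Floating-point
choices: IBA is clamped to [0, 1] after penalties; monotonicity assertions
tolerate 1e-9; the intron-cap oracle uses 50-digit decimal arithmetic.

## Known limitations

* The compact alignment dialect is this package's own; upstream aligners'
  residue-level formats must be converted (or parsed via plain GFF, losing
  junction detail and hence IBA for those chains).
* Frameshift/in-frame-stop handling trusts the aligner's event calls; no
  re-translation validates them.
* The external predictor contract (adapter templates) is exercised only
  with mocks in the test suite; template quoting is the user's
  responsibility.
* `evaluate_support` measures support against hint sets produced by this
  package; predictors' internal support bookkeeping may differ.
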