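# Methods

This note records the models, parameter choices and numerical conventions
behind `perloss`, and what the simulation-based tests do and do not
demonstrate about real data.

## The screen

The unit of analysis is the **gene family**: a connected component of the
cross-species similarity graph, with an edge wherever either direction of a
hit pair reaches the clustering E-value cutoff (default 1e-5). Component
clustering stands in for Markov clustering: the downstream screen consumes
only per-species presence/absence, which components preserve at the
near-orthogroup granularity the simulator produces; precomputed OrthoMCL
groups files can be ingested for fidelity on real data, and both paths flow
through identical code.

The phyletic screen keeps families absent from **all** annual species. The
strict variant additionally requires presence in all perennials; the
relaxed variant waives perennials with transcriptome-only data, because
absence from an incomplete transcript catalogue is weak evidence. The
relaxed result is a superset of the strict result by construction.

Elimination filters then run in a fixed order — phyletic screen →
annotation keywords → misannotation → annotation-release exclusion list →
transcript completeness — and the first failing filter supplies the
family's single primary reason code (the full per-filter vector is kept for
auditing). The order is a reproducibility device, not a scientific claim:
the filters are independent, but stable reason codes require a convention.

The transcript-completeness filter compares, on a log10 scale, the best
E-value from the reference genome perennial's family members into the
entire gene set of each transcriptome-level annual against the best
family-internal E-value between the two genome perennials. The boundary is
inclusive: exactly one order of magnitude eliminates. E-values are floored
at 1e-180 before taking logs so the comparison never involves −inf. Without
a perennial–perennial hit the filter is not evaluable and retains the
family with a note.

The misannotation check eliminates a family when an annual sister genome
carries an *intact* reading frame covering ≥ 90% of a perennial member's
CDS at ≥ 90% identity — presence of a degraded copy (stops, frameshifts,
heavy truncation) is precisely the interesting outcome and never triggers
it — or when a perennial protein matches no reading frame of its own CDS.

## Similarity scoring

A built-in optimal local aligner (affine gaps; nucleotide match 2 /
mismatch −3, gap open 5 extend 2; protein BLOSUM62, gap open 11 extend 1;
a gap of length k costs open + k·extend) replaces an external search tool
so the pipeline is hermetic and deterministic. The accompanying E-value is
the Karlin–Altschul-shaped surrogate E = K·m·n·exp(−λ·score) with fixed
constants per scheme (nucleotide λ = 1.28, K = 0.46; protein λ = 0.267,
K = 0.041). Only order relations and order-of-magnitude ratios of E-values
are consumed anywhere, so absolute calibration is non-critical; externally
computed BLAST outfmt-6 tables can be ingested and take the same code
paths.

All-vs-all runs and genome scans preselect candidate pairs/regions by
shared exact k-mers (k = 12 nucleotide, k = 5 protein) before the quadratic
DP; the reported scores are still full optimal local alignments, and the
prefilter can be disabled. A pair sharing no k-mer cannot reach the hit
score threshold at the divergences this pipeline handles, so the prefilter
changes runtime, not results, in its operating range.

In translated transcript catalogues the reading frame of a 5'-truncated
transcript is unknown; the frame minimising internal stops (ties: longest
translation, then lowest frame) is used.

## Synteny windows and pseudogene calls

Bidirectional best hits require a *unique* best score in both directions;
ties disqualify the gene, and the resulting map is an injective partial
matching. The window between two flank BBHs excludes the flank genes
themselves. With a single BBH, the search side is the side of the lost gene
relative to its flank in the perennial, flipped when the anchored pair is
inverted (flank and BBH partner on opposite strands); the inferred
direction is logged on the window. The 40 kb window is clipped to the
contig, so its length is exactly min(40000, distance to the contig edge).
When the two flank BBHs disagree on contig, the better-scoring flank is
used as a single anchor (logged). An intact homolog among the next four
annotated genes in the search direction short-circuits the scan as a real
gene; a degraded homolog does not.

Candidate loci are merged from chained local hits with a 1 kb gap
tolerance. A locus is called against the ortholog CDS from the local
alignment: maximal gap runs with net length not divisible by three count as
frameshifts; codons read in the ortholog-projected frame that are stops
(excluding the ortholog's final codon) count as premature stops. Verdicts:
`not_found` below 30 bp or without a positive alignment; `highly_diverged`
when the aligned fraction is < 0.3 or identity < 60%; `pseudogene` with
≥ 1 lesion; `real_gene` for a lesion-free frame covering ≥ 90% of the
ortholog; lesion-free partial coverage is reported `highly_diverged`.

## dN/dS and dating

The estimator is Nei–Gojobori (1986). Site counts per sense codon come from
the nine single-nucleotide neighbours with mutations to stops excluded from
the denominator (s = 3 · synonymous/non-stop, n = 3 − s, so n + s = 3
exactly and N + S equals three times the compared columns). Differences
between codons are averaged over all orderings of the 1–3 changes;
orderings passing through a stop codon are excluded, and if every ordering
is blocked all are used with equal weight and the result flagged. Distances
use the Jukes–Cantor correction; p ≥ 3/4 makes the correction undefined and
flags the pair as a poor alignment. dS = 0 leaves the ratio undefined — such
pairs are counted and excluded from backgrounds, and classification of such
a candidate is refused with the reason rather than guessed.

Codon alignments are protein-guided: translations (internal stops kept as a
dedicated symbol scored −4 against everything, including itself) are
globally aligned under BLOSUM62 and back-translated so every protein gap is
a 3-base gap. Columns where the pseudogene row holds a stop codon are
deleted before estimation; gap and stop columns are skipped pairwise with
no gap penalty entering the counts.

Background envelopes take one gene per species per family (first by sorted
id when several), use linear interpolation between order statistics for the
percentiles, and refuse to summarise fewer than 20 usable ratios.
Classification against the envelope is strict (> p95, < p5); ties classify
`within`.

This NG86 estimator deliberately replaces likelihood codon models with
transition/transversion and codon-frequency machinery: the downstream logic
consumes only ratios and percentiles, the simulator's mutation process is
ts/tv-unbiased (matching NG86's assumptions), and externally computed
dN/dS tables can be substituted where fidelity to a specific estimator
matters.

## The synthetic clade generator

The generator emulates the study design: `n_pairs` annual/perennial sister
pairs (default 4, the first 2 with genome-level data, the rest
transcriptome-only) plus genome-level annual outgroups (default 1). The
tree is a star of monophyletic pairs — each pair ancestor one branch below
the root, each species one branch below its pair ancestor, outgroups on a
double-length root branch — the simplest shape in which sister species are
mutually closest, which is the only topological property the screen uses.

Sequences are sense-codon strings (uniform codon usage, no forced start
codon, no terminal stop). Evolution is a uniform base-substitution point
process at `branch_sub_rate` proposals per site per branch (default 0.05):
synonymous proposals always fix, nonsynonymous ones with probability
`omega` (default 0.15, a typical genome-wide purifying-selection level),
stop-creating proposals are rejected while constrained. With ω ≥ 1 every
proposal fixes, stops included, which also lets lesioned sequences of any
length evolve. There are no indels outside planted lesions, no ts/tv bias,
no rate heterogeneity and no intron structure.

A fraction `loss_fraction` (default 0.1) of families is planted as lost in
*every* annual lineage; each annual independently draws a fate
(pseudogenized 0.7 / deleted 0.3 by default). Pseudogenes follow a
two-phase model: constrained evolution for a fraction 1 − `age` of the
branch, then the lesion (premature stop, 1-bp frameshift, deletion
removing ≥ 2/3, or a terminal domain-scale truncation of 25–50%), then
unconstrained evolution for the remaining fraction `age`. Age → 0 makes the
pseudogene's dN/dS converge to ω, age → 1 to the neutral expectation —
the gradient the dating analysis reads. This two-phase decay model is an
assumption, not an inference from data. Optionally a further fraction of
families is planted as *misannotated*: intact in the annual genome but
absent from its annotation, the case the misannotation filter must catch.

Genomes place genes in a conserved order, `genes_per_contig` (default 20)
per contig, separated by independent random spacers of `intergenic_bp`
(default 2000) — long enough to exercise between-flank and 40 kb window
logic at desk scale while keeping whole-genome scans cheap. Spacers are
unrelated between species, so only genic sequence can anchor a scan.
Transcript catalogues drop each gene with probability
1 − `transcript_detection_prob` (default 0.9) and truncate surviving
transcripts with probability `truncation_prob` (default 0.1, uniform cut
keeping ≥ 30%); pseudogenized and deleted genes are never transcribed.

What passing tests on this generator do **not** show about real data:
robustness to assembly fragmentation and sequencing error, paralog-rich
families (the simulator is single-copy), intron-containing gene models,
segmental rearrangements breaking synteny, biased codon usage, and the
behaviour of true OrthoMCL/BLAST outputs — those enter only through the
ingestion paths.

## Study sizes used in tests and the acceptance script

Screen recovery uses 200 families with 10% planted losses and perfect
transcript detection; completeness-filter safety uses 20 (tests) or 10
(script) independent 30-family clades at detection 0.7; window geometry a
60-family two-pair clade with all-pseudogenized fates; calling rates 100
planted lesions and 100 intact copies; the dating study a 500-family
background. The dating study runs at a per-branch divergence of 0.03 on
100-codon genes — chosen a priori so that the sampling spread of NG86
ratios makes the age classes (0.1 / 0.5 / 0.9) straddle the background's
95th percentile informatively rather than saturating at 0 or 1; note that
because the perennial branch stays constrained, a pseudogene of age a has
expected pairwise ratio (ω + (ω + (1 − ω)a))/2, not ω + (1 − ω)a.

## Known limitations

* Component clustering can chain distinct families through a promiscuous
  member; at simulated divergences this does not occur, but on real data
  the OrthoMCL ingestion path is the safer choice.
* The E-value surrogate is uncalibrated against any specific search tool;
  thresholds expressed in E-value terms (1e-5 clustering cutoff, the
  one-order completeness margin) are meaningful relative to it, not
  portable verbatim to external tables with different statistics.
* Premature stops are read in the ortholog-projected frame, so stops
  arising downstream of a frameshift may be attributed to the frameshift
  rather than counted individually; the verdict is unaffected.
* Manual alignment curation (routine in small-scale published analyses)
  has no automated counterpart here; borderline alignments are flagged and
  excluded rather than repaired.
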