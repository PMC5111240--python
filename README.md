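# perloss

Comparative-genomics screening for genes **lost in annual plant lineages but
retained in their perennial sister species**.

Transitions between the perennial and annual life history have happened many
times in plants, and one candidate mechanism is simple gene loss: a gene the
perennial needs (for example for repeated flowering or vernalization
response) is deleted or pseudogenized in the annual. Given several
annual/perennial sister-species pairs, genes supporting perenniality should
be repeatedly lost across the annual lineages while staying intact in every
perennial. `perloss` implements that screen as a reusable, tested pipeline:

1. **Gene families** — all-vs-all protein similarity (built-in local
   aligner, or ingested BLAST outfmt-6 tables) clustered into families;
   OrthoMCL-style groups files can be ingested directly.
2. **Phyletic screen** — families absent from *all* annual species and
   present in the required perennials (transcriptome-level perennials are
   optional, since their catalogues are incomplete), followed by a fixed
   funnel of elimination filters: annotation keywords
   (transposon / self-incompatibility / ribosomal), misannotation checks
   against the annual sister genomes, an annotation-release exclusion list,
   and a transcript-completeness E-value filter (eliminate when the best hit
   into a transcriptome-level annual is ≥ 1 order of magnitude better than
   the hit between the two genome perennials).
3. **Synteny** — the remains of each lost gene are bracketed by the
   bidirectional best hits (BBHs) of its two flanking genes: scan between
   the two BBHs; with a single BBH, check the next 4 annotated genes in the
   right direction, else scan 40 kb on that side; with none, scan the whole
   genome. Located loci are characterised as `real_gene`, `pseudogene`
   (premature stops / frameshifts counted), `highly_diverged` or
   `not_found`.
4. **Dating** — for each candidate pseudogene, a protein-guided codon
   alignment to its functional ortholog (stop columns in the pseudogene row
   deleted) yields Nei–Gojobori (1986) dN/dS: per-codon site counts over
   the nine single-nucleotide neighbours (stop mutations excluded), pathway
   averaging over multi-hit codons, Jukes–Cantor correction
   d = −(3/4)·ln(1 − (4/3)p). The ratio is placed against the genome-wide
   background envelope (5th percentile / median / 95th percentile over all
   ortholog pairs of that species pair; dS = 0 and poor alignments excluded).
   A ratio above the 95th percentile means pseudogenization was not recent —
   purifying selection on nonsynonymous sites relaxed long ago.

A first-class **synthetic-data generator** simulates a clade of sister pairs
with planted deletions, pseudogenizations (premature stop, frameshift,
large deletion, truncation, at a configurable "age") and transcriptome-only
species with configurable missingness, plus a ground-truth ledger, so every
stage is testable without external genome releases.

## Worked example

```python
from perloss.synthetic_data import SimConfig, simulate_clade
from perloss.pipeline import PipelineInputs, PipelineConfig, run_pipeline

clade = simulate_clade(SimConfig(
    n_families=40, genes_per_contig=10, loss_fraction=0.1,
    transcript_detection_prob=1.0, truncation_prob=0.0, seed=5,
))
result = run_pipeline(PipelineInputs.from_clade(clade), PipelineConfig())
print(result.funnel_counts())
for report in result.reports:
    for annual, entry in sorted(report.per_annual.items()):
        ratio = "-" if entry.dnds is None or entry.dnds.ratio is None \
                else f"{entry.dnds.ratio:.2f}"
        print(report.family_id, annual, entry.outcome, ratio, entry.classification)
```

prints

```
{'total_families': 40, 'phyletic_screen': 4, 'annotation_keywords': 4,
 'misannotation': 4, 'current_annotation': 4, 'completeness': 4,
 'strict_screen': 4, 'relaxed_screen': 4, 'final_candidates': 4}
FAM00036 annual_1 pseudogene_syntenic 0.47 above_p95
FAM00036 annual_2 pseudogene_syntenic 0.24 within
FAM00037 annual_1 not_found 0.89 above_p95
FAM00037 annual_2 not_found - None
FAM00038 annual_1 not_found - None
FAM00038 annual_2 not_found - None
FAM00039 annual_1 pseudogene_syntenic 0.26 within
FAM00039 annual_2 pseudogene_syntenic 0.41 above_p95
```

Four of the forty families were planted as annual-lost; the phyletic screen
recovers exactly those four, no elimination filter fires on them, and the
synteny scan finds the pseudogenized remains where a pseudogene (rather
than a full deletion) was planted. The dN/dS column is the candidate's
NG86 ratio against its perennial ortholog; `above_p95` means it exceeds the
95th percentile of the genome-wide background for that species pair
(here median 0.137, p95 0.466 for `annual_1`/`perennial_1`), i.e. an old
pseudogenization.

The same run is available from a shell:

```bash
perloss simulate -c sim.yaml --seed 5 -o simdir
perloss all -i simdir -o outdir       # hits, groups, funnel, candidates TSVs
```

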