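"""Synteny-anchored localisation and characterisation of lost-gene remains.

For a gene present in a perennial but missing from the annual sister's
annotation, the expected location of its remains is bracketed by the
bidirectional best hits (BBHs) of its two flanking genes:

* both flank BBHs on one annual contig -> scan the sequence strictly
  between them;
* a single flank BBH -> first check the next four annotated genes in the
  direction pointing away from the conserved flank for a surviving homolog,
  otherwise scan 40 kb on that side of the BBH gene (clipped to the
  contig);
* no flank BBH -> scan the entire genome.

A located locus is then aligned back to the functional ortholog's CDS and
characterised: premature stop codons and frameshift-inducing indels make a
pseudogene; an intact open reading frame over >= 90% of the ortholog makes
a (possibly misannotated) real gene; weak or fragmentary homology is
reported as highly diverged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import GeneModel, SimilarityHit, qualified_id, split_qualified
from .molevol import STOP_CODONS
from .similarity import (
    NUCLEOTIDE,
    PROTEIN,
    GenomeLocus,
    GenomeSearcher,
    ScoringScheme,
    align_local,
    evalue_from_score,
    local_score,
    revcomp,
)

BASIS_BETWEEN_BBH = "between_bbh"
BASIS_SINGLE_BBH_40KB = "single_bbh_40kb"
BASIS_WHOLE_GENOME = "whole_genome"

VERDICT_REAL_GENE = "real_gene"
VERDICT_PSEUDOGENE = "pseudogene"
VERDICT_HIGHLY_DIVERGED = "highly_diverged"
VERDICT_NOT_FOUND = "not_found"


@dataclass
class SyntenyWindow:
    """A genomic interval expected to contain a lost gene's remains."""

    species: str
    contig: str | None
    start: int
    end: int
    basis: str
    anchor_genes: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.basis != BASIS_WHOLE_GENOME and self.end <= self.start:
            raise ValueError(
                f"window on {self.contig}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PseudogeneCall:
    """Characterisation of a degraded locus against its functional ortholog."""

    verdict: str
    locus: tuple[str | None, int, int, str] | None = None  # contig, start, end, strand
    aligned_fraction: float = 0.0
    identity_pct: float = 0.0
    premature_stops: list[int] = field(default_factory=list)  # ortholog codon indices
    frameshifts: list[int] = field(default_factory=list)  # ortholog nt positions
    in_frame_locus: str = ""  # aligned locus segment trimmed to codon phase

    @property
    def n_lesions(self) -> int:
        return len(self.premature_stops) + len(self.frameshifts)


# ---------------------------------------------------------------------------
# bidirectional best hits

def _unique_best(hits: Sequence[SimilarityHit]) -> dict[str, tuple[str, float]]:
    best: dict[str, tuple[str, float]] = {}
    tied: set[str] = set()
    for hit in hits:
        entry = best.get(hit.query)
        if entry is None or hit.bitscore > entry[1]:
            best[hit.query] = (hit.subject, hit.bitscore)
            tied.discard(hit.query)
        elif hit.bitscore == entry[1] and hit.subject != entry[0]:
            tied.add(hit.query)
    return {q: v for q, v in best.items() if q not in tied}


def compute_bbh_map(
    hits_ab: Sequence[SimilarityHit], hits_ba: Sequence[SimilarityHit]
) -> dict[str, tuple[str, float]]:
    """Bidirectional best hits from the two reciprocal hit tables.

    A pair (a, b) is a BBH iff b is a's unique best hit and a is b's unique
    best hit; ties (equal best score to several subjects) disqualify the
    gene.  The map records both directions (an injective partial matching)
    with the forward score.
    """
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    bbh: dict[str, tuple[str, float]] = {}
    for a, (b, score) in best_ab.items():
        back = best_ba.get(b)
        if back is not None and back[0] == a:
            bbh[a] = (b, score)
            bbh[b] = (a, back[1])
    return bbh


# ---------------------------------------------------------------------------
# annotation geometry

def _sorted_contig_genes(annotation: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    by_contig: dict[str, list[GeneModel]] = {}
    for gene in annotation:
        if gene.contig is None or gene.start is None:
            continue
        by_contig.setdefault(gene.contig, []).append(gene)
    for genes in by_contig.values():
        genes.sort(key=lambda g: (g.start, g.gene_id))
    return by_contig


def flanking_genes(
    target_gene: str, annotation: Sequence[GeneModel]
) -> tuple[GeneModel | None, GeneModel | None]:
    """Nearest annotated neighbours (by start) on the target's contig.

    Either neighbour is None at a contig edge.  The target must carry
    coordinates and be present in the annotation.
    """
    by_contig = _sorted_contig_genes(annotation)
    for genes in by_contig.values():
        for i, gene in enumerate(genes):
            if gene.gene_id == target_gene:
                left = genes[i - 1] if i > 0 else None
                right = genes[i + 1] if i + 1 < len(genes) else None
                return left, right
    raise ValueError(f"target gene {target_gene!r} absent from annotation")


def _resolve(annotation_index: Mapping[str, GeneModel], gene_id: str) -> GeneModel | None:
    return annotation_index.get(gene_id)


def syntenic_window(
    target: GeneModel,
    perennial_annotation: Sequence[GeneModel],
    annual_annotation: Sequence[GeneModel],
    annual_genome: Mapping[str, str],
    bbh_map: Mapping[str, tuple[str, float]],
    window_bp: int = 40_000,
) -> list[SyntenyWindow]:
    """Windows in the annual genome expected to hold the target's remains.

    Returns a single window for the between-BBH and single-BBH cases and one
    whole-genome window per contig when neither flank has a BBH.  When the
    two flank BBHs land on different annual contigs, the better-scoring
    flank is used as a single anchor (logged in the window note).
    """
    left, right = flanking_genes(target.gene_id, perennial_annotation)
    annual_index = {g.gene_id: g for g in annual_annotation}

    def bbh_gene(flank: GeneModel | None) -> tuple[GeneModel | None, float]:
        if flank is None:
            return None, 0.0
        entry = bbh_map.get(qualified_id(flank.species, flank.gene_id))
        if entry is None:
            return None, 0.0
        _, partner_gene = split_qualified(entry[0])
        partner = _resolve(annual_index, partner_gene)
        return partner, entry[1]

    left_hit, left_score = bbh_gene(left)
    right_hit, right_score = bbh_gene(right)
    note = ""

    if left_hit is not None and right_hit is not None:
        if left_hit.contig == right_hit.contig:
            lo_gene, hi_gene = sorted((left_hit, right_hit), key=lambda g: g.start)
            if hi_gene.start > lo_gene.end:
                return [
                    SyntenyWindow(
                        species=lo_gene.species,
                        contig=lo_gene.contig,
                        start=lo_gene.end,
                        end=hi_gene.start,
                        basis=BASIS_BETWEEN_BBH,
                        anchor_genes=(left_hit.gene_id, right_hit.gene_id),
                    )
                ]
            note = "flank BBHs adjacent/overlapping; using better flank"
        else:
            note = "flank BBHs on different contigs; using better flank"
        if left_score >= right_score:
            right_hit = None
        else:
            left_hit = None

    single = left_hit or right_hit
    if single is not None:
        flank = left if single is left_hit else right
        # side of the lost gene relative to the flank, in perennial coordinates
        side_right = flank.start < target.start
        # flip when the anchored pair is inverted between the genomes
        if (flank.strand or "+") != (single.strand or "+"):
            side_right = not side_right
        contig_seq = annual_genome[single.contig]
        if side_right:
            start, end = single.end, min(single.end + window_bp, len(contig_seq))
        else:
            start, end = max(single.start - window_bp, 0), single.start
        direction = "right" if side_right else "left"
        if end <= start:
            note = (note + "; " if note else "") + "window clipped to nothing at contig edge"
            return [
                SyntenyWindow(
                    species=single.species,
                    contig=contig,
                    start=0,
                    end=len(seq),
                    basis=BASIS_WHOLE_GENOME,
                    note=note,
                )
                for contig, seq in sorted(annual_genome.items())
            ]
        return [
            SyntenyWindow(
                species=single.species,
                contig=single.contig,
                start=start,
                end=end,
                basis=BASIS_SINGLE_BBH_40KB,
                anchor_genes=(single.gene_id,),
                note=(note + "; " if note else "") + f"search direction {direction}",
            )
        ]

    species = annual_annotation[0].species if annual_annotation else target.species
    return [
        SyntenyWindow(
            species=species,
            contig=contig,
            start=0,
            end=len(seq),
            basis=BASIS_WHOLE_GENOME,
        )
        for contig, seq in sorted(annual_genome.items())
    ]


def extension_genes(
    anchor: GeneModel,
    annual_annotation: Sequence[GeneModel],
    direction_right: bool,
    n_genes: int = 4,
) -> list[GeneModel]:
    """The next ``n_genes`` annotated genes beyond the anchor, in one direction."""
    by_contig = _sorted_contig_genes(annual_annotation)
    genes = by_contig.get(anchor.contig, [])
    idx = next((i for i, g in enumerate(genes) if g.gene_id == anchor.gene_id), None)
    if idx is None:
        return []
    if direction_right:
        return genes[idx + 1 : idx + 1 + n_genes]
    return list(reversed(genes[max(idx - n_genes, 0) : idx]))


# ---------------------------------------------------------------------------
# window scanning

def scan_window(
    window: SyntenyWindow,
    query_cds: str,
    genome: Mapping[str, str],
    scheme: ScoringScheme = NUCLEOTIDE,
    score_threshold: float = 50.0,
    merge_gap: int = 1000,
) -> list[GenomeLocus]:
    """Local-alignment scan of a window for remains of the query gene.

    Both strands are searched; chained local hits within ``merge_gap`` are
    merged into loci ranked by total score.
    """
    searcher = GenomeSearcher(
        {window.contig: genome[window.contig]}, scheme=scheme, merge_gap=merge_gap
    )
    return searcher.search(
        query_cds,
        contig=window.contig,
        interval=(window.start, window.end),
        score_threshold=score_threshold,
    )


# ---------------------------------------------------------------------------
# pseudogene calling

def call_pseudogene(
    locus_seq: str,
    functional_ortholog_cds: str,
    scheme: ScoringScheme = NUCLEOTIDE,
    min_identity: float = 60.0,
    locus: tuple[str | None, int, int, str] | None = None,
) -> PseudogeneCall:
    """Characterise a candidate locus against the intact ortholog CDS.

    The locus (already in the ortholog's reading orientation) is locally
    aligned to the CDS.  Indel runs whose length is not a multiple of three
    count as frameshifts; stop codons read in the ortholog-projected frame
    count as premature stops (the ortholog's final codon is exempt).
    Verdicts: ``highly_diverged`` when the aligned fraction is below 0.3 or
    identity below ``min_identity``; ``pseudogene`` when lesions exist;
    ``real_gene`` for an intact frame over >= 90% of the ortholog.
    """
    if len(locus_seq) < 30:
        return PseudogeneCall(verdict=VERDICT_NOT_FOUND, locus=locus)
    aln = align_local(functional_ortholog_cds, locus_seq, scheme)
    if aln.aln_len == 0:
        return PseudogeneCall(verdict=VERDICT_NOT_FOUND, locus=locus)

    aligner_aln = _full_alignment(functional_ortholog_cds, locus_seq, scheme)
    gapped_q, gapped_t = aligner_aln[0], aligner_aln[1]
    q_start = aligner_aln.aligned[0][0][0]

    # frameshifts: maximal gap runs whose net indel length is not a multiple
    # of three (run_t counts bases deleted from the locus, run_q bases
    # inserted into it; a local alignment never starts or ends in a gap)
    frameshifts: list[int] = []
    q_pos = int(q_start)
    run_q = run_t = 0
    run_start: int | None = None
    for qc, tc in zip(gapped_q, gapped_t):
        if qc == "-" or tc == "-":
            if run_start is None:
                run_start = q_pos
            if qc == "-":
                run_q += 1
            else:
                run_t += 1
        elif run_start is not None:
            if (run_t - run_q) % 3 != 0:
                frameshifts.append(run_start)
            run_start, run_q, run_t = None, 0, 0
        if qc != "-":
            q_pos += 1

    # premature stops: project the locus onto ortholog codons
    stops: list[int] = []
    n_codons = len(functional_ortholog_cds) // 3
    codon_chars: dict[int, list[str]] = {}
    q_pos = int(q_start)
    for qc, tc in zip(gapped_q, gapped_t):
        if qc == "-":
            continue
        if tc != "-":
            codon_chars.setdefault(q_pos // 3, []).append(tc)
        q_pos += 1
    aligned_codons = sorted(codon_chars)
    for codon_idx in aligned_codons:
        chars = codon_chars[codon_idx]
        if len(chars) != 3:
            continue
        codon = "".join(chars)
        if codon in STOP_CODONS and codon_idx < n_codons - 1:
            stops.append(codon_idx)

    qa, qb = aln.query_interval
    aligned_fraction = (qb - qa) / len(functional_ortholog_cds)
    # locus segment trimmed to the ortholog codon phase, for codon alignment
    ta, tb = aln.subject_interval
    phase = (3 - qa % 3) % 3
    in_frame = locus_seq[ta + phase : tb]
    in_frame = in_frame[: len(in_frame) - len(in_frame) % 3]

    call = PseudogeneCall(
        verdict=VERDICT_NOT_FOUND,
        locus=locus,
        aligned_fraction=aligned_fraction,
        identity_pct=aln.identity_pct,
        premature_stops=stops,
        frameshifts=frameshifts,
        in_frame_locus=in_frame,
    )
    if aligned_fraction < 0.3 or aln.identity_pct < min_identity:
        call.verdict = VERDICT_HIGHLY_DIVERGED
    elif call.n_lesions >= 1:
        call.verdict = VERDICT_PSEUDOGENE
    elif aligned_fraction >= 0.9:
        call.verdict = VERDICT_REAL_GENE
    else:
        call.verdict = VERDICT_HIGHLY_DIVERGED
    return call


def _full_alignment(query: str, target: str, scheme: ScoringScheme):
    from .similarity import _aligner

    return _aligner(scheme, "local").align(query, target)[0]


# ---------------------------------------------------------------------------
# end-to-end location of a lost gene's remains

@dataclass
class LostGeneResult:
    """Where (and in what state) a lost gene's remains were found."""

    windows: list[SyntenyWindow]
    call: PseudogeneCall
    syntenic: bool | None = None  # None when nothing was found anywhere
    locus_hit: GenomeLocus | None = None


def find_extension_homolog(
    target_protein: str,
    candidates: Sequence[GeneModel],
    evalue_cutoff: float = 1e-5,
) -> GeneModel | None:
    """First annotated gene among ``candidates`` homologous to the target."""
    for gene in candidates:
        if not gene.protein:
            continue
        score = local_score(target_protein, gene.protein, PROTEIN)
        evalue = evalue_from_score(score, len(target_protein), len(gene.protein), PROTEIN)
        if evalue <= evalue_cutoff:
            return gene
    return None


def locate_lost_gene(
    target: GeneModel,
    perennial_annotation: Sequence[GeneModel],
    annual_annotation: Sequence[GeneModel],
    annual_searcher: GenomeSearcher,
    bbh_map: Mapping[str, tuple[str, float]],
    window_bp: int = 40_000,
    n_extension_genes: int = 4,
    evalue_cutoff: float = 1e-5,
    score_threshold: float = 50.0,
) -> LostGeneResult:
    """Full search cascade for the remains of one lost gene.

    Syntenic windows are derived from the flank BBHs; in the single-BBH case
    the next ``n_extension_genes`` annotated genes in the search direction
    are first checked for a surviving homolog (an intact one short-circuits
    the scan as a real gene).  When the syntenic windows yield nothing, the
    entire genome is scanned; the result records whether the located locus
    was syntenic.
    """
    genome = annual_searcher.contigs
    windows = syntenic_window(
        target,
        perennial_annotation,
        annual_annotation,
        genome,
        bbh_map,
        window_bp=window_bp,
    )
    basis = windows[0].basis
    annual_index = {g.gene_id: g for g in annual_annotation}

    if basis == BASIS_SINGLE_BBH_40KB and target.protein:
        anchor = annual_index.get(windows[0].anchor_genes[0])
        if anchor is not None:
            direction_right = windows[0].note.endswith("right")
            ext = extension_genes(
                anchor, annual_annotation, direction_right, n_extension_genes
            )
            homolog = find_extension_homolog(target.protein, ext, evalue_cutoff)
            if homolog is not None:
                locus_seq = homolog.cds
                call = call_pseudogene(
                    locus_seq,
                    target.cds,
                    locus=(homolog.contig, homolog.start, homolog.end, homolog.strand or "+"),
                )
                if call.verdict == VERDICT_REAL_GENE:
                    return LostGeneResult(windows=windows, call=call, syntenic=True)

    def best_locus(wins: Sequence[SyntenyWindow]) -> GenomeLocus | None:
        loci: list[GenomeLocus] = []
        for win in wins:
            loci.extend(
                annual_searcher.search(
                    target.cds,
                    contig=win.contig,
                    interval=(win.start, win.end),
                    score_threshold=score_threshold,
                )
            )
        loci.sort(key=lambda h: (-h.score, h.contig, h.start))
        return loci[0] if loci else None

    hit = best_locus(windows)
    syntenic = basis != BASIS_WHOLE_GENOME
    if hit is None and basis != BASIS_WHOLE_GENOME:
        whole = [
            SyntenyWindow(
                species=windows[0].species,
                contig=contig,
                start=0,
                end=len(seq),
                basis=BASIS_WHOLE_GENOME,
            )
            for contig, seq in sorted(genome.items())
            if len(seq) > 0
        ]
        hit = best_locus(whole)
        syntenic = False
    if hit is None:
        return LostGeneResult(
            windows=windows, call=PseudogeneCall(verdict=VERDICT_NOT_FOUND), syntenic=None
        )
    locus_seq = genome[hit.contig][hit.start : hit.end]
    if hit.strand == "-":
        locus_seq = revcomp(locus_seq)
    call = call_pseudogene(
        locus_seq, target.cds, locus=(hit.contig, hit.start, hit.end, hit.strand)
    )
    return LostGeneResult(windows=windows, call=call, syntenic=syntenic, locus_hit=hit)
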