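"""End-to-end orchestration: similarity -> families -> screen -> synteny -> dating.

The pipeline consumes a species table plus per-species gene sets (CDS +
protein FASTA and GFF3 + genome FASTA for genome-level species, transcript
FASTA for transcriptome-level species), screens gene families for the
perennial-retained / annual-lost phyletic pattern, hunts the remains of
each candidate in the annual genomes via flank-BBH synteny, and dates the
pseudogenization by placing each candidate's dN/dS against the genome-wide
background envelope of its species pair.  Every stage writes a plain TSV
artifact and the run is deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import loss_screen, molevol
from .family_builder import GeneFamily, cluster_families
from .io_formats import (
    GENOME,
    GeneModel,
    SimilarityHit,
    SpeciesProfile,
    qualified_id,
    read_fasta,
    read_gff3,
    read_species_table,
    write_blast_tab,
    write_orthomcl_groups,
)
from .loss_screen import FunnelResult, run_funnel
from .molevol import (
    BackgroundDistribution,
    DnDsResult,
    UndefinedRatioError,
    classify_candidate,
    ng86_dnds,
    protein_guided_codon_align,
    strip_stop_columns,
    translate_cds,
)
from .similarity import NUCLEOTIDE, PROTEIN, GenomeSearcher, all_vs_all
from .synteny_pseudo import (
    VERDICT_NOT_FOUND,
    VERDICT_PSEUDOGENE,
    VERDICT_REAL_GENE,
    LostGeneResult,
    compute_bbh_map,
    locate_lost_gene,
)

OUTCOME_REAL_GENE = "real_gene"
OUTCOME_PSEUDO_SYNTENIC = "pseudogene_syntenic"
OUTCOME_PSEUDO_NONSYNTENIC = "pseudogene_nonsyntenic"
OUTCOME_NOT_FOUND = "not_found"


@dataclass
class PipelineConfig:
    """Global parameters; defaults are the screen's canonical constants.

    ``window_bp`` (40 kb) and ``extension_genes`` (4) govern the synteny
    search; ``evalue_order_threshold`` (1 order of magnitude, boundary
    inclusive) the transcript-completeness filter; ``cluster_evalue_cutoff``
    the family graph; ``percentiles`` the background envelope.
    """

    window_bp: int = 40_000
    extension_genes: int = 4
    evalue_order_threshold: float = 1.0
    cluster_evalue_cutoff: float = 1e-5
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0)
    evalue_floor: float = 1e-180
    score_threshold: float = 50.0
    misannotation_identity: float = 90.0
    background_min_usable: int = 20
    keyword_classes: dict[str, tuple[str, ...]] | None = None
    exclusion_list: tuple[str, ...] = ()
    reference_perennial: str | None = None
    comparison_perennial: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.percentiles) != list(self.percentiles):
            raise ValueError("percentiles must be sorted ascending")
        for name in ("window_bp", "extension_genes", "evalue_order_threshold",
                     "cluster_evalue_cutoff", "evalue_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "percentiles" in data:
            data["percentiles"] = tuple(data["percentiles"])
        if "exclusion_list" in data:
            data["exclusion_list"] = tuple(data["exclusion_list"])
        return cls(**data)


@dataclass
class PipelineInputs:
    """In-memory view of the per-species inputs."""

    profiles: list[SpeciesProfile]
    genes: dict[str, list[GeneModel]]
    genomes: dict[str, dict[str, str]]
    transcripts: dict[str, dict[str, str]]

    @classmethod
    def from_clade(cls, clade) -> "PipelineInputs":
        return cls(
            profiles=list(clade.species),
            genes={sp: list(models) for sp, models in clade.genes.items()},
            genomes={sp: dict(c) for sp, c in clade.genomes.items()},
            transcripts={sp: dict(t) for sp, t in clade.transcripts.items()},
        )

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PipelineInputs":
        indir = Path(indir)
        profiles = read_species_table(indir / "species_table.tsv")
        genes: dict[str, list[GeneModel]] = {}
        genomes: dict[str, dict[str, str]] = {}
        transcripts: dict[str, dict[str, str]] = {}
        for profile in profiles:
            name = profile.name
            if profile.data_level == GENOME:
                cds = read_fasta(indir / f"{name}.cds.fasta")
                prot = read_fasta(indir / f"{name}.protein.fasta")
                skeletons = {g.gene_id: g for g in read_gff3(indir / f"{name}.gff3")}
                models = []
                for gene_id in sorted(cds):
                    skel = skeletons.get(gene_id)
                    models.append(
                        GeneModel(
                            gene_id=gene_id,
                            species=name,
                            contig=skel.contig if skel else None,
                            start=skel.start if skel else None,
                            end=skel.end if skel else None,
                            strand=skel.strand if skel else None,
                            cds=cds[gene_id],
                            protein=prot.get(gene_id, translate_cds(cds[gene_id])),
                        )
                    )
                genes[name] = models
                genomes[name] = read_fasta(indir / f"{name}.genome.fasta")
            else:
                transcripts[name] = read_fasta(indir / f"{name}.transcripts.fasta")
        return cls(profiles=profiles, genes=genes, genomes=genomes, transcripts=transcripts)

    def genome_pairs(self) -> list[tuple[str, str]]:
        """(annual, perennial) sister pairs where both members are genome-level."""
        by_pair: dict[str, dict[str, SpeciesProfile]] = {}
        for p in self.profiles:
            if p.pair_id:
                by_pair.setdefault(p.pair_id, {})[p.life_history] = p
        pairs = []
        for pair_id in sorted(by_pair):
            members = by_pair[pair_id]
            if len(members) == 2 and all(
                m.data_level == GENOME for m in members.values()
            ):
                pairs.append((members["annual"].name, members["perennial"].name))
        return pairs


def best_frame_translation(seq: str) -> str:
    """Translation in the reading frame with fewest internal stops.

    Transcript catalogues can be 5'-truncated out of frame; among the three
    forward frames the one minimising internal stops (ties: longest, then
    lowest frame) is the best available proxy for the encoded protein.
    """
    candidates = []
    for frame in range(3):
        prot = translate_cds(seq[frame:])
        candidates.append((prot.count("*"), -len(prot), frame, prot))
    return min(candidates)[3]


@dataclass
class CandidateOutcome:
    """Per-annual-species outcome for one candidate family."""

    outcome: str
    verdict: str
    result: LostGeneResult | None = None
    dnds: DnDsResult | None = None
    classification: str | None = None
    classification_refused: str | None = None


@dataclass
class CandidateReport:
    family_id: str
    perennial_genes: dict[str, list[str]]
    per_annual: dict[str, CandidateOutcome] = field(default_factory=dict)


@dataclass
class PipelineResult:
    inputs: PipelineInputs
    config: PipelineConfig
    hits: list[SimilarityHit]
    families: list[GeneFamily]
    funnel: FunnelResult
    bbh_maps: dict[tuple[str, str], dict[str, tuple[str, float]]]
    backgrounds: dict[tuple[str, str], BackgroundDistribution]
    reports: list[CandidateReport]

    def funnel_counts(self) -> dict[str, int]:
        counts = {"total_families": len(self.families)}
        for row in self.funnel.rows:
            counts[row.stage] = row.n_out
        counts["strict_screen"] = len(self.funnel.strict)
        counts["relaxed_screen"] = len(self.funnel.relaxed)
        counts["final_candidates"] = len(self.funnel.retained)
        return counts


def _protein_sets(inputs: PipelineInputs) -> dict[str, dict[str, str]]:
    sets: dict[str, dict[str, str]] = {}
    for profile in inputs.profiles:
        name = profile.name
        if profile.data_level == GENOME:
            sets[name] = {
                g.gene_id: g.protein for g in inputs.genes[name] if g.protein
            }
        else:
            sets[name] = {
                tid: prot
                for tid, seq in sorted(inputs.transcripts[name].items())
                if (prot := best_frame_translation(seq))
            }
    return sets


def _gene_model_index(inputs: PipelineInputs) -> dict[str, GeneModel]:
    index: dict[str, GeneModel] = {}
    for name, models in inputs.genes.items():
        for g in models:
            index[g.qualified_id] = g
    for name, catalogue in inputs.transcripts.items():
        for tid, seq in catalogue.items():
            index[qualified_id(name, tid)] = GeneModel(
                gene_id=tid, species=name, cds=seq, protein=best_frame_translation(seq)
            )
    return index


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute all stages in order; optionally write every artifact as TSV."""
    config = config or PipelineConfig()

    # 1. all-vs-all protein similarity across every species
    protein_sets = _protein_sets(inputs)
    hits = all_vs_all(protein_sets, PROTEIN, score_threshold=config.score_threshold)

    # 2. families from the similarity graph
    universe = {sp: sorted(seqs) for sp, seqs in protein_sets.items()}
    families = cluster_families(hits, universe, config.cluster_evalue_cutoff)

    # 3. screening funnel
    gene_models = _gene_model_index(inputs)
    gene_keywords = {
        qid: model.annotation_keywords for qid, model in gene_models.items()
    }
    genome_pairs = inputs.genome_pairs()
    searchers = {
        annual: GenomeSearcher(inputs.genomes[annual], scheme=NUCLEOTIDE)
        for annual, _ in genome_pairs
    }
    funnel = run_funnel(
        families,
        inputs.profiles,
        hits,
        gene_models,
        searchers,
        gene_keywords=gene_keywords,
        keyword_classes=config.keyword_classes,
        exclusion_list=config.exclusion_list,
        reference_perennial=config.reference_perennial,
        genome_perennial=config.comparison_perennial,
        evalue_floor=config.evalue_floor,
        order_threshold=config.evalue_order_threshold,
        misannotation_identity=config.misannotation_identity,
    )

    # 4. BBH maps per genome-level sister pair (nucleotide, gene sets)
    bbh_maps: dict[tuple[str, str], dict[str, tuple[str, float]]] = {}
    for annual, perennial in genome_pairs:
        nt_sets = {
            annual: {g.gene_id: g.cds for g in inputs.genes[annual]},
            perennial: {g.gene_id: g.cds for g in inputs.genes[perennial]},
        }
        nt_hits = all_vs_all(nt_sets, NUCLEOTIDE, score_threshold=config.score_threshold)
        fwd = [h for h in nt_hits if h.query.startswith(annual + "|")]
        rev = [h for h in nt_hits if h.query.startswith(perennial + "|")]
        bbh_maps[(annual, perennial)] = compute_bbh_map(fwd, rev)

    # 5. genome-wide background envelope per pair
    backgrounds: dict[tuple[str, str], BackgroundDistribution] = {}
    cds_index = {
        qid: model.cds for qid, model in gene_models.items() if model.cds
    }
    for annual, perennial in genome_pairs:
        gene_pairs = []
        for fam in families:
            genes_a = fam.genes_of(annual)
            genes_p = fam.genes_of(perennial)
            if genes_a and genes_p:
                gene_pairs.append(
                    (
                        fam.family_id,
                        cds_index[qualified_id(perennial, genes_p[0])],
                        cds_index[qualified_id(annual, genes_a[0])],
                    )
                )
        backgrounds[(annual, perennial)] = molevol.background_percentiles(
            gene_pairs,
            species_pair=(annual, perennial),
            min_usable=config.background_min_usable,
            percentiles=config.percentiles,
        )

    # 6. per-candidate synteny search, pseudogene calling, dating
    reports: list[CandidateReport] = []
    perennial_names = {
        p.name for p in inputs.profiles if p.life_history == "perennial"
    }
    for fam in funnel.retained:
        report = CandidateReport(
            family_id=fam.family_id,
            perennial_genes={
                sp: fam.genes_of(sp)
                for sp in sorted(perennial_names)
                if fam.present_in(sp)
            },
        )
        for annual, perennial in genome_pairs:
            genes_p = fam.genes_of(perennial)
            if not genes_p:
                report.per_annual[annual] = CandidateOutcome(
                    outcome=OUTCOME_NOT_FOUND, verdict=VERDICT_NOT_FOUND
                )
                continue
            target = next(
                g for g in inputs.genes[perennial] if g.gene_id == genes_p[0]
            )
            result = locate_lost_gene(
                target,
                inputs.genes[perennial],
                inputs.genes[annual],
                searchers[annual],
                bbh_maps[(annual, perennial)],
                window_bp=config.window_bp,
                n_extension_genes=config.extension_genes,
                evalue_cutoff=config.cluster_evalue_cutoff,
                score_threshold=config.score_threshold,
            )
            call = result.call
            if call.verdict == VERDICT_REAL_GENE:
                outcome = OUTCOME_REAL_GENE
            elif call.verdict == VERDICT_PSEUDOGENE:
                outcome = (
                    OUTCOME_PSEUDO_SYNTENIC if result.syntenic else OUTCOME_PSEUDO_NONSYNTENIC
                )
            else:
                outcome = OUTCOME_NOT_FOUND
            entry = CandidateOutcome(outcome=outcome, verdict=call.verdict, result=result)
            if call.in_frame_locus and len(call.in_frame_locus) >= 30:
                aln = protein_guided_codon_align(target.cds, call.in_frame_locus)
                aln = strip_stop_columns(aln, pseudogene_row=1)
                entry.dnds = ng86_dnds(aln)
                try:
                    entry.classification = classify_candidate(
                        entry.dnds, backgrounds[(annual, perennial)]
                    )
                except UndefinedRatioError as exc:
                    entry.classification_refused = exc.reason
            report.per_annual[annual] = entry
        reports.append(report)

    result = PipelineResult(
        inputs=inputs,
        config=config,
        hits=hits,
        families=families,
        funnel=funnel,
        bbh_maps=bbh_maps,
        backgrounds=backgrounds,
        reports=reports,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


# ---------------------------------------------------------------------------
# artifacts

def summarize_funnel(funnel: FunnelResult) -> list[dict]:
    """One row per filter stage with in/out counts and a reasons histogram."""
    rows = []
    for row in funnel.rows:
        rows.append(
            {
                "stage": row.stage,
                "n_in": row.n_in,
                "n_out": row.n_out,
                "reasons": json.dumps(dict(sorted(row.reasons.items()))),
            }
        )
    return rows


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_blast_tab(result.hits, outdir / "hits.protein.tsv")
    write_orthomcl_groups(result.families, outdir / "groups.txt")

    with open(outdir / "funnel.tsv", "w") as fh:
        fh.write("stage\tn_in\tn_out\treasons\n")
        for row in summarize_funnel(result.funnel):
            fh.write(f"{row['stage']}\t{row['n_in']}\t{row['n_out']}\t{row['reasons']}\n")

    with open(outdir / "screen_decisions.tsv", "w") as fh:
        fh.write("family_id\tverdict\treason\tevidence\n")
        for family_id in sorted(result.funnel.decisions):
            d = result.funnel.decisions[family_id]
            fh.write(f"{d.family_id}\t{d.verdict}\t{d.reason or '.'}\t{d.evidence}\n")

    annuals = [p.name for p in result.inputs.profiles if p.is_annual]
    perennials = [p.name for p in result.inputs.profiles if not p.is_annual]
    with open(outdir / "venn_absent_annuals.tsv", "w") as fh:
        fh.write("pattern\tcount\n")
        counts = loss_screen.venn_decompose(result.families, annuals, mode="absence")
        for pattern in sorted(counts, key=lambda p: (len(p), sorted(p))):
            fh.write(",".join(sorted(pattern)) + f"\t{counts[pattern]}\n")
    missing_all = [
        fam for fam in result.families if not any(fam.present_in(s) for s in annuals)
    ]
    with open(outdir / "venn_present_perennials.tsv", "w") as fh:
        fh.write("pattern\tcount\n")
        counts = loss_screen.venn_decompose(missing_all, perennials, mode="presence")
        for pattern in sorted(counts, key=lambda p: (len(p), sorted(p))):
            fh.write(",".join(sorted(pattern)) + f"\t{counts[pattern]}\n")

    with open(outdir / "background_dnds.tsv", "w") as fh:
        fh.write(
            "annual\tperennial\tn_ratios\tp5\tmedian\tp95\t"
            "n_excluded_poor_alignment\tn_excluded_ds_zero\n"
        )
        for (annual, perennial), bg in sorted(result.backgrounds.items()):
            fh.write(
                f"{annual}\t{perennial}\t{len(bg.ratios)}\t{bg.p5:.4f}\t"
                f"{bg.median:.4f}\t{bg.p95:.4f}\t"
                f"{bg.n_excluded_poor_alignment}\t{bg.n_excluded_ds_zero}\n"
            )

    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write(
            "family_id\tannual\toutcome\tverdict\tcontig\tstart\tend\tstrand\t"
            "aligned_fraction\tidentity_pct\tpremature_stops\tframeshifts\t"
            "dn\tds\tdnds\tclassification\n"
        )
        for report in result.reports:
            for annual in sorted(report.per_annual):
                entry = report.per_annual[annual]
                call = entry.result.call if entry.result else None
                locus = call.locus if call and call.locus else (".", ".", ".", ".")
                dn = ds = ratio = "."
                if entry.dnds is not None:
                    dn = "." if entry.dnds.dN is None else f"{entry.dnds.dN:.4f}"
                    ds = "." if entry.dnds.dS is None else f"{entry.dnds.dS:.4f}"
                    ratio = "." if entry.dnds.ratio is None else f"{entry.dnds.ratio:.4f}"
                classification = entry.classification or entry.classification_refused or "."
                stops = len(call.premature_stops) if call else 0
                shifts = len(call.frameshifts) if call else 0
                fh.write(
                    f"{report.family_id}\t{annual}\t{entry.outcome}\t{entry.verdict}\t"
                    f"{locus[0]}\t{locus[1]}\t{locus[2]}\t{locus[3]}\t"
                    f"{(call.aligned_fraction if call else 0):.3f}\t"
                    f"{(call.identity_pct if call else 0):.1f}\t"
                    f"{stops}\t{shifts}\t{dn}\t{ds}\t{ratio}\t{classification}\n"
                )
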