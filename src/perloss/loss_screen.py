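"""The screening funnel for perennial-retained / annual-lost gene families.

Families first pass a phyletic screen (absent from every annual species;
present in the required perennials), then a fixed sequence of elimination
filters:

1. annotation-keyword exclusions (transposon, self-incompatibility and
   ribosomal families are uninformative for life-history transitions),
2. misannotation checks against the annual sister genomes (an intact,
   near-identical copy of the "lost" gene in the annual genome means the
   loss is an annotation artifact; a perennial protein that matches no
   reading frame of its own CDS is itself misannotated),
3. an optional exclusion list standing in for re-checks against newer
   annotation releases,
4. the transcript-completeness filter: when the best hit from the reference
   perennial into a transcriptome-level annual's gene set is at least one
   order of magnitude better (on E-value) than its hit to the comparison
   genome perennial, the family's "loss" is more plausibly an incomplete
   transcript and the family is eliminated.

Each eliminated family carries exactly one primary reason (the first
failing filter in this fixed order); the full per-filter outcome vector is
retained for auditing.  Filters only ever remove families.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .family_builder import GeneFamily
from .io_formats import GENOME, PERENNIAL, SimilarityHit, SpeciesProfile, qualified_id
from .molevol import translate_cds
from .similarity import EVALUE_FLOOR, GenomeSearcher, floor_evalue
from .synteny_pseudo import VERDICT_REAL_GENE, call_pseudogene

VERDICT_RETAINED = "retained"
VERDICT_ELIMINATED = "eliminated"

REASON_HAS_ANNUAL = "has_annual_member"
REASON_FAILS_PERENNIAL = "fails_perennial_requirement"
REASON_COMPLETENESS = "completeness_filter"
REASON_TRANSPOSON = "annotation_transposon"
REASON_SELF_INCOMPAT = "annotation_self_incompatibility"
REASON_RIBOSOMAL = "annotation_ribosomal"
REASON_MISANNOT_COMPLETE = "misannotation_complete_gene_in_annual"
REASON_MISANNOT_FRAME = "misannotation_wrong_frame"
REASON_NOT_IN_ANNOTATION = "not_in_current_annotation"

DEFAULT_KEYWORD_CLASSES: dict[str, tuple[str, ...]] = {
    REASON_TRANSPOSON: ("transposon", "transposase", "gag-pol", "retrotransposon"),
    REASON_SELF_INCOMPAT: ("s-locus", "self-incompatibility", "srk", "scr"),
    REASON_RIBOSOMAL: ("ribosomal protein", "rrna"),
}


@dataclass
class PresencePattern:
    family_id: str
    absent_annuals: frozenset[str]
    present_perennials: frozenset[str]


@dataclass
class ScreenDecision:
    family_id: str
    verdict: str
    reason: str | None = None
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.verdict == VERDICT_ELIMINATED and not self.reason:
            raise ValueError(f"{self.family_id}: eliminated without a reason")


@dataclass
class FunnelRow:
    stage: str
    n_in: int
    n_out: int
    reasons: Counter = field(default_factory=Counter)


# ---------------------------------------------------------------------------
# phyletic decomposition

def venn_decompose(
    families: Sequence[GeneFamily],
    species_subset: Sequence[str],
    mode: str = "absence",
) -> dict[frozenset[str], int]:
    """Count families per phyletic pattern over a species subset.

    ``absence`` assigns each family the set of subset species it lacks;
    ``presence`` the set it contains.  Families with an empty pattern do
    not qualify, so the counts partition the qualifying families.
    """
    if mode not in {"absence", "presence"}:
        raise ValueError("mode must be 'absence' or 'presence'")
    counts: dict[frozenset[str], int] = {}
    for fam in families:
        if mode == "absence":
            pattern = frozenset(sp for sp in species_subset if not fam.present_in(sp))
        else:
            pattern = frozenset(sp for sp in species_subset if fam.present_in(sp))
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def presence_pattern(
    family: GeneFamily, profiles: Sequence[SpeciesProfile]
) -> PresencePattern:
    annuals = [p.name for p in profiles if p.is_annual]
    perennials = [p.name for p in profiles if not p.is_annual]
    return PresencePattern(
        family_id=family.family_id,
        absent_annuals=frozenset(s for s in annuals if not family.present_in(s)),
        present_perennials=frozenset(s for s in perennials if family.present_in(s)),
    )


# ---------------------------------------------------------------------------
# phyletic screens

def screen_strict(
    families: Sequence[GeneFamily], profiles: Sequence[SpeciesProfile]
) -> list[GeneFamily]:
    """Families present in ALL perennials and absent from ALL annuals."""
    annuals = [p.name for p in profiles if p.is_annual]
    perennials = [p.name for p in profiles if not p.is_annual]
    return [
        fam
        for fam in families
        if not any(fam.present_in(s) for s in annuals)
        and all(fam.present_in(s) for s in perennials)
    ]


def screen_relaxed(
    families: Sequence[GeneFamily],
    profiles: Sequence[SpeciesProfile],
    optional_perennials: Iterable[str] | None = None,
) -> list[GeneFamily]:
    """Families absent from all annuals and present in all REQUIRED perennials.

    Transcriptome-level perennials are optional by default: their catalogues
    are incomplete, so absence there is weak evidence.  The result is a
    superset of the strict screen.
    """
    if optional_perennials is None:
        optional = {
            p.name for p in profiles if not p.is_annual and p.data_level != GENOME
        }
    else:
        optional = set(optional_perennials)
        by_name = {p.name: p for p in profiles}
        for name in sorted(optional):
            profile = by_name.get(name)
            if profile is not None and profile.data_level == GENOME:
                warnings.warn(
                    f"optional perennial {name!r} is genome-level; its absence "
                    "would be strong evidence",
                    stacklevel=2,
                )
    annuals = [p.name for p in profiles if p.is_annual]
    required = [
        p.name for p in profiles if not p.is_annual and p.name not in optional
    ]
    return [
        fam
        for fam in families
        if not any(fam.present_in(s) for s in annuals)
        and all(fam.present_in(s) for s in required)
    ]


# ---------------------------------------------------------------------------
# elimination filters

def annotation_exclusion(
    family: GeneFamily,
    gene_keywords: Mapping[str, Iterable[str]],
    keyword_classes: Mapping[str, Sequence[str]] | None = None,
) -> ScreenDecision:
    """Eliminate a family if ANY member carries a configured keyword.

    Matching is case-insensitive substring over the configured lists.
    ``gene_keywords`` maps qualified gene ids to annotation keyword sets.
    """
    classes = keyword_classes or DEFAULT_KEYWORD_CLASSES
    for qid in family.qualified_members():
        keywords = [k.lower() for k in gene_keywords.get(qid, ())]
        for reason in sorted(classes):
            for needle in classes[reason]:
                for kw in keywords:
                    if needle.lower() in kw:
                        return ScreenDecision(
                            family_id=family.family_id,
                            verdict=VERDICT_ELIMINATED,
                            reason=reason,
                            evidence=f"{qid}: {kw!r} matches {needle!r}",
                        )
    return ScreenDecision(family_id=family.family_id, verdict=VERDICT_RETAINED)


def _matches_some_frame(protein: str, cds: str) -> bool:
    for frame in range(3):
        if translate_cds(cds[frame:]) == protein:
            return True
    return False


def misannotation_check(
    family: GeneFamily,
    gene_models: Mapping[str, "object"],
    annual_searchers: Mapping[str, GenomeSearcher],
    min_identity: float = 90.0,
    min_coverage: float = 0.9,
) -> ScreenDecision:
    """Eliminate families whose "loss" looks like an annotation artifact.

    (a) If an annual sister genome contains an intact open reading frame
    covering >= ``min_coverage`` of a perennial member's CDS at
    >= ``min_identity`` percent identity, the gene is present but
    unannotated there.  A degraded copy (premature stops, frameshifts,
    heavy truncation) does NOT trigger this: that is the interesting case.
    (b) If a perennial member's protein matches no reading frame of its own
    CDS, the perennial annotation itself is wrong.

    ``gene_models`` maps qualified ids to objects with ``cds``/``protein``.
    """
    for qid in family.qualified_members():
        model = gene_models.get(qid)
        if model is None or not model.cds:
            continue
        if model.protein and not _matches_some_frame(model.protein, model.cds):
            return ScreenDecision(
                family_id=family.family_id,
                verdict=VERDICT_ELIMINATED,
                reason=REASON_MISANNOT_FRAME,
                evidence=f"{qid}: protein matches no reading frame of its CDS",
            )
        for annual, searcher in sorted(annual_searchers.items()):
            loci = searcher.search(model.cds)
            if not loci:
                continue
            best = loci[0]
            if best.query_coverage < min_coverage or best.identity_pct < min_identity:
                continue
            contig_seq = searcher.contigs[best.contig]
            locus_seq = contig_seq[best.start : best.end]
            if best.strand == "-":
                from .similarity import revcomp

                locus_seq = revcomp(locus_seq)
            call = call_pseudogene(locus_seq, model.cds)
            if call.verdict == VERDICT_REAL_GENE:
                return ScreenDecision(
                    family_id=family.family_id,
                    verdict=VERDICT_ELIMINATED,
                    reason=REASON_MISANNOT_COMPLETE,
                    evidence=(
                        f"{qid}: intact copy in {annual} at "
                        f"{best.contig}:{best.start}-{best.end} "
                        f"({best.identity_pct:.1f}% id, {best.query_coverage:.2f} cov)"
                    ),
                )
    return ScreenDecision(family_id=family.family_id, verdict=VERDICT_RETAINED)


def completeness_filter(
    family: GeneFamily,
    hits: Sequence[SimilarityHit],
    reference_perennial: str,
    genome_perennial: str,
    transcriptome_annuals: Sequence[str],
    evalue_floor: float = EVALUE_FLOOR,
    order_threshold: float = 1.0,
) -> ScreenDecision:
    """Eliminate families whose loss may be an incomplete annual transcript.

    Compares the best E-value from the reference perennial's family members
    into any transcriptome-level annual's ENTIRE gene set against the best
    family-internal E-value between the two genome perennials.  Elimination
    requires the annual hit to be at least ``order_threshold`` orders of
    magnitude better (boundary inclusive); E-values are floored before the
    log10 comparison.  Without a perennial-perennial hit the family is
    retained with a warning (the test cannot be evaluated).
    """
    ref_members = {
        qualified_id(reference_perennial, g) for g in family.genes_of(reference_perennial)
    }
    cmp_members = {
        qualified_id(genome_perennial, g) for g in family.genes_of(genome_perennial)
    }
    if not ref_members or not cmp_members:
        return ScreenDecision(
            family_id=family.family_id,
            verdict=VERDICT_RETAINED,
            evidence="completeness filter not evaluable: missing perennial member",
        )
    e_perennial = None
    e_annual: dict[str, float] = {}
    annual_prefixes = {sp: sp + "|" for sp in transcriptome_annuals}
    for hit in hits:
        if hit.query in ref_members and hit.subject in cmp_members:
            e_perennial = min(e_perennial, hit.evalue) if e_perennial is not None else hit.evalue
        elif hit.query in cmp_members and hit.subject in ref_members:
            e_perennial = min(e_perennial, hit.evalue) if e_perennial is not None else hit.evalue
        elif hit.query in ref_members:
            for sp, prefix in annual_prefixes.items():
                if hit.subject.startswith(prefix):
                    e_annual[sp] = min(e_annual.get(sp, hit.evalue), hit.evalue)
    if e_perennial is None:
        return ScreenDecision(
            family_id=family.family_id,
            verdict=VERDICT_RETAINED,
            evidence="completeness filter not evaluable: no perennial-perennial hit",
        )
    if not e_annual:
        return ScreenDecision(
            family_id=family.family_id,
            verdict=VERDICT_RETAINED,
            evidence="no transcriptome-annual hit",
        )
    best_annual = min(e_annual.values())
    log_gap = math.log10(floor_evalue(e_perennial, evalue_floor)) - math.log10(
        floor_evalue(best_annual, evalue_floor)
    )
    per_annual = ", ".join(f"{sp}: {e:.3g}" for sp, e in sorted(e_annual.items()))
    if log_gap >= order_threshold:
        return ScreenDecision(
            family_id=family.family_id,
            verdict=VERDICT_ELIMINATED,
            reason=REASON_COMPLETENESS,
            evidence=(
                f"annual hit {best_annual:.3g} beats perennial-perennial "
                f"{e_perennial:.3g} by {log_gap:.2f} orders ({per_annual})"
            ),
        )
    return ScreenDecision(
        family_id=family.family_id,
        verdict=VERDICT_RETAINED,
        evidence=f"gap {log_gap:.2f} orders ({per_annual})",
    )


def exclusion_list_filter(
    family: GeneFamily, excluded: Iterable[str]
) -> ScreenDecision:
    """Stand-in for re-checks against newer annotation releases.

    ``excluded`` lists family ids or qualified gene ids known to be absent
    from the current annotation.
    """
    excluded = set(excluded)
    if family.family_id in excluded:
        return ScreenDecision(
            family_id=family.family_id,
            verdict=VERDICT_ELIMINATED,
            reason=REASON_NOT_IN_ANNOTATION,
            evidence="family listed in annotation exclusion list",
        )
    for qid in family.qualified_members():
        if qid in excluded:
            return ScreenDecision(
                family_id=family.family_id,
                verdict=VERDICT_ELIMINATED,
                reason=REASON_NOT_IN_ANNOTATION,
                evidence=f"{qid} listed in annotation exclusion list",
            )
    return ScreenDecision(family_id=family.family_id, verdict=VERDICT_RETAINED)


# ---------------------------------------------------------------------------
# the funnel

@dataclass
class FunnelResult:
    retained: list[GeneFamily]
    decisions: dict[str, ScreenDecision]  # primary decision per screened family
    outcome_vectors: dict[str, dict[str, ScreenDecision]]
    rows: list[FunnelRow]
    strict: list[GeneFamily]
    relaxed: list[GeneFamily]


def run_funnel(
    families: Sequence[GeneFamily],
    profiles: Sequence[SpeciesProfile],
    hits: Sequence[SimilarityHit],
    gene_models: Mapping[str, "object"],
    annual_searchers: Mapping[str, GenomeSearcher],
    gene_keywords: Mapping[str, Iterable[str]] | None = None,
    keyword_classes: Mapping[str, Sequence[str]] | None = None,
    exclusion_list: Iterable[str] = (),
    reference_perennial: str | None = None,
    genome_perennial: str | None = None,
    evalue_floor: float = EVALUE_FLOOR,
    order_threshold: float = 1.0,
    misannotation_identity: float = 90.0,
) -> FunnelResult:
    """Run the complete screening funnel in its fixed filter order."""
    gene_keywords = gene_keywords or {}
    strict = screen_strict(families, profiles)
    relaxed = screen_relaxed(families, profiles)
    rows = [
        FunnelRow(stage="phyletic_screen", n_in=len(families), n_out=len(relaxed))
    ]
    transcriptome_annuals = [
        p.name for p in profiles if p.is_annual and p.data_level != GENOME
    ]
    genome_perennials = sorted(
        p.name for p in profiles if p.life_history == PERENNIAL and p.data_level == GENOME
    )
    if reference_perennial is None and len(genome_perennials) >= 2:
        genome_perennial = genome_perennial or genome_perennials[0]
        reference_perennial = genome_perennials[-1]

    stages: list[tuple[str, callable]] = [
        (
            "annotation_keywords",
            lambda fam: annotation_exclusion(fam, gene_keywords, keyword_classes),
        ),
        (
            "misannotation",
            lambda fam: misannotation_check(
                fam, gene_models, annual_searchers, min_identity=misannotation_identity
            ),
        ),
        (
            "current_annotation",
            lambda fam: exclusion_list_filter(fam, exclusion_list),
        ),
    ]
    if reference_perennial and genome_perennial and transcriptome_annuals:
        stages.append(
            (
                "completeness",
                lambda fam: completeness_filter(
                    fam,
                    hits,
                    reference_perennial,
                    genome_perennial,
                    transcriptome_annuals,
                    evalue_floor=evalue_floor,
                    order_threshold=order_threshold,
                ),
            )
        )

    decisions: dict[str, ScreenDecision] = {}
    outcome_vectors: dict[str, dict[str, ScreenDecision]] = {}
    current = list(relaxed)
    for stage_name, stage_fn in stages:
        surviving = []
        row = FunnelRow(stage=stage_name, n_in=len(current), n_out=0)
        for fam in current:
            decision = stage_fn(fam)
            outcome_vectors.setdefault(fam.family_id, {})[stage_name] = decision
            if decision.verdict == VERDICT_ELIMINATED:
                decisions[fam.family_id] = decision
                row.reasons[decision.reason] += 1
            else:
                surviving.append(fam)
        row.n_out = len(surviving)
        rows.append(row)
        current = surviving
    for fam in current:
        decisions[fam.family_id] = ScreenDecision(
            family_id=fam.family_id, verdict=VERDICT_RETAINED
        )
    return FunnelResult(
        retained=current,
        decisions=decisions,
        outcome_vectors=outcome_vectors,
        rows=rows,
        strict=strict,
        relaxed=relaxed,
    )
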