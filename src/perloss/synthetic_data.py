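"""Simulate a toy clade of annual/perennial sister pairs with planted gene loss.

The generator emulates the study design the pipeline targets: several
annual/perennial sister pairs plus extra annual outgroups, some species with
full genome annotation (CDS/protein FASTA + GFF3 + contig sequences) and
some with transcript FASTA only.  A configurable fraction of gene families
is "lost" in every annual lineage — deleted outright, pseudogenized in
place (premature stop, frameshift, large deletion, or terminal truncation),
or, to exercise misannotation screening, left intact in the genome but
dropped from the annotation.  A ground-truth ledger records every planted
fate so downstream stages can be scored exactly.

Sequence evolution is deliberately simple: uniform base substitution with no
transition/transversion bias (matching the assumptions of the NG86 estimator
used downstream), an acceptance probability of ``omega`` for nonsynonymous
proposals, and rejection of stop-creating changes while a gene is under
constraint.  Pseudogenes evolve in two phases: constrained for a fraction
``1 - age`` of the annual branch, then the lesion is applied, then
unconstrained (omega = 1, stops tolerated) for the remaining fraction
``age``.  ``age`` close to 1 therefore means the gene died essentially at
the species split.

The tree is a star of monophyletic sister pairs: each pair's ancestor sits
one branch below the root and each species one branch below its pair
ancestor; outgroup annuals hang off the root on a branch of twice the unit
length so that sister species are always each other's closest relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import (
    ANNUAL,
    GENOME,
    PERENNIAL,
    TRANSCRIPTOME,
    GeneModel,
    SpeciesProfile,
    write_fasta,
    write_gff3,
    write_species_table,
)
from .molevol import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate_cds
from .similarity import revcomp

BASES = "ACGT"

MODE_PREMATURE_STOP = "premature_stop"
MODE_FRAMESHIFT = "frameshift"
MODE_DELETION = "deletion"
MODE_TRUNCATION = "truncation"
PSEUDOGENE_MODES = (MODE_PREMATURE_STOP, MODE_FRAMESHIFT, MODE_DELETION, MODE_TRUNCATION)

FATE_DELETED = "deleted"
FATE_PSEUDOGENIZED = "pseudogenized"
FATE_REAL = "real"

STATUS_RETAINED = "retained_all"
STATUS_LOST = "lost_in_annuals"

_SEED_MOD = 2**31


@dataclass
class SimConfig:
    """Study-design knobs of the simulated clade.

    Defaults mirror the target design: four sister pairs (the first two with
    genome-level data, the rest transcriptome-only) plus one genome-level
    annual outgroup; 2 kb intergenic spacers; branch divergence of 0.05
    substitution proposals per site under purifying selection (omega 0.15);
    one family in ten planted as perennial-retained / annual-lost.
    """

    n_pairs: int = 4
    n_outgroup_annuals: int = 1
    n_genome_pairs: int = 2
    n_families: int = 200
    genes_per_contig: int = 20
    intergenic_bp: int = 2000
    gene_length_codons: tuple[int, int] = (100, 200)
    branch_sub_rate: float = 0.05
    omega: float = 0.15
    loss_fraction: float = 0.1
    pseudogene_modes: dict[str, float] = field(
        default_factory=lambda: {
            MODE_PREMATURE_STOP: 0.4,
            MODE_FRAMESHIFT: 0.3,
            MODE_DELETION: 0.15,
            MODE_TRUNCATION: 0.15,
        }
    )
    pseudogene_age: float = 0.5
    fate_weights: dict[str, float] = field(
        default_factory=lambda: {FATE_PSEUDOGENIZED: 0.7, FATE_DELETED: 0.3}
    )
    misannotated_fraction: float = 0.0
    transcriptome_species: frozenset[str] | None = None
    transcript_detection_prob: float = 0.9
    truncation_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 < self.omega:
            raise ValueError("omega must be positive")
        for name in (
            "loss_fraction",
            "pseudogene_age",
            "misannotated_fraction",
            "transcript_detection_prob",
            "truncation_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        unknown = set(self.pseudogene_modes) - set(PSEUDOGENE_MODES)
        if unknown:
            raise ValueError(f"unknown pseudogene modes {sorted(unknown)}")
        n_planted = self.n_lost + self.n_misannotated
        if n_planted > self.n_families:
            raise ValueError(
                f"{n_planted} planted families exceed n_families={self.n_families}"
            )

    @property
    def n_lost(self) -> int:
        return int(round(self.n_families * self.loss_fraction))

    @property
    def n_misannotated(self) -> int:
        return int(round(self.n_families * self.misannotated_fraction))


@dataclass
class TruthRecord:
    """Ground truth for one family: its status and per-annual-species fate."""

    family_id: str
    status: str
    fates: dict[str, str] = field(default_factory=dict)
    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    pseudogene_mode: str | None = None
    pseudogene_age: float | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Ancestral CDS of ``n_codons`` codons drawn uniformly from sense codons."""
    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_cds(ancestor_cds: str, branch_sub_rate: float, omega: float, seed) -> str:
    """Evolve a CDS along one branch under an omega-constrained point process.

    ``branch_sub_rate`` is the expected number of substitution proposals per
    site.  Synonymous proposals are always accepted, nonsynonymous ones with
    probability ``omega``, and proposals creating internal stop codons are
    rejected while constrained (omega < 1).  With omega >= 1 every proposal
    is accepted regardless of codon structure, which also permits evolving
    lesioned sequences whose length is no longer a multiple of three.
    """
    rng = _rng(seed)
    seq = list(ancestor_cds)
    length = len(seq)
    constrained = omega < 1.0
    if constrained:
        if length % 3:
            raise ValueError("constrained evolution requires a length divisible by 3")
        for i in range(0, length, 3):
            codon = ancestor_cds[i : i + 3]
            aa = CODON_TO_AA.get(codon)
            if aa is None:
                raise ValueError(f"invalid codon {codon!r} at position {i}")
            if aa == "*":
                raise ValueError(f"internal stop codon {codon!r} at position {i}")
    n_proposals = int(rng.poisson(branch_sub_rate * length)) if length else 0
    for _ in range(n_proposals):
        pos = int(rng.integers(length))
        old = seq[pos]
        alternatives = [b for b in BASES if b != old]
        new = alternatives[int(rng.integers(3))]
        if not constrained:
            seq[pos] = new
            continue
        codon_start = pos - pos % 3
        current = "".join(seq[codon_start : codon_start + 3])
        offset = pos - codon_start
        proposed = current[:offset] + new + current[offset + 1 :]
        if CODON_TO_AA[proposed] == "*":
            continue
        if CODON_TO_AA[proposed] != CODON_TO_AA[current] and rng.random() >= omega:
            continue
        seq[pos] = new
    return "".join(seq)


def _apply_lesion(cds: str, mode: str, rng: np.random.Generator) -> str:
    length = len(cds)
    if mode == MODE_PREMATURE_STOP:
        n_codons = length // 3
        # interior sense codon -> random stop codon
        candidates = [
            i for i in range(1, n_codons - 1) if cds[3 * i : 3 * i + 3] not in STOP_CODONS
        ]
        target = candidates[int(rng.integers(len(candidates)))]
        stop = sorted(STOP_CODONS)[int(rng.integers(3))]
        return cds[: 3 * target] + stop + cds[3 * target + 3 :]
    if mode == MODE_FRAMESHIFT:
        lo, hi = int(0.1 * length), max(int(0.9 * length), int(0.1 * length) + 1)
        pos = int(rng.integers(lo, hi))
        if rng.random() < 0.5:
            return cds[:pos] + BASES[int(rng.integers(4))] + cds[pos:]
        return cds[:pos] + cds[pos + 1 :]
    if mode == MODE_DELETION:
        if length < 9:
            raise ValueError("deletion mode needs a gene of at least 9 bp")
        keep = int(length * float(rng.uniform(0.15, 1.0 / 3.0)))
        keep = max(keep, 3)
        return cds[:keep] if rng.random() < 0.5 else cds[length - keep :]
    if mode == MODE_TRUNCATION:
        cut_codons = int((length // 3) * float(rng.uniform(0.25, 0.5)))
        cut = 3 * max(cut_codons, 1)
        return cds[cut:] if rng.random() < 0.5 else cds[: length - cut]
    raise ValueError(f"unknown pseudogene mode {mode!r}")


def plant_pseudogenization(
    cds: str,
    mode: str,
    age: float,
    branch_sub_rate: float,
    seed,
    omega: float = 0.15,
) -> str:
    """Pseudogenize a CDS along a branch.

    The sequence evolves constrained for a fraction ``1 - age`` of the
    branch, the lesion is applied, then it evolves unconstrained (omega 1,
    stops tolerated) for the remaining fraction ``age``.
    """
    if mode not in PSEUDOGENE_MODES:
        raise ValueError(f"unknown pseudogene mode {mode!r}")
    if mode == MODE_DELETION and len(cds) < 9:
        raise ValueError("deletion mode needs a gene of at least 9 bp")
    base_seed = int(seed) % _SEED_MOD
    constrained = evolve_cds(cds, branch_sub_rate * (1.0 - age), omega, base_seed)
    lesion_rng = np.random.default_rng((base_seed + 1) % _SEED_MOD)
    lesioned = _apply_lesion(constrained, mode, lesion_rng)
    return evolve_cds(lesioned, branch_sub_rate * age, 1.0, (base_seed + 2) % _SEED_MOD)


def emit_transcriptome(
    genes: Mapping[str, str],
    detection_prob: float,
    truncation_prob: float,
    seed,
) -> dict[str, str]:
    """Down-sample a gene set into an imperfect transcript catalogue.

    Each gene is detected independently with ``detection_prob``; detected
    transcripts are truncated at a random end with ``truncation_prob``,
    keeping a uniform fraction of at least 30% of the sequence.
    """
    rng = _rng(seed)
    transcripts: dict[str, str] = {}
    for gene_id in sorted(genes):
        seq = genes[gene_id]
        if rng.random() >= detection_prob:
            continue
        if rng.random() < truncation_prob:
            keep = int(len(seq) * float(rng.uniform(0.3, 1.0)))
            keep = max(keep, 1)
            seq = seq[:keep] if rng.random() < 0.5 else seq[len(seq) - keep :]
        transcripts[gene_id] = seq
    return transcripts


# ---------------------------------------------------------------------------
# whole-clade simulation

@dataclass
class SimulatedClade:
    """In-memory result of :func:`simulate_clade`, writable as plain text."""

    config: SimConfig
    species: list[SpeciesProfile]
    genes: dict[str, list[GeneModel]]  # annotated genes of genome-level species
    genomes: dict[str, dict[str, str]]  # species -> contig -> sequence
    transcripts: dict[str, dict[str, str]]  # transcriptome-level species
    truth: list[TruthRecord]

    def profile(self, name: str) -> SpeciesProfile:
        return next(p for p in self.species if p.name == name)

    def truth_by_family(self) -> dict[str, TruthRecord]:
        return {t.family_id: t for t in self.truth}

    def lost_family_ids(self) -> set[str]:
        return {t.family_id for t in self.truth if t.status == STATUS_LOST}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_species_table(self.species, outdir / "species_table.tsv")
        for sp in self.species:
            name = sp.name
            if sp.data_level == GENOME:
                models = self.genes[name]
                write_fasta({g.gene_id: g.cds for g in models}, outdir / f"{name}.cds.fasta")
                write_fasta(
                    {g.gene_id: g.protein for g in models}, outdir / f"{name}.protein.fasta"
                )
                write_fasta(self.genomes[name], outdir / f"{name}.genome.fasta")
                write_gff3(models, outdir / f"{name}.gff3")
            else:
                write_fasta(self.transcripts[name], outdir / f"{name}.transcripts.fasta")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "family_id\tstatus\tspecies\tfate\tcontig\tstart\tend\tmode\tage\n"
            )
            for rec in self.truth:
                if not rec.fates:
                    fh.write(
                        f"{rec.family_id}\t{rec.status}\t.\t.\t.\t.\t.\t.\t.\n"
                    )
                    continue
                for species in sorted(rec.fates):
                    contig, start, end = rec.intervals.get(species, (".", ".", "."))
                    mode = rec.pseudogene_mode or "."
                    age = "." if rec.pseudogene_age is None else f"{rec.pseudogene_age:g}"
                    fh.write(
                        f"{rec.family_id}\t{rec.status}\t{species}\t{rec.fates[species]}\t"
                        f"{contig}\t{start}\t{end}\t{mode}\t{age}\n"
                    )


def _species_layout(config: SimConfig) -> list[SpeciesProfile]:
    profiles: list[SpeciesProfile] = []
    transcriptome = config.transcriptome_species
    for i in range(1, config.n_pairs + 1):
        default_level = GENOME if i <= config.n_genome_pairs else TRANSCRIPTOME
        for life, prefix in ((ANNUAL, "annual"), (PERENNIAL, "perennial")):
            name = f"{prefix}_{i}"
            level = default_level
            if transcriptome is not None:
                level = TRANSCRIPTOME if name in transcriptome else GENOME
            profiles.append(
                SpeciesProfile(
                    name=name, life_history=life, data_level=level, pair_id=f"pair{i}"
                )
            )
    for j in range(1, config.n_outgroup_annuals + 1):
        name = f"outgroup_annual_{j}"
        level = GENOME
        if transcriptome is not None and name in transcriptome:
            level = TRANSCRIPTOME
        profiles.append(SpeciesProfile(name=name, life_history=ANNUAL, data_level=level))
    return profiles


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_SEED_MOD))


def simulate_clade(config: SimConfig) -> SimulatedClade:
    """Simulate gene sets, genomes and transcript catalogues for a clade.

    Deterministic given ``config.seed``; gene order is conserved across all
    species so flanking genes are syntenic, and lost families receive their
    planted fate in every annual species.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = _species_layout(config)
    species_names = [p.name for p in profiles]
    pair_of = {p.name: p.pair_id for p in profiles}
    pair_ids = sorted({p.pair_id for p in profiles if p.pair_id})

    n_fam = config.n_families
    lo, hi = config.gene_length_codons
    lengths = rng.integers(lo, hi + 1, size=n_fam)
    ancestors = [random_cds(int(n), rng) for n in lengths]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_fam)]

    planted = rng.choice(n_fam, size=config.n_lost + config.n_misannotated, replace=False)
    lost = set(int(i) for i in planted[: config.n_lost])
    misannotated = set(int(i) for i in planted[config.n_lost :])

    mode_names = sorted(config.pseudogene_modes)
    mode_w = np.array([config.pseudogene_modes[m] for m in mode_names], dtype=float)
    mode_w = mode_w / mode_w.sum()
    fate_names = sorted(config.fate_weights)
    fate_w = np.array([config.fate_weights[f] for f in fate_names], dtype=float)
    fate_w = fate_w / fate_w.sum()

    # per-family sequences for every species; lost/misannotated bookkeeping
    seqs: dict[str, list[str | None]] = {name: [None] * n_fam for name in species_names}
    annotated: dict[str, list[bool]] = {name: [True] * n_fam for name in species_names}
    truth: list[TruthRecord] = []
    annual_names = [p.name for p in profiles if p.is_annual]

    for f in range(n_fam):
        family_id = f"g{f:04d}"
        root = ancestors[f]
        record = TruthRecord(
            family_id=family_id,
            status=STATUS_LOST if f in lost or f in misannotated else STATUS_RETAINED,
        )
        family_mode = mode_names[int(rng.choice(len(mode_names), p=mode_w))]
        if f in lost:
            record.pseudogene_mode = family_mode
            record.pseudogene_age = config.pseudogene_age
        pair_anc: dict[str, str] = {}
        for pid in pair_ids:
            pair_anc[pid] = evolve_cds(
                root, config.branch_sub_rate, config.omega, _spawn_seed(rng)
            )
        for profile in profiles:
            name = profile.name
            parent = pair_anc[pair_of[name]] if pair_of[name] else root
            rate = config.branch_sub_rate if pair_of[name] else 2 * config.branch_sub_rate
            branch_seed = _spawn_seed(rng)
            if profile.is_annual and f in lost:
                fate = fate_names[int(rng.choice(len(fate_names), p=fate_w))]
                record.fates[name] = fate
                annotated[name][f] = False
                if fate == FATE_DELETED:
                    seqs[name][f] = None
                else:
                    seqs[name][f] = plant_pseudogenization(
                        parent,
                        family_mode,
                        config.pseudogene_age,
                        rate,
                        branch_seed,
                        omega=config.omega,
                    )
            elif profile.is_annual and f in misannotated:
                record.fates[name] = FATE_REAL
                annotated[name][f] = False
                seqs[name][f] = evolve_cds(parent, rate, config.omega, branch_seed)
            else:
                seqs[name][f] = evolve_cds(parent, rate, config.omega, branch_seed)
        truth.append(record)

    # assemble genomes / annotations / transcript catalogues
    genes: dict[str, list[GeneModel]] = {}
    genomes: dict[str, dict[str, str]] = {}
    transcripts: dict[str, dict[str, str]] = {}
    truth_by_idx = {i: truth[i] for i in range(n_fam)}

    for profile in profiles:
        name = profile.name
        if profile.data_level == TRANSCRIPTOME:
            catalogue = {
                f"g{f:04d}": seqs[name][f]
                for f in range(n_fam)
                if annotated[name][f] and seqs[name][f]
            }
            transcripts[name] = emit_transcriptome(
                catalogue,
                config.transcript_detection_prob,
                config.truncation_prob,
                _spawn_seed(rng),
            )
            continue
        models: list[GeneModel] = []
        contigs: dict[str, str] = {}
        for c_start in range(0, n_fam, config.genes_per_contig):
            contig_name = f"{name}_ctg{c_start // config.genes_per_contig + 1}"
            parts: list[str] = []
            pos = 0
            for f in range(c_start, min(c_start + config.genes_per_contig, n_fam)):
                spacer = "".join(
                    BASES[i] for i in rng.integers(4, size=config.intergenic_bp)
                )
                parts.append(spacer)
                pos += len(spacer)
                seq = seqs[name][f]
                rec = truth_by_idx[f]
                if seq is None:
                    if profile.is_annual and rec.fates.get(name) == FATE_DELETED:
                        rec.intervals[name] = (contig_name, pos, pos)
                    continue
                placed = seq if strands[f] == "+" else revcomp(seq)
                start, end = pos, pos + len(placed)
                parts.append(placed)
                pos = end
                if annotated[name][f]:
                    models.append(
                        GeneModel(
                            gene_id=f"g{f:04d}",
                            species=name,
                            contig=contig_name,
                            start=start,
                            end=end,
                            strand=strands[f],
                            cds=seq,
                            protein=translate_cds(seq),
                        )
                    )
                else:
                    rec.intervals[name] = (contig_name, start, end)
            tail = "".join(BASES[i] for i in rng.integers(4, size=config.intergenic_bp))
            parts.append(tail)
            contigs[contig_name] = "".join(parts)
        genes[name] = models
        genomes[name] = contigs

    return SimulatedClade(
        config=config,
        species=profiles,
        genes=genes,
        genomes=genomes,
        transcripts=transcripts,
        truth=truth,
    )


def simulate_ortholog_pairs(
    n_pairs: int,
    branch_sub_rate: float,
    omega: float,
    seed,
    n_codons: tuple[int, int] = (100, 200),
) -> list[tuple[str, str, str]]:
    """Independent ortholog pairs (family_id, cds_a, cds_b) for backgrounds.

    Each pair descends from a fresh random ancestor along two branches of the
    given rate under the given omega — the composition of a genome-wide
    background set of constrained ortholog pairs.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    lo, hi = n_codons
    for i in range(n_pairs):
        anc = random_cds(int(rng.integers(lo, hi + 1)), rng)
        a = evolve_cds(anc, branch_sub_rate, omega, _spawn_seed(rng))
        b = evolve_cds(anc, branch_sub_rate, omega, _spawn_seed(rng))
        pairs.append((f"bg{i:04d}", a, b))
    return pairs


def simulate_aged_pseudogene_pair(
    age: float,
    branch_sub_rate: float,
    omega: float,
    seed,
    n_codons: tuple[int, int] = (100, 200),
    mode: str = MODE_PREMATURE_STOP,
) -> tuple[str, str]:
    """(functional ortholog, pseudogene) diverging from one ancestor.

    The functional copy evolves fully constrained; the pseudogene follows the
    two-phase constrained -> lesion -> unconstrained process at the given age.
    """
    rng = np.random.default_rng(seed)
    anc = random_cds(int(rng.integers(n_codons[0], n_codons[1] + 1)), rng)
    functional = evolve_cds(anc, branch_sub_rate, omega, _spawn_seed(rng))
    pseudo = plant_pseudogenization(
        anc, mode, age, branch_sub_rate, _spawn_seed(rng), omega=omega
    )
    return functional, pseudo
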