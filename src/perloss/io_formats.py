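"""Readers and writers for the plain-text formats the pipeline exchanges.

The pipeline compares annotated gene sets across a clade of annual/perennial
sister species.  Genome-level species come with CDS + protein FASTA and GFF3
coordinates; transcriptome-level species contribute transcript FASTA only.
Similarity evidence travels as 12-column BLAST tabular text and gene families
as OrthoMCL-style groups lines.

Conventions
-----------
* Internal coordinates are 0-based half-open; the GFF3 reader/writer converts
  at the boundary (GFF3 is 1-based inclusive).
* Gene identifiers are unique within a species and become globally unique as
  ``species|gene`` (the OrthoMCL groups convention).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

ANNUAL = "annual"
PERENNIAL = "perennial"
GENOME = "genome"
TRANSCRIPTOME = "transcriptome"

_LIFE_HISTORIES = frozenset({ANNUAL, PERENNIAL})
_DATA_LEVELS = frozenset({GENOME, TRANSCRIPTOME})


class ParseError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a model invariant."""


def qualified_id(species: str, gene_id: str) -> str:
    """Globally unique gene id, ``species|gene``."""
    return f"{species}|{gene_id}"


def split_qualified(qid: str) -> tuple[str, str]:
    species, _, gene = qid.partition("|")
    if not gene:
        raise ParseError(f"gene id {qid!r} lacks a 'species|gene' separator")
    return species, gene


@dataclass(frozen=True)
class SpeciesProfile:
    """One species in the study design.

    ``pair_id`` links the annual and perennial member of a sister pair;
    outgroup species leave it empty.
    """

    name: str
    life_history: str
    data_level: str
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.life_history not in _LIFE_HISTORIES:
            raise ValidationError(f"unknown life history {self.life_history!r}")
        if self.data_level not in _DATA_LEVELS:
            raise ValidationError(f"unknown data level {self.data_level!r}")

    @property
    def is_annual(self) -> bool:
        return self.life_history == ANNUAL


def validate_species_profiles(profiles: Iterable[SpeciesProfile]) -> None:
    """Check that every pair_id maps to exactly one annual and one perennial."""
    pairs: dict[str, list[SpeciesProfile]] = {}
    seen: set[str] = set()
    for p in profiles:
        if p.name in seen:
            raise ValidationError(f"duplicate species name {p.name!r}")
        seen.add(p.name)
        if p.pair_id:
            pairs.setdefault(p.pair_id, []).append(p)
    for pair_id, members in pairs.items():
        histories = sorted(m.life_history for m in members)
        if histories != [ANNUAL, PERENNIAL]:
            raise ValidationError(
                f"pair {pair_id!r} must contain exactly one annual and one "
                f"perennial, got {[m.name for m in members]}"
            )


def read_species_table(path: str | Path) -> list[SpeciesProfile]:
    """Read the tab-separated species table (name, life_history, data_level, pair_id)."""
    profiles = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "life_history", "data_level"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: species table must carry columns {sorted(required)}")
        for row in reader:
            profiles.append(
                SpeciesProfile(
                    name=row["name"],
                    life_history=row["life_history"],
                    data_level=row["data_level"],
                    pair_id=(row.get("pair_id") or ""),
                )
            )
    validate_species_profiles(profiles)
    return profiles


def write_species_table(profiles: Iterable[SpeciesProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("name\tlife_history\tdata_level\tpair_id\n")
        for p in profiles:
            fh.write(f"{p.name}\t{p.life_history}\t{p.data_level}\t{p.pair_id}\n")


@dataclass
class GeneModel:
    """One annotated gene.

    Coordinates (contig/start/end/strand) are absent for transcriptome-level
    species.  ``cds`` is the spliced coding sequence in reading orientation;
    ``protein`` its conceptual translation with the terminal stop dropped.
    """

    gene_id: str
    species: str
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    cds: str = ""
    protein: str = ""
    annotation_keywords: set[str] = field(default_factory=set)
    transcripts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start

    @property
    def qualified_id(self) -> str:
        return qualified_id(self.species, self.gene_id)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity hit, BLAST-tabular flavoured.

    ``query``/``subject`` are qualified ``species|gene`` ids whenever the hit
    crosses species.  Coordinates, when present, are 1-based inclusive as in
    BLAST tabular output.
    """

    query: str
    subject: str
    bitscore: float
    evalue: float
    identity_pct: float
    aln_len: int
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query}->{self.subject}: negative E-value")
        if self.aln_len < 1:
            raise ValidationError(f"hit {self.query}->{self.subject}: alignment length < 1")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercased sequence map.

    Ids are the first whitespace-delimited header token.  Duplicate ids and
    empty records are errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ParseError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {record.id!r}")
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene skeletons (coordinates, no sequence) from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Each ``gene`` feature yields one skeleton; ids of its ``mRNA`` children
    are recorded for downstream primary-transcript selection.
    """
    genes: dict[str, GeneModel] = {}
    mrnas: list[tuple[str, str]] = []  # (parent gene id, mRNA id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in {"gene", "mRNA"}:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValidationError(f"{path}: line {lineno}: end < start")
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise ParseError(f"{path}: line {lineno}: gene feature lacks ID attribute")
                if gene_id in genes:
                    raise ParseError(f"{path}: line {lineno}: duplicate gene ID {gene_id!r}")
                genes[gene_id] = GeneModel(
                    gene_id=gene_id,
                    species="",
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in {"+", "-"} else None,
                )
            else:
                parent = attrs.get("Parent", "")
                mrna_id = attrs.get("ID", "")
                if parent and mrna_id:
                    mrnas.append((parent, mrna_id))
    for parent, mrna_id in mrnas:
        if parent in genes:
            genes[parent].transcripts = genes[parent].transcripts + (mrna_id,)
    return list(genes.values())


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "perloss") -> None:
    """Write single-exon gene/mRNA/CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if g.contig is None or g.start is None or g.end is None:
                raise ValidationError(f"gene {g.gene_id} has no coordinates; cannot emit GFF3")
            start1, end1 = g.start + 1, g.end
            strand = g.strand or "+"
            fh.write(
                f"{g.contig}\t{source}\tgene\t{start1}\t{end1}\t.\t{strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\t{source}\tmRNA\t{start1}\t{end1}\t.\t{strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\t{source}\tCDS\t{start1}\t{end1}\t.\t{strand}\t0\t"
                f"ID={mrna}.cds;Parent={mrna}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6, 12 columns)

_BLAST_COLUMNS = 12


def read_blast_tab(path: str | Path) -> list[SimilarityHit]:
    """Read 12-column BLAST tabular hits in file order."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _BLAST_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_BLAST_COLUMNS} columns, got {len(cols)}"
                )
            try:
                hits.append(
                    SimilarityHit(
                        query=cols[0],
                        subject=cols[1],
                        identity_pct=float(cols[2]),
                        aln_len=int(cols[3]),
                        mismatch=int(cols[4]),
                        gapopen=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_blast_tab(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity_pct:.2f}\t{h.aln_len}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# OrthoMCL groups

def read_orthomcl_groups(path: str | Path):
    """Read OrthoMCL-style groups lines ("FAM: sp|g sp|g ...") into GeneFamily objects."""
    from .family_builder import GeneFamily  # local import avoids a module cycle

    families: list[GeneFamily] = []
    seen_genes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            family_id, sep, rest = line.partition(":")
            if not sep:
                raise ParseError(f"{path}: line {lineno}: missing 'FAMID:' prefix")
            members: dict[str, set[str]] = {}
            for token in rest.split():
                try:
                    species, gene = split_qualified(token)
                except ParseError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
                if token in seen_genes:
                    raise ParseError(
                        f"{path}: line {lineno}: gene {token!r} appears in more than one family"
                    )
                seen_genes.add(token)
                members.setdefault(species, set()).add(gene)
            families.append(GeneFamily(family_id=family_id.strip(), members=members))
    return families


def write_orthomcl_groups(families, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in families:
            tokens = sorted(
                qualified_id(sp, g) for sp, genes in fam.members.items() for g in genes
            )
            fh.write(f"{fam.family_id}: " + " ".join(tokens) + "\n")
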