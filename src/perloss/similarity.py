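"""Built-in all-vs-all pairwise similarity scoring.

A desk-scale stand-in for BLAST: optimal local alignment by dynamic
programming (Biopython's PairwiseAligner) plus a Karlin–Altschul-style
E-value surrogate ``E = K * m * n * exp(-lambda * score)``.  Only order
relations and order-of-magnitude ratios of these E-values are consumed
downstream, so the absolute calibration of (K, lambda) is non-critical; the
constants used per scoring scheme are documented on the scheme objects.

Externally computed BLAST tabular hits can be ingested instead
(:func:`perloss.io_formats.read_blast_tab`) and flow through identical
downstream code paths.

To keep all-vs-all runs tractable on simulated clades, candidate pairs are
preselected by shared exact k-mers before the quadratic DP is run.  Pairs
sharing no k-mer cannot produce a hit above any useful score threshold at
the divergences this pipeline handles; the prefilter can be disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SimilarityHit, qualified_id

EVALUE_FLOOR = 1e-180

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus the (K, lambda) pair of the E-value surrogate.

    Gap costs follow the BLAST convention: a gap of length ``k`` costs
    ``gap_open + k * gap_extend``.
    """

    name: str
    mode: str  # "nucleotide" | "protein"
    gap_open: float
    gap_extend: float
    lambda_: float
    K: float
    match: float | None = None
    mismatch: float | None = None
    kmer: int = 12


NUCLEOTIDE = ScoringScheme(
    name="blastn-like", mode="nucleotide", gap_open=5, gap_extend=2,
    lambda_=1.28, K=0.46, match=2, mismatch=-3, kmer=12,
)
PROTEIN = ScoringScheme(
    name="blastp-like", mode="protein", gap_open=11, gap_extend=1,
    lambda_=0.267, K=0.041, kmer=5,
)


@lru_cache(maxsize=None)
def _stop_aware_blosum62():
    # '*' (stop in a translated pseudogene frame) scores as a mismatch to
    # everything, including itself, so stops never anchor an alignment.
    mat = substitution_matrices.load("BLOSUM62").copy()
    for x in mat.alphabet:
        mat[x, "*"] = -4.0
        mat["*", x] = -4.0
    return mat


@lru_cache(maxsize=None)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scheme.mode == "nucleotide":
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    else:
        aligner.substitution_matrix = _stop_aware_blosum62()
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    identity_pct: float
    aln_len: int
    mismatch: int
    gapopen: int
    query_interval: tuple[int, int]  # 0-based half-open on the query
    subject_interval: tuple[int, int]


_EMPTY = LocalAlignment(0.0, 0.0, 0, 0, 0, (0, 0), (0, 0))


def align_local(seq_a: str, seq_b: str, scheme: ScoringScheme = NUCLEOTIDE) -> LocalAlignment:
    """Optimal local alignment of ``seq_a`` (query) vs ``seq_b`` (subject).

    Returns a zero-score sentinel (``aln_len == 0``) when no positive-scoring
    local alignment exists.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(scheme, "local")
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return _EMPTY
    aln = aligner.align(seq_a, seq_b)[0]
    rows_a, rows_b = aln[0], aln[1]
    identities = sum(1 for x, y in zip(rows_a, rows_b) if x == y and x != "-")
    mismatches = sum(1 for x, y in zip(rows_a, rows_b) if x != y and x != "-" and y != "-")
    gapopens = 0
    for row in (rows_a, rows_b):
        in_gap = False
        for ch in row:
            if ch == "-" and not in_gap:
                gapopens += 1
            in_gap = ch == "-"
    aln_len = len(rows_a)
    blocks_a, blocks_b = aln.aligned
    qa, qb = int(blocks_a[0][0]), int(blocks_a[-1][1])
    sa, sb = int(blocks_b[0][0]), int(blocks_b[-1][1])
    identity_pct = 100.0 * identities / aln_len if aln_len else 0.0
    return LocalAlignment(
        score=float(score), identity_pct=identity_pct, aln_len=aln_len,
        mismatch=mismatches, gapopen=gapopens,
        query_interval=(qa, qb), subject_interval=(sa, sb),
    )


def local_score(seq_a: str, seq_b: str, scheme: ScoringScheme = NUCLEOTIDE) -> float:
    """Score-only local alignment (no traceback; much faster)."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    return float(_aligner(scheme, "local").score(seq_a, seq_b))


def evalue_from_score(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """E-value surrogate ``K * m * n * exp(-lambda * score)``.

    Strictly decreasing in score and linear in either sequence/database
    length; not floored here (flooring to ``EVALUE_FLOOR`` happens where
    log10 comparisons are made).
    """
    return scheme.K * m * n * math.exp(-scheme.lambda_ * score)


def floor_evalue(evalue: float, floor: float = EVALUE_FLOOR) -> float:
    return max(evalue, floor)


# ---------------------------------------------------------------------------
# k-mer candidate preselection

def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_index(seqs: Mapping[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for name, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(name)
    return index


def candidate_subjects(query: str, index: Mapping[str, set[str]], k: int) -> set[str]:
    found: set[str] = set()
    for i in range(len(query) - k + 1):
        found |= index.get(query[i : i + k], set())
    return found


# ---------------------------------------------------------------------------
# all-vs-all

def all_vs_all(
    gene_sets: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme = PROTEIN,
    score_threshold: float = 50.0,
    prefilter: bool = True,
) -> list[SimilarityHit]:
    """All-vs-all cross-species similarity search.

    ``gene_sets`` maps species -> {gene_id: sequence}.  For every ordered
    (query gene, subject species) pair the best local hit is retained, plus
    every hit with score >= ``score_threshold``.  Both directions of every
    species pair are searched, mirroring reciprocal BLAST runs.  Hit ids are
    qualified ``species|gene``.
    """
    species = sorted(gene_sets)
    if len(species) < 2:
        raise ValueError("all_vs_all needs at least two species")
    hits: list[SimilarityHit] = []
    indexes: dict[str, dict[str, set[str]]] = {}
    if prefilter:
        for sp in species:
            indexes[sp] = _kmer_index(gene_sets[sp], scheme.kmer)
    db_len = {sp: sum(len(s) for s in gene_sets[sp].values()) for sp in species}
    for sp_q in species:
        for sp_s in species:
            if sp_q == sp_s:
                continue
            subjects = gene_sets[sp_s]
            if not subjects:
                continue
            for gene_q in sorted(gene_sets[sp_q]):
                seq_q = gene_sets[sp_q][gene_q]
                if not seq_q:
                    continue
                if prefilter:
                    cands = candidate_subjects(seq_q, indexes[sp_s], scheme.kmer)
                else:
                    cands = set(subjects)
                if not cands:
                    continue
                scored = [
                    (local_score(seq_q, subjects[g], scheme), g)
                    for g in sorted(cands)
                    if subjects[g]
                ]
                if not scored:
                    continue
                best = max(s for s, _ in scored)
                if best <= 0:
                    continue
                keep = [(s, g) for s, g in scored if s >= score_threshold or s == best]
                keep.sort(key=lambda t: (-t[0], t[1]))
                for score, gene_s in keep:
                    aln = align_local(seq_q, subjects[gene_s], scheme)
                    if aln.aln_len == 0:
                        continue
                    evalue = evalue_from_score(score, len(seq_q), db_len[sp_s], scheme)
                    hits.append(
                        SimilarityHit(
                            query=qualified_id(sp_q, gene_q),
                            subject=qualified_id(sp_s, gene_s),
                            bitscore=score,
                            evalue=evalue,
                            identity_pct=aln.identity_pct,
                            aln_len=aln.aln_len,
                            mismatch=aln.mismatch,
                            gapopen=aln.gapopen,
                            qstart=aln.query_interval[0] + 1,
                            qend=aln.query_interval[1],
                            sstart=aln.subject_interval[0] + 1,
                            send=aln.subject_interval[1],
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# anchored genomic search (blastn stand-in against long targets)

@dataclass(frozen=True)
class GenomeLocus:
    """A merged homologous locus on a genomic target."""

    contig: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str  # strand of the query match: '+' or '-'
    score: float
    identity_pct: float
    query_coverage: float  # fraction of the query covered by merged hits


def _cluster_positions(positions: Sequence[int], max_gap: int) -> list[tuple[int, int]]:
    clusters = []
    lo = hi = positions[0]
    for p in positions[1:]:
        if p - hi > max_gap:
            clusters.append((lo, hi))
            lo = p
        hi = p
    clusters.append((lo, hi))
    return clusters


class GenomeSearcher:
    """k-mer-anchored local search of a query against large genomic targets.

    Exact shared k-mers select candidate slabs of the target; the optimal
    local alignment is then computed query-vs-slab only.  Overlapping or
    nearby slab hits are merged into loci (``merge_gap`` tolerance) and
    ranked by total score.  Both strands are searched.
    """

    def __init__(
        self,
        contigs: Mapping[str, str],
        scheme: ScoringScheme = NUCLEOTIDE,
        k: int | None = None,
        merge_gap: int = 1000,
    ) -> None:
        self.contigs = dict(contigs)
        self.scheme = scheme
        self.k = k or scheme.kmer
        self.merge_gap = merge_gap
        self._indexes: dict[str, dict[str, list[int]]] = {}

    def _index(self, contig: str) -> dict[str, list[int]]:
        if contig not in self._indexes:
            seq = self.contigs[contig]
            idx: dict[str, list[int]] = {}
            k = self.k
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append(i)
            self._indexes[contig] = idx
        return self._indexes[contig]

    def search(
        self,
        query: str,
        contig: str | None = None,
        interval: tuple[int, int] | None = None,
        score_threshold: float = 50.0,
    ) -> list[GenomeLocus]:
        """Search ``query`` on one contig (optionally one interval) or everywhere."""
        if not query:
            raise ValueError("empty query")
        contig_names = [contig] if contig is not None else sorted(self.contigs)
        raw: list[GenomeLocus] = []
        for name in contig_names:
            target = self.contigs[name]
            lo, hi = interval if interval is not None else (0, len(target))
            lo, hi = max(0, lo), min(len(target), hi)
            if hi - lo < self.k:
                continue
            region = target[lo:hi]
            raw.extend(self._search_region(query, name, region, lo, score_threshold))
        return self._merge(raw)

    def _search_region(
        self, query: str, contig: str, region: str, offset: int, score_threshold: float
    ) -> list[GenomeLocus]:
        hits: list[GenomeLocus] = []
        k = self.k
        use_index = offset == 0 and len(region) == len(self.contigs[contig])
        index = self._index(contig) if use_index else None
        for strand in "+-":
            q = query if strand == "+" else revcomp(query)
            positions: list[int] = []
            if index is not None:
                for i in range(len(q) - k + 1):
                    positions.extend(index.get(q[i : i + k], ()))
            else:
                kmers = kmer_set(q, k)
                for i in range(len(region) - k + 1):
                    if region[i : i + k] in kmers:
                        positions.append(i + offset)
            if not positions:
                continue
            positions = sorted(set(positions))
            pad = len(q)
            for lo, hi in _cluster_positions(positions, max_gap=pad + self.merge_gap):
                slab_lo = max(0, lo - pad)
                slab_hi = min(len(self.contigs[contig]), hi + k + pad)
                slab = self.contigs[contig][slab_lo:slab_hi]
                aln = align_local(q, slab, self.scheme)
                if aln.aln_len == 0 or aln.score < score_threshold:
                    continue
                s0, s1 = aln.subject_interval
                q0, q1 = aln.query_interval
                hits.append(
                    GenomeLocus(
                        contig=contig,
                        start=slab_lo + s0,
                        end=slab_lo + s1,
                        strand=strand,
                        score=aln.score,
                        identity_pct=aln.identity_pct,
                        query_coverage=(q1 - q0) / len(q),
                    )
                )
        return hits

    def _merge(self, hits: list[GenomeLocus]) -> list[GenomeLocus]:
        merged: list[GenomeLocus] = []
        keyed = sorted(hits, key=lambda h: (h.contig, h.strand, h.start, h.end))
        for h in keyed:
            if (
                merged
                and merged[-1].contig == h.contig
                and merged[-1].strand == h.strand
                and h.start - merged[-1].end <= self.merge_gap
            ):
                prev = merged[-1]
                merged[-1] = GenomeLocus(
                    contig=prev.contig,
                    start=min(prev.start, h.start),
                    end=max(prev.end, h.end),
                    strand=prev.strand,
                    score=prev.score + h.score,
                    identity_pct=max(prev.identity_pct, h.identity_pct),
                    query_coverage=min(1.0, prev.query_coverage + h.query_coverage),
                )
            else:
                merged.append(h)
        merged.sort(key=lambda h: (-h.score, h.contig, h.start))
        return merged
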