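"""Codon-level molecular evolution: protein-guided alignment and NG86 dN/dS.

Pseudogenization is dated by comparing the dN/dS ratio of a candidate
pseudogene (vs its intact ortholog) against a genome-wide background
envelope (5th percentile, median, 95th percentile) computed over ordinary
ortholog pairs.  A recently silenced gene still carries the signature of
purifying selection (ratio near the background); an anciently silenced one
drifts toward the neutral expectation of 1.

dN/dS uses the Nei–Gojobori (1986) counting method: per-codon synonymous and
nonsynonymous site fractions from the nine single-nucleotide neighbours,
pathway averaging over the orderings of multi-nucleotide codon differences,
and the Jukes–Cantor multiple-hit correction.  Mutations to or through stop
codons are excluded from site and pathway counts (when every pathway between
two codons passes through a stop, all pathways are used with equal weight
and the result is flagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

from .similarity import PROTEIN, _aligner

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
BASES = "ACGT"
GAP_CODON = "---"


class UndefinedRatioError(ValueError):
    """dN/dS is undefined for this pair (dS == 0 or a failed correction)."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def translate_cds(cds: str, stop_symbol: str = "*") -> str:
    """Translate complete codons; internal stops become ``stop_symbol``.

    A trailing incomplete codon is ignored; a terminal stop is dropped.
    """
    n = len(cds) - len(cds) % 3
    aas = []
    for i in range(0, n, 3):
        codon = cds[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        aas.append(stop_symbol if aa == "*" else aa if aa else "X")
    if aas and aas[-1] == stop_symbol:
        aas.pop()
    return "".join(aas)


# ---------------------------------------------------------------------------
# NG86 counting

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts ``(n, s)`` of a sense codon.

    Over the nine single-nucleotide neighbours, mutations to stop codons are
    excluded from the denominator; the synonymous fraction times three gives
    ``s`` and ``n = 3 - s``.
    """
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"invalid codon {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0
    non_stop = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            n_aa = CODON_TO_AA[neighbour]
            if n_aa == "*":
                continue
            non_stop += 1
            if n_aa == aa:
                syn += 1
    s = 3.0 * syn / non_stop
    return 3.0 - s, s


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Average (nonsyn, syn) differences between two sense codons.

    Differences are averaged over all orderings of the single-base changes;
    orderings whose intermediate codons are stops are excluded.  When every
    ordering is blocked, all orderings are used with equal weight and the
    third element of the result is True.
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0, False
    open_paths: list[tuple[int, int]] = []
    blocked_paths: list[tuple[int, int]] = []
    for order in permutations(diffs):
        current = codon_a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and nxt != codon_b:
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked_paths if blocked else open_paths).append((nd, sd))
    paths = open_paths or blocked_paths
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd, not open_paths


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the correction is undefined (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# codon alignments

@dataclass
class CodonAlignment:
    """A pair of gapped codon rows (each entry a triplet or '---')."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.codons_a)

    def row(self, index: int) -> tuple[str, ...]:
        return (self.codons_a, self.codons_b)[index]

    def degapped(self, index: int) -> str:
        return "".join(c for c in self.row(index) if c != GAP_CODON)

    def columns(self):
        return zip(self.codons_a, self.codons_b)


def protein_guided_codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Globally align two CDS in codon space via their translations.

    Translations (internal stops kept as '*', scored as universal
    mismatches) are aligned with BLOSUM62 and affine gaps (open 11,
    extend 1); every protein gap is expanded back to a 3-base codon gap.
    Trailing incomplete codons are trimmed.
    """
    rows = []
    codon_lists = []
    for cds in (cds_a, cds_b):
        n = len(cds) - len(cds) % 3
        codons = [cds[i : i + 3] for i in range(0, n, 3)]
        prot = "".join(
            "*" if CODON_TO_AA.get(c) in ("*", None) else CODON_TO_AA[c] for c in codons
        )
        if not prot:
            raise ValueError("empty translation; cannot align")
        rows.append(prot)
        codon_lists.append(codons)
    aligner = _aligner(PROTEIN, "global")
    aln = aligner.align(rows[0], rows[1])[0]
    gapped_a, gapped_b = aln[0], aln[1]
    out_a: list[str] = []
    out_b: list[str] = []
    it_a = iter(codon_lists[0])
    it_b = iter(codon_lists[1])
    for ch_a, ch_b in zip(gapped_a, gapped_b):
        out_a.append(GAP_CODON if ch_a == "-" else next(it_a))
        out_b.append(GAP_CODON if ch_b == "-" else next(it_b))
    return CodonAlignment(tuple(out_a), tuple(out_b))


def strip_stop_columns(alignment: CodonAlignment, pseudogene_row: int = 1) -> CodonAlignment:
    """Remove every column where the pseudogene row holds a stop codon."""
    keep = [
        i
        for i, codon in enumerate(alignment.row(pseudogene_row))
        if codon not in STOP_CODONS
    ]
    return CodonAlignment(
        tuple(alignment.codons_a[i] for i in keep),
        tuple(alignment.codons_b[i] for i in keep),
    )


# ---------------------------------------------------------------------------
# dN/dS

POOR_ALIGNMENT = "poor_alignment"
STOP_PATHWAYS_USED = "stop_pathways_used"


@dataclass
class DnDsResult:
    """NG86 estimates for one aligned pair."""

    N: float = 0.0
    S: float = 0.0
    Nd: float = 0.0
    Sd: float = 0.0
    pN: float = 0.0
    pS: float = 0.0
    dN: float | None = None
    dS: float | None = None
    ratio: float | None = None
    n_columns: int = 0
    flags: set[str] = field(default_factory=set)


def ng86_dnds(alignment: CodonAlignment) -> DnDsResult:
    """NG86 dN/dS over the comparable (gap-free, sense-codon) columns.

    Sites are averaged over both rows.  ``ratio`` is None when dS is zero;
    a failed Jukes–Cantor correction or zero comparable columns flags the
    result as a poor alignment.
    """
    N = S = Nd = Sd = 0.0
    n_cols = 0
    flags: set[str] = set()
    for codon_a, codon_b in alignment.columns():
        if codon_a == GAP_CODON or codon_b == GAP_CODON:
            continue
        if CODON_TO_AA.get(codon_a, "*") == "*" or CODON_TO_AA.get(codon_b, "*") == "*":
            continue
        n_cols += 1
        n1, s1 = ng86_site_counts(codon_a)
        n2, s2 = ng86_site_counts(codon_b)
        N += (n1 + n2) / 2.0
        S += (s1 + s2) / 2.0
        nd, sd, forced = _pathway_counts(codon_a, codon_b)
        Nd += nd
        Sd += sd
        if forced:
            flags.add(STOP_PATHWAYS_USED)
    result = DnDsResult(N=N, S=S, Nd=Nd, Sd=Sd, n_columns=n_cols, flags=flags)
    if n_cols == 0:
        result.flags.add(POOR_ALIGNMENT)
        return result
    result.pN = Nd / N if N > 0 else 0.0
    result.pS = Sd / S if S > 0 else 0.0
    result.dN = _jukes_cantor(result.pN)
    result.dS = _jukes_cantor(result.pS)
    if result.dN is None or result.dS is None:
        result.flags.add(POOR_ALIGNMENT)
    elif result.dS > 0:
        result.ratio = result.dN / result.dS
    return result


def pairwise_dnds(cds_a: str, cds_b: str, pseudogene_row: int | None = None) -> DnDsResult:
    """Convenience: align, optionally strip pseudogene stop columns, estimate."""
    aln = protein_guided_codon_align(cds_a, cds_b)
    if pseudogene_row is not None:
        aln = strip_stop_columns(aln, pseudogene_row)
    return ng86_dnds(aln)


# ---------------------------------------------------------------------------
# background envelope and classification

@dataclass
class BackgroundDistribution:
    """Genome-wide dN/dS percentile envelope for one species pair."""

    species_pair: tuple[str, str]
    ratios: list[float]
    p5: float
    median: float
    p95: float
    n_excluded_poor_alignment: int = 0
    n_excluded_ds_zero: int = 0


def background_percentiles(
    gene_pairs: Iterable[tuple[str, str, str]],
    species_pair: tuple[str, str] = ("a", "b"),
    min_usable: int = 20,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
) -> BackgroundDistribution:
    """Percentile envelope of dN/dS over ortholog pairs.

    ``gene_pairs`` yields (family_id, cds_a, cds_b).  Families with a poor
    alignment or dS == 0 are excluded and counted.  Percentiles use linear
    interpolation between closest order statistics.  Fewer than
    ``min_usable`` usable ratios is an error (percentiles unstable).
    """
    ratios: list[float] = []
    n_poor = 0
    n_ds_zero = 0
    for _family_id, cds_a, cds_b in gene_pairs:
        res = pairwise_dnds(cds_a, cds_b)
        if POOR_ALIGNMENT in res.flags:
            n_poor += 1
        elif res.ratio is None:
            n_ds_zero += 1
        else:
            ratios.append(res.ratio)
    if len(ratios) < min_usable:
        raise ValueError(
            f"only {len(ratios)} usable dN/dS ratios (< {min_usable}); "
            "background percentiles would be unstable"
        )
    p5, median, p95 = (float(v) for v in np.percentile(ratios, list(percentiles)))
    return BackgroundDistribution(
        species_pair=tuple(species_pair),
        ratios=ratios,
        p5=p5,
        median=median,
        p95=p95,
        n_excluded_poor_alignment=n_poor,
        n_excluded_ds_zero=n_ds_zero,
    )


ABOVE_P95 = "above_p95"
WITHIN = "within"
BELOW_P5 = "below_p5"


def classify_candidate(result: DnDsResult, background: BackgroundDistribution) -> str:
    """Place a candidate's ratio relative to the background envelope.

    Strict comparisons against p95/p5; a ratio equal to either bound
    classifies as ``within``.  An undefined ratio refuses classification.
    """
    if result.ratio is None:
        reason = POOR_ALIGNMENT if POOR_ALIGNMENT in result.flags else "ds_zero"
        raise UndefinedRatioError(reason)
    if result.ratio > background.p95:
        return ABOVE_P95
    if result.ratio < background.p5:
        return BELOW_P5
    return WITHIN
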