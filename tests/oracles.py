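"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch against the published
definitions (NG86 counting, affine-gap dynamic programming, union-find
components, double-argmax best hits) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# NG86

def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Exhaustive neighbour enumeration of (n, s) for a sense codon."""
    aa = _aa(codon)
    assert aa != "*"
    syn = 0
    usable = 0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour in STOPS:
                continue
            usable += 1
            if _aa(neighbour) == aa:
                syn += 1
    s = Fraction(3 * syn, usable)
    return float(3 - s), float(s)


def _enumerate_paths(codon_a: str, codon_b: str):
    """All orderings of the differing positions, as (nd, sd, hits_stop)."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]

    def recurse(current: str, remaining: list[int]):
        if not remaining:
            yield 0, 0, False
            return
        for idx, pos in enumerate(remaining):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            step_syn = _aa(nxt) == _aa(current)
            step_stop = nxt in STOPS and nxt != codon_b
            rest = remaining[:idx] + remaining[idx + 1 :]
            for nd, sd, stop in recurse(nxt, rest):
                yield (
                    nd + (0 if step_syn else 1),
                    sd + (1 if step_syn else 0),
                    stop or step_stop,
                )

    return list(recurse(codon_a, diffs))


def oracle_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Nd, Sd) between two sense codons."""
    paths = _enumerate_paths(codon_a, codon_b)
    open_paths = [(nd, sd) for nd, sd, stop in paths if not stop]
    use = open_paths or [(nd, sd) for nd, sd, _ in paths]
    nd = sum(p[0] for p in use) / len(use)
    sd = sum(p[1] for p in use) / len(use)
    return nd, sd


def oracle_dnds(codons_a: list[str], codons_b: list[str]):
    """Full NG86 pipeline over paired sense codons (no gaps, no stops)."""
    N = S = Nd = Sd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        n1, s1 = oracle_site_counts(ca)
        n2, s2 = oracle_site_counts(cb)
        N += (n1 + n2) / 2
        S += (s1 + s2) / 2
        nd, sd = oracle_pair_differences(ca, cb)
        Nd += nd
        Sd += sd

    def jc(p):
        if p >= 0.75:
            return None
        if p <= 0:
            return 0.0
        return -0.75 * math.log(1 - 4 * p / 3)

    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    return {"N": N, "S": S, "Nd": Nd, "Sd": Sd, "dN": jc(pN), "dS": jc(pS)}


# ---------------------------------------------------------------------------
# affine-gap dynamic programming (Gotoh)

NEG = float("-inf")


def gotoh_score(
    a: str,
    b: str,
    substitution,
    gap_open: float,
    gap_extend: float,
    local: bool,
) -> float:
    """Optimal alignment score; a gap of length k costs gap_open + k*gap_extend.

    ``substitution(x, y)`` returns the pairing score.  Local mode returns the
    best local score (>= 0); global mode penalises end gaps.
    """
    m, n = len(a), len(b)
    first_gap = gap_open + gap_extend
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = -(gap_open + gap_extend * i)
        if local:
            M[i][0] = 0.0
    for j in range(1, n + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
        if local:
            M[0][j] = 0.0
    best_local = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            score = diag + substitution(a[i - 1], b[j - 1])
            M[i][j] = max(score, 0.0) if local else score
            X[i][j] = max(
                max(M[i - 1][j], Y[i - 1][j]) - first_gap, X[i - 1][j] - gap_extend
            )
            Y[i][j] = max(
                max(M[i][j - 1], X[i][j - 1]) - first_gap, Y[i][j - 1] - gap_extend
            )
            if local:
                best_local = max(best_local, M[i][j])
    if local:
        return best_local
    return max(M[m][n], X[m][n], Y[m][n])


def nucleotide_sub(match: float = 2.0, mismatch: float = -3.0):
    return lambda x, y: match if x == y else mismatch


def blosum62_sub():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")

    def sub(x, y):
        if x == "*" or y == "*":
            return -4.0
        return float(mat[x, y])

    return sub


# ---------------------------------------------------------------------------
# graph components (union-find)

def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(frozenset(g) for g in groups.values())


# ---------------------------------------------------------------------------
# bidirectional best hits by double argmax

def oracle_bbh(hits_ab, hits_ba):
    """Brute-force BBH: unique best subject per query in both directions."""

    def bests(hits):
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query, []).append(h)
        out = {}
        for q, rows in by_query.items():
            top = max(r.bitscore for r in rows)
            subjects = {r.subject for r in rows if r.bitscore == top}
            if len(subjects) == 1:
                out[q] = next(iter(subjects))
        return out

    ab = bests(hits_ab)
    ba = bests(hits_ba)
    pairs = set()
    for a, b in ab.items():
        if ba.get(b) == a:
            pairs.add((a, b))
    return pairs
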