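"""BBH maps, flanking-gene geometry, synteny windows and pseudogene calls."""

import numpy as np
import pytest

from oracles import oracle_bbh
from perloss import synteny_pseudo as SP
from perloss import synthetic_data as SD
from perloss.io_formats import GeneModel, SimilarityHit
from perloss.similarity import revcomp


def _hit(q, s, score):
    return SimilarityHit(
        query=q, subject=s, bitscore=score, evalue=1e-30, identity_pct=90.0, aln_len=100
    )


class TestBbhMap:
    def test_symmetric_unique_bests_recorded(self):
        ab = [_hit("a|1", "b|1", 100), _hit("a|1", "b|2", 40)]
        ba = [_hit("b|1", "a|1", 95)]
        bbh = SP.compute_bbh_map(ab, ba)
        assert bbh["a|1"] == ("b|1", 100)
        assert bbh["b|1"] == ("a|1", 95)

    def test_non_reciprocal_best_yields_no_bbh(self):
        ab = [_hit("a|1", "b|1", 100)]
        ba = [_hit("b|1", "a|2", 90), _hit("b|1", "a|1", 50)]
        assert SP.compute_bbh_map(ab, ba) == {}

    def test_tied_best_disqualifies(self):
        ab = [_hit("a|1", "b|1", 80), _hit("a|1", "b|2", 80)]
        ba = [_hit("b|1", "a|1", 80)]
        assert SP.compute_bbh_map(ab, ba) == {}

    @pytest.mark.parametrize("case", range(10))
    def test_matches_double_argmax_oracle(self, case):
        rng = np.random.default_rng(700 + case)
        ab, ba = [], []
        for q in range(8):
            for s in range(8):
                if rng.random() < 0.5:
                    ab.append(_hit(f"a|{q}", f"b|{s}", float(rng.integers(10, 90))))
                if rng.random() < 0.5:
                    ba.append(_hit(f"b|{q}", f"a|{s}", float(rng.integers(10, 90))))
        bbh = SP.compute_bbh_map(ab, ba)
        pairs = {(a, b) for a, (b, _) in bbh.items() if a.startswith("a|")}
        assert pairs == oracle_bbh(ab, ba)

    def test_map_is_injective_partial_matching(self, pipeline_result):
        for bbh in pipeline_result.bbh_maps.values():
            partners = [p for p, _ in bbh.values()]
            assert len(partners) == len(set(partners))
            for gene, (partner, _) in bbh.items():
                assert bbh[partner][0] == gene


def _gene(gid, contig, start, end, strand="+", species="sp", cds="", protein=""):
    return GeneModel(
        gene_id=gid, species=species, contig=contig, start=start, end=end,
        strand=strand, cds=cds, protein=protein,
    )


ANNOT = [
    _gene("g1", "c1", 0, 100),
    _gene("g2", "c1", 200, 300),
    _gene("g3", "c1", 400, 500),
    _gene("g4", "c2", 0, 100),
]


class TestFlankingGenes:
    def test_middle_gene_has_both_neighbours(self):
        left, right = SP.flanking_genes("g2", ANNOT)
        assert (left.gene_id, right.gene_id) == ("g1", "g3")

    def test_contig_edges(self):
        left, right = SP.flanking_genes("g1", ANNOT)
        assert left is None and right.gene_id == "g2"
        left, right = SP.flanking_genes("g4", ANNOT)
        assert left is None and right is None

    def test_input_order_irrelevant(self):
        shuffled = [ANNOT[2], ANNOT[0], ANNOT[3], ANNOT[1]]
        assert SP.flanking_genes("g2", shuffled) == SP.flanking_genes("g2", ANNOT)

    def test_missing_target_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            SP.flanking_genes("nope", ANNOT)


class TestSyntenicWindow:
    PER = [
        _gene("pL", "pc1", 0, 1000, species="per"),
        _gene("target", "pc1", 2000, 3000, species="per"),
        _gene("pR", "pc1", 4000, 5000, species="per"),
    ]
    ANN = [
        _gene("aL", "ac1", 5000, 6000, species="ann"),
        _gene("aR", "ac1", 16_000, 17_000, species="ann"),
    ]
    GENOME = {"ac1": "A" * 60_000}

    def target(self):
        return self.PER[1]

    def test_between_bbh_window_is_strictly_between(self):
        bbh = {"per|pL": ("ann|aL", 100.0), "per|pR": ("ann|aR", 100.0)}
        (win,) = SP.syntenic_window(self.target(), self.PER, self.ANN, self.GENOME, bbh)
        assert win.basis == SP.BASIS_BETWEEN_BBH
        assert (win.start, win.end) == (6000, 16_000)  # excludes the flanks

    def test_single_left_bbh_gives_40kb_to_the_right(self):
        bbh = {"per|pL": ("ann|aL", 100.0)}
        (win,) = SP.syntenic_window(self.target(), self.PER, self.ANN, self.GENOME, bbh)
        assert win.basis == SP.BASIS_SINGLE_BBH_40KB
        assert (win.start, win.end) == (6000, 46_000)
        assert win.length == 40_000

    def test_single_bbh_window_clipped_at_contig_edge(self):
        genome = {"ac1": "A" * 20_000}
        bbh = {"per|pL": ("ann|aL", 100.0)}
        (win,) = SP.syntenic_window(self.target(), self.PER, self.ANN, genome, bbh)
        assert win.length == min(40_000, 20_000 - 6000)

    def test_inverted_anchor_flips_the_search_side(self):
        annot = [_gene("aL", "ac1", 50_000, 51_000, species="ann", strand="-")]
        bbh = {"per|pL": ("ann|aL", 100.0)}
        (win,) = SP.syntenic_window(self.target(), self.PER, annot, self.GENOME, bbh)
        # lost gene is right of pL in the perennial; the anchor is inverted,
        # so the remains are expected LEFT of aL in the annual
        assert (win.start, win.end) == (10_000, 50_000)

    def test_no_bbh_searches_whole_genome(self):
        genome = {"ac1": "A" * 9000, "ac2": "C" * 7000}
        wins = SP.syntenic_window(self.target(), self.PER, self.ANN, genome, {})
        assert [w.basis for w in wins] == [SP.BASIS_WHOLE_GENOME] * 2
        assert {(w.contig, w.length) for w in wins} == {("ac1", 9000), ("ac2", 7000)}

    def test_bbhs_on_different_contigs_fall_back_to_better_flank(self):
        annot = [
            _gene("aL", "ac1", 5000, 6000, species="ann"),
            _gene("aR", "ac2", 1000, 2000, species="ann"),
        ]
        genome = {"ac1": "A" * 60_000, "ac2": "C" * 60_000}
        bbh = {"per|pL": ("ann|aL", 120.0), "per|pR": ("ann|aR", 80.0)}
        (win,) = SP.syntenic_window(self.target(), self.PER, annot, genome, bbh)
        assert win.basis == SP.BASIS_SINGLE_BBH_40KB
        assert win.anchor_genes == ("aL",)
        assert "different contigs" in win.note


def random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


class TestScanWindow:
    def test_exact_copy_found_at_full_identity(self):
        rng = np.random.default_rng(70)
        gene = random_dna(300, rng)
        contig = random_dna(3000, rng) + gene + random_dna(3000, rng)
        window = SP.SyntenyWindow("sp", "c1", 1000, 6000, SP.BASIS_BETWEEN_BBH)
        (locus,) = SP.scan_window(window, gene, {"c1": contig})
        assert (locus.start, locus.end) == (3000, 3300)
        assert locus.identity_pct == 100.0

    def test_random_window_yields_nothing(self):
        rng = np.random.default_rng(71)
        window = SP.SyntenyWindow("sp", "c1", 0, 5000, SP.BASIS_BETWEEN_BBH)
        assert SP.scan_window(window, random_dna(300, rng), {"c1": random_dna(5000, rng)}) == []

    def test_reverse_complement_found_on_minus_strand(self):
        rng = np.random.default_rng(72)
        gene = random_dna(300, rng)
        contig = random_dna(2000, rng) + revcomp(gene) + random_dna(2000, rng)
        window = SP.SyntenyWindow("sp", "c1", 0, len(contig), SP.BASIS_BETWEEN_BBH)
        (locus,) = SP.scan_window(window, gene, {"c1": contig})
        assert (locus.start, locus.end, locus.strand) == (2000, 2300, "-")


class TestCallPseudogene:
    def test_planted_premature_stop_detected(self):
        cds = SD.random_cds(150, np.random.default_rng(73))
        degraded = SD.plant_pseudogenization(cds, "premature_stop", 0.2, 0.05, 99)
        call = SP.call_pseudogene(degraded, cds)
        assert call.verdict == SP.VERDICT_PSEUDOGENE
        assert len(call.premature_stops) >= 1

    def test_intact_copy_is_a_real_gene(self):
        cds = SD.random_cds(150, np.random.default_rng(74))
        evolved = SD.evolve_cds(cds, 0.05, 0.15, 100)
        call = SP.call_pseudogene(evolved, cds)
        assert call.verdict == SP.VERDICT_REAL_GENE
        assert call.aligned_fraction >= 0.9
        assert call.n_lesions == 0

    def test_planted_frameshift_located_within_two_codons(self):
        rng = np.random.default_rng(75)
        cds = SD.random_cds(150, rng)
        pos = 200  # delete one base at a known position
        degraded = cds[:pos] + cds[pos + 1 :]
        call = SP.call_pseudogene(degraded, cds)
        assert call.verdict == SP.VERDICT_PSEUDOGENE
        assert len(call.frameshifts) >= 1
        assert min(abs(p - pos) for p in call.frameshifts) <= 6

    def test_short_locus_is_not_found(self):
        cds = SD.random_cds(100, np.random.default_rng(76))
        assert SP.call_pseudogene("ACGTACGT", cds).verdict == SP.VERDICT_NOT_FOUND
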