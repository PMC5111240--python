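"""NG86 counting vs brute-force enumeration, codon alignments, backgrounds."""

import numpy as np
import pytest
from scipy import stats

from oracles import blosum62_sub, gotoh_score, oracle_dnds, oracle_site_counts
from perloss import molevol as M
from perloss import synthetic_data as SD


def random_sense_codons(n, rng):
    idx = rng.integers(len(M.SENSE_CODONS), size=n)
    return [M.SENSE_CODONS[i] for i in idx]


class TestSiteCounts:
    def test_phenylalanine_example(self):
        n, s = M.ng86_site_counts("TTT")
        assert s == pytest.approx(1.0 / 3.0)
        assert n == pytest.approx(8.0 / 3.0)

    def test_tryptophan_has_no_synonymous_sites(self):
        n, s = M.ng86_site_counts("TGG")
        assert s == 0.0
        assert n == 3.0

    def test_all_sense_codons_match_enumeration_and_normalise(self):
        for codon in M.SENSE_CODONS:
            n, s = M.ng86_site_counts(codon)
            assert (n, s) == oracle_site_counts(codon)
            assert n + s == pytest.approx(3.0)

    def test_stop_and_invalid_codons_rejected(self):
        with pytest.raises(ValueError):
            M.ng86_site_counts("TAA")
        with pytest.raises(ValueError):
            M.ng86_site_counts("AXT")


class TestCodonAlignment:
    def test_identical_cds_align_without_gaps(self):
        cds = "ATGTTTAAACCCGGG"
        aln = M.protein_guided_codon_align(cds, cds)
        assert M.GAP_CODON not in aln.codons_a + aln.codons_b
        assert aln.degapped(0) == aln.degapped(1) == cds

    def test_single_codon_deletion_gives_one_codon_gap(self):
        cds_a = "ATGTTTAAACCCGGG"
        cds_b = "ATGTTTCCCGGG"  # AAA removed
        aln = M.protein_guided_codon_align(cds_a, cds_b)
        assert aln.codons_b.count(M.GAP_CODON) == 1
        assert aln.codons_a.count(M.GAP_CODON) == 0
        assert aln.degapped(1) == cds_b

    @pytest.mark.parametrize("case", range(10))
    def test_protein_alignment_score_matches_global_dp_oracle(self, case):
        rng = np.random.default_rng(800 + case)
        a = "".join(random_sense_codons(int(rng.integers(10, 31)), rng))
        b = "".join(random_sense_codons(int(rng.integers(10, 31)), rng))
        prot_a, prot_b = M.translate_cds(a), M.translate_cds(b)
        from perloss.similarity import PROTEIN, _aligner

        score = _aligner(PROTEIN, "global").score(prot_a, prot_b)
        expected = gotoh_score(
            prot_a, prot_b, blosum62_sub(), gap_open=11, gap_extend=1, local=False
        )
        assert score == pytest.approx(expected)

    def test_empty_translation_rejected(self):
        with pytest.raises(ValueError):
            M.protein_guided_codon_align("AT", "ATGTTT")


class TestStripStopColumns:
    def test_stop_column_removed(self):
        aln = M.CodonAlignment(("ATG", "TTT", "CCC"), ("ATG", "TAA", "CCC"))
        stripped = M.strip_stop_columns(aln, pseudogene_row=1)
        assert stripped.codons_b == ("ATG", "CCC")
        assert stripped.codons_a == ("ATG", "CCC")

    def test_no_stops_is_identity(self):
        aln = M.CodonAlignment(("ATG", "TTT"), ("ATG", "TTC"))
        assert M.strip_stop_columns(aln) == aln

    def test_column_count_drops_by_number_of_stops(self):
        rng = np.random.default_rng(9)
        codons = random_sense_codons(30, rng)
        pseudo = list(codons)
        for pos in (3, 11, 25):
            pseudo[pos] = "TGA"
        aln = M.CodonAlignment(tuple(codons), tuple(pseudo))
        stripped = M.strip_stop_columns(aln, pseudogene_row=1)
        n_stops = sum(1 for c in pseudo if c in M.STOP_CODONS)
        assert stripped.n_columns == aln.n_columns - n_stops == 27
        assert all(c not in M.STOP_CODONS for c in stripped.codons_b)


class TestNg86DnDs:
    def test_identical_sequences_have_undefined_ratio(self):
        cds = "".join(random_sense_codons(50, np.random.default_rng(10)))
        res = M.ng86_dnds(M.protein_guided_codon_align(cds, cds))
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.ratio is None  # dS == 0 rule

    def test_single_synonymous_difference(self):
        rng = np.random.default_rng(12)
        codons = random_sense_codons(20, rng)
        codons[7] = "TTA"
        other = list(codons)
        other[7] = "TTG"  # Leu -> Leu, one synonymous change
        res = M.ng86_dnds(M.CodonAlignment(tuple(codons), tuple(other)))
        assert res.Nd == 0.0
        assert res.Sd == 1.0
        assert res.dN == 0.0
        assert res.dS > 0.0

    @pytest.mark.parametrize("case", range(25))
    def test_matches_pathway_enumeration_oracle(self, case):
        rng = np.random.default_rng(2000 + case)
        n = int(rng.integers(5, 31))
        anc = "".join(random_sense_codons(n, rng))
        der = SD.evolve_cds(anc, float(rng.uniform(0.0, 0.4)), 1.0, 2100 + case)
        codons_a = [anc[i : i + 3] for i in range(0, len(anc), 3)]
        codons_b = [der[i : i + 3] for i in range(0, len(der), 3)]
        keep = [
            (a, b)
            for a, b in zip(codons_a, codons_b)
            if a not in M.STOP_CODONS and b not in M.STOP_CODONS
        ]
        res = M.ng86_dnds(
            M.CodonAlignment(tuple(a for a, _ in keep), tuple(b for _, b in keep))
        )
        exp = oracle_dnds([a for a, _ in keep], [b for _, b in keep])
        for key in ("N", "S", "Nd", "Sd"):
            assert abs(getattr(res, key) - exp[key]) < 1e-9

    def test_symmetric_in_inputs(self):
        rng = np.random.default_rng(13)
        anc = "".join(random_sense_codons(40, rng))
        der = SD.evolve_cds(anc, 0.15, 1.0, 77)
        aln = M.protein_guided_codon_align(anc, der)
        rev = M.CodonAlignment(aln.codons_b, aln.codons_a)
        a, b = M.ng86_dnds(aln), M.ng86_dnds(rev)
        assert (a.N, a.S, a.Nd, a.Sd) == (b.N, b.S, b.Nd, b.Sd)

    def test_ds_increases_with_branch_length(self):
        rng = np.random.default_rng(14)
        anc = "".join(random_sense_codons(200, rng))
        rates = [0.01, 0.03, 0.06, 0.1, 0.15, 0.25]
        ds = []
        for i, rate in enumerate(rates):
            vals = []
            for rep in range(10):
                der = SD.evolve_cds(anc, rate, 0.15, 3000 + 50 * i + rep)
                res = M.ng86_dnds(M.protein_guided_codon_align(anc, der))
                vals.append(res.dS)
            ds.append(np.mean(vals))
        rho, _ = stats.spearmanr(rates, ds)
        assert rho > 0.9


class TestBackground:
    def test_percentiles_by_linear_interpolation(self):
        pairs_ratio = [i / 100 for i in range(101)]
        bg = M.BackgroundDistribution(("a", "b"), pairs_ratio, 0, 0, 0)
        p5, med, p95 = np.percentile(pairs_ratio, [5, 50, 95])
        assert (p5, med, p95) == (0.05, 0.50, 0.95)

    def test_background_from_gene_pairs(self):
        pairs = SD.simulate_ortholog_pairs(40, 0.05, 0.15, seed=21, n_codons=(80, 120))
        bg = M.background_percentiles(pairs, ("a", "b"))
        assert bg.p5 <= bg.median <= bg.p95
        assert len(bg.ratios) + bg.n_excluded_poor_alignment + bg.n_excluded_ds_zero == 40

    def test_constant_ratios_collapse_the_envelope(self):
        bg = M.BackgroundDistribution(("a", "b"), [0.2] * 50, 0.2, 0.2, 0.2)
        assert bg.p5 == bg.median == bg.p95 == 0.2

    def test_too_few_usable_ratios_refused(self):
        pairs = SD.simulate_ortholog_pairs(5, 0.05, 0.15, seed=22)
        with pytest.raises(ValueError, match="unstable"):
            M.background_percentiles(pairs, ("a", "b"))


class TestClassification:
    BG = M.BackgroundDistribution(("a", "b"), [0.1, 0.8], p5=0.1, median=0.4, p95=0.8)

    def test_above_p95(self):
        res = M.DnDsResult(ratio=1.2, dS=0.3, dN=0.36)
        assert M.classify_candidate(res, self.BG) == M.ABOVE_P95

    def test_tie_with_p95_is_within(self):
        res = M.DnDsResult(ratio=0.8, dS=0.3, dN=0.24)
        assert M.classify_candidate(res, self.BG) == M.WITHIN

    def test_below_p5(self):
        res = M.DnDsResult(ratio=0.05, dS=0.3, dN=0.015)
        assert M.classify_candidate(res, self.BG) == M.BELOW_P5

    def test_undefined_ratio_refused_with_reason(self):
        res = M.DnDsResult(ratio=None, dS=0.0, dN=0.1)
        with pytest.raises(M.UndefinedRatioError) as err:
            M.classify_candidate(res, self.BG)
        assert err.value.reason == "ds_zero"
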