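"""Phyletic decomposition, strict/relaxed screens and elimination filters."""

import numpy as np
import pytest

from perloss import loss_screen as LS
from perloss import synthetic_data as SD
from perloss.family_builder import GeneFamily
from perloss.io_formats import GeneModel, SimilarityHit, SpeciesProfile
from perloss.molevol import translate_cds
from perloss.similarity import GenomeSearcher

PROFILES = [
    SpeciesProfile("ann1", "annual", "genome", "p1"),
    SpeciesProfile("per1", "perennial", "genome", "p1"),
    SpeciesProfile("ann2", "annual", "transcriptome", "p2"),
    SpeciesProfile("per2", "perennial", "transcriptome", "p2"),
]


def fam(fid, present):
    return GeneFamily(family_id=fid, members={sp: {f"{fid}.{sp}"} for sp in present})


class TestVennDecompose:
    def test_single_absence_pattern(self):
        families = [fam("f1", ["per1", "per2", "ann2"])]  # missing ann1 only
        counts = LS.venn_decompose(families, ["ann1", "ann2"], mode="absence")
        assert counts == {frozenset({"ann1"}): 1}

    def test_counts_partition_qualifying_families(self):
        rng = np.random.default_rng(60)
        species = ["a", "b", "c", "d"]
        families = []
        for i in range(100):
            present = [s for s in species if rng.random() < 0.6]
            families.append(fam(f"f{i}", present))
        counts = LS.venn_decompose(families, species, mode="absence")
        qualifying = sum(
            1 for f in families if any(not f.present_in(s) for s in species)
        )
        assert sum(counts.values()) == qualifying

    def test_matches_per_family_brute_force(self):
        rng = np.random.default_rng(61)
        species = ["a", "b", "c", "d"]
        families = [
            fam(f"f{i}", [s for s in species if rng.random() < 0.5]) for i in range(100)
        ]
        counts = LS.venn_decompose(families, species, mode="presence")
        expected: dict[frozenset, int] = {}
        for f in families:
            pattern = frozenset(s for s in species if f.present_in(s))
            if pattern:
                expected[pattern] = expected.get(pattern, 0) + 1
        assert counts == expected


class TestPhyleticScreens:
    def test_strict_requires_all_perennials_no_annuals(self):
        keep = fam("keep", ["per1", "per2"])
        missing_perennial = fam("m1", ["per1"])
        has_annual = fam("m2", ["per1", "per2", "ann1"])
        result = LS.screen_strict([keep, missing_perennial, has_annual], PROFILES)
        assert [f.family_id for f in result] == ["keep"]

    def test_relaxed_waives_transcriptome_perennials(self):
        relaxed_only = fam("r", ["per1"])  # per2 is transcriptome-level
        assert LS.screen_relaxed([relaxed_only], PROFILES) == [relaxed_only]
        assert LS.screen_strict([relaxed_only], PROFILES) == []

    def test_strict_subset_of_relaxed(self):
        rng = np.random.default_rng(62)
        names = [p.name for p in PROFILES]
        families = [
            fam(f"f{i}", [s for s in names if rng.random() < 0.5]) for i in range(60)
        ]
        strict = set(f.family_id for f in LS.screen_strict(families, PROFILES))
        relaxed = set(f.family_id for f in LS.screen_relaxed(families, PROFILES))
        assert strict <= relaxed

    def test_genome_level_optional_perennial_warns(self):
        with pytest.warns(UserWarning, match="genome-level"):
            LS.screen_relaxed([], PROFILES, optional_perennials=["per1"])


def _hit(q, s, evalue):
    return SimilarityHit(
        query=q, subject=s, bitscore=50.0, evalue=evalue, identity_pct=90.0, aln_len=50
    )


class TestCompletenessFilter:
    FAMILY = GeneFamily("f", {"per1": {"x"}, "per2": {"y"}})

    def run(self, e_annual, e_perennial):
        hits = [
            _hit("per2|y", "per1|x", e_perennial),
            _hit("per2|y", "ann2|t1", e_annual),
        ]
        return LS.completeness_filter(
            self.FAMILY, hits,
            reference_perennial="per2", genome_perennial="per1",
            transcriptome_annuals=["ann2"],
        )

    def test_two_orders_better_eliminates(self):
        decision = self.run(1e-52, 1e-50)
        assert decision.verdict == LS.VERDICT_ELIMINATED
        assert decision.reason == LS.REASON_COMPLETENESS

    def test_equal_evalues_retain(self):
        assert self.run(1e-50, 1e-50).verdict == LS.VERDICT_RETAINED

    def test_exactly_one_order_eliminates(self):
        assert self.run(1e-51, 1e-50).verdict == LS.VERDICT_ELIMINATED

    def test_floored_evalues_compare_equal(self):
        assert self.run(1e-300, 1e-200).verdict == LS.VERDICT_RETAINED

    def test_missing_perennial_hit_retains_with_warning_note(self):
        decision = LS.completeness_filter(
            self.FAMILY, [], "per2", "per1", ["ann2"]
        )
        assert decision.verdict == LS.VERDICT_RETAINED
        assert "not evaluable" in decision.evidence


class TestAnnotationExclusion:
    def test_transposon_keyword_eliminates(self):
        family = fam("f", ["per1"])
        keywords = {"per1|f.per1": {"retrotransposon gag-pol polyprotein"}}
        decision = LS.annotation_exclusion(family, keywords)
        assert decision.verdict == LS.VERDICT_ELIMINATED
        assert decision.reason == LS.REASON_TRANSPOSON

    def test_no_keywords_retains(self):
        decision = LS.annotation_exclusion(fam("f", ["per1"]), {})
        assert decision.verdict == LS.VERDICT_RETAINED

    def test_any_member_with_ribosomal_keyword_eliminates(self):
        family = GeneFamily("f", {"per1": {"a", "b"}})
        keywords = {"per1|b": {"60S ribosomal protein L10"}}
        decision = LS.annotation_exclusion(family, keywords)
        assert decision.verdict == LS.VERDICT_ELIMINATED
        assert decision.reason == LS.REASON_RIBOSOMAL


class TestMisannotationCheck:
    def _setup(self, lesion=None):
        rng = np.random.default_rng(63)
        cds = SD.random_cds(120, rng)
        copy = cds
        if lesion == "stop":
            mid = (len(cds) // 2) // 3 * 3
            copy = cds[:mid] + "TAA" + cds[mid + 3 :]
        spacer = SD.random_cds(400, rng)
        genome = {"c1": spacer + copy + spacer}
        model = GeneModel(
            gene_id="x", species="per1", cds=cds, protein=translate_cds(cds)
        )
        family = GeneFamily("f", {"per1": {"x"}})
        return family, {"per1|x": model}, {"ann1": GenomeSearcher(genome)}

    def test_exact_full_copy_in_annual_genome_eliminates(self):
        family, models, searchers = self._setup()
        decision = LS.misannotation_check(family, models, searchers)
        assert decision.verdict == LS.VERDICT_ELIMINATED
        assert decision.reason == LS.REASON_MISANNOT_COMPLETE

    def test_copy_with_internal_stop_is_not_a_misannotation(self):
        family, models, searchers = self._setup(lesion="stop")
        decision = LS.misannotation_check(family, models, searchers)
        assert decision.verdict == LS.VERDICT_RETAINED

    def test_wrong_frame_protein_eliminates(self):
        rng = np.random.default_rng(64)
        cds = SD.random_cds(100, rng)
        model = GeneModel(
            gene_id="x", species="per1", cds=cds,
            protein=translate_cds(cds[1:]) + "WWWW",  # matches no frame
        )
        family = GeneFamily("f", {"per1": {"x"}})
        decision = LS.misannotation_check(family, {"per1|x": model}, {})
        assert decision.verdict == LS.VERDICT_ELIMINATED
        assert decision.reason == LS.REASON_MISANNOT_FRAME


class TestFunnelOnSimulatedClade:
    def test_monotone_telescoping_and_single_reason(self, pipeline_result):
        rows = pipeline_result.funnel.rows
        for row in rows:
            assert row.n_out <= row.n_in
        for prev, nxt in zip(rows[1:], rows[2:]):
            assert prev.n_out == nxt.n_in
        for family_id, decision in pipeline_result.funnel.decisions.items():
            if decision.verdict == LS.VERDICT_ELIMINATED:
                assert decision.reason is not None

    def test_reason_histogram_sums_to_eliminated(self, pipeline_result):
        rows = pipeline_result.funnel.rows[1:]
        for row in rows:
            assert sum(row.reasons.values()) == row.n_in - row.n_out

    def test_no_retained_family_has_a_real_gene_fate(self, clade, pipeline_result):
        """Misannotation screening removes families intact in an annual genome."""
        truth = clade.truth_by_family()
        real_fate_families = {
            t.family_id
            for t in clade.truth
            if any(f == SD.FATE_REAL for f in t.fates.values())
        }
        assert real_fate_families  # fixture plants some
        retained_truth_ids = {
            sorted(
                {g for sp in f.members for g in f.members[sp]}
            )[0]
            for f in pipeline_result.funnel.retained
        }
        assert retained_truth_ids.isdisjoint(real_fate_families)
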