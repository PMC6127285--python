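"""Causality grading, genotype models and the stepwise family search."""

import random

import pytest

import secondhit as sh
from secondhit.cnv import CnvCall
from secondhit.prioritize import assess_causality, check_genotype_model
from secondhit.variants import VariantRecord


def result_for(results, family_id):
    return next(r for r in results if r.family_id == family_id)


class TestAssessCausality:
    def test_known_pathogenic_presumed_causal_without_relatives(
        self, cohort, gene_map
    ):
        # presumption rule: phenotype-consistent database-pathogenic allele
        # is accepted when no relatives are available
        fam = cohort.family("J")
        m15 = next(v for v in fam.candidates if v.variant_id == "M15")
        a = assess_causality(m15, fam, gene_map=gene_map)
        assert a.segregates == "NA"
        assert a.classification == "causal"

    def test_novel_frameshift_with_segregation_is_causal(self, cohort, gene_map):
        fam = cohort.family("H")
        m13 = next(v for v in fam.candidates if v.variant_id == "M13")
        a = assess_causality(m13, fam, gene_map=gene_map)
        assert a.novel_with_damaging_prediction
        assert a.classification == "causal"

    def test_in_cis_deep_intronic_excluded(self, cohort, gene_map):
        fam = cohort.family("X")
        m36 = next(v for v in fam.candidates if v.variant_id == "m36")
        a = assess_causality(m36, fam, gene_map=gene_map)
        assert a.segregates == "no"
        assert a.classification == "excluded"

    def test_deep_intronic_without_segregation_capped_at_candidate(
        self, cohort, gene_map
    ):
        fam = cohort.family("S")
        m39 = next(v for v in fam.candidates if v.variant_id == "m39")
        a = assess_causality(m39, fam, gene_map=gene_map)
        assert a.splice_flagged
        assert a.classification == "candidate"

    def test_phenotype_inconsistent_gene_excluded(self, cohort, gene_map):
        fam = cohort.family("B")  # cone dystrophy
        variant = VariantRecord(gene="MYO7A", hgvs_c="c.1A > T",
                                db_label="pathogenic")
        a = assess_causality(variant, fam, gene_map=gene_map)
        assert not a.phenotype_consistent
        assert a.classification == "excluded"


class TestGenotypeModel:
    def make(self, zygosity, classification, cohort, gene_map, seg="unavailable"):
        fam = cohort.family("E")
        v = VariantRecord(gene="USH2A", hgvs_c="c.1A > T", zygosity=zygosity,
                          db_label="pathogenic" if classification == "causal"
                          else "absent", segregation=seg)
        return assess_causality(v, fam, gene_map=gene_map)

    def test_one_homozygous_causal_completes(self, cohort, gene_map):
        a = self.make("hom", "causal", cohort, gene_map)
        assert check_genotype_model([a], "recessive") == "completed"

    def test_two_het_causal_complete_with_phase_flag(self, cohort, gene_map):
        a = self.make("het", "causal", cohort, gene_map)
        b = self.make("het", "causal", cohort, gene_map)
        b.variant.hgvs_c = "c.2A > T"
        assert check_genotype_model([a, b], "recessive") == "completed"

    def test_single_het_in_recessive_gene_is_incomplete(self, cohort, gene_map):
        # the cohort's defining monoallelic state
        a = self.make("het", "causal", cohort, gene_map)
        assert check_genotype_model([a], "recessive") == "incomplete"

    def test_empty_allele_list_incomplete(self):
        assert check_genotype_model([], "recessive") == "incomplete"

    def test_dominant_needs_confirmed_segregation(self, cohort, gene_map):
        unseg = self.make("het", "causal", cohort, gene_map)
        assert check_genotype_model([unseg], "dominant") == "incomplete"
        seg = self.make("het", "causal", cohort, gene_map, seg="consistent")
        assert check_genotype_model([seg], "dominant") == "completed"


class TestPrioritizeFamilies:
    def test_family_E_solved_compound_het(self, cohort_results):
        r = result_for(cohort_results, "E")
        assert r.status == "solved"
        assert r.causal_gene == "USH2A"
        assert sorted(r.allele_ids()) == ["M8", "M9"]
        assert any("second hit" in n for n in r.notes)

    def test_family_B_solved_at_different_locus(self, cohort_results):
        # prior ABCA4 variant is MAF-rejected; a homozygous CNGB3
        # frameshift explains the cone-dystrophy phenotype instead
        r = result_for(cohort_results, "B")
        assert r.status == "solved"
        assert r.causal_gene == "CNGB3"
        assert r.allele_ids() == ["M3"]
        assert any("different locus" in n for n in r.notes)

    def test_family_S_is_candidate_not_solved(self, cohort_results):
        r = result_for(cohort_results, "S")
        assert r.status == "candidate"
        assert r.causal_gene == "USH2A"

    def test_family_C_dominant_gene_unconfirmed(self, cohort_results):
        r = result_for(cohort_results, "C")
        assert r.status == "candidate"
        assert r.causal_gene == "FSCN2"

    def test_excluded_alleles_never_causal(self, cohort_results):
        for r in cohort_results:
            for a in r.causal_alleles:
                assert a.classification != "excluded"

    def test_unphased_compound_hets_flagged(self, cohort_results):
        r = result_for(cohort_results, "E")  # no relatives available
        assert any("phase unconfirmed" in n for n in r.notes)

    def test_determinism(self, cohort):
        first = {r.family_id: r.status for r in sh.run_cohort(cohort)}
        second = {r.family_id: r.status for r in sh.run_cohort(cohort)}
        assert first == second

    def test_candidate_order_permutation_invariance(self, cohort, gene_map):
        rng = random.Random(5)
        for fam in cohort.families:
            base = sh.prioritize_family(
                sh.screen_family(fam), gene_map=gene_map
            )
            shuffled_candidates = list(fam.candidates)
            rng.shuffle(shuffled_candidates)
            shuffled = fam.model_copy(update={"candidates": shuffled_candidates})
            other = sh.prioritize_family(
                sh.screen_family(shuffled), gene_map=gene_map
            )
            assert other.status == base.status
            assert other.causal_gene == base.causal_gene
            assert sorted(other.allele_ids()) == sorted(base.allele_ids())

    def test_removing_prior_variant_never_solves_unsolved(self, cohort, gene_map):
        # the fallback search is a superset of the prior-gene search
        for fam in cohort.families:
            base = sh.prioritize_family(sh.screen_family(fam), gene_map=gene_map)
            if base.status != "unsolved" or not fam.prior_variant_ids:
                continue
            stripped = fam.model_copy(update={
                "candidates": [
                    v for v in fam.candidates
                    if v.variant_id not in fam.prior_variant_ids
                ],
            })
            r = sh.prioritize_family(sh.screen_family(stripped), gene_map=gene_map)
            assert r.status == "unsolved"

    def test_cnv_call_supplied_as_extra_allele(self, cohort, gene_map):
        # a family-R-like case where the CNV arrives from the caller
        fam = cohort.family("R").model_copy(update={"candidates": []})
        call = CnvCall(
            sample="R-II:6", chrom="chr1", start=215_949_321, end=216_272_841,
            first_interval=10, last_interval=300, direction="deletion",
            mean_ratio=0.01, zygosity="homozygous", n_intervals=290,
            gene="USH2A",
            refined_breakpoints=(215_949_321, 216_272_841),
        )
        r = sh.prioritize_family(fam, cnv_calls=[call], gene_map=gene_map)
        assert r.status == "solved"
        assert r.causal_gene == "USH2A"
        assert r.causal_alleles[0].variant.consequence == "cnv-deletion"
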