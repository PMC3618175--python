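"""Six-class genotype classifier, backcross screen and mtDNA assignment."""

import zlib

import numpy as np
import pytest

from nightsong.hybrid_genetics import (
    HYBRID_CLASSES,
    REFERENCE_LOCI,
    GenotypeRecord,
    LocusSpec,
    assign_maternal_lineage,
    backcross_het_expectation,
    genotype_class_freqs,
    map_distance_cm,
    posterior_hybrid_class,
    prob_all_homozygous,
    read_genotypes_tsv,
    read_loci_tsv,
    write_genotypes_tsv,
    write_loci_tsv,
)
from nightsong.synthetic_data import PedigreeSpec, simulate_genotypes

DIAGNOSTIC = [l for l in REFERENCE_LOCI if l.is_diagnostic]
LU10 = next(l for l in REFERENCE_LOCI if l.name == "Lu10")


class TestClassFrequencies:
    def test_f1_heterozygote_certain_at_diagnostic_locus(self):
        lu03 = next(l for l in REFERENCE_LOCI if l.name == "Lu03")
        table = genotype_class_freqs("F1", lu03)
        assert table[("C", "T")] == pytest.approx(1.0)

    def test_f2_segregation_at_diagnostic_locus(self):
        lu03 = next(l for l in REFERENCE_LOCI if l.name == "Lu03")
        table = genotype_class_freqs("F2", lu03)
        assert table[("T", "T")] == pytest.approx(0.25)   # LM homozygote
        assert table[("C", "T")] == pytest.approx(0.5)
        assert table[("C", "C")] == pytest.approx(0.25)

    def test_pure_lm_hardy_weinberg_at_partial_locus(self):
        # Lu10: T 80% / C 20% in LM -> HW expansion
        table = genotype_class_freqs("PureLM", LU10)
        assert table[("T", "T")] == pytest.approx(0.64)
        assert table[("C", "T")] == pytest.approx(0.32)
        assert table[("C", "C")] == pytest.approx(0.04)

    @pytest.mark.parametrize("cls", HYBRID_CLASSES)
    @pytest.mark.parametrize("sex", ["male_ZZ", "female_ZW"])
    def test_tables_sum_to_one(self, cls, sex):
        for locus in REFERENCE_LOCI:
            table = genotype_class_freqs(cls, locus, sex)
            assert sum(table.values()) == pytest.approx(1.0)

    def test_female_z_locus_single_copy(self):
        adamts6 = next(l for l in REFERENCE_LOCI if l.name == "ADAMTS6")
        table = genotype_class_freqs("PureLL", adamts6, "female_ZW")
        assert set(table) == {("T",), ("C",)}
        assert table[("C",)] == pytest.approx(1.0)


class TestPosterior:
    def test_all_het_five_diagnostic_loci_closed_form(self):
        # per-locus likelihoods for a heterozygote at a fixed-difference
        # locus: F1 -> 1, F2/BC1 -> 0.5, pures -> 0; over 5 loci the F1
        # posterior is 1 / (1 + 3 * 0.5**5)
        rec = GenotypeRecord(
            "het5", "male_ZZ",
            {l.name: tuple(sorted(l.alleles)) for l in DIAGNOSTIC},
        )
        post = posterior_hybrid_class(rec, DIAGNOSTIC, pseudo_count=0.0)
        expect = 1.0 / (1.0 + 3.0 * 0.5**5)
        assert post.posterior["F1"] == pytest.approx(expect, rel=1e-12)
        # adding the two partially informative loci with F1-consistent
        # genotypes raises the posterior further
        rec7 = GenotypeRecord(
            "het7", "male_ZZ",
            {l.name: tuple(sorted(l.alleles)) for l in REFERENCE_LOCI},
        )
        post7 = posterior_hybrid_class(rec7, REFERENCE_LOCI, pseudo_count=0.0)
        assert post7.posterior["F1"] > post.posterior["F1"]

    def test_homozygous_lm_is_pure_with_certainty_unsmoothed(self):
        calls = {}
        for l in DIAGNOSTIC:
            lm_allele = l.alleles[0] if l.freq_LM[0] == 1.0 else l.alleles[1]
            calls[l.name] = (lm_allele, lm_allele)
        rec = GenotypeRecord("pure", "male_ZZ", calls)
        post = posterior_hybrid_class(rec, DIAGNOSTIC, pseudo_count=0.0)
        # F1 and BC1_LL carry a zero factor, F2/BC1_LM contribute 0.25**5
        # and 0.5**5 against PureLM's 1
        assert post.posterior["F1"] == 0.0
        assert post.posterior["PureLL"] == 0.0
        assert post.posterior["PureLM"] > 0.96
        assert post.modal_class == "PureLM"

    def test_simulated_f1_males_high_posterior(self):
        recs = simulate_genotypes(PedigreeSpec("F1"), REFERENCE_LOCI, n=100, seed=11)
        p = [posterior_hybrid_class(r, REFERENCE_LOCI).posterior["F1"] for r in recs]
        assert float(np.median(p)) > 0.95

    def test_parameter_recovery_within_information_limit(self):
        # the classifier is the exact Bayes rule under the generating model,
        # so recovery is bounded by what seven loci can distinguish: pure
        # species and F1 are fully identifiable; F2 and BC1 overlap in their
        # genotype distributions (an F2 that segregated mostly heterozygous/
        # one-sided looks like a BC1) and only plurality recovery is
        # attainable — with 30 diagnostic loci the same classifier exceeds
        # 95% for every class
        n = 500
        rates = {}
        for cls in HYBRID_CLASSES:
            recs = simulate_genotypes(
                PedigreeSpec(cls), REFERENCE_LOCI, n=n,
                seed=zlib.crc32(cls.encode()) % 2**31,
            )
            modal = [posterior_hybrid_class(r, REFERENCE_LOCI).modal_class
                     for r in recs]
            rates[cls] = sum(m == cls for m in modal) / n
        for cls in ("PureLM", "PureLL", "F1"):
            assert rates[cls] >= 0.95
        for cls in ("F2", "BC1_LM", "BC1_LL"):
            assert rates[cls] > 0.5

    def test_parameter_recovery_with_many_diagnostic_loci(self):
        loci = tuple(
            LocusSpec(f"D{i:02d}", "autosomal", float(i), ("A", "B"),
                      (1.0, 0.0), (0.0, 1.0))
            for i in range(30)
        )
        for cls in HYBRID_CLASSES:
            recs = simulate_genotypes(
                PedigreeSpec(cls), loci, n=200,
                seed=zlib.crc32(cls.encode()) % 2**31,
            )
            rate = np.mean(
                [posterior_hybrid_class(r, loci).modal_class == cls for r in recs]
            )
            assert rate >= 0.95, cls

    def test_label_swap_symmetry(self):
        # swapping the species frequency vectors everywhere permutes the
        # posterior exactly: PureLM<->PureLL, BC1_LM<->BC1_LL
        swapped = [l.swapped_species() for l in REFERENCE_LOCI]
        recs = simulate_genotypes(PedigreeSpec("BC1_LM"), REFERENCE_LOCI, n=20, seed=3)
        for r in recs:
            a = posterior_hybrid_class(r, REFERENCE_LOCI).posterior
            b = posterior_hybrid_class(r, swapped).posterior
            assert a["PureLM"] == pytest.approx(b["PureLL"], abs=1e-12)
            assert a["PureLL"] == pytest.approx(b["PureLM"], abs=1e-12)
            assert a["BC1_LM"] == pytest.approx(b["BC1_LL"], abs=1e-12)
            assert a["F1"] == pytest.approx(b["F1"], abs=1e-12)
            assert a["F2"] == pytest.approx(b["F2"], abs=1e-12)

    def test_missing_loci_skipped_and_all_missing_fails(self):
        rec = GenotypeRecord("x", "male_ZZ", {"Lu03": ("C", "T"), "Lu04": None})
        post = posterior_hybrid_class(rec, REFERENCE_LOCI)
        assert post.n_loci_used == 1
        with pytest.raises(ValueError):
            posterior_hybrid_class(GenotypeRecord("y", "male_ZZ", {}), REFERENCE_LOCI)


class TestBackcrossScreen:
    def test_heterozygosity_expectations(self):
        assert backcross_het_expectation(1) == 0.5
        assert backcross_het_expectation(2) == 0.25
        assert backcross_het_expectation(3) == 0.125
        with pytest.raises(ValueError):
            backcross_het_expectation(0)

    def test_prob_all_homozygous_closed_form(self):
        assert prob_all_homozygous(1, 5) == pytest.approx(0.5**5)
        assert prob_all_homozygous(2, 5) == pytest.approx(0.75**5)
        with pytest.raises(ValueError):
            prob_all_homozygous(2, 0)

    def test_prob_all_homozygous_matches_gene_dropping(self):
        # BC2 at the five diagnostic loci: fraction of simulated
        # individuals homozygous everywhere ~ 0.75**5
        recs = simulate_genotypes(PedigreeSpec("BC2_LL"), DIAGNOSTIC, n=20000, seed=9)
        all_hom = np.mean(
            [all(g[0] == g[-1] for g in r.calls.values()) for r in recs]
        )
        assert all_hom == pytest.approx(0.75**5, abs=0.01)


class TestMapDistance:
    def test_z_locus_separation(self):
        assert map_distance_cm(13.8, 1.43) == pytest.approx(19.734)
        assert map_distance_cm(13.8, 1.43, rounded=True) == 20.0

    def test_degenerate_inputs(self):
        assert map_distance_cm(0.0, 1.43) == 0.0
        assert map_distance_cm(1.0, 1.0) == 1.0


class TestMaternalLineage:
    REF_LM = "ACGTACGTAC"
    REF_LL = "ACGAACGTTC"  # differs at positions 3 and 8

    def test_exact_match(self):
        a = assign_maternal_lineage(self.REF_LL, self.REF_LM, self.REF_LL)
        assert a.species == "LL"
        assert (a.matched_sites, a.total_sites) == (2, 2)

    def test_one_site_mutated_keeps_majority(self):
        ref_lm = "AAATTT"
        ref_ll = "GAGTTA"  # diagnostic at positions 0, 2, 5
        a = assign_maternal_lineage("GAGTTT", ref_lm, ref_ll)  # 2 LL, 1 LM vote
        assert a.species == "LL"
        assert (a.matched_sites, a.total_sites) == (2, 3)

    def test_even_split_is_tie(self):
        a = assign_maternal_lineage("GAATTT", "AAATTT", "GAATTA")
        assert a.species == "indeterminate"

    def test_identical_references_indeterminate(self):
        a = assign_maternal_lineage("ACGT", "ACGT", "ACGT")
        assert a.species == "indeterminate"
        assert a.total_sites == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_maternal_lineage("ACG", "ACGT", "ACGT")


class TestReferenceLoci:
    def test_five_of_seven_fully_diagnostic(self):
        assert sum(l.is_diagnostic for l in REFERENCE_LOCI) == 5
        assert {l.name for l in REFERENCE_LOCI if not l.is_diagnostic} == {
            "Lu01", "Lu10",
        }

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            LocusSpec("bad", "autosomal", 1.0, ("A", "C"), (0.6, 0.5), (1.0, 0.0))


def test_tsv_round_trips(tmp_path):
    recs = simulate_genotypes(PedigreeSpec("F1"), REFERENCE_LOCI, n=3, seed=0)
    p = tmp_path / "g.tsv"
    write_genotypes_tsv(recs, p)
    back = read_genotypes_tsv(p)
    assert {r.individual_id for r in back} == {r.individual_id for r in recs}
    assert back[0].calls == recs[0].calls

    lp = tmp_path / "loci.tsv"
    write_loci_tsv(list(REFERENCE_LOCI), lp)
    loci = read_loci_tsv(lp)
    assert [l.name for l in loci] == [l.name for l in REFERENCE_LOCI]
    assert loci[0].freq_LM == pytest.approx(REFERENCE_LOCI[0].freq_LM)
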