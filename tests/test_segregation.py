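"""Segregation tests: cross typing, MC chi-squared, combination, q-values."""
import numpy as np
import pytest
from scipy import stats

from famsel.segregation import (CrossType, HET_FRACTION, chisq_mc,
                                classify_cross, combine_crosses,
                                expected_counts, family_has_composite,
                                qvalues, run_level_analysis, site_genotype)
from famsel.supertypes import SupertypeModel
from famsel.types import Locus
from famsel.simulate import SimulationConfig, simulate_families

from conftest import geno, synthetic_sequence, trio_family


class TestClassifyCross:
    @pytest.mark.parametrize("mother, father, expected", [
        (("A", "A"), ("A", "B"), CrossType.HOMxHET),
        (("A", "B"), ("A", "A"), CrossType.HETxHOM),
        (("A", "B"), ("A", "B"), CrossType.HETxHET_same),
        (("A", "B"), ("A", "C"), CrossType.HETxHET_oneshared),
        (("A", "B"), ("B", "C"), CrossType.HETxHET_oneshared),
        (("A", "A"), ("A", "A"), CrossType.uninformative),
        (("A", "B"), ("C", "D"), CrossType.uninformative),
        (("A", "A"), ("B", "C"), CrossType.uninformative),
        (("A", "A"), ("B", "B"), CrossType.uninformative),
    ])
    def test_mapping(self, mother, father, expected):
        assert classify_cross(mother, father) is expected

    def test_orientation_is_mother_by_father(self):
        assert classify_cross(("A", "A"), ("A", "B")) is CrossType.HOMxHET
        assert classify_cross(("A", "B"), ("A", "A")) is CrossType.HETxHOM


class TestExpectedCounts:
    @pytest.mark.parametrize("cross, n, expected", [
        (CrossType.HETxHOM, 108, (54, 54)),
        (CrossType.HOMxHET, 10, (5, 5)),
        (CrossType.HETxHET_same, 4, (2, 2)),
        (CrossType.HETxHET_oneshared, 8, (6, 2)),
    ])
    def test_mendelian_fractions(self, cross, n, expected):
        assert expected_counts(cross, n) == expected

    def test_sum_is_exact_for_any_n(self):
        for cross in HET_FRACTION:
            for n in range(1, 30):
                e_het, e_hom = expected_counts(cross, n)
                assert e_het + e_hom == n

    def test_uninformative_is_an_error(self):
        with pytest.raises(ValueError):
            expected_counts(CrossType.uninformative, 5)


def exact_mc_p(het, hom, frac):
    """Oracle: exact tail probability by full binomial enumeration."""
    n = het + hom
    e = frac * n

    def chi2(k):
        return (k - e) ** 2 / e + ((n - k) - (n - e)) ** 2 / (n - e)

    obs = chi2(het)
    return sum(stats.binom.pmf(k, n, frac) for k in range(n + 1)
               if chi2(k) >= obs - 1e-12)


class TestChisqMc:
    def test_site12_worked_value(self):
        chi2, p = chisq_mc((70, 38), 0.5, B=2000, seed=1)
        assert chi2 == pytest.approx(512 / 54)
        assert round(chi2, 2) == 9.48

    def test_balanced_counts_give_zero_and_p_one(self):
        chi2, p = chisq_mc((54, 54), 0.5, B=500, seed=2)
        assert chi2 == 0.0 and p == 1.0

    def test_half_fraction_identity(self, rng):
        """chi2 at fraction 1/2 equals (het - hom)^2 / n."""
        for _ in range(20):
            n = int(rng.integers(2, 200))
            het = int(rng.integers(0, n + 1))
            chi2, _ = chisq_mc((het, n - het), 0.5, B=1, seed=rng)
            assert chi2 == pytest.approx((het - (n - het)) ** 2 / n)

    def test_large_b_converges_to_exact_enumeration(self):
        chi2, p = chisq_mc((6, 2), 0.75, B=200_000, seed=3)
        exact = exact_mc_p(6, 2, 0.75)
        assert abs(p - exact) < 3 * np.sqrt(exact * (1 - exact) / 200_000) \
            + 1 / 200_000

    def test_p_never_zero(self):
        _, p = chisq_mc((40, 0), 0.5, B=100, seed=4)
        assert p == pytest.approx(1 / 101)


class TestCombineCrosses:
    def test_single_type_equals_its_own_result(self):
        stat, df, _ = combine_crosses({CrossType.HETxHOM: (70, 38)}, B=500,
                                      seed=1)
        assert stat == pytest.approx(512 / 54) and df == 1

    def test_all_observed_equal_expected_gives_zero(self):
        stat, df, p = combine_crosses(
            {CrossType.HETxHOM: (50, 50),
             CrossType.HETxHET_oneshared: (30, 10)}, B=500, seed=2)
        assert stat == 0.0 and p == 1.0

    def test_pooled_counts_hand_computation(self):
        # (70,38) at 1/2 pools with (30,30) at 3/4:
        # pooled obs (100,68), pooled exp (99,69), chi2 = 1/99 + 1/69
        stat, df, _ = combine_crosses(
            {CrossType.HETxHOM: (70, 38),
             CrossType.HETxHET_oneshared: (30, 30)}, B=100, seed=3)
        assert stat == pytest.approx(1 / 99 + 1 / 69)
        assert df == 1

    def test_sum_mode_adds_statistics(self):
        tables = {CrossType.HETxHOM: (70, 38),
                  CrossType.HETxHET_same: (30, 30)}
        stat, df, _ = combine_crosses(tables, mode="sum", B=100, seed=4)
        assert stat == pytest.approx(512 / 54 + 0.0)
        assert df == 2

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            combine_crosses({CrossType.HETxHOM: (0, 0)})


class TestSiteGenotype:
    def setup_method(self):
        self.seqs = {
            (Locus.DRB1, "a1"): synthetic_sequence(Locus.DRB1, "a1",
                                                   {67: "L"}),
            (Locus.DRB1, "a2"): synthetic_sequence(Locus.DRB1, "a2",
                                                   {67: "F"}),
            (Locus.DRB1, "a3"): synthetic_sequence(Locus.DRB1, "a3",
                                                   {67: "L"}),
        }

    def test_heterozygous_residues(self):
        assert site_genotype(("a1", "a2"), Locus.DRB1, 67, self.seqs) \
            == ("F", "L")

    def test_distinct_alleles_same_residue_is_homozygous(self):
        assert site_genotype(("a1", "a3"), Locus.DRB1, 67, self.seqs) \
            == ("L", "L")

    def test_missing_sequence_returns_none(self):
        assert site_genotype(("a1", "013017"), Locus.DRB1, 67,
                             self.seqs) is None


class TestRunLevelAnalysis:
    def test_null_simulation_shows_no_signal(self):
        cfg = SimulationConfig(seed=9, n_families=10)
        fams, _ = simulate_families(cfg)
        for locus in Locus:
            res = run_level_analysis(fams, "allele", locus, B=2000, seed=5)
            assert res, locus
            for r in res:
                assert r.p_mc > 0.001
                assert r.exp_het + r.exp_hom == r.obs_het + r.obs_hom

    def test_supertype_level_is_a_coarsening(self):
        cfg = SimulationConfig(seed=10, n_families=10)
        fams, _ = simulate_families(cfg)
        allele_res = run_level_analysis(fams, "allele", Locus.DRB1, B=200,
                                        seed=1)
        # collapse all DRB1 alleles into two classes
        alleles = sorted({c.name for f in fams
                          for r in (f.dam, f.sire, *f.offspring)
                          for c in r.genotype[Locus.DRB1]})
        classes = {a: 1 + (i % 2) for i, a in enumerate(alleles)}
        model = SupertypeModel(locus=Locus.DRB1, classes=classes, k=2,
                               linkage=np.empty((0, 4)),
                               merge_heights=np.empty(0),
                               polymorphic_positions=[])
        st_res = run_level_analysis(fams, "supertype", Locus.DRB1,
                                    supertype_model=model, B=200, seed=1)
        n_allele = sum(r.n for r in allele_res if r.cross is not None)
        n_super = sum(r.n for r in st_res if r.cross is not None)
        assert n_super <= n_allele

    def test_dup_policy_partitions_offspring(self):
        cfg = SimulationConfig(seed=11, n_families=10)
        fams, _ = simulate_families(cfg)
        assert any(family_has_composite(f) for f in fams)

        def combined_n(policy):
            res = run_level_analysis(fams, "allele", Locus.DQB1, B=100,
                                     seed=2, dup_policy=policy)
            return sum(r.n for r in res if r.cross is None)

        assert combined_n("exclude_dup_families") \
            + combined_n("only_dup_families") == combined_n("composite")

    def test_breed_subsets_are_independent_rows(self):
        cfg = SimulationConfig(seed=12, n_families=4)
        fams, _ = simulate_families(cfg)
        res = run_level_analysis(fams, "allele", Locus.DQA1, by="breed",
                                 B=100, seed=3)
        subsets = {r.subset for r in res}
        assert len(subsets) > 1
        assert all(r.subset in {f.dam.breed for f in fams} for r in res)

    def test_site_level_rederives_crosses_and_reports_q(self):
        seqs = {}
        for name, res9 in (("a", "L"), ("b", "F"), ("c", "L")):
            seqs[(Locus.DRB1, name)] = synthetic_sequence(
                Locus.DRB1, name, {9: res9, 11: "A"})
        fam = trio_family(geno(drb1="a/b"), geno(drb1="a/a"),
                          [geno(drb1="a/a"), geno(drb1="a/b")])
        res = run_level_analysis([fam], "site", Locus.DRB1,
                                 allele_seqs=seqs, codons=(9, 11), B=100,
                                 seed=4)
        by_codon = {}
        for r in res:
            by_codon.setdefault(r.codon_position, []).append(r)
        assert set(by_codon) == {9}  # codon 11 monomorphic -> uninformative
        combined = [r for r in by_codon[9] if r.cross is None]
        assert combined and combined[0].q_value is not None


class TestQvalues:
    def test_all_ones_stay_one(self):
        assert np.allclose(qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_bh_closed_form_when_pi0_is_one(self):
        with pytest.warns(UserWarning, match="pi0 = 1"):
            q = qvalues([0.001, 0.5, 0.9])
        assert np.allclose(q, [0.003, 0.75, 0.9])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0.01, 1.0, size=40)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_near_one_for_uniform_p(self, rng):
        p = rng.uniform(1e-9, 1.0, size=1000)
        q = qvalues(p)
        # under a pure null the smoother pi0 estimate should be near 1,
        # and max q approaches pi0
        assert 0.85 <= q.max() <= 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.0, 0.5])
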