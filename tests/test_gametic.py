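import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gametivar import (ChromSpec, EffectTable, GeneticMap, HaplotypePair,
                       SimSpec, build_P, crv, enumerate_gametes,
                       gametic_covariance, gametic_variance, gebv,
                       hom_statistic, individual_report, oracle_moments,
                       simulate_dataset)
from gametivar.gametic import cross_products

from .conftest import random_het_pair


def single_het_P():
    pair = HaplotypePair("i", "1", [1], [0])
    gmap = GeneticMap("1", ["m1"], positions_cM=np.array([0.0]))
    return build_P(pair, gmap)


class TestGameticVariance:
    def test_single_het_locus_binomial(self):
        # n*p*q*alpha^2 with n=1, p=q=0.5, alpha=2
        assert gametic_variance([2.0], single_het_P()) == pytest.approx(1.0)

    def test_empty(self):
        pair = HaplotypePair("i", "1", [1, 1], [1, 1])
        gmap = GeneticMap("1", ["m1", "m2"], positions_cM=np.array([0.0, 1.0]))
        assert gametic_variance([], build_P(pair, gmap)) == 0.0

    def test_two_fully_linked_coupled_loci(self, coupling_pair):
        gmap = GeneticMap("1", ["m1", "m2"], positions_cM=np.array([0.0, 0.0]))
        P = build_P(coupling_pair, gmap)
        # gamete values {+1, -1} each w.p. 1/2 on the centered scale
        assert gametic_variance([1.0, 1.0], P) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gametic_variance([1.0, 2.0], single_het_P())

    @given(st.floats(-5, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_quadratic_scaling(self, c, seed):
        rng = np.random.default_rng(seed)
        pair = random_het_pair(rng, 8)
        gmap = GeneticMap("1", [f"m{i}" for i in range(8)],
                          adjacent_rates=rng.uniform(0, 0.5, 7))
        P = build_P(pair, gmap)
        a = rng.normal(size=P.n_het)
        assert gametic_variance(c * a, P) == pytest.approx(
            c * c * gametic_variance(a, P), rel=1e-9, abs=1e-12)


class TestGameticCovariance:
    def test_reduces_to_variance(self):
        P = single_het_P()
        assert gametic_covariance([3.0], [3.0], P) == pytest.approx(
            gametic_variance([3.0], P))

    def test_single_locus_cross(self):
        assert gametic_covariance([1.0], [-2.0], single_het_P()) == \
            pytest.approx(-0.5)

    def test_symmetric_in_traits(self):
        rng = np.random.default_rng(0)
        pair = random_het_pair(rng, 6)
        gmap = GeneticMap("1", [f"m{i}" for i in range(6)],
                          adjacent_rates=rng.uniform(0, 0.5, 5))
        P = build_P(pair, gmap)
        ax, ay = rng.normal(size=(2, P.n_het))
        assert gametic_covariance(ax, ay, P) == pytest.approx(
            gametic_covariance(ay, ax, P))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_cauchy_schwarz_in_rate_mode(self, seed):
        rng = np.random.default_rng(seed)
        pair = random_het_pair(rng, 10)
        gmap = GeneticMap("1", [f"m{i}" for i in range(10)],
                          adjacent_rates=rng.uniform(0, 0.5, 9))
        P = build_P(pair, gmap)
        ax, ay = rng.normal(size=(2, P.n_het))
        cxy = gametic_covariance(ax, ay, P)
        assert cxy**2 <= (gametic_variance(ax, P)
                          * gametic_variance(ay, P)) + 1e-9


class TestHomStatistic:
    def test_fully_heterozygous_is_zero(self, coupling_pair):
        assert hom_statistic(coupling_pair, [1.0, 2.0]) == 0.0

    def test_sum_of_squares(self):
        pair = HaplotypePair("i", "1", [1, 0], [1, 0])
        assert hom_statistic(pair, [1.0, 2.0]) == pytest.approx(5.0)

    def test_invariant_to_homozygote_class(self):
        aa = HaplotypePair("i", "1", [0], [0])
        AA = HaplotypePair("i", "1", [1], [1])
        assert hom_statistic(aa, [3.0]) == hom_statistic(AA, [3.0])


class TestCRV:
    @pytest.mark.parametrize("sigma,hom,expected", [
        (2.0, 0.0, 1.0),        # no homozygous effects -> sigma/sqrt(sigma^2)
        (1.0, 6.0, 0.5),        # 1/sqrt(3 + 1)
        (0.0, 4.0, 0.0),
        (0.0, 0.0, 0.0),        # degenerate 0/0 defined as 0
    ])
    def test_examples(self, sigma, hom, expected):
        assert crv(sigma, hom) == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            crv(-1.0, 0.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_bounded_in_unit_interval(self, sigma, hom):
        assert 0.0 <= crv(sigma, hom) <= 1.0


class TestGEBV:
    def test_all_heterozygous_is_zero(self, coupling_pair):
        eff = EffectTable(["m1", "m2"], ["t"], np.array([[5.0], [7.0]]))
        per, total = gebv({"1": coupling_pair}, {"1": eff}, "t")
        assert total == 0.0

    def test_genotype_dot_product(self):
        pair = HaplotypePair("i", "1", [1, 0], [1, 0])  # genotypes (1, -1)
        eff = EffectTable(["m1", "m2"], ["t"], np.array([[2.0], [3.0]]))
        per, total = gebv({"1": pair}, {"1": eff}, "t")
        assert total == pytest.approx(-1.0)

    def test_linear_in_effects(self):
        rng = np.random.default_rng(1)
        pair = random_het_pair(rng, 5)
        a = rng.normal(size=(5, 1))
        e1 = EffectTable([f"m{i}" for i in range(5)], ["t"], a)
        e2 = EffectTable([f"m{i}" for i in range(5)], ["t"], 2 * a)
        _, t1 = gebv({"1": pair}, {"1": e1}, "t")
        _, t2 = gebv({"1": pair}, {"1": e2}, "t")
        assert t2 == pytest.approx(2 * t1)


class TestIndividualReport:
    def _dataset(self, seed=0, n_chrom=2, n_markers=8, n_traits=2):
        spec = SimSpec(
            n_individuals=1,
            chromosomes=tuple(
                ChromSpec(str(c + 1), n_markers, rate_range=(0.0, 0.5))
                for c in range(n_chrom)),
            n_traits=n_traits,
            seed=seed,
        )
        individuals, maps, effects = simulate_dataset(spec)
        by_chrom = next(iter(individuals.values()))
        eff_by_chrom = {
            c: EffectTable(maps[c].marker_ids, effects.trait_names,
                           effects.effects[[effects.marker_ids.index(m)
                                            for m in maps[c].marker_ids]])
            for c in maps}
        return by_chrom, maps, eff_by_chrom, effects

    def test_totals_are_sums_over_chromosomes(self):
        by_chrom, maps, eff, _ = self._dataset()
        rep = individual_report(by_chrom, maps, eff)
        for t in rep.trait_names:
            assert rep.variance_total[t] == pytest.approx(
                sum(rep.variance[t].values()), rel=1e-9)
            assert rep.gebv_total[t] == pytest.approx(
                sum(rep.gebv[t].values()), rel=1e-9)
            assert rep.hom_total[t] == pytest.approx(
                sum(rep.hom[t].values()), rel=1e-9)
        for pk in rep.covariance_total:
            assert rep.covariance_total[pk] == pytest.approx(
                sum(rep.covariance[pk].values()), rel=1e-9)

    def test_single_chromosome_totals_equal_chromosome_values(self):
        by_chrom, maps, eff, _ = self._dataset(n_chrom=1)
        rep = individual_report(by_chrom, maps, eff)
        for t in rep.trait_names:
            assert rep.variance_total[t] == rep.variance[t]["1"]

    def test_total_variance_matches_multichromosome_enumeration(self):
        # gametes across chromosomes are products of per-chromosome
        # distributions; variances of independent sums add
        by_chrom, maps, eff, _ = self._dataset(seed=3, n_chrom=2, n_markers=6)
        rep = individual_report(by_chrom, maps, eff)
        for i, t in enumerate(rep.trait_names):
            total = 0.0
            for c, gmap in maps.items():
                dist = enumerate_gametes(by_chrom[c], gmap.adjacent_rates)
                _, cov = oracle_moments(dist, eff[c].effects)
                total += cov[i, i]
            assert rep.variance_total[t] == pytest.approx(total, rel=1e-10)

    def test_missing_chromosome_in_map_is_reported(self):
        by_chrom, maps, eff, _ = self._dataset()
        del maps["2"], eff["2"]
        with pytest.raises(ValueError, match="2"):
            individual_report(by_chrom, maps, eff)

    def test_blocked_accumulation_matches_dense(self):
        by_chrom, maps, eff, _ = self._dataset(seed=5, n_chrom=1,
                                               n_markers=30, n_traits=3)
        pair, gmap = by_chrom["1"], maps["1"]
        dense = cross_products(pair, gmap, eff["1"].effects)
        blocked = cross_products(pair, gmap, eff["1"].effects,
                                 dense_threshold=4)
        np.testing.assert_allclose(blocked, dense, rtol=1e-12)
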