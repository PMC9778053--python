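import numpy as np
import pytest
from scipy import stats

from embai import (
    DataError,
    compute_grm,
    make_scenario_multi_qtn,
    make_scenario_one_qtn,
    simulate_genotypes,
    simulate_phenotype,
)
from embai.simdata import SimulationScenario


class TestSimulateGenotypes:
    def test_hwe_and_maf_distribution(self):
        """Large panel: empirical MAF stays near its bounds and per-column
        HWE chi-square tests are non-significant for the vast majority."""
        g = simulate_genotypes(2000, 10_000, 0.1, 0.5, seed=1)
        assert g.maf.min() >= 0.05 and g.maf.max() <= 0.55
        counts = np.stack(
            [(g.dosages == d).sum(axis=0) for d in (0.0, 1.0, 2.0)], axis=1
        )
        p = g.allele_freq
        expected = 2000 * np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
        # one df: genotype frequencies constrained by the estimated p
        frac_ok = np.mean(chi2 < stats.chi2.ppf(0.95, df=1))
        assert frac_ok >= 0.94

    def test_hwe_proportions_at_half(self):
        g = simulate_genotypes(20_000, 1, maf_low=0.5, maf_high=0.5, seed=3)
        freqs = [(g.dosages == d).mean() for d in (0.0, 1.0, 2.0)]
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    @pytest.mark.parametrize("bounds", [(0.6, 0.7), (0.0, 0.3), (0.4, 0.2)])
    def test_invalid_maf_bounds(self, bounds):
        with pytest.raises(DataError):
            simulate_genotypes(10, 5, *bounds, seed=0)

    def test_no_monomorphic_columns(self):
        g = simulate_genotypes(5, 200, 0.1, 0.15, seed=2)
        assert (g.dosages.min(axis=0) < g.dosages.max(axis=0)).all()

    def test_reproducible(self):
        a = simulate_genotypes(50, 80, seed=7)
        b = simulate_genotypes(50, 80, seed=7)
        assert np.array_equal(a.dosages, b.dosages)


class TestOneQtnScenario:
    def test_qtn_variance_no_background(self):
        """With no polygenic term the QTN variance is h2/(1-h2)*sigma_e^2."""
        g = simulate_genotypes(500, 100, seed=5)
        scen = make_scenario_one_qtn(g, background_multiplier=0.0, seed=6)
        p = g.allele_freq[97]
        v_qtn = scen.qtn_effects[0] ** 2 * 2 * p * (1 - p)
        assert v_qtn == pytest.approx(10.0 / 9.0, rel=1e-12)
        assert scen.qtn_indices == (98,)

    def test_effect_from_variance_at_half_frequency(self):
        # 2p(1-p) = 0.5 at p = 0.5, so a = sqrt(v / 0.5)
        dos = np.tile([0.0, 1.0, 1.0, 2.0], (25, 1)).reshape(100, 1)
        dos = np.repeat(dos, 98, axis=1)
        from embai import GenotypeMatrix

        g = GenotypeMatrix(dos, tuple(f"m{i}" for i in range(98)))
        scen = make_scenario_one_qtn(g, background_multiplier=0.0, seed=0)
        v = 10.0 / 9.0
        assert scen.qtn_effects[0] == pytest.approx(np.sqrt(v / 0.5), rel=1e-12)

    def test_too_few_markers(self):
        g = simulate_genotypes(10, 50, seed=1)
        with pytest.raises(DataError):
            make_scenario_one_qtn(g, 2.0, seed=1)

    def test_realized_pve_full_scale(self):
        """Realized QTN variance share stays near the target heritability."""
        g = simulate_genotypes(2000, 10_000, seed=7)
        K = compute_grm(g)
        scen = make_scenario_one_qtn(g, background_multiplier=2.0, seed=7)
        ds = simulate_phenotype(g, scen, K)
        pve = ds.genetic.var() / ds.phenotype.var()
        assert pve == pytest.approx(0.1, abs=0.03)


class TestMultiQtnScenario:
    def test_total_variance_split(self):
        g = simulate_genotypes(400, 2000, seed=8)
        scen = make_scenario_multi_qtn(g, background_multiplier=0.0, seed=9)
        p = g.allele_freq[np.asarray(scen.qtn_indices) - 1]
        v = np.asarray(scen.qtn_effects) ** 2 * 2 * p * (1 - p)
        # total_pve 0.5 with sigma_e^2 = 10 -> total genetic variance 10
        assert v.sum() == pytest.approx(10.0, rel=1e-10)
        assert np.allclose(v, v[0])  # equal split
        assert len(scen.qtn_indices) == 50

    def test_qtn_maf_filter(self):
        g = simulate_genotypes(400, 2000, seed=10)
        scen = make_scenario_multi_qtn(g, background_multiplier=2.0, seed=11)
        assert (g.maf[np.asarray(scen.qtn_indices) - 1] > 0.3).all()

    def test_insufficient_common_markers(self):
        g = simulate_genotypes(100, 60, maf_low=0.1, maf_high=0.2, seed=12)
        with pytest.raises(DataError):
            make_scenario_multi_qtn(g, 2.0, seed=1)

    def test_realized_pve_over_seeds(self):
        """Across replicates the mean realized genetic share is ~ 0.5."""
        shares = []
        for seed in range(20):
            g = simulate_genotypes(500, 1500, seed=100 + seed)
            scen = make_scenario_multi_qtn(g, background_multiplier=0.0, seed=200 + seed)
            ds = simulate_phenotype(g, scen)
            shares.append(ds.genetic.var() / ds.phenotype.var())
        assert np.mean(shares) == pytest.approx(0.5, abs=0.05)


class TestSimulatePhenotype:
    def test_zero_background_gives_zero_polygenic(self):
        g = simulate_genotypes(50, 120, seed=13)
        scen = make_scenario_one_qtn(g, background_multiplier=0.0, seed=14)
        ds = simulate_phenotype(g, scen)
        assert np.all(ds.polygenic == 0.0)

    def test_exact_decomposition_and_reproducibility(self):
        g = simulate_genotypes(80, 150, seed=15)
        K = compute_grm(g)
        scen = make_scenario_one_qtn(g, background_multiplier=5.0, seed=16)
        a = simulate_phenotype(g, scen, K)
        b = simulate_phenotype(g, scen, K)
        rebuilt = scen.mu + a.genetic + a.polygenic + a.residual
        assert np.array_equal(a.phenotype, rebuilt)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_null_scenario_mean_and_variance(self):
        """No QTN, no background: y is iid N(10, 10)."""
        ys = []
        for seed in range(100):
            g = simulate_genotypes(50, 5, seed=seed)
            scen = SimulationScenario(
                n=50, q=5, qtn_indices=(), qtn_effects=(),
                background_multiplier=0.0, seed=1000 + seed,
            )
            ys.append(simulate_phenotype(g, scen).phenotype)
        y = np.concatenate(ys)
        assert y.mean() == pytest.approx(10.0, abs=0.1)
        # variance of the variance estimate: 2 sigma^4 / n per replicate
        se = np.sqrt(2 * 10.0**2 / y.size)
        assert abs(y.var(ddof=1) - 10.0) < 3 * se * np.sqrt(2)

    def test_kinship_required_with_background(self):
        g = simulate_genotypes(30, 100, seed=17)
        scen = make_scenario_one_qtn(g, background_multiplier=2.0, seed=18)
        with pytest.raises(DataError):
            simulate_phenotype(g, scen, kinship=None)

    def test_dimension_mismatch(self):
        g = simulate_genotypes(30, 100, seed=19)
        other = simulate_genotypes(31, 100, seed=19)
        scen = make_scenario_one_qtn(g, background_multiplier=0.0, seed=20)
        with pytest.raises(DataError):
            simulate_phenotype(other, scen)
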