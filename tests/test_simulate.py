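"""Haplodiploid panel generator: inbreeding arithmetic, LD calibration,
pedigree behaviour, phenotype model and fixture round-trips."""

import math

import numpy as np
import pytest

from linepanel.genotypes import read_brood_table, read_genotype_matrix
from linepanel.simulate import (
    CausalSnp,
    SimulationConfig,
    expected_segregating_fraction,
    inbreeding_coefficient,
    line_variance_for_h2,
    mc_fullsib_inbreeding,
    simulate_founder_haplotypes,
    simulate_inbred_lines,
    simulate_panel,
    simulate_phenotypes,
    write_fixture,
)


class TestInbreedingArithmetic:
    @pytest.mark.parametrize(
        "t,expected",
        [(0, 0.0), (1, 0.25), (2, 0.375), (10, 0.88623046875)],
    )
    def test_fullsib_recursion_series(self, t, expected):
        assert inbreeding_coefficient(t) == pytest.approx(expected, abs=1e-12)

    def test_negative_generation_rejected(self):
        with pytest.raises(ValueError):
            inbreeding_coefficient(-1)

    @pytest.mark.parametrize("F,frac", [(0.87, 0.13), (1.0, 0.0), (0.0, 1.0)])
    def test_segregating_fraction(self, F, frac):
        assert expected_segregating_fraction(F) == pytest.approx(frac)

    def test_segregating_fraction_domain(self):
        with pytest.raises(ValueError):
            expected_segregating_fraction(1.5)

    @pytest.mark.parametrize("t", [1, 4, 10])
    def test_recursion_matches_pedigree_monte_carlo(self, t):
        f_hat, se = mc_fullsib_inbreeding(t, n_rep=40_000, seed=17 + t)
        assert abs(f_hat - inbreeding_coefficient(t)) < 3 * se


class TestFounderPool:
    def test_determinism(self):
        cfg = SimulationConfig(
            n_chromosomes=2, chromosome_length_bp=500_000, snps_per_chromosome=200
        )
        a = simulate_founder_haplotypes(cfg, seed=3)
        b = simulate_founder_haplotypes(cfg, seed=3)
        for chrom in a.chromosomes:
            np.testing.assert_array_equal(a.haplotypes[chrom], b.haplotypes[chrom])
            np.testing.assert_array_equal(a.positions[chrom], b.positions[chrom])

    def test_zero_length_chromosome_gives_empty_pool(self):
        cfg = SimulationConfig(chromosome_length_bp=0, snps_per_chromosome=0)
        pool = simulate_founder_haplotypes(cfg, seed=0)
        assert all(pool.positions[c].size == 0 for c in pool.chromosomes)

    def test_ld_calibration_hyperbolic(self):
        """Binned mean r^2 across the pool tracks 1/(1+p*x) within 10%
        out to five half-decay distances."""
        cfg = SimulationConfig(
            n_founder_haplotypes=300, n_chromosomes=5,
            chromosome_length_bp=2_000_000, snps_per_chromosome=1200, seed=3,
        )
        pool = simulate_founder_haplotypes(cfg)
        p = cfg.p_sim
        rng = np.random.default_rng(0)
        r2s, ds = [], []
        for chrom in pool.chromosomes:
            H = pool.haplotypes[chrom].astype(float)
            pos = pool.positions[chrom]
            n = pos.size
            i = rng.integers(0, n - 1, size=12_000)
            j = np.minimum(i + rng.integers(1, 120, size=i.size), n - 1)
            for a, b in zip(i, j):
                d = pos[b] - pos[a]
                if d <= 0 or d > 5 / p:
                    continue
                x, y = H[:, a], H[:, b]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    continue
                r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
                r2s.append(r * r)
                ds.append(d)
        r2s, ds = np.asarray(r2s), np.asarray(ds)
        edges = np.array([0, 1e4, 3e4, 6e4, 9e4])
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (ds >= lo) & (ds < hi)
            assert m.sum() > 500
            x = ds[m].mean()
            assert r2s[m].mean() == pytest.approx(1 / (1 + p * x), rel=0.10)


class TestInbredLines:
    def test_zero_generations_reproduces_founder_female(self):
        cfg = SimulationConfig(
            n_lines=20, n_founder_haplotypes=60, n_chromosomes=1,
            chromosome_length_bp=300_000, snps_per_chromosome=200,
            mother_son_generations=0, fullsib_generations=0, missing_rate=0.0,
        )
        pool = simulate_founder_haplotypes(cfg, seed=5)
        G, _ = simulate_inbred_lines(pool, cfg, seed=5)
        # founder frequencies are symmetric -> expected heterozygosity ~0.5
        het = np.nanmean(G.het_fraction_per_line())
        assert het == pytest.approx(0.5, abs=0.06)

    def test_nine_generations_heterozygosity_below_neutral_expectation(self, small_panel):
        het = np.nanmean(small_panel.genotypes.het_fraction_per_line())
        assert het < 1 - inbreeding_coefficient(9)
        assert het > 0.0    # residual segregation remains

    def test_determinism(self):
        cfg = SimulationConfig(
            n_lines=6, n_founder_haplotypes=30, n_chromosomes=1,
            chromosome_length_bp=200_000, snps_per_chromosome=100,
            wolbachia_lost_lines=0, outlier_lines=0,
        )
        pool = simulate_founder_haplotypes(cfg, seed=2)
        a, _ = simulate_inbred_lines(pool, cfg, seed=2)
        b, _ = simulate_inbred_lines(pool, cfg, seed=2)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_metadata_flags(self, flagged_panel):
        meta = flagged_panel.metadata
        assert sum(not m.wolbachia_positive for m in meta) == 8
        assert sum(m.excluded for m in meta) == 1


class TestPhenotypes:
    def _tiny_G(self):
        import pandas as pd
        from linepanel.genotypes import GenotypeMatrix

        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "ref": ["A"], "alt": ["C"]})
        calls = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        return GenotypeMatrix([f"L{i:02d}" for i in range(20)], sites, calls)

    def test_no_variance_means_common_sex_ratio(self):
        G = self._tiny_G()
        cfg = SimulationConfig(
            n_lines=20, wolbachia_lost_lines=0, outlier_lines=0,
            sigma2_line_logit=0.0, broods_per_line=40, beta0=0.0,
        )
        broods, truth = simulate_phenotypes(G, cfg, seed=1)
        assert np.allclose(truth["p_line"], 0.5)
        mean_sr = np.mean([b.sex_ratio for b in broods])
        assert mean_sr == pytest.approx(0.5, abs=0.02)

    def test_causal_snp_shifts_lines_by_genotype(self):
        G = self._tiny_G()
        cfg = SimulationConfig(
            n_lines=20, wolbachia_lost_lines=0, outlier_lines=0,
            sigma2_line_logit=1e-6,
            causal_snps=(CausalSnp("chr1", 10, beta_sex_ratio=2.0),),
        )
        _, truth = simulate_phenotypes(G, cfg, seed=1)
        p = np.array(truth["p_line"])
        assert p[10:].mean() > p[:10].mean()
        logit = lambda q: math.log(q / (1 - q))
        assert logit(p[10:].mean()) - logit(p[:10].mean()) == pytest.approx(2.0, abs=0.1)

    def test_variance_partition_formula_solves_target(self):
        s2 = line_variance_for_h2(0.106, 60.0, math.log(0.14 / 0.86))
        p = 0.14
        h2 = s2 * p * (1 - p) / (s2 * p * (1 - p) + 1 / 60.0)
        assert h2 == pytest.approx(0.106, rel=1e-9)

    def test_nonpositive_clutch_mean_rejected(self):
        G = self._tiny_G()
        cfg = SimulationConfig(
            n_lines=20, wolbachia_lost_lines=0, outlier_lines=0, mu_clutch=1e-9,
        )
        with pytest.raises(ValueError, match="clutch"):
            simulate_phenotypes(G, cfg, seed=1)


class TestFixtureRoundTrip:
    def test_files_roundtrip_and_are_deterministic(self, tmp_path, flagged_panel):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            write_fixture(d, flagged_panel.genotypes, flagged_panel.broods,
                          flagged_panel.metadata, truth=flagged_panel.truth)
        for name in ("panel.vcf", "broods.csv", "metadata.csv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        G2 = read_genotype_matrix(d1 / "panel.vcf")
        np.testing.assert_array_equal(G2.calls, flagged_panel.genotypes.calls)
        broods2 = read_brood_table(d1 / "broods.csv")
        assert broods2 == flagged_panel.broods

    def test_empty_broods_gives_header_only_csv(self, tmp_path, flagged_panel):
        paths = write_fixture(tmp_path / "e", flagged_panel.genotypes, [],
                              flagged_panel.metadata)
        lines = paths["broods"].read_text().strip().splitlines()
        assert lines == ["line_id,female_id,n_males,n_females"]


def test_full_panel_determinism():
    cfg = SimulationConfig(
        n_lines=8, n_founder_haplotypes=30, n_chromosomes=2,
        chromosome_length_bp=300_000, snps_per_chromosome=80,
        wolbachia_lost_lines=2, outlier_lines=1, broods_per_line=4, seed=9,
    )
    a, b = simulate_panel(cfg), simulate_panel(cfg)
    np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
    assert a.broods == b.broods
    assert a.truth == b.truth
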