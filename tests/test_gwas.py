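"""Single-marker mixed-model scan, permutation null and empirical threshold."""

import numpy as np
import pytest
from scipy.stats import kstest

from linepanel.genotypes import ALT_HOM, REF_HOM, apply_gwas_filters
from linepanel.gwas import (
    association_scan,
    empirical_threshold,
    permutation_null,
    run_gwas,
    snp_association,
)
from linepanel.simulate import null_panel_config, qtl_panel, simulate_panel

from conftest import toy_matrix


@pytest.fixture(scope="module")
def null_scan():
    """Null panel (no causal SNPs) with a thinned, quasi-independent scan."""
    panel = simulate_panel(null_panel_config(3))
    G, _ = apply_gwas_filters(panel.genotypes, panel.metadata)
    thin = np.zeros(G.n_snps, bool)
    thin[::16] = True
    Gt = G.subset(snp_mask=thin)
    res = association_scan(panel.broods, Gt, "sex_ratio")
    return panel, Gt, res


@pytest.fixture(scope="module")
def qtl_scan():
    """Panel with one causal sex-ratio SNP explaining half the line variance."""
    panel = qtl_panel(101, variance_fraction=0.75)
    G, _ = apply_gwas_filters(panel.genotypes, panel.metadata)
    causal = panel.truth["causal_snps"][0]
    thin = np.zeros(G.n_snps, bool)
    thin[::16] = True
    thin[((G.sites["chrom"] == causal["chrom"])
          & (G.sites["pos"] == causal["pos"])).to_numpy()] = True
    Gt = G.subset(snp_mask=thin)
    res = association_scan(panel.broods, Gt, "sex_ratio")
    return panel, Gt, res, causal


class TestSnpAssociation:
    def test_monomorphic_rejected(self, null_scan):
        panel, Gt, _ = null_scan
        mono = toy_matrix(np.zeros((Gt.n_lines, 1), np.int8),
                          line_ids=Gt.line_ids)
        with pytest.raises(ValueError, match="monomorphic"):
            snp_association(panel.broods, mono, 0, "sex_ratio")

    def test_injected_effect_detected(self, qtl_scan):
        panel, Gt, res, causal = qtl_scan
        row = res[(res.chrom == causal["chrom"]) & (res.pos == causal["pos"])]
        assert float(row["p"].iloc[0]) < 1e-3
        assert np.sign(float(row["beta"].iloc[0])) == np.sign(causal["beta_sex_ratio"])

    def test_null_p_values_uniform(self, null_scan):
        _, _, res = null_scan
        p = res["p"].dropna().to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01

    def test_allele_label_swap_flips_direction_only(self, null_scan):
        panel, Gt, res = null_scan
        j = 5
        flipped = Gt.calls.copy()
        flipped[:, j] = np.where(Gt.calls[:, j] == REF_HOM, ALT_HOM,
                                 np.where(Gt.calls[:, j] == ALT_HOM, REF_HOM,
                                          Gt.calls[:, j]))
        Gf = toy_matrix(flipped[:, [j]], line_ids=Gt.line_ids)
        Go = toy_matrix(Gt.calls[:, [j]], line_ids=Gt.line_ids)
        a = snp_association(panel.broods, Go, 0, "sex_ratio")
        b = snp_association(panel.broods, Gf, 0, "sex_ratio")
        assert a.p_value == pytest.approx(b.p_value, rel=1e-2, abs=1e-3)
        assert a.direction == -b.direction

    def test_clutch_trait_scan_calibrated(self, null_scan):
        panel, Gt, _ = null_scan
        res = association_scan(panel.broods, Gt, "clutch")
        p = res["p"].dropna().to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01


class TestPermutationNull:
    def test_zero_permutations_rejected(self, null_scan):
        panel, Gt, _ = null_scan
        with pytest.raises(ValueError):
            permutation_null(panel.broods, Gt, "sex_ratio", n_perm=0)

    def test_same_seed_identical(self, null_scan):
        panel, Gt, _ = null_scan
        sub = Gt.subset(snp_mask=np.arange(Gt.n_snps) < 20)
        a = permutation_null(panel.broods, sub, "sex_ratio", n_perm=3, seed=5)
        b = permutation_null(panel.broods, sub, "sex_ratio", n_perm=3, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_min_p_matches_order_statistic_expectation(self, null_scan):
        """Min of ~200 null p-values has expectation ~1/201."""
        panel, Gt, _ = null_scan
        sub = Gt.subset(snp_mask=np.arange(Gt.n_snps) < 20)
        mins = []
        for s in range(5):
            store = permutation_null(panel.broods, sub, "sex_ratio",
                                     n_perm=10, seed=100 + s)
            mins.append(np.concatenate(store).min())
        assert 0.0005 < np.mean(mins) < 0.02


class TestEmpiricalThreshold:
    def test_exchangeable_null_finds_nothing(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(size=500)
        store = [rng.uniform(size=500) for _ in range(20)]
        thr = empirical_threshold(obs, store, q=0.1)
        assert thr.p_threshold is None
        assert thr.q_min > 0.1

    def test_spiked_mixture_recovered(self):
        rng = np.random.default_rng(1)
        obs = np.concatenate([np.full(10, 1e-8), rng.uniform(size=490)])
        store = [rng.uniform(size=500) for _ in range(20)]
        thr = empirical_threshold(obs, store, q=0.1)
        assert thr.p_threshold is not None and thr.p_threshold >= 1e-8
        assert np.sum(obs <= thr.p_threshold) >= 10

    def test_threshold_monotone_in_q(self):
        rng = np.random.default_rng(2)
        obs = np.concatenate([1e-7 * (1 + np.arange(20)), rng.uniform(size=480)])
        store = [rng.uniform(size=500) for _ in range(20)]
        t_strict = empirical_threshold(obs, store, q=0.01)
        t_loose = empirical_threshold(obs, store, q=0.2)
        if t_strict.p_threshold is not None and t_loose.p_threshold is not None:
            assert t_strict.p_threshold <= t_loose.p_threshold

    def test_neg_log10_consistent(self):
        obs = np.array([2.0e-6, 0.4, 0.5, 0.6])
        store = [np.array([0.3, 0.5, 0.7, 0.9]) for _ in range(10)]
        thr = empirical_threshold(obs, store, q=0.1)
        assert thr.p_threshold == pytest.approx(2.0e-6)
        assert thr.neg_log10_threshold == pytest.approx(-np.log10(2.0e-6))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            empirical_threshold([], [np.array([0.5])])
        with pytest.raises(ValueError):
            empirical_threshold([0.5], [])


class TestRunGwas:
    def test_end_to_end_recovers_causal_and_is_deterministic(self, qtl_scan):
        panel, Gt, _, causal = qtl_scan
        run1 = run_gwas(Gt, panel.broods, traits=("sex_ratio",), n_perm=5, seed=3)
        run2 = run_gwas(Gt, panel.broods, traits=("sex_ratio",), n_perm=5, seed=3)
        res = run1.results["sex_ratio"]
        top = res.loc[res["p"].idxmin()]
        assert top["chrom"] == causal["chrom"]
        assert abs(top["pos"] - causal["pos"]) < 200_000   # causal or LD proxy
        assert res["p"].equals(run2.results["sex_ratio"]["p"])
        thr1, thr2 = run1.thresholds["sex_ratio"], run2.thresholds["sex_ratio"]
        assert thr1.p_threshold == thr2.p_threshold


class TestPowerRegression:
    def test_halfvariance_qtl_detection_rate(self):
        """Fixed-seed regression: a causal SNP explaining half the among-line
        logit variance is recovered past the empirical q=0.1 threshold in a
        majority of replicate panels (25 lines x 38 broods, thinned scan).

        At this panel size the causal line-level t-statistic is ~4, while the
        permutation threshold demands p below ~1e-3, so per-replicate
        detection sits near 60%; the fixed seeds pin the realised rate.
        """
        hits = 0
        for s in range(12):
            panel = qtl_panel(500 + s)
            G, _ = apply_gwas_filters(panel.genotypes, panel.metadata)
            causal = panel.truth["causal_snps"][0]
            thin = np.zeros(G.n_snps, bool)
            thin[::50] = True
            thin[((G.sites["chrom"] == causal["chrom"])
                  & (G.sites["pos"] == causal["pos"])).to_numpy()] = True
            Gt = G.subset(snp_mask=thin)
            res = association_scan(panel.broods, Gt, "sex_ratio")
            store = permutation_null(panel.broods, Gt, "sex_ratio",
                                     n_perm=10, seed=500 + s)
            thr = empirical_threshold(res, store, q=0.1)
            if thr.p_threshold is None:
                continue
            sig = res[res["p"] <= thr.p_threshold]
            if bool(((sig["chrom"] == causal["chrom"])
                     & (abs(sig["pos"] - causal["pos"]) < 200_000)).any()):
                hits += 1
        assert hits >= 6
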