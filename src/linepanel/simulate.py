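"""Synthetic haplodiploid iso-female line panels with known ground truth.

The generator emulates the construction of an inbred-line genome reference
panel from an outbred haplodiploid (wasp-like) source population:

1. a founder haplotype pool with a configurable allele-frequency spectrum and
   hyperbolic linkage-disequilibrium decay, mean r^2(x) = 1/(1 + p_sim * x);
2. iso-female lines, each founded by one mated female and driven towards
   homozygosity by an explicit haplodiploid pedigree (one mother-son mating
   followed by full-sib matings; males are haploid and develop from
   unfertilised eggs, so a son carries a single recombined maternal
   haplotype and his sperm are clonal);
3. brood-level phenotypes: each brood's male count is binomial with a
   line-specific probability, logit(p_line) = beta0 + sum(beta_j g_j) + u_line,
   and clutch size is a rounded truncated normal with line effects and
   optional pleiotropic SNP effects.

Hyperbolic LD is obtained by giving every founder haplotype a private
recombination-intensity multiplier lambda ~ Gamma(shape=1/2, scale=1) in a
copy/refresh Markov walk along the chromosome: within one haplotype allelic
correlation decays as exp(-p*lambda*x), and averaging over the Gamma mixture
yields panel correlation (1 + p*x)^(-1/2), i.e. mean r^2 exactly 1/(1 + p*x).
A plain (single-rate) Markov walk can only produce exponential decay.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    ALT_HOM,
    HET,
    MISSING,
    REF_HOM,
    BroodRecord,
    GenotypeMatrix,
    LineMetadata,
    write_brood_table,
    write_genotype_matrix,
    write_line_metadata,
)

_NUC = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# inbreeding arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InbreedingModel:
    """Inbreeding coefficient F_t and expected within-line heterozygosity."""

    generation: int
    F: float

    @property
    def expected_heterozygosity(self) -> float:
        return 1.0 - self.F


def inbreeding_coefficient(t: int, scheme: str = "full-sib-diploid") -> float:
    """Inbreeding coefficient after ``t`` generations of regular inbreeding.

    The diploid full-sib recursion is F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4
    with F_0 = F_{-1} = 0; it is the classical analytic reference against
    which the explicit haplodiploid pedigree is compared.
    """
    if scheme != "full-sib-diploid":
        raise ValueError(f"unknown inbreeding scheme {scheme!r}")
    if t < 0:
        raise ValueError("t must be >= 0")
    f_prev2, f_prev1 = 0.0, 0.0
    for _ in range(t):
        f_prev2, f_prev1 = f_prev1, (1.0 + 2.0 * f_prev1 + f_prev2) / 4.0
    return f_prev1


def expected_segregating_fraction(F: float) -> float:
    """Expected fraction of sites still segregating within a line: 1 - F."""
    if not (0.0 <= F <= 1.0):
        raise ValueError("F must lie in [0, 1]")
    return 1.0 - F


def mc_fullsib_inbreeding(t: int, n_rep: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo IBD estimate of F under diploid full-sib mating.

    Tracks allele labels through ``t`` generations of brother-sister mating
    starting from four distinct founder alleles.  Returns (F_hat, std_error);
    used as the independent check of :func:`inbreeding_coefficient`.
    """
    rng = np.random.default_rng(seed)
    sire = np.tile([0, 1], (n_rep, 1))
    dam = np.tile([2, 3], (n_rep, 1))
    for _ in range(t):
        picks = rng.integers(0, 2, size=(n_rep, 4))
        rows = np.arange(n_rep)
        child1 = np.stack([sire[rows, picks[:, 0]], dam[rows, picks[:, 1]]], axis=1)
        child2 = np.stack([sire[rows, picks[:, 2]], dam[rows, picks[:, 3]]], axis=1)
        sire, dam = child1, child2
    # F of a would-be offspring of the final sib pair
    pick = np.random.default_rng(seed + 1).integers(0, 2, size=(n_rep, 2))
    rows = np.arange(n_rep)
    ibd = sire[rows, pick[:, 0]] == dam[rows, pick[:, 1]]
    f_hat = float(ibd.mean())
    se = float(math.sqrt(max(f_hat * (1 - f_hat), 1e-12) / n_rep))
    return f_hat, se


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalSnp:
    """A causal variant: effects on logit sex ratio and/or clutch size."""

    chromosome: str
    position: int            # snapped to the nearest simulated SNP
    beta_sex_ratio: float = 0.0   # logit units per alt allele
    beta_clutch: float = 0.0      # offspring per alt allele


def line_variance_for_h2(target_h2: float, mean_clutch: float, beta0: float) -> float:
    """Logit-scale among-line variance giving a target broad-sense H^2.

    Variance partition on the arcsine-square-root scale: the within-brood
    sampling variance of asin(sqrt(r)) is ~ 1/(4n) for clutch n regardless of
    p (delta method), and the among-line variance is ~ p(1-p) sigma_L^2 / 4,
    so H^2 = p(1-p) sigma_L^2 / (p(1-p) sigma_L^2 + 1/n).
    """
    if not (0.0 <= target_h2 < 1.0):
        raise ValueError("target_h2 must lie in [0, 1)")
    p = 1.0 / (1.0 + math.exp(-beta0))
    return (target_h2 / (1.0 - target_h2)) / (mean_clutch * p * (1.0 - p))


@dataclass(frozen=True)
class SimulationConfig:
    """Panel generator settings; defaults are the emulated study conditions.

    34 lines (8 wolbachia-lost + 1 flagged outlier -> 25 analysable),
    ~1e5 SNPs over 5 chromosomes, hyperbolic LD with half-decay 17.8 kb,
    one mother-son mating plus 8 full-sib generations, ~38 broods per line
    with mean clutch 60, and among-line variances giving broad-sense
    heritabilities of ~0.106 (sex ratio, transformed scale) and ~0.078
    (clutch size).
    """

    n_lines: int = 34
    n_founder_haplotypes: int = 200
    n_chromosomes: int = 5
    chromosome_length_bp: int = 59_000_000
    snps_per_chromosome: int = 20_000
    founder_spectrum: str = "symmetric"      # "symmetric" (f=0.5) or "beta"
    founder_beta_a: float = 5.0
    founder_beta_b: float = 5.0
    p_sim: float = 1.0 / 17_800.0            # per-bp LD decay rate
    ld_mixture: str = "gamma"                # "gamma": hyperbolic mean r^2 decay;
                                             # "fixed": single-rate exponential decay
    ld_block_bp: int = 0                     # >0: lognormal regional LD-rate blocks
    ld_block_sigma: float = 0.0
    crossovers_per_chromosome: float = 1.5   # mean per female meiosis
    mother_son_generations: int = 1
    fullsib_generations: int = 8
    missing_rate: float = 0.042
    wolbachia_lost_lines: int = 8
    outlier_lines: int = 1
    broods_per_line: int = 38
    mu_clutch: float = 60.0
    sigma_clutch: float = 15.0
    beta0: float = math.log(0.14 / 0.86)     # mean proportion male ~0.14
    target_h2_sex_ratio: float = 0.106
    target_h2_clutch: float = 0.078
    sigma2_line_logit: float | None = None   # None -> from target_h2_sex_ratio
    sigma2_line_clutch: float | None = None  # None -> from target_h2_clutch
    causal_snps: tuple[CausalSnp, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.sigma_clutch < 0 or self.missing_rate < 0:
            raise ValueError("variances/rates must be >= 0")
        if self.sigma2_line_logit is not None and self.sigma2_line_logit < 0:
            raise ValueError("sigma2_line_logit must be >= 0")
        if self.mu_clutch <= 0:
            raise ValueError("mean clutch must be positive")
        if self.wolbachia_lost_lines + self.outlier_lines >= self.n_lines:
            raise ValueError("all lines excluded by metadata flags")

    def resolved_sigma2_line_logit(self) -> float:
        if self.sigma2_line_logit is not None:
            return self.sigma2_line_logit
        return line_variance_for_h2(self.target_h2_sex_ratio, self.mu_clutch, self.beta0)

    def resolved_sigma2_line_clutch(self) -> float:
        if self.sigma2_line_clutch is not None:
            return self.sigma2_line_clutch
        h2 = self.target_h2_clutch
        return h2 / (1.0 - h2) * self.sigma_clutch**2

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

@dataclass
class FounderPool:
    """Haplotype pool per chromosome: positions (1-based) and 0/1 alleles."""

    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]   # (n_hap, n_snps) uint8
    chromosome_length_bp: int

    @property
    def n_haplotypes(self) -> int:
        if not self.chromosomes:
            return 0
        return self.haplotypes[self.chromosomes[0]].shape[0]


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_founder_haplotypes(cfg: SimulationConfig, seed: int | None = None) -> FounderPool:
    """Draw the founder haplotype pool with hyperbolic mean LD decay.

    Each haplotype walks along the chromosome copying its previous allele
    state with probability exp(-p_sim * lambda_h * m(x) * gap); refreshes
    draw a fresh latent uniform.  ``lambda_h ~ Gamma(1/2, 1)`` per haplotype
    produces mean r^2 = 1/(1 + p_sim * x) across the pool (exactly so under
    the symmetric frequency spectrum).  Optional lognormal block multipliers
    m(x) add regional LD-rate variation for decay-landscape studies.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chroms = _chrom_names(cfg.n_chromosomes)
    positions: dict[str, np.ndarray] = {}
    haplos: dict[str, np.ndarray] = {}
    n_hap = cfg.n_founder_haplotypes
    if cfg.ld_mixture == "gamma":
        lam = rng.gamma(shape=0.5, scale=1.0, size=n_hap)
    elif cfg.ld_mixture == "fixed":
        # homogeneous rate: r^2 decays exponentially, no long-range tail
        lam = np.ones(n_hap)
    else:
        raise ValueError(f"unknown ld_mixture {cfg.ld_mixture!r}")
    for chrom in chroms:
        if cfg.chromosome_length_bp <= 0 or cfg.snps_per_chromosome == 0:
            positions[chrom] = np.empty(0, dtype=np.int64)
            haplos[chrom] = np.empty((n_hap, 0), dtype=np.uint8)
            continue
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chromosome_length_bp + 1),
                size=min(cfg.snps_per_chromosome, cfg.chromosome_length_bp),
                replace=False,
            )
        )
        n_snp = pos.size
        if cfg.founder_spectrum == "beta":
            freq = rng.beta(cfg.founder_beta_a, cfg.founder_beta_b, size=n_snp)
        else:
            freq = np.full(n_snp, 0.5)
        gaps = np.diff(pos).astype(float)
        if cfg.ld_block_bp > 0 and cfg.ld_block_sigma > 0:
            block = (pos[1:] // cfg.ld_block_bp).astype(np.int64)
            mult = np.exp(
                rng.normal(-0.5 * cfg.ld_block_sigma**2, cfg.ld_block_sigma,
                           size=int(block.max()) + 1)
            )
            gap_rate = gaps * mult[block]
        else:
            gap_rate = gaps
        # copy probabilities per (haplotype, gap)
        rho = np.exp(-cfg.p_sim * lam[:, None] * gap_rate[None, :])
        refresh = np.empty((n_hap, n_snp), dtype=bool)
        refresh[:, 0] = True
        refresh[:, 1:] = rng.random((n_hap, n_snp - 1)) >= rho
        fresh_u = rng.random((n_hap, n_snp))
        idx = np.where(refresh, np.arange(n_snp)[None, :], 0)
        idx = np.maximum.accumulate(idx, axis=1)
        u = np.take_along_axis(fresh_u, idx, axis=1)
        haplos[chrom] = (u < freq[None, :]).astype(np.uint8)
        positions[chrom] = pos.astype(np.int64)
    return FounderPool(chroms, positions, haplos, cfg.chromosome_length_bp)


# ---------------------------------------------------------------------------
# haplodiploid pedigree
# ---------------------------------------------------------------------------

def _gamete(hap_a, hap_b, boundaries, pool: FounderPool, cfg, rng) -> np.ndarray:
    """One recombined egg from a diploid female (Poisson crossovers/chrom)."""
    out = np.empty_like(hap_a)
    for (chrom, lo, hi) in boundaries:
        pos = pool.positions[chrom]
        n_x = rng.poisson(cfg.crossovers_per_chromosome)
        phase = rng.integers(0, 2)
        if n_x == 0:
            seg = hap_a[lo:hi] if phase == 0 else hap_b[lo:hi]
        else:
            cuts = np.sort(rng.integers(1, pool.chromosome_length_bp + 1, size=n_x))
            which = (phase + np.searchsorted(cuts, pos)) % 2
            seg = np.where(which == 0, hap_a[lo:hi], hap_b[lo:hi])
        out[lo:hi] = seg
    return out


def simulate_inbred_lines(
    pool: FounderPool, cfg: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, list[LineMetadata]]:
    """Found and inbreed lines through the explicit haplodiploid pedigree.

    Each line starts from one founder female (two pool haplotypes); her son
    (a single recombined maternal haplotype) backcrosses to her, followed by
    ``fullsib_generations`` brother-sister matings.  The line genotype is the
    final female's diploid genotype; residual heterozygosity is whatever the
    pedigree leaves segregating.  Missing calls are added at ``missing_rate``.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    boundaries = []
    lo = 0
    for chrom in pool.chromosomes:
        hi = lo + pool.positions[chrom].size
        boundaries.append((chrom, lo, hi))
        lo = hi
    n_snps = lo
    if pool.n_haplotypes < 2 * cfg.n_lines:
        raise ValueError("founder pool too small for the requested line count")
    hap_all = np.concatenate([pool.haplotypes[c] for c in pool.chromosomes], axis=1) \
        if n_snps else np.empty((pool.n_haplotypes, 0), np.uint8)
    founder_idx = rng.choice(pool.n_haplotypes, size=(cfg.n_lines, 2), replace=False)

    total_gens = cfg.mother_son_generations + cfg.fullsib_generations
    calls = np.empty((cfg.n_lines, n_snps), dtype=np.int8)
    for i in range(cfg.n_lines):
        fem = (hap_all[founder_idx[i, 0]].copy(), hap_all[founder_idx[i, 1]].copy())
        male = _gamete(*fem, boundaries, pool, cfg, rng)  # her son
        for _ in range(total_gens):
            egg = _gamete(*fem, boundaries, pool, cfg, rng)
            next_male = _gamete(*fem, boundaries, pool, cfg, rng)
            fem = (egg, male)        # daughter = egg + father's clonal sperm
            male = next_male         # her brother (same mother)
        dose = fem[0].astype(np.int8) + fem[1].astype(np.int8)
        calls[i] = np.where(dose == 1, HET, np.where(dose == 2, ALT_HOM, REF_HOM))
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    # allele labels: ref/alt nucleotides per site
    chrom_col = np.concatenate(
        [np.repeat(c, pool.positions[c].size) for c in pool.chromosomes]
    ) if n_snps else np.array([], dtype=object)
    pos_col = np.concatenate([pool.positions[c] for c in pool.chromosomes]) \
        if n_snps else np.array([], dtype=np.int64)
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    sites = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col, "ref": _NUC[ref_i], "alt": _NUC[alt_i]}
    )
    line_ids = [f"L{i + 1:02d}" for i in range(cfg.n_lines)]
    G = GenotypeMatrix(line_ids, sites, calls)

    meta = []
    lost = set(range(cfg.wolbachia_lost_lines))
    outlier = set(range(cfg.wolbachia_lost_lines,
                        cfg.wolbachia_lost_lines + cfg.outlier_lines))
    for i, lid in enumerate(line_ids):
        meta.append(
            LineMetadata(
                lid,
                wolbachia_positive=i not in lost,
                excluded=i in outlier,
                exclusion_reason="sex-ratio outlier (transient infection)" if i in outlier else "",
            )
        )
    return G, meta


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _causal_dosage(G: GenotypeMatrix, snp: CausalSnp) -> tuple[int, np.ndarray]:
    """Snap a causal SNP to the nearest simulated site; per-line dosage in [0,1]."""
    on_chrom = np.flatnonzero((G.sites["chrom"] == snp.chromosome).to_numpy())
    if on_chrom.size == 0:
        raise ValueError(f"causal SNP chromosome {snp.chromosome} not simulated")
    pos = G.sites["pos"].to_numpy()[on_chrom]
    j = int(on_chrom[np.argmin(np.abs(pos - snp.position))])
    c = G.calls[:, j].astype(float)
    dose = np.where(c == ALT_HOM, 1.0, np.where(c == HET, 0.5, np.where(c == REF_HOM, 0.0, np.nan)))
    if np.isnan(dose).any():
        dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
    return j, dose


def simulate_phenotypes(
    G: GenotypeMatrix, cfg: SimulationConfig, seed: int | None = None
) -> tuple[list[BroodRecord], dict]:
    """Draw brood phenotypes for every line; returns (broods, truth table).

    logit(p_line) = beta0 + sum_j beta_j * g_j + u_line, u ~ N(0, sigma2_L);
    n_males ~ Binomial(clutch, p_line); clutch = round(Normal(mu_c +
    clutch line effect + pleiotropic terms, sigma_c)) truncated at 1.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    s2_sr = cfg.resolved_sigma2_line_logit()
    s2_cl = cfg.resolved_sigma2_line_clutch()
    n = G.n_lines
    u = rng.normal(0.0, math.sqrt(s2_sr), size=n)
    c_line = rng.normal(0.0, math.sqrt(s2_cl), size=n)
    eta = cfg.beta0 + u
    clutch_mu = cfg.mu_clutch + c_line
    causal_truth = []
    for snp in cfg.causal_snps:
        j, dose = _causal_dosage(G, snp)
        eta = eta + snp.beta_sex_ratio * dose
        clutch_mu = clutch_mu + snp.beta_clutch * dose
        causal_truth.append(
            {
                "chrom": str(G.sites["chrom"].iloc[j]),
                "pos": int(G.sites["pos"].iloc[j]),
                "snp_index": j,
                "beta_sex_ratio": snp.beta_sex_ratio,
                "beta_clutch": snp.beta_clutch,
            }
        )
    if np.any(clutch_mu <= 0):
        raise ValueError("clutch model produced a non-positive mean clutch")
    p_line = 1.0 / (1.0 + np.exp(-eta))
    broods: list[BroodRecord] = []
    for i, lid in enumerate(G.line_ids):
        raw = rng.normal(clutch_mu[i], cfg.sigma_clutch, size=cfg.broods_per_line)
        clutch = np.maximum(1, np.rint(raw)).astype(int)
        males = rng.binomial(clutch, p_line[i])
        for b in range(cfg.broods_per_line):
            broods.append(
                BroodRecord(lid, f"{lid}_f{b + 1:02d}", int(males[b]), int(clutch[b] - males[b]))
            )
    truth = {
        "sigma2_line_logit": s2_sr,
        "sigma2_line_clutch": s2_cl,
        "beta0": cfg.beta0,
        "line_ids": list(G.line_ids),
        "u_line": u.tolist(),
        "p_line": p_line.tolist(),
        "clutch_mu_line": clutch_mu.tolist(),
        "causal_snps": causal_truth,
    }
    return broods, truth


@dataclass
class Panel:
    """A complete simulated panel: genotypes, metadata, broods, truth."""

    genotypes: GenotypeMatrix
    metadata: list[LineMetadata]
    broods: list[BroodRecord]
    truth: dict
    config: SimulationConfig


def simulate_panel(cfg: SimulationConfig, seed: int | None = None) -> Panel:
    """Run the full generator: founders -> inbred lines -> phenotypes."""
    seed = cfg.seed if seed is None else seed
    pool = simulate_founder_haplotypes(cfg, seed)
    G, meta = simulate_inbred_lines(pool, cfg, seed)
    broods, truth = simulate_phenotypes(G, cfg, seed)
    return Panel(G, meta, broods, truth, cfg)


# ---------------------------------------------------------------------------
# study-condition scenario builders
# ---------------------------------------------------------------------------

def null_panel_config(seed: int = 0, snps_per_chromosome: int = 400) -> SimulationConfig:
    """Null GWAS panel at study scale: 25 analysable lines, 5 chromosomes
    (~2000 SNPs total by default), 38 broods/line, no causal variants."""
    return SimulationConfig(
        n_lines=25, n_founder_haplotypes=120, n_chromosomes=5,
        chromosome_length_bp=40_000_000, snps_per_chromosome=snps_per_chromosome,
        wolbachia_lost_lines=0, outlier_lines=0, broods_per_line=38, seed=seed,
    )


def _common_snp_near(G: GenotypeMatrix, chromosome: str, position: int,
                     maf_min: float = 0.35) -> int:
    """Panel SNP position nearest a target with MAF >= maf_min (causal anchor)."""
    sub = G.sites[G.sites["chrom"] == chromosome]
    maf = G.maf()[sub.index]
    ok = sub[maf >= maf_min]
    if ok.empty:
        ok = sub
    pos = ok["pos"].to_numpy()
    return int(pos[np.argmin(np.abs(pos - position))])


def qtl_panel(seed: int, variance_fraction: float = 0.5) -> Panel:
    """Panel with one common causal sex-ratio SNP on chromosome 1.

    The causal effect is sized so that beta^2 * maf(1-maf) equals
    ``variance_fraction`` of the default among-line logit variance; the
    residual line variance is reduced accordingly so total line variance
    (and hence H^2) stays at the default study regime.
    """
    base = null_panel_config(seed)
    s2_tot = base.resolved_sigma2_line_logit()
    beta = math.sqrt(variance_fraction * s2_tot / 0.25)
    pool = simulate_founder_haplotypes(base, seed)
    G, meta = simulate_inbred_lines(pool, base, seed)
    pos = _common_snp_near(G, "chr1", base.chromosome_length_bp // 2)
    cfg = base.replace(
        sigma2_line_logit=(1.0 - variance_fraction) * s2_tot,
        causal_snps=(CausalSnp("chr1", pos, beta_sex_ratio=beta),),
    )
    broods, truth = simulate_phenotypes(G, cfg, seed)
    return Panel(G, meta, broods, truth, cfg)


def pleiotropic_panel(seed: int, with_effects: bool = True) -> Panel:
    """Panel with a pair of strong shared (sex-ratio + clutch) causal SNPs.

    A truth-recovery fixture for the cross-trait window-overlap test: two
    tightly linked common SNPs in the 400-800 kb window of chromosome 5
    affect both traits proportionally, line noise is reduced so both scans
    rank the local LD satellites concordantly, and founder LD uses the
    homogeneous single-rate ("fixed") mode so the causal cluster stays
    window-localised rather than echoing genome-wide (the hyperbolic
    mixture's long-range tail creates distant perfect genotype proxies in a
    25-line panel, which dilute any window-localised overlap signal by
    construction).  ``with_effects=False`` gives the matched null fixture.
    """
    base = SimulationConfig(
        n_lines=25, n_founder_haplotypes=120, n_chromosomes=5,
        chromosome_length_bp=2_000_000, snps_per_chromosome=250,
        wolbachia_lost_lines=0, outlier_lines=0, broods_per_line=38,
        sigma2_line_logit=0.005, sigma2_line_clutch=0.25, sigma_clutch=5.0,
        ld_mixture="fixed", p_sim=1.0 / 15_000, seed=seed,
    )
    pool = simulate_founder_haplotypes(base, seed)
    G, meta = simulate_inbred_lines(pool, base, seed)
    cfg = base
    if with_effects:
        p1 = _common_snp_near(G, "chr5", 590_000)
        p2 = _common_snp_near(G, "chr5", 612_000)
        causal = [CausalSnp("chr5", p1, beta_sex_ratio=0.8, beta_clutch=18.0)]
        if p2 != p1:
            causal.append(CausalSnp("chr5", p2, beta_sex_ratio=0.8, beta_clutch=18.0))
        shift_sr = sum(c.beta_sex_ratio for c in causal) * 0.5
        shift_cl = sum(c.beta_clutch for c in causal) * 0.5
        cfg = base.replace(
            causal_snps=tuple(causal),
            beta0=base.beta0 - shift_sr,          # keep mean sex ratio at the default
            mu_clutch=base.mu_clutch - shift_cl + 15.0,
        )
    broods, truth = simulate_phenotypes(G, cfg, seed)
    return Panel(G, meta, broods, truth, cfg)


# ---------------------------------------------------------------------------
# reference genome + toy annotation for the effects stage
# ---------------------------------------------------------------------------

def synthesize_reference(
    G: GenotypeMatrix, chromosome_length_bp: int, seed: int = 0
) -> dict[str, str]:
    """Random reference sequences whose base at every SNP equals the ref allele.

    Labelled synthetic: a stand-in genome so the variant-effect classifier can
    run end-to-end; no real genome sequence is reproduced.
    """
    rng = np.random.default_rng(seed + 3)
    genome = {}
    for chrom in G.sites["chrom"].unique():
        seq = rng.integers(0, 4, size=chromosome_length_bp)
        sub = G.sites[G.sites["chrom"] == chrom]
        ref_idx = np.searchsorted(_NUC, np.array([], dtype=str)) if sub.empty else None
        for pos, ref in zip(sub["pos"], sub["ref"]):
            seq[pos - 1] = "ACGT".index(ref)
        genome[str(chrom)] = "".join(_NUC[seq])
    return genome


def toy_annotation_gff3(
    chromosomes: Sequence[str],
    chromosome_length_bp: int,
    gene_spacing_bp: int = 50_000,
    seed: int = 0,
) -> str:
    """Deterministic toy gene models (3 exons, contiguous CDS) tiled per chromosome.

    Gene span 3.3 kb; exons of 300/600/300 bp separated by 900/1200 bp introns;
    the CDS covers exon interiors so total CDS length is divisible by 3.
    Alternating strand per gene exercises strand-aware classification.
    """
    rows = ["##gff-version 3"]
    for chrom in chromosomes:
        g = 0
        start = 10_000
        while start + 3_400 < chromosome_length_bp:
            g += 1
            strand = "+" if g % 2 else "-"
            gid = f"{chrom}_g{g}"
            e1 = (start, start + 299)
            e2 = (start + 1_200, start + 1_799)
            e3 = (start + 3_000, start + 3_299)
            # CDS: 300 + 600 + 300 = 1200 bp, divisible by 3
            gene = (e1[0], e3[1])
            rows.append(f"{chrom}\ttoy\tgene\t{gene[0]}\t{gene[1]}\t.\t{strand}\t.\tID=gene:{gid}")
            rows.append(
                f"{chrom}\ttoy\tmRNA\t{gene[0]}\t{gene[1]}\t.\t{strand}\t.\t"
                f"ID=tx:{gid}.t1;Parent=gene:{gid}"
            )
            for k, (lo, hi) in enumerate((e1, e2, e3), 1):
                rows.append(
                    f"{chrom}\ttoy\texon\t{lo}\t{hi}\t.\t{strand}\t.\t"
                    f"ID=exon:{gid}.e{k};Parent=tx:{gid}.t1"
                )
            if strand == "+":
                cds = [(e1[0] + 60, e1[1]), (e2[0], e2[1]), (e3[0], e3[1] - 60)]
            else:
                cds = [(e1[0] + 60, e1[1]), (e2[0], e2[1]), (e3[0], e3[1] - 60)]
            phase = 0
            spans = cds if strand == "+" else cds[::-1]
            for k, (lo, hi) in enumerate(spans, 1):
                rows.append(
                    f"{chrom}\ttoy\tCDS\t{lo}\t{hi}\t.\t{strand}\t{phase}\t"
                    f"ID=cds:{gid}.c{k};Parent=tx:{gid}.t1"
                )
                phase = (3 - ((hi - lo + 1) - phase) % 3) % 3
            start += gene_spacing_bp
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(
    out_dir,
    G: GenotypeMatrix,
    broods: Sequence[BroodRecord],
    meta: Sequence[LineMetadata],
    truth: dict | None = None,
    genome: dict[str, str] | None = None,
    annotation_gff3: str | None = None,
) -> dict[str, Path]:
    """Write a panel to plain-text files; re-reading reproduces the objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "panel.vcf",
        "broods": out / "broods.csv",
        "metadata": out / "metadata.csv",
    }
    write_genotype_matrix(G, paths["vcf"])
    write_brood_table(broods, paths["broods"])
    write_line_metadata(meta, paths["metadata"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    if genome is not None:
        paths["fasta"] = out / "reference.fasta"
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    if annotation_gff3 is not None:
        paths["gff3"] = out / "annotation.gff3"
        paths["gff3"].write_text(annotation_gff3)
    return paths
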