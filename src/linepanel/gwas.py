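"""Single-marker mixed-model GWAS with a permutation-based empirical q-threshold.

Sex ratio is modelled per SNP as a binomial GLMM with a logit link and an
iso-female-line random intercept.  Because the candidate genotype is constant
within a line and broods are conditionally independent given the line effect,
the brood-level GLMM reduces exactly to a line-aggregated binomial
logit-normal model (one observation per line), which is fitted by
Gauss-Hermite quadrature maximum likelihood.  Clutch size uses the analogous
linear mixed model (exact ML via a 1-D profile over the variance ratio).
P-values come from likelihood-ratio tests on the genotype effect.

Significance is judged against an empirical false-discovery threshold: the
line-to-genotype assignment is permuted (breaking genotype-phenotype linkage
while preserving the brood structure within lines), the full scan is re-run
per permutation, and for a candidate p-value cutoff t the estimated FDR is
q_hat(t) = mean permutation count of null p <= t divided by the observed
count, made monotone step-up style.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .genotypes import ALT_HOM, REF_HOM, BroodRecord, GenotypeMatrix, broods_to_frame

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 100
DEFAULT_Q = 0.1
_N_QUAD = 20

_nodes, _weights = hermgauss(_N_QUAD)
_Z = _nodes * math.sqrt(2.0)              # standard-normal quadrature points
_LOGW = np.log(_weights / math.sqrt(math.pi))


class NonConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# binomial logit-normal likelihood (sex ratio)
# ---------------------------------------------------------------------------

def _binom_ll_and_grad(theta, y, n, g):
    """Marginal log-likelihood and gradient for (b0, b, s=log sigma).

    One aggregated observation per line: y successes of n with
    logit p = b0 + b*g + sigma*z, z ~ N(0,1) integrated by quadrature.
    """
    b0, b, s = theta
    sigma = math.exp(s)
    eta = b0 + b * g[:, None] + sigma * _Z[None, :]          # (L, Q)
    # stable binomial log-pmf kernel (constants cancel in LRs but keep them out)
    f = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    a = _LOGW[None, :] + f
    amax = a.max(axis=1, keepdims=True)
    w = np.exp(a - amax)
    tot = w.sum(axis=1, keepdims=True)
    ll = float(np.sum(amax[:, 0] + np.log(tot[:, 0])))
    r = w / tot                                               # posterior weights
    u = y[:, None] - n[:, None] / (1.0 + np.exp(-eta))        # dll/deta
    ru = r * u
    g0 = float(ru.sum())
    g1 = float((ru.sum(axis=1) * g).sum())
    g2 = float((ru * (sigma * _Z[None, :])).sum())
    return ll, np.array([g0, g1, g2])


def _logit(p):
    p = np.clip(p, 1e-4, 1 - 1e-4)
    return np.log(p / (1 - p))


def _fit_binom(y, n, g, include_beta: bool, x0=None):
    """Maximise the logit-normal likelihood; returns (ll, params, converged).

    The alternative (genotype) fit is multi-started: once from the null
    optimum (beta = 0) and once from group-mean logits with a small random-
    effect scale.  With strong genotype effects the null optimum is a
    near-stationary saddle of the full likelihood (a large sigma absorbs the
    group difference and per-line scores vanish), so a single start there
    can terminate at beta ~ 0; the moment start covers that basin.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    g = np.asarray(g, float)
    phat = np.clip(y.sum() / n.sum(), 1e-4, 1 - 1e-4)
    if x0 is None:
        x0 = np.array([math.log(phat / (1 - phat)), 0.0, math.log(0.2)])
    if include_beta:
        def obj(th):
            ll, gr = _binom_ll_and_grad(th, y, n, g)
            return -ll, -gr
        b00 = float(_logit(np.average(y[g == 0].sum() / n[g == 0].sum()))) \
            if np.any(g == 0) else float(x0[0])
        b01 = float(_logit(y[g == 1].sum() / n[g == 1].sum())) \
            if np.any(g == 1) else b00
        starts = [x0]
        # the saddle pathology needs a sizeable group split; skip the second
        # optimisation for clearly null-ish SNPs (scan throughput)
        if abs(b01 - b00) >= 0.25:
            starts.append(np.array([b00, b01 - b00, -2.0]))
        best = None
        for s0 in starts:
            res = minimize(obj, s0, jac=True, method="L-BFGS-B",
                           bounds=[(-20, 20), (-20, 20), (-9, 3)])
            if best is None or -res.fun > -best.fun:
                best = res
        return -float(best.fun), best.x, bool(best.success)
    else:
        def obj0(th2):
            th = np.array([th2[0], 0.0, th2[1]])
            ll, gr = _binom_ll_and_grad(th, y, n, g)
            return -ll, -gr[[0, 2]]
        best = None
        for s0 in (x0[[0, 2]], np.array([float(x0[0]), -2.0])):
            res = minimize(obj0, s0, jac=True, method="L-BFGS-B",
                           bounds=[(-20, 20), (-9, 3)])
            if best is None or -res.fun > -best.fun:
                best = res
        return (-float(best.fun), np.array([best.x[0], 0.0, best.x[1]]),
                bool(best.success))


# ---------------------------------------------------------------------------
# linear mixed model via 1-D profile (clutch size)
# ---------------------------------------------------------------------------

def _lmm_profile_ll(lam, m, ybar, ss_within, X):
    """ML log-likelihood of y ~ X + line random intercept, profiled over
    fixed effects and sigma_e^2, at variance ratio lam = V_line/V_res."""
    w = m / (1.0 + lam * m)
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ ybar)
    resid = ybar - X @ beta
    rss = ss_within + float(np.sum(w * resid**2))
    N = float(m.sum())
    s2 = rss / N
    ll = -0.5 * (N * (math.log(2 * math.pi) + math.log(s2) + 1.0)
                 + float(np.sum(np.log1p(lam * m))))
    return ll, beta, s2


def _fit_lmm(m, ybar, ss_within, X):
    def neg(log_lam):
        return -_lmm_profile_ll(math.exp(log_lam), m, ybar, ss_within, X)[0]

    grid = np.linspace(-10.0, 6.0, 24)
    best = float(grid[int(np.argmin([neg(v) for v in grid]))])
    opt = minimize_scalar(neg, bounds=(best - 1.5, best + 1.5), method="bounded")
    lam = math.exp(float(opt.x))
    ll, beta, s2 = _lmm_profile_ll(lam, m, ybar, ss_within, X)
    ll0, beta0_, s20 = _lmm_profile_ll(0.0, m, ybar, ss_within, X)
    if ll0 > ll:
        lam, ll, beta, s2 = 0.0, ll0, beta0_, s20
    return ll, beta, lam, s2


# ---------------------------------------------------------------------------
# per-trait scan machinery
# ---------------------------------------------------------------------------

@dataclass
class TraitData:
    """Line-level sufficient statistics for one trait."""

    trait: str
    line_ids: list[str]
    # sex ratio: aggregated male/total counts; clutch: per-line mean/SS/m
    y: np.ndarray
    n: np.ndarray
    m: np.ndarray
    ybar: np.ndarray
    ss_within: float
    ssw_per_line: np.ndarray | None = None


def prepare_trait(broods: Sequence[BroodRecord], trait: str,
                  line_ids: Sequence[str]) -> TraitData:
    df = broods_to_frame(broods)
    df = df[df["line_id"].isin(set(line_ids))]
    order = {l: k for k, l in enumerate(line_ids)}
    missing = set(line_ids) - set(df["line_id"])
    if missing:
        raise ValueError(f"no broods for lines {sorted(missing)}")
    grp = df.groupby("line_id", sort=False)
    agg = grp[["n_males", "clutch_size"]].sum().reindex(line_ids)
    m = grp.size().reindex(line_ids).to_numpy(float)
    if trait == "sex_ratio":
        y = agg["n_males"].to_numpy(float)
        n = agg["clutch_size"].to_numpy(float)
        return TraitData(trait, list(line_ids), y, n, m, y / n, 0.0)
    elif trait == "clutch":
        ybar = grp["clutch_size"].mean().reindex(line_ids).to_numpy(float)
        ssw_per_line = np.array(
            [
                float(((grp.get_group(l)["clutch_size"].to_numpy(float)
                        - ybar[order[l]]) ** 2).sum())
                for l in line_ids
            ]
        )
        return TraitData(trait, list(line_ids), agg["n_males"].to_numpy(float),
                         agg["clutch_size"].to_numpy(float), m, ybar,
                         float(ssw_per_line.sum()), ssw_per_line)
    raise ValueError(f"unknown trait {trait!r}")


@dataclass(frozen=True)
class AssociationResult:
    chromosome: str
    position: int
    trait: str
    beta: float
    direction: int              # sign of the alt-allele effect
    p_value: float
    neg_log10_p: float
    maf: float
    n_lines: int
    converged: bool = True


def _line_genotypes(G: GenotypeMatrix) -> np.ndarray:
    """(n_lines, n_snps) codes 0/1 with NaN for het/missing lines."""
    return np.where(G.calls == ALT_HOM, 1.0,
                    np.where(G.calls == REF_HOM, 0.0, np.nan))


def _scan_trait(td: TraitData, codes: np.ndarray,
                line_perm: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, int]:
    """LR-test p-values for every SNP column of ``codes`` against one trait.

    ``line_perm`` permutes the line-to-genotype assignment (the permutation
    unit of the empirical threshold).  Returns (p, beta, n_nonconverged);
    monomorphic-in-subset SNPs get NaN p.
    """
    if line_perm is not None:
        codes = codes[line_perm]
    L, S = codes.shape
    p_out = np.full(S, np.nan)
    beta_out = np.full(S, np.nan)
    null_cache: dict[bytes, float] = {}
    n_fail = 0
    for s in range(S):
        gcol = codes[:, s]
        ok = ~np.isnan(gcol)
        gi = gcol[ok]
        if gi.size < 2 or np.all(gi == gi[0]):
            continue
        key = ok.tobytes()
        if td.trait == "sex_ratio":
            y, n = td.y[ok], td.n[ok]
            if key not in null_cache:
                ll0, th0, ok0 = _fit_binom(y, n, np.zeros_like(gi), include_beta=False)
                null_cache[key] = (ll0, th0)
            ll0, th0 = null_cache[key]
            x0 = np.array([th0[0], 0.0, th0[2]])
            ll1, th1, conv = _fit_binom(y, n, gi, include_beta=True, x0=x0)
            if not conv:
                n_fail += 1
                continue
            lr = max(0.0, 2.0 * (ll1 - ll0))
            beta_out[s] = th1[1]
        else:
            m, ybar = td.m[ok], td.ybar[ok]
            # within-line SS restricted to included lines
            ssw = td.ss_within if ok.all() else _ssw_subset(td, ok)
            X1 = np.column_stack([np.ones(gi.size), gi])
            X0 = np.ones((gi.size, 1))
            if key not in null_cache:
                null_cache[key] = _fit_lmm(m, ybar, ssw, X0)[0]
            ll0 = null_cache[key]
            ll1, beta, _, _ = _fit_lmm(m, ybar, ssw, X1)
            lr = max(0.0, 2.0 * (ll1 - ll0))
            beta_out[s] = beta[1]
        p_out[s] = chi2.sf(lr, 1)
    return p_out, beta_out, n_fail


def _ssw_subset(td: TraitData, ok: np.ndarray) -> float:
    return float(np.sum(td.ssw_per_line[ok]))


def snp_association(
    broods: Sequence[BroodRecord], G: GenotypeMatrix, snp_index: int, trait: str
) -> AssociationResult:
    """Mixed-model association test for one SNP (see module docstring).

    Lines heterozygous or missing at the SNP are dropped for this test;
    a SNP monomorphic among the remaining lines raises ``ValueError``.
    """
    td = prepare_trait(broods, trait, G.line_ids)
    codes = _line_genotypes(G)[:, [snp_index]]
    gi = codes[~np.isnan(codes[:, 0]), 0]
    if gi.size < 2 or np.all(gi == gi[0]):
        raise ValueError("SNP monomorphic among usable lines")
    maf = G.maf()
    p, beta, n_fail = _scan_trait(td, codes)
    site = G.sites.iloc[snp_index]
    pv = float(p[0])
    return AssociationResult(
        chromosome=str(site["chrom"]),
        position=int(site["pos"]),
        trait=trait,
        beta=float(beta[0]),
        direction=int(np.sign(beta[0])) if beta[0] == beta[0] else 0,
        p_value=pv,
        neg_log10_p=float(-np.log10(pv)),
        maf=float(maf[snp_index]),
        n_lines=int(gi.size),
        converged=n_fail == 0,
    )


def association_scan(
    broods: Sequence[BroodRecord], G: GenotypeMatrix, trait: str,
    line_perm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP association table for one trait across the whole matrix."""
    td = prepare_trait(broods, trait, G.line_ids)
    codes = _line_genotypes(G)
    maf = G.maf()
    p, beta, n_fail = _scan_trait(td, codes, line_perm=line_perm)
    if n_fail:
        log.warning("%d SNP fits did not converge", n_fail)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    return pd.DataFrame(
        {
            "chrom": G.sites["chrom"],
            "pos": G.sites["pos"],
            "trait": trait,
            "beta": beta,
            "p": p,
            "neg_log10_p": nlp,
            "maf": maf,
            "n_lines": (~np.isnan(codes)).sum(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# permutation null and empirical threshold
# ---------------------------------------------------------------------------

def permutation_null(
    broods: Sequence[BroodRecord],
    G: GenotypeMatrix,
    trait: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[np.ndarray]:
    """Null p-value store: ``n_perm`` full scans with permuted line identity.

    Each permutation shuffles which line carries which genotype row (the
    brood structure within lines is untouched), then re-runs the whole scan.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    td = prepare_trait(broods, trait, G.line_ids)
    codes = _line_genotypes(G)
    maf = G.maf()
    store = []
    for k in range(n_perm):
        perm = rng.permutation(G.n_lines)
        p, _, _ = _scan_trait(td, codes, line_perm=perm)
        store.append(p[~np.isnan(p)])
    return store


@dataclass
class GwasThreshold:
    q_target: float
    p_threshold: float | None
    neg_log10_threshold: float | None
    q_min: float
    n_perm: int
    n_observed: int
    null_store: list = field(default_factory=list, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_threshold is not None


def empirical_threshold(
    observed_p: Sequence[float] | pd.DataFrame,
    null_store: Sequence[np.ndarray],
    q: float = DEFAULT_Q,
) -> GwasThreshold:
    """Largest observed p-value whose step-up empirical FDR is <= q.

    For each observed p (ascending) t: q_hat(t) = mean per-permutation count
    of null p <= t, divided by the observed count <= t; q_hat is made
    monotone by a running minimum from the largest t downwards.  If no t
    attains q, the threshold is None and ``q_min`` reports the best
    attainable level (no SNP is declared significant).
    """
    if isinstance(observed_p, pd.DataFrame):
        observed_p = observed_p["p"].to_numpy()
    obs = np.sort(np.asarray(observed_p, float))
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        raise ValueError("empty observed p-value list")
    if not null_store:
        raise ValueError("empty null store")
    null_all = np.sort(np.concatenate([np.asarray(s, float) for s in null_store]))
    n_perm = len(null_store)
    null_counts = np.searchsorted(null_all, obs, side="right") / n_perm
    obs_counts = np.arange(1, obs.size + 1)
    q_hat = null_counts / obs_counts
    q_step = np.minimum.accumulate(q_hat[::-1])[::-1]
    passing = np.flatnonzero(q_step <= q)
    q_min = float(q_step.min())
    if passing.size == 0:
        return GwasThreshold(q, None, None, q_min, n_perm, obs.size, list(null_store))
    t = float(obs[passing[-1]])
    return GwasThreshold(q, t, float(-np.log10(t)), q_min, n_perm, obs.size, list(null_store))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class GwasRun:
    results: dict[str, pd.DataFrame]
    thresholds: dict[str, GwasThreshold]

    def significant(self, trait: str) -> pd.DataFrame:
        thr = self.thresholds[trait]
        res = self.results[trait]
        if thr.p_threshold is None:
            return res.iloc[0:0]
        return res[res["p"] <= thr.p_threshold]


def run_gwas(
    G: GenotypeMatrix,
    broods: Sequence[BroodRecord],
    traits: Sequence[str] = ("sex_ratio", "clutch"),
    q: float = DEFAULT_Q,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> GwasRun:
    """Scan every trait, build its permutation null and empirical threshold.

    ``G`` must already be filtered (see ``genotypes.apply_gwas_filters``).
    Deterministic given ``seed``; trait k uses seed + k so single-trait runs
    reproduce the same null store.
    """
    results, thresholds = {}, {}
    for k, trait in enumerate(traits):
        res = association_scan(broods, G, trait)
        store = permutation_null(broods, G, trait, n_perm=n_perm, seed=seed + k)
        thr = empirical_threshold(res.dropna(subset=["p"]), store, q=q)
        results[trait] = res
        thresholds[trait] = thr
    return GwasRun(results, thresholds)
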