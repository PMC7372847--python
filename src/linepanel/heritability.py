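"""Among-line variation tests and broad-sense heritability for line panels.

In an iso-female line design the among-line variance captures the total
genetic variance, so the intraclass correlation of a one-way random-effects
model is the broad-sense heritability H^2 = V_line / (V_line + V_residual).
Sex ratio is analysed on the arcsine-square-root scale, clutch size
untransformed; the among-line test is a quasi-binomial GLM F-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, f as f_dist

from .genotypes import BroodRecord, broods_to_frame


@dataclass(frozen=True)
class AmongLineTest:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    dispersion: float
    boundary_lines: tuple[str, ...] = ()   # lines with all-male/all-female totals

    def summary(self) -> str:
        return (
            f"Binomial GLM (quasi-F): F_{self.df_num},{self.df_den} = "
            f"{self.f_statistic:.3f}, P = {self.p_value:.3g} "
            f"(dispersion = {self.dispersion:.3f})"
        )


def among_line_ftest(broods: Sequence[BroodRecord]) -> AmongLineTest:
    """Quasi-binomial GLM F-test for among-line variation in sex ratio.

    Fits (n_males, n_females) ~ line with a logit link, estimates the
    dispersion from the full model's Pearson chi-square, and compares the
    line model to the intercept-only model with an F-test on the scaled
    deviance difference; df = (n_lines - 1, n_broods - n_lines).
    """
    df = broods_to_frame(broods)
    lines = df["line_id"].unique()
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    endog = df[["n_males", "n_females"]].to_numpy(float)
    X_full = pd.get_dummies(df["line_id"], drop_first=True, dtype=float)
    X_full.insert(0, "const", 1.0)
    full = sm.GLM(endog, X_full.to_numpy(), family=sm.families.Binomial()).fit()
    null = sm.GLM(endog, np.ones((len(df), 1)), family=sm.families.Binomial()).fit()
    df_num = len(lines) - 1
    df_den = len(df) - len(lines)
    phi = float(full.pearson_chi2 / df_den)
    f_stat = float((null.deviance - full.deviance) / df_num / phi)
    p = float(f_dist.sf(f_stat, df_num, df_den))
    totals = df.groupby("line_id")[["n_males", "n_females"]].sum()
    boundary = tuple(totals.index[(totals["n_males"] == 0) | (totals["n_females"] == 0)])
    return AmongLineTest(f_stat, df_num, df_den, p, phi, boundary)


# ---------------------------------------------------------------------------
# one-way random-effects REML
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    transform: str
    v_line: float
    v_residual: float
    h2: float
    likelihood_ratio: float
    p_value: float
    n_lines: int
    n_obs: int

    def summary(self) -> str:
        return (
            f"{self.trait} ({self.transform}): H^2 = {self.h2:.3f} "
            f"(V_line = {self.v_line:.4g}, V_res = {self.v_residual:.4g}); "
            f"LR = {self.likelihood_ratio:.3f}, P = {self.p_value:.3g}"
        )


def _oneway_reml_profile(lam: float, m: np.ndarray, ybar: np.ndarray, ss_within: float):
    """Restricted log-likelihood of the one-way model profiled over sigma_e^2.

    lam = V_line / V_residual.  Returns (llR, mu_hat, sigma_e2_hat).
    """
    w = m / (1.0 + lam * m)
    mu = float(np.sum(w * ybar) / np.sum(w))
    rss = ss_within + float(np.sum(m * (ybar - mu) ** 2 / (1.0 + lam * m)))
    n = int(m.sum())
    s2 = rss / (n - 1)
    ll = -0.5 * (
        (n - 1) * (math.log(2 * math.pi) + math.log(s2) + 1.0)
        + float(np.sum(np.log1p(lam * m)))
        + math.log(float(np.sum(w)))
    )
    return ll, mu, s2


def broad_sense_h2(
    values: Sequence[float],
    line_ids: Sequence[str],
    trait: str = "trait",
    transform: str = "identity",
) -> HeritabilityEstimate:
    """Broad-sense heritability from a one-way random-effects model (REML).

    ``transform``: "arcsine-sqrt" (applied to proportions; the conventional
    variance-stabilising scale for brood sex ratios) or "identity".  The
    restricted likelihood is profiled over the variance ratio and maximised
    on a log grid plus local refinement; the LR statistic compares the fitted
    model to the no-line-effect boundary (lam = 0) and is referred to
    chi-square(1), which is conservative at the boundary.
    """
    y = np.asarray(values, float)
    ids = np.asarray(line_ids)
    if transform == "arcsine-sqrt":
        if np.any((y < 0) | (y > 1)):
            raise ValueError("arcsine-sqrt transform needs values in [0, 1]")
        y = np.arcsin(np.sqrt(y))
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    lines, inv = np.unique(ids, return_inverse=True)
    if lines.size < 3:
        raise ValueError("need >= 3 lines")
    m = np.bincount(inv).astype(float)
    if np.all(m == 1):
        raise ValueError("one observation per line: variance components unidentifiable")
    tot = np.bincount(inv, weights=y)
    ybar = tot / m
    ss_within = float(np.sum((y - ybar[inv]) ** 2))
    if np.var(y) < 1e-300:      # degenerate constant data: boundary estimate
        return HeritabilityEstimate(trait, transform, 0.0, 0.0, 0.0, 0.0, 1.0,
                                    int(lines.size), int(m.sum()))

    def neg_ll(log_lam):
        return -_oneway_reml_profile(math.exp(log_lam), m, ybar, ss_within)[0]

    grid = np.linspace(-12.0, 6.0, 40)
    best = grid[int(np.argmin([neg_ll(g) for g in grid]))]
    opt = minimize_scalar(neg_ll, bracket=(best - 1.0, best, best + 1.0)
                          if best not in (grid[0], grid[-1]) else None,
                          bounds=(-14.0, 8.0), method="bounded")
    lam_hat = math.exp(float(opt.x))
    ll_hat, _, s2_hat = _oneway_reml_profile(lam_hat, m, ybar, ss_within)
    ll0, _, s20 = _oneway_reml_profile(0.0, m, ybar, ss_within)
    if ll0 >= ll_hat:            # boundary: no among-line variance
        lam_hat, ll_hat, s2_hat = 0.0, ll0, s20
    v_line = lam_hat * s2_hat
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(chi2.sf(lr, 1)) if lr > 0 else 1.0
    return HeritabilityEstimate(
        trait=trait,
        transform=transform,
        v_line=float(v_line),
        v_residual=float(s2_hat),
        h2=float(v_line / (v_line + s2_hat)) if (v_line + s2_hat) > 0 else 0.0,
        likelihood_ratio=float(lr),
        p_value=p,
        n_lines=int(lines.size),
        n_obs=int(m.sum()),
    )


@dataclass(frozen=True)
class TraitCorrelation:
    slope: float
    std_error: float
    t_statistic: float
    p_value: float
    intercept: float
    r_squared: float
    n_lines: int

    def summary(self) -> str:
        return (
            f"line-mean regression: b = {self.slope:.4g} (s.e. = {self.std_error:.4g}), "
            f"t = {self.t_statistic:.3f}, P = {self.p_value:.3g}, R^2 = {self.r_squared:.3f}"
        )


def trait_correlation(
    line_means_x: Sequence[float], line_means_y: Sequence[float]
) -> TraitCorrelation:
    """OLS of line-mean trait y on line-mean trait x (e.g. sex ratio on clutch)."""
    x = np.asarray(line_means_x, float)
    y = np.asarray(line_means_y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched line means for >= 3 lines")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TraitCorrelation(
        slope=float(res.params[1]),
        std_error=float(res.bse[1]),
        t_statistic=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_lines=int(x.size),
    )


def line_means(broods: Sequence[BroodRecord], trait: str = "sex_ratio") -> dict[str, float]:
    """Per-line mean of a brood-level trait ('sex_ratio' or 'clutch_size')."""
    df = broods_to_frame(broods)
    return df.groupby("line_id")[trait].mean().to_dict()
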