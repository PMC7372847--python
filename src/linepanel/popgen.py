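"""Window diversity statistics, pairwise line F_ST and the structure check.

Diversity (pi, Watterson's theta, Tajima's D) is computed from per-site
allele counts after coverage standardisation, using the classical estimators
with n equal to the subsampled draw count.  Pairwise F_ST between inbred
lines uses the Hudson estimator per site combined as a ratio of averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .genotypes import ALT_HOM, HET, MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

# defaults mirroring the pooled-window settings used for the panel
DEFAULT_TARGET_COVERAGE = 20
DEFAULT_MAX_COVERAGE = 400
DEFAULT_MIN_COVERAGE = 10
DEFAULT_POOL_SIZE = 60
DEFAULT_MIN_COUNT = 5
DEFAULT_MIN_COVERED_FRACTION = 0.5
DEFAULT_WINDOW_BP = 400_000


@dataclass
class SiteCounts:
    """Allele counts at one site (read counts or pseudo-reads)."""

    chromosome: str
    position: int
    counts: np.ndarray          # per-allele counts, length >= 2
    usable: bool = True

    @property
    def coverage(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class WindowDiversity:
    chromosome: str
    start: int                  # 1-based inclusive
    end: int                    # inclusive
    pi_per_site: float
    theta_per_site: float
    tajimas_d: float | None     # None when S == 0
    covered_fraction: float
    n_sites: int
    n_segregating: int


def subsample_coverage(
    site: SiteCounts,
    target: int = DEFAULT_TARGET_COVERAGE,
    max_cov: int = DEFAULT_MAX_COVERAGE,
    min_cov: int = DEFAULT_MIN_COVERAGE,
    with_replacement: bool = True,
    seed: int | np.random.Generator = 0,
) -> SiteCounts:
    """Standardise a site to exactly ``target`` draws (multinomial, with
    replacement by default).  Sites outside [min_cov, max_cov] are flagged
    unusable and returned unchanged."""
    if target <= 0:
        raise ValueError("target coverage must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = site.coverage
    if cov < min_cov or cov > max_cov:
        return SiteCounts(site.chromosome, site.position, site.counts.copy(), usable=False)
    p = np.asarray(site.counts, float) / cov
    if with_replacement:
        new = rng.multinomial(target, p)
    else:
        pool = np.repeat(np.arange(len(p)), np.asarray(site.counts, int))
        pick = rng.choice(pool, size=min(target, cov), replace=False)
        new = np.bincount(pick, minlength=len(p))
    return SiteCounts(site.chromosome, site.position, new.astype(int), usable=True)


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def site_pi(counts: np.ndarray, min_count: int = 0) -> float:
    """Per-site heterozygosity (n/(n-1)) * (1 - sum f_i^2); alleles with
    count < min_count are treated as absent."""
    c = np.asarray(counts, float)
    c = c[c >= max(min_count, 1)] if min_count > 1 else c[c > 0]
    n = c.sum()
    if n < 2 or c.size < 2:
        return 0.0
    f = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(f**2)))


def window_diversity(
    sites: Iterable[SiteCounts],
    pool_size: int = DEFAULT_POOL_SIZE,
    window: int = DEFAULT_WINDOW_BP,
    step: int | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    min_cov: int = DEFAULT_MIN_COVERAGE,
    min_covered_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
) -> list[WindowDiversity]:
    """Per-window pi, Watterson's theta and Tajima's D from subsampled sites.

    ``step`` defaults to ``window`` (non-overlapping).  A site contributes if
    usable and covered >= min_cov; segregation requires a minor allele with
    count >= min_count.  n for the estimator constants is the site draw count
    (post-subsampling these are all equal).  Windows below the covered
    fraction, or with zero usable sites, are omitted (logged).
    """
    step = window if step is None else step
    by_chrom: dict[str, list[SiteCounts]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s)
    out: list[WindowDiversity] = []
    for chrom, ss in by_chrom.items():
        ss.sort(key=lambda s: s.position)
        max_pos = ss[-1].position
        start = 1
        while start <= max_pos:
            end = start + window - 1
            in_win = [s for s in ss if start <= s.position <= end
                      and s.usable and s.coverage >= min_cov]
            if not in_win:
                log.info("window %s:%d-%d has no usable sites; omitted", chrom, start, end)
                start += step
                continue
            frac = len(in_win) / window
            if frac < min_covered_fraction:
                start += step
                continue
            n = int(in_win[0].coverage)
            const = _tajima_constants(n)
            pi_sum = 0.0
            S = 0
            for s in in_win:
                c = np.asarray(s.counts, float)
                keep = c[c >= min_count]
                if keep.size >= 2:
                    S += 1
                    pi_sum += site_pi(keep)
            L = len(in_win)
            theta_sum = S / const["a1"]
            if S > 0:
                denom = np.sqrt(const["e1"] * S + const["e2"] * S * (S - 1))
                d = float((pi_sum - theta_sum) / denom) if denom > 0 else None
            else:
                d = None
            out.append(
                WindowDiversity(
                    chrom, start, end,
                    pi_per_site=pi_sum / L,
                    theta_per_site=theta_sum / L,
                    tajimas_d=d,
                    covered_fraction=frac,
                    n_sites=L,
                    n_segregating=S,
                )
            )
            start += step
    return out


def windows_to_frame(wins: Sequence[WindowDiversity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.chromosome, w.start, w.end, w.pi_per_site, w.theta_per_site,
             w.tajimas_d, w.covered_fraction, w.n_sites, w.n_segregating)
            for w in wins
        ],
        columns=["chrom", "start", "end", "pi", "theta", "tajimas_d",
                 "covered_fraction", "n_sites", "n_segregating"],
    )


# ---------------------------------------------------------------------------
# pairwise F_ST between lines
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    line_ids: list[str]
    values: np.ndarray          # symmetric, diagonal 0, clamped to [0, 1]
    raw: np.ndarray             # unclamped ratio-of-averages
    n_sites: np.ndarray         # variable sites per pair

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def pairwise_fst(G: GenotypeMatrix, universe: str = "pair") -> FstMatrix:
    """Hudson-style pairwise F_ST between inbred lines.

    A line is a two-allele 'population': within-line alt frequency is 0, 0.5
    (residual het) or 1.  Per site, with n=2 alleles per line,
    num = (p1-p2)^2 - p1(1-p1) - p2(1-p2) and den = p1(1-p2) + p2(1-p1).

    ``universe="pair"`` (default) combines sites variable within the pair as
    a ratio of averages, the robust Hudson form.  For nearly-fixed inbred
    lines this is necessarily large (~0.8-0.95): concordantly fixed sites
    contribute nothing to either sum, so the estimate is dominated by
    oppositely fixed sites.  ``universe="panel"`` instead averages per-site
    values over ALL panel-variable sites called in both lines, counting
    concordantly fixed sites as 0 — a mean-of-ratios convention whose value
    approximates the chance two lines fixed for opposite alleles, landing in
    the 0.2-0.5 range typically printed for inbred-line panels.

    Values are clamped into [0, 1] for reporting; the raw ratio is kept.
    """
    if G.n_lines < 2:
        raise ValueError("need >= 2 lines")
    if universe not in ("pair", "panel"):
        raise ValueError(f"unknown universe {universe!r}")
    code = G.calls.astype(float)
    p = np.where(code == MISSING, np.nan,
                 np.where(code == HET, 0.5, np.where(code == ALT_HOM, 1.0, 0.0)))
    n = G.n_lines
    vals = np.zeros((n, n))
    raw = np.zeros((n, n))
    nsites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            p1, p2 = p[i], p[j]
            ok = ~np.isnan(p1) & ~np.isnan(p2)
            variable = ok & ((p1 != p2) | ((p1 > 0) & (p1 < 1)) | ((p2 > 0) & (p2 < 1)))
            if not variable.any():
                log.info("pair (%s, %s) has no variable sites", G.line_ids[i], G.line_ids[j])
                raw[i, j] = raw[j, i] = np.nan
                vals[i, j] = vals[j, i] = np.nan
                continue
            a, b = p1[variable], p2[variable]
            num = (a - b) ** 2 - a * (1 - a) - b * (1 - b)
            den = a * (1 - b) + b * (1 - a)
            if universe == "pair":
                r = float(num.mean() / den.mean())
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    per_site = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
                # denominator: all panel-variable sites called in both lines
                r = float(per_site.sum() / ok.sum())
            raw[i, j] = raw[j, i] = r
            vals[i, j] = vals[j, i] = min(max(r, 0.0), 1.0)
            nsites[i, j] = nsites[j, i] = int(variable.sum())
    return FstMatrix(list(G.line_ids), vals, raw, nsites)


def cluster_lines(F: FstMatrix) -> np.ndarray:
    """Complete-linkage hierarchical clustering of lines on F_ST distance.

    Returns the scipy linkage matrix; leaf order is the line-id order of the
    F_ST matrix, which fixes tie-breaking deterministically.
    """
    d = F.condensed()
    if np.isnan(d).any():
        raise ValueError("F_ST matrix has missing entries; cannot cluster")
    return linkage(d, method="complete")


@dataclass(frozen=True)
class PopStructureCheck:
    spearman_r: float
    p_value: float
    n_pairs: int
    tied: bool = False          # degenerate ranks (constant vector)


def structure_check(F: FstMatrix, line_means: dict[str, float]) -> PopStructureCheck:
    """Correlate pairwise F_ST with pairwise absolute phenotype distance.

    Spearman rank correlation over the off-diagonal pairs; if either vector
    is constant the correlation is reported as 0 with ``tied=True``.
    A non-significant correlation supports running the association scan
    without a relatedness correction.
    """
    ids = F.line_ids
    if len(ids) < 3:
        raise ValueError("need >= 3 lines for the structure check")
    missing = set(ids) - set(line_means)
    if missing:
        raise ValueError(f"no phenotype mean for lines {sorted(missing)}")
    x, y = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            x.append(F.values[i, j])
            y.append(abs(line_means[ids[i]] - line_means[ids[j]]))
    x, y = np.asarray(x), np.asarray(y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return PopStructureCheck(0.0, 1.0, len(x), tied=True)
    r, p = spearmanr(x, y)
    return PopStructureCheck(float(r), float(p), len(x))


# ---------------------------------------------------------------------------
# pseudo-pileup from a genotype matrix (pipeline convenience)
# ---------------------------------------------------------------------------

def site_counts_from_genotypes(
    G: GenotypeMatrix, depth: int = 40, seed: int = 0
) -> list[SiteCounts]:
    """Simulate pooled pseudo-read counts per site from panel allele frequencies."""
    rng = np.random.default_rng(seed)
    freqs = G.allele_frequency()
    out = []
    for j, r in enumerate(G.sites.itertuples(index=False)):
        f = freqs[j]
        if np.isnan(f):
            continue
        alt = rng.binomial(depth, f)
        out.append(SiteCounts(r.chrom, int(r.pos), np.array([depth - alt, alt])))
    return out
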