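"""Linkage-disequilibrium decay: pairwise r^2, hyperbolic fits, landscapes.

LD between SNP pairs is the squared Pearson correlation of homozygous allele
codes across lines (heterozygous and missing calls excluded pairwise).  The
decay model is r^2 = 1/(1 + p*x) with x the pair distance in bp; the
half-decay distance is 1/p exactly, and the distance at which the curve
crosses a level r^2 = v is (1/v - 1)/p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .genotypes import ALT_HOM, REF_HOM, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 1_000_000     # pair distance cap, bp
DEFAULT_MIN_COMPLETE = 10        # minimum lines complete at both SNPs


class FitError(RuntimeError):
    """Nonlinear decay fit failed to converge."""


def pairwise_r2(
    G: GenotypeMatrix,
    max_dist: int = DEFAULT_MAX_DIST,
    min_complete: int = DEFAULT_MIN_COMPLETE,
    max_pairs: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to ``max_dist`` apart.

    Returns a DataFrame (i, j, chrom, dist, r2, n) with global SNP indices.
    Pairs with fewer than ``min_complete`` pairwise-complete lines, or with a
    SNP monomorphic within the complete subset, are skipped (counted).  If
    ``max_pairs`` is set, candidate pairs are subsampled reproducibly.
    """
    x = np.where((G.calls == REF_HOM) | (G.calls == ALT_HOM),
                 (G.calls == ALT_HOM).astype(float), np.nan)
    chroms = G.sites["chrom"].to_numpy()
    pos = G.sites["pos"].to_numpy()
    cand_i, cand_j = [], []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        for a in range(idx.size):
            hi = np.searchsorted(p, p[a] + max_dist, side="right")
            if hi > a + 1:
                cand_i.append(np.full(hi - a - 1, idx[a]))
                cand_j.append(idx[a + 1 : hi])
    if not cand_i:
        return pd.DataFrame(columns=["i", "j", "chrom", "dist", "r2", "n"])
    ii = np.concatenate(cand_i)
    jj = np.concatenate(cand_j)
    if max_pairs is not None and ii.size > max_pairs:
        keep = np.random.default_rng(seed).choice(ii.size, size=max_pairs, replace=False)
        keep.sort()
        ii, jj = ii[keep], jj[keep]
    n_skipped = 0
    rows_i, rows_j, rows_r2, rows_n = [], [], [], []
    for a, b in zip(ii, jj):
        xa, xb = x[:, a], x[:, b]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        n_ok = int(ok.sum())
        if n_ok < min_complete:
            n_skipped += 1
            continue
        u, v = xa[ok], xb[ok]
        su, sv = u.std(), v.std()
        if su == 0.0 or sv == 0.0:
            n_skipped += 1
            continue
        r = float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))
        rows_i.append(a)
        rows_j.append(b)
        rows_r2.append(r * r)
        rows_n.append(n_ok)
    if n_skipped:
        log.info("skipped %d pairs (incomplete or monomorphic)", n_skipped)
    rows_i = np.asarray(rows_i, dtype=int)
    out = pd.DataFrame(
        {
            "i": rows_i,
            "j": np.asarray(rows_j, dtype=int),
            "chrom": chroms[rows_i] if rows_i.size else np.array([], dtype=object),
            "dist": pos[np.asarray(rows_j, dtype=int)] - pos[rows_i] if rows_i.size else
                    np.array([], dtype=int),
            "r2": rows_r2,
            "n": rows_n,
        }
    )
    return out


@dataclass(frozen=True)
class LDDecayFit:
    """Fitted hyperbolic decay r^2 = 1/(1 + p*x)."""

    p: float                     # per bp, > 0 (0 flags the degenerate boundary)
    n_pairs: int
    rss: float = float("nan")
    boundary: bool = False       # True when p collapsed to ~0 (r^2 flat at 1)

    @property
    def half_decay_bp(self) -> float:
        """Distance at which r^2 = 0.5; equals 1/p by construction."""
        return np.inf if self.p == 0 else 1.0 / self.p


def fit_decay(pairs: pd.DataFrame, p0: float | None = None, xtol: float = 1e-12) -> LDDecayFit:
    """Nonlinear least squares for p in r^2 = 1/(1 + p*x).

    Deterministic given inputs: start at p0 = 1/median(distance) and solve
    with trust-region least squares (bounded p >= 0).  Requires >= 10 pairs
    spanning at least two distance decades.
    """
    if len(pairs) < 10:
        raise ValueError("need >= 10 pairs to fit the decay model")
    x = pairs["dist"].to_numpy(float)
    y = pairs["r2"].to_numpy(float)
    if np.log10(x.max() / max(x.min(), 1.0)) < 1.0:
        log.warning("pair distances span < 2 decades; fit may be ill-conditioned")
    if p0 is None:
        p0 = 1.0 / max(float(np.median(x)), 1.0)
    res = least_squares(
        lambda p: 1.0 / (1.0 + p[0] * x) - y, x0=[p0], bounds=([0.0], [np.inf]), xtol=xtol
    )
    if not res.success:
        raise FitError(f"decay fit did not converge: {res.message}")
    p = float(res.x[0])
    boundary = p < 1.0 / (10.0 * x.max())    # half-decay beyond 10x the data span
    if boundary:
        log.warning("decay rate collapsed to boundary p ~ 0 (flat r^2)")
    return LDDecayFit(p=p, n_pairs=len(pairs), rss=float(2 * res.cost), boundary=boundary)


def distance_at_r2(fit: LDDecayFit, level: float) -> float:
    """Distance (bp) at which the fitted curve falls to ``level``: (1/level - 1)/p."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if fit.p == 0:
        return np.inf
    return (1.0 / level - 1.0) / fit.p


def decay_landscape(
    G: GenotypeMatrix,
    max_dist: int = DEFAULT_MAX_DIST,
    min_complete: int = DEFAULT_MIN_COMPLETE,
    min_pairs: int = 10,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-focal-SNP hyperbolic fits over flanking pairs (landscape table).

    Each SNP is fitted on all its pairs within ``max_dist`` up- and
    down-stream.  SNPs with < ``min_pairs`` usable pairs or failed fits get
    NaN.  Returns (chrom, pos, n_pairs, half_decay_bp, log10_half_decay).
    """
    if pairs is None:
        pairs = pairwise_r2(G, max_dist=max_dist, min_complete=min_complete)
    half = np.full(G.n_snps, np.nan)
    npairs = np.zeros(G.n_snps, dtype=int)
    if len(pairs):
        by_snp: dict[int, list[int]] = {}
        for row, (a, b) in enumerate(zip(pairs["i"].to_numpy(), pairs["j"].to_numpy())):
            by_snp.setdefault(int(a), []).append(row)
            by_snp.setdefault(int(b), []).append(row)
        for s, rows in by_snp.items():
            sub = pairs.iloc[rows]
            npairs[s] = len(sub)
            if len(sub) < min_pairs:
                continue
            try:
                fit = fit_decay(sub)
            except (FitError, ValueError):
                continue
            half[s] = fit.half_decay_bp
    with np.errstate(divide="ignore", invalid="ignore"):
        log10_half = np.log10(half)
    return pd.DataFrame(
        {
            "chrom": G.sites["chrom"],
            "pos": G.sites["pos"],
            "n_pairs": npairs,
            "half_decay_bp": half,
            "log10_half_decay": log10_half,
        }
    )
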