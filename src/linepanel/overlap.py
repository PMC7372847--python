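"""Windowed rank-overlap test for a shared genetic basis of two traits.

Within each genomic window the SNPs are ranked by association p-value
separately for each trait; for an increasing rank cutoff r the overlap
between the two top-r sets is scored with the exact two-set intersection
(hypergeometric upper tail) against a universe of the window's SNP count.
The window's summary p is the minimum over cutoffs, and its significance is
judged against the same summary computed on scans where SNP identities were
permuted: a window is flagged only if the observed summary p undercuts every
one of the permuted summaries.  The permutation absorbs the min-over-cutoffs
selection, so no further multiplicity correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (25_000, 50_000, 100_000, 200_000, 400_000)
DEFAULT_N_PERM = 100
DEFAULT_MAX_RANK = 25


def overlap_exact_p(k: int, n_a: int, n_b: int, universe: int) -> float:
    """Exact upper-tail intersection probability P(X >= k).

    X is the overlap of a uniformly random n_a-subset with a fixed n_b-subset
    of a ``universe``-element window: hypergeometric with n_a draws and n_b
    successes.  k = 0 returns 1 (the tail includes zero overlap).
    """
    if not (0 <= k <= min(n_a, n_b) <= universe) or max(n_a, n_b) > universe:
        raise ValueError(f"inconsistent sizes k={k}, nA={n_a}, nB={n_b}, N={universe}")
    return float(hypergeom.sf(k - 1, universe, n_b, n_a))


@dataclass
class WindowOverlapTest:
    chromosome: str
    start: int                 # 1-based inclusive
    end: int
    window_size: int
    n_snps: int                # universe N
    overlap_counts: list[int]  # k_r per rank cutoff
    cutoff_p: list[float]      # exact p per cutoff
    summary_p: float           # min over cutoffs
    perm_summary_p: np.ndarray | None = None
    significant: bool | None = None


def _window_summary(order_a: np.ndarray, order_b: np.ndarray, n: int,
                    max_rank: int) -> tuple[list[int], list[float], float]:
    """Overlap counts and exact p per cutoff for one window.

    ``order_a``/``order_b``: SNP indices sorted by ascending p per trait.
    """
    rmax = min(max_rank, n)
    ks, ps = [], []
    in_a = np.zeros(n, dtype=bool)
    in_b = np.zeros(n, dtype=bool)
    for r in range(1, rmax + 1):
        in_a[order_a[r - 1]] = True
        in_b[order_b[r - 1]] = True
        k = int(np.count_nonzero(in_a & in_b))
        ks.append(k)
        ps.append(overlap_exact_p(k, r, r, n))
    return ks, ps, min(ps) if ps else 1.0


def _summaries_for_scan(pos: np.ndarray, pa: np.ndarray, pb: np.ndarray,
                        edges: np.ndarray, max_rank: int,
                        rng: np.random.Generator):
    """Per-window (indices, orders, summary) for one assignment of p to SNPs.

    Ties in p (exact-LD SNP clumps give bit-identical p-values) are broken
    randomly and independently per trait; a shared deterministic tie order
    would manufacture cross-trait agreement out of nothing.
    """
    out = []
    ta = rng.random(pos.size)
    tb = rng.random(pos.size)
    for w in range(edges.size - 1):
        idx = np.flatnonzero((pos >= edges[w]) & (pos < edges[w + 1]))
        if idx.size < 2:
            continue
        sa = np.lexsort((ta[idx], pa[idx]))
        sb = np.lexsort((tb[idx], pb[idx]))
        ks, ps, summ = _window_summary(sa, sb, idx.size, max_rank)
        out.append((w, idx, ks, ps, summ))
    return out


def window_scan(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    max_rank: int = DEFAULT_MAX_RANK,
    seed: int = 0,
) -> list[WindowOverlapTest]:
    """Rank-overlap tests in non-overlapping windows for every window size.

    ``res_a``/``res_b``: association tables (chrom, pos, p) over the same
    SNPs (asserted).  Windows with < 2 SNPs are skipped.  ``seed`` fixes the
    per-trait random tie-breaking.
    """
    a = res_a.dropna(subset=["p"]).reset_index(drop=True)
    b = res_b.dropna(subset=["p"]).reset_index(drop=True)
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValueError("the two result sets must cover the same SNPs")
    tests: list[WindowOverlapTest] = []
    rng = np.random.default_rng(seed)
    for chrom, sub in merged.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        pa = sub["p_a"].to_numpy()
        pb = sub["p_b"].to_numpy()
        for wsize in window_sizes:
            edges = np.arange(1, pos.max() + wsize + 1, wsize)
            for w, idx, ks, ps, summ in _summaries_for_scan(pos, pa, pb, edges,
                                                            max_rank, rng):
                tests.append(
                    WindowOverlapTest(
                        chromosome=str(chrom),
                        start=int(edges[w]),
                        end=int(edges[w + 1] - 1),
                        window_size=int(wsize),
                        n_snps=int(idx.size),
                        overlap_counts=ks,
                        cutoff_p=ps,
                        summary_p=float(summ),
                    )
                )
    return tests


def overlap_permutation(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    n_perm: int = DEFAULT_N_PERM,
    max_rank: int = DEFAULT_MAX_RANK,
    seed: int = 0,
    mode: str = "independent",
) -> list[WindowOverlapTest]:
    """Window scan plus SNP-identity permutation null and significance flags.

    Each permutation re-assigns p-values to SNP positions at random,
    preserving each trait's p-value multiset and every window's SNP count,
    and the scan is re-run; a window is significant iff its observed summary
    p is strictly below all ``n_perm`` permuted summaries for that window.

    ``mode="independent"`` (default) permutes the two traits' assignments
    independently: the null is "no per-SNP coupling between the traits",
    controlling for window SNP-count structure.  ``mode="joint"`` moves the
    (p_a, p_b) pairs together, preserving any genome-wide per-SNP coupling;
    that null asks whether the coupling is concentrated in the window
    beyond what reshuffling the coupled pairs produces — a far stricter
    reference that genuine locally-shared architecture generally cannot
    beat whenever its LD halo leaks outside a single window, so the
    independent mode is the operative test.
    """
    if mode not in ("independent", "joint"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    tests = window_scan(res_a, res_b, window_sizes, max_rank, seed=seed)
    a = res_a.dropna(subset=["p"]).reset_index(drop=True)
    b = res_b.dropna(subset=["p"]).reset_index(drop=True)
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    key = {}
    for t in tests:
        t.perm_summary_p = np.full(n_perm, np.nan)
        key[(t.chromosome, t.window_size, t.start)] = t
    pos_all = merged["pos"].to_numpy()
    chrom_all = merged["chrom"].to_numpy()
    pa_all = merged["p_a"].to_numpy()
    pb_all = merged["p_b"].to_numpy()
    n = len(merged)
    for k in range(n_perm):
        perm = rng.permutation(n)
        if mode == "joint":
            pa, pb = pa_all[perm], pb_all[perm]
        else:
            pa = pa_all[perm]
            pb = pb_all[rng.permutation(n)]
        for chrom in pd.unique(chrom_all):
            cmask = chrom_all == chrom
            pos = pos_all[cmask]
            for wsize in set(t.window_size for t in tests):
                edges = np.arange(1, pos.max() + wsize + 1, wsize)
                for w, idx, _, _, summ in _summaries_for_scan(
                    pos, pa[cmask], pb[cmask], edges, max_rank, rng
                ):
                    t = key.get((str(chrom), int(wsize), int(edges[w])))
                    if t is not None:
                        t.perm_summary_p[k] = summ
    for t in tests:
        t.significant = bool(np.all(t.summary_p < np.nan_to_num(t.perm_summary_p, nan=np.inf)))
    return tests


def overlap_to_frame(tests: Sequence[WindowOverlapTest]) -> pd.DataFrame:
    rows = []
    for t in tests:
        perm_min = (
            float(np.nanmin(t.perm_summary_p))
            if t.perm_summary_p is not None and np.isfinite(t.perm_summary_p).any()
            else np.nan
        )
        rows.append(
            (t.chromosome, t.start, t.end, t.window_size, t.n_snps,
             t.summary_p, perm_min, t.significant)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "window_size", "n_snps",
                 "summary_p", "perm_min_p", "significant"],
    )


def cumulative_overlap_curve(test: WindowOverlapTest) -> pd.DataFrame:
    """Per-cutoff overlap curve for one window (plotting convenience)."""
    r = np.arange(1, len(test.overlap_counts) + 1)
    return pd.DataFrame(
        {"rank": r, "overlap": test.overlap_counts, "exact_p": test.cutoff_p}
    )
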