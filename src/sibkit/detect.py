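"""Sibling-pair recombination break detector.

The detector scans a pair of sibling dosage vectors along one
chromosome. At each variant i it counts the number of loci with
identical dosage in the flanking windows [i-N, i) and [i, i+N), and
forms the indicator

    Z = (N_plus - N_minus) / (a + N - max(N_plus, N_minus))

which is large in magnitude when one window sits in a fully identical
(type 1) region and the other does not. Local maxima of |Z| above a
threshold are called as breaks. Our sign convention follows the formula:
Z > 0 means the right window is the more similar one (the scan is
entering an identity region left to right).

Boundaries between fully identical and partially identical regions are
half of all crossovers, so the method by design detects 1/2 the total
number of breaks; calls within N variants of a chromosome end are
suppressed, an undercount that is documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectorParams",
    "WindowSimilarity",
    "BreakCall",
    "window_similarity",
    "z_indicator",
    "z_profile",
    "call_breaks",
    "match_calls",
    "calibrate",
    "maf_mask",
]

MISSING = -1


@dataclass(frozen=True)
class DetectorParams:
    """Tuning parameters for the sliding-window scan.

    N         flanking-window size in variants
    a         positive denominator offset, a << N
    theta     |Z| calling threshold
    min_sep   minimum variant separation between retained calls
    tau       max mismatches per window still treated as near-maximal
              similarity in diagnostics
    min_frac_observed  windows with fewer co-observed loci than this
              fraction of N are skipped
    """

    N: int = 50
    a: float = 2.0
    theta: float = 5.0
    min_sep: int | None = None
    tau: int = 2
    min_frac_observed: float = 0.8

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError("window size N must be >= 10")
        if not 0 < self.a < self.N:
            raise ValueError("need 0 < a << N")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.min_sep is None:
            object.__setattr__(self, "min_sep", self.N)
        if self.min_sep < self.N:
            raise ValueError("min_sep must be >= N")


class WindowSimilarity(NamedTuple):
    n_minus: int   # identical-in-state loci in [i-N, i)
    n_plus: int    # identical-in-state loci in [i, i+N)
    obs_minus: int  # co-observed loci per window (effective N)
    obs_plus: int


@dataclass(frozen=True)
class BreakCall:
    pair_id: str
    chrom: str
    start_bp: int        # 0-based half-open bp bracket between the
    end_bp: int          # variants flanking the peak
    index: int           # variant index of the peak (break between index-1, index)
    z: float
    direction: str       # "gain_identity" (Z>0) or "loss_identity" (Z<0)

    @property
    def midpoint(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0


def window_similarity(s1: np.ndarray, s2: np.ndarray, i: int, N: int) -> WindowSimilarity:
    """Identical-in-state counts in the two windows flanking variant i.

    Missing dosages (< 0) are excluded pairwise; the co-observed count
    per window is returned alongside.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if not N <= i <= s1.size - N:
        raise ValueError(f"windows around i={i} extend past chromosome ends")
    wl = slice(i - N, i)
    wr = slice(i, i + N)
    ok_l = (s1[wl] >= 0) & (s2[wl] >= 0)
    ok_r = (s1[wr] >= 0) & (s2[wr] >= 0)
    return WindowSimilarity(
        n_minus=int(((s1[wl] == s2[wl]) & ok_l).sum()),
        n_plus=int(((s1[wr] == s2[wr]) & ok_r).sum()),
        obs_minus=int(ok_l.sum()),
        obs_plus=int(ok_r.sum()),
    )


def z_indicator(n_minus: float, n_plus: float, N: int, a: float) -> float:
    """Z = (N+ - N-) / (a + N - max(N+, N-)); antisymmetric under window swap."""
    return (n_plus - n_minus) / (a + N - max(n_plus, n_minus))


def z_profile(
    s1: np.ndarray,
    s2: np.ndarray,
    params: DetectorParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Z over all valid scan positions.

    Returns (indices, Z). Counts use pairwise-complete loci; each
    window's count is rescaled to the nominal N by the co-observed
    fraction, and positions where either window has fewer than
    min_frac_observed * N co-observed loci get Z = 0.
    """
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    N = params.N
    L = s1.size
    if L < 2 * N + 1:
        return np.array([], dtype=int), np.array([])
    ok = ((s1 >= 0) & (s2 >= 0))
    eq = ((s1 == s2) & ok).astype(np.int64)
    ceq = np.concatenate(([0], np.cumsum(eq)))
    cok = np.concatenate(([0], np.cumsum(ok.astype(np.int64))))
    idx = np.arange(N, L - N + 1)
    n_minus = ceq[idx] - ceq[idx - N]
    n_plus = ceq[idx + N] - ceq[idx]
    o_minus = cok[idx] - cok[idx - N]
    o_plus = cok[idx + N] - cok[idx]
    good = (o_minus >= params.min_frac_observed * N) & (o_plus >= params.min_frac_observed * N)
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = np.where(o_minus > 0, n_minus * N / np.maximum(o_minus, 1), 0.0)
        sp = np.where(o_plus > 0, n_plus * N / np.maximum(o_plus, 1), 0.0)
    z = (sp - sm) / (params.a + N - np.maximum(sp, sm))
    z[~good] = 0.0
    return idx, z


def call_breaks(
    s1: np.ndarray,
    s2: np.ndarray,
    positions: np.ndarray,
    params: DetectorParams | None = None,
    pair_id: str = "pair",
    chrom: str = "chr",
) -> list[BreakCall]:
    """Scan one chromosome of one sibling pair and call breaks.

    Candidate peaks are local maxima of |Z| with |Z| >= theta; greedy
    non-maximum suppression keeps the largest |Z| within min_sep
    variants (ties to the smaller index). The reported interval is the
    bp gap between the variants flanking the peak. No calls are made
    within N variants of either chromosome end, so telomeric breaks are
    undercounted by construction.
    """
    if params is None:
        params = DetectorParams()
    positions = np.asarray(positions)
    s1 = np.asarray(s1)
    if s1.size != positions.size:
        raise ValueError("dosages and positions differ in length")
    if s1.size < 2 * params.N + 1:
        import warnings

        warnings.warn(f"chromosome {chrom}: too few variants for N={params.N}; no calls")
        return []
    idx, z = z_profile(s1, s2, params)
    az = np.abs(z)
    # local maxima of |Z| above threshold; plateau duplicates are thinned
    # by the non-maximum suppression below (ties keep the smaller index)
    interior = np.zeros(az.size, dtype=bool)
    if az.size >= 3:
        interior[1:-1] = (az[1:-1] >= az[:-2]) & (az[1:-1] >= az[2:]) & (az[1:-1] >= params.theta)
    cand = np.flatnonzero(interior)
    order = cand[np.lexsort((cand, -az[cand]))]
    kept: list[int] = []
    for c in order:
        if all(abs(c - k) >= params.min_sep for k in kept):
            kept.append(c)
    kept.sort()
    calls = []
    for c in kept:
        i = int(idx[c])
        calls.append(BreakCall(
            pair_id=pair_id, chrom=chrom,
            # 0-based half-open gap strictly between the flanking variants
            start_bp=int(positions[i - 1]), end_bp=int(positions[i]) - 1,
            index=i, z=float(z[c]),
            direction="gain_identity" if z[c] > 0 else "loss_identity",
        ))
    return calls


def maf_mask(genotypes: np.ndarray, min_maf: float = 0.05) -> np.ndarray:
    """Variant mask keeping minor-allele frequency >= min_maf.

    Clusters of low-MAF variants are near-monomorphic and make non-IBD
    regions look identical in state, so they are excluded upstream of
    the scan. genotypes: (individuals, variants), missing < 0.
    """
    g = np.asarray(genotypes, dtype=float)
    g[g < 0] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    return maf >= min_maf


def match_calls(
    calls: Sequence[BreakCall],
    truth_indices: Sequence[int],
    tol_variants: int = 25,
) -> tuple[int, int, int]:
    """Greedy 1-1 matching of calls to truth boundary indices.

    Returns (n_matched, n_calls, n_truth). A call matches a truth
    boundary when their variant indices differ by at most tol_variants.
    """
    truth = sorted(truth_indices)
    used = [False] * len(truth)
    matched = 0
    for call in sorted(calls, key=lambda c: c.index):
        best, best_d = None, tol_variants + 1
        for j, t in enumerate(truth):
            if used[j]:
                continue
            d = abs(call.index - t)
            if d < best_d:
                best, best_d = j, d
        if best is not None and best_d <= tol_variants:
            used[best] = True
            matched += 1
    return matched, len(calls), len(truth)


def calibrate(
    grid: dict[str, Sequence],
    pairs_data: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, Sequence[int]]],
    tol_variants: int = 25,
    edge_exclude: int | None = None,
) -> tuple[DetectorParams, pd.DataFrame]:
    """Grid-search (N, a, theta) against oracle break positions.

    grid maps parameter names ("N", "a", "theta") to candidate values;
    pairs_data is a sequence of (s1, s2, positions, truth_indices)
    tuples, the truth typically from the parent-informed oracle.
    Returns the F1-maximizing parameters on identity-boundary recovery
    plus the full precision/recall table.

    Breaks within ``edge_exclude`` variants of a chromosome end
    (default: the largest window in the grid) are outside the scan's
    reach and are excluded from both the call and the truth sets, so
    the documented telomeric undercount does not distort the scores.
    """
    names = list(grid)
    combos = list(product(*(grid[n] for n in names)))
    if not combos:
        raise ValueError("empty calibration grid")
    if edge_exclude is None:
        edge_exclude = int(max(grid["N"])) if "N" in grid else DetectorParams().N
    rows = []
    for combo in combos:
        kwargs = dict(zip(names, combo))
        params = DetectorParams(**kwargs)
        tp = n_call = n_truth = 0
        for s1, s2, positions, truth_idx in pairs_data:
            L = len(positions)
            lo, hi = edge_exclude, L - edge_exclude
            calls = [c for c in call_breaks(s1, s2, positions, params)
                     if lo <= c.index <= hi]
            truth = [t for t in truth_idx if lo <= t <= hi]
            m, c, t = match_calls(calls, truth, tol_variants)
            tp += m
            n_call += c
            n_truth += t
        precision = tp / n_call if n_call else 0.0
        recall = tp / n_truth if n_truth else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({**kwargs, "precision": precision, "recall": recall, "f1": f1})
    table = pd.DataFrame(rows)
    best = table.sort_values(["f1"] + names, ascending=[False] + [True] * len(names)).iloc[0]
    best_params = DetectorParams(**{n: best[n] for n in names})
    # restore integer types mangled by the DataFrame round trip
    best_params = replace(best_params, N=int(best_params.N))
    return best_params, table
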