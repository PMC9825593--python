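"""Aggregate break catalogs into genetic-map estimates.

The sibling-pair detector records boundaries between fully identical
and partially identical IBD regions, which are an unbiased sample of
half of all crossovers generated by the pair's four meioses. A catalog
of B_c such boundaries on chromosome c over n pairs therefore estimates
the sex-averaged per-meiosis genetic length as

    cM_c = 100 * B_c / (2 * n_pairs)

(4 meioses per pair x 1/2 detection = divisor 2), with a Poisson
standard error 100 * sqrt(B_c) / (2 * n_pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneticMap

__all__ = [
    "BreakCatalog",
    "estimate_map_length",
    "cumulative_map",
    "density_histogram",
    "compare_maps",
    "ancestry_ztest",
    "total_events",
]


@dataclass
class BreakCatalog:
    """Break calls across pairs: a table plus the pair count.

    The table needs columns chrom, start, end (0-based half-open bp
    bracket) and optionally pair_id, z, direction. Break positions for
    binning are interval midpoints.
    """

    calls: pd.DataFrame
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        missing = {"chrom", "start", "end"} - set(self.calls.columns)
        if missing:
            raise ValueError(f"catalog table lacks columns: {sorted(missing)}")

    @classmethod
    def from_calls(cls, calls, n_pairs: int) -> "BreakCatalog":
        rows = [
            (c.pair_id, c.chrom, c.start_bp, c.end_bp, c.z, c.direction)
            for c in calls
        ]
        df = pd.DataFrame(rows, columns=["pair_id", "chrom", "start", "end", "z", "direction"])
        return cls(df, n_pairs)

    @classmethod
    def from_boundaries(cls, boundaries, n_pairs: int) -> "BreakCatalog":
        """Catalog of truth identity boundaries (regions.Boundary)."""
        rows = [
            (b.chrom, b.left_bp, b.right_bp - 1, b.transition) for b in boundaries
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "transition"])
        return cls(df, n_pairs)

    def midpoints(self) -> pd.Series:
        return (self.calls["start"] + self.calls["end"]) / 2.0

    def counts_by_chrom(self) -> pd.Series:
        return self.calls.groupby("chrom").size()


def estimate_map_length(catalog: BreakCatalog) -> pd.DataFrame:
    """Per-chromosome genetic length in cM with Poisson standard errors."""
    counts = catalog.counts_by_chrom()
    denom = 2.0 * catalog.n_pairs
    return pd.DataFrame({
        "chrom": counts.index,
        "B": counts.values,
        "cM": 100.0 * counts.values / denom,
        "SE": 100.0 * np.sqrt(counts.values) / denom,
    }).reset_index(drop=True)


def cumulative_map(
    catalog: BreakCatalog,
    chrom: str,
    bin_bp: int,
    chrom_length_bp: int | None = None,
) -> pd.DataFrame:
    """Cumulative genetic length along one chromosome.

    A running sum of binned break counts rescaled so the endpoint equals
    the estimate_map_length value for the chromosome; an empty catalog
    yields a flat zero curve.
    """
    if bin_bp <= 0:
        raise ValueError("bin size must be positive")
    sub = catalog.calls[catalog.calls["chrom"] == chrom]
    mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
    if chrom_length_bp is None:
        chrom_length_bp = int(sub["end"].max()) if len(sub) else bin_bp
    edges = np.arange(0, chrom_length_bp + bin_bp, bin_bp)
    counts, _ = np.histogram(mids, bins=edges)
    total_cM = 100.0 * len(sub) / (2.0 * catalog.n_pairs)
    cum = np.cumsum(counts)
    curve = total_cM * cum / cum[-1] if cum.size and cum[-1] > 0 else np.zeros(counts.size)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "cum_cM": curve})


def density_histogram(
    catalog: BreakCatalog,
    chrom: str,
    bin_bp: int,
    chrom_length_bp: int | None = None,
) -> pd.DataFrame:
    """Raw break counts per bp bin on one chromosome."""
    if bin_bp <= 0:
        raise ValueError("bin size must be positive")
    sub = catalog.calls[catalog.calls["chrom"] == chrom]
    mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
    if chrom_length_bp is None:
        chrom_length_bp = int(sub["end"].max()) if len(sub) else bin_bp
    edges = np.arange(0, chrom_length_bp + bin_bp, bin_bp)
    counts, _ = np.histogram(mids, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})


def compare_maps(
    est: pd.DataFrame,
    catalog: BreakCatalog,
    refs: dict[str, GeneticMap],
    bin_bp: int = 500_000,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-chromosome length differences and cumulative-curve residuals.

    est is the estimate_map_length table; refs maps chromosome label to
    a reference GeneticMap. Residual curves are computed on the
    reference's bp grid after linear interpolation of the estimated
    cumulative curve. Returns (per-chromosome table, {chrom: residuals}).
    """
    shared = [c for c in est["chrom"] if c in refs]
    if not shared:
        raise ValueError("no shared chromosomes between estimate and reference")
    rows, residuals = [], {}
    for chrom in shared:
        ref = refs[chrom]
        est_cM = float(est.loc[est["chrom"] == chrom, "cM"].iloc[0])
        delta = est_cM - ref.length_cM
        rows.append({
            "chrom": chrom,
            "est_cM": est_cM,
            "ref_cM": ref.length_cM,
            "delta_cM": delta,
            "ratio": est_cM / ref.length_cM if ref.length_cM > 0 else np.nan,
        })
        curve = cumulative_map(catalog, chrom, bin_bp, int(ref.positions[-1]))
        grid = ref.positions.astype(float)
        est_on_grid = np.interp(grid, curve["bin_end"], curve["cum_cM"])
        residuals[chrom] = pd.DataFrame({
            "bp": grid,
            "est_cum_cM": est_on_grid,
            "ref_cum_cM": ref.cum_cM,
            "residual_cM": est_on_grid - ref.cum_cM,
        })
    return pd.DataFrame(rows), residuals


def ancestry_ztest(mean_deviation: float, null_sd: float, n: int) -> float:
    """z = mean deviation over the standard error of a group mean.

    Used to compare a group's mean per-individual break count against a
    null distribution with the given SD.
    """
    if null_sd <= 0:
        raise ValueError("null_sd must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return mean_deviation / (null_sd / np.sqrt(n))


def total_events(n_pairs: int, mean_breaks_per_individual: float) -> float:
    """Catalog size implied by a mean per-individual detected-break count."""
    return n_pairs * 2 * mean_breaks_per_individual
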