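"""IBD region types for sibling pairs, truth segmentation and the trio oracle.

For one sibling pair at one locus there are 16 ordered joint
inheritance patterns (each sib carries one of the father's two
chromatids and one of the mother's two). Grouping by how many parental
sides match between the sibs gives exactly three region types:

* type 1 — identical: both paternal and maternal chromatids match
  (4 of 16 patterns); the sibs are IBD on both sides, so their
  genotypes agree at essentially every locus.
* type 2 — partially identical: exactly one side matches (8 patterns).
* type 3 — no IBD: neither side matches (4 patterns).

A crossover in any one of the four gametes toggles that side's match
state, moving the pair between adjacent types; 1<->3 jumps would need
simultaneous paternal and maternal crossovers at the same point and
are flagged when they appear in discretized data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "InheritancePattern",
    "RegionSegment",
    "Boundary",
    "classify_pair_state",
    "enumerate_pair_states",
    "region_types",
    "segment_truth",
    "label_crossovers",
    "trio_informative_breaks",
]

InheritancePattern = tuple[tuple[str, str], tuple[str, str]]


@dataclass(frozen=True)
class RegionSegment:
    chrom: str
    start_idx: int   # 0-based half-open variant-index range
    end_idx: int
    start_bp: int    # 0-based half-open bp range
    end_bp: int
    region_type: int


@dataclass(frozen=True)
class Boundary:
    """A region-type change between consecutive variants."""

    chrom: str
    index: int            # boundary sits between variants index-1 and index
    left_bp: int          # 1-based bp of the flanking variants
    right_bp: int
    type_left: int
    type_right: int
    side: str             # "paternal" | "maternal" | "both"

    @property
    def midpoint(self) -> float:
        return (self.left_bp + self.right_bp) / 2.0

    @property
    def transition(self) -> str:
        return f"{self.type_left}-{self.type_right}"

    @property
    def is_type12(self) -> bool:
        return {self.type_left, self.type_right} == {1, 2}


def classify_pair_state(pattern: InheritancePattern) -> int:
    """Region type of a joint inheritance pattern ((p1, m1), (p2, m2)).

    Type 1 iff both parental sides match, 2 iff exactly one, 3 iff none.
    """
    (p1, m1), (p2, m2) = pattern
    for c in (p1, m1, p2, m2):
        if c not in ("a", "b"):
            raise ValueError(f"chromatid label must be 'a' or 'b', got {c!r}")
    matches = int(p1 == p2) + int(m1 == m2)
    return 3 - matches


def enumerate_pair_states() -> dict[int, list[InheritancePattern]]:
    """All 16 ordered joint patterns grouped by region type."""
    out: dict[int, list[InheritancePattern]] = {1: [], 2: [], 3: []}
    for p1, m1, p2, m2 in product("ab", repeat=4):
        pat = ((p1, m1), (p2, m2))
        out[classify_pair_state(pat)].append(pat)
    return out


def region_types(inherit_pair: np.ndarray) -> np.ndarray:
    """Per-variant region type (1/2/3) from a (2 sibs, 2 parents, M) truth array."""
    if inherit_pair.ndim != 3 or inherit_pair.shape[:2] != (2, 2):
        raise ValueError("expected inheritance array of shape (2, 2, M)")
    pat_match = inherit_pair[0, 0] == inherit_pair[1, 0]
    mat_match = inherit_pair[0, 1] == inherit_pair[1, 1]
    return (3 - pat_match.astype(np.int8) - mat_match.astype(np.int8)).astype(np.int8)


def segment_truth(
    inherit_pair: np.ndarray,
    positions: np.ndarray,
    chrom: str = "chr",
) -> tuple[list[RegionSegment], list[Boundary]]:
    """Tile a chromosome into constant-type segments and list the boundaries.

    Boundaries carry the causal parental side: the side whose chromatid
    match state toggles across the boundary ("both" marks the unlikely
    simultaneous toggle, i.e. an apparent 1<->3 jump).
    """
    positions = np.asarray(positions)
    if inherit_pair.shape[-1] != positions.size:
        raise ValueError("inheritance vectors and positions differ in length")
    types = region_types(inherit_pair)
    pat_match = inherit_pair[0, 0] == inherit_pair[1, 0]
    mat_match = inherit_pair[0, 1] == inherit_pair[1, 1]

    change = np.flatnonzero(np.diff(types) != 0) + 1
    side_change_p = np.diff(pat_match.astype(np.int8)) != 0
    side_change_m = np.diff(mat_match.astype(np.int8)) != 0

    boundaries: list[Boundary] = []
    for i in change:
        p, m = side_change_p[i - 1], side_change_m[i - 1]
        side = "both" if (p and m) else ("paternal" if p else "maternal")
        boundaries.append(Boundary(
            chrom=chrom, index=int(i),
            left_bp=int(positions[i - 1]), right_bp=int(positions[i]),
            type_left=int(types[i - 1]), type_right=int(types[i]),
            side=side,
        ))

    edges = np.concatenate(([0], change, [types.size]))
    segments = [
        RegionSegment(
            chrom=chrom,
            start_idx=int(a), end_idx=int(b),
            # 0-based half-open bp: from the first variant's base to one
            # past the last variant's base
            start_bp=int(positions[a]) - 1, end_bp=int(positions[b - 1]),
            region_type=int(types[a]),
        )
        for a, b in zip(edges[:-1], edges[1:])
    ]
    return segments, boundaries


def label_crossovers(cohort) -> pd.DataFrame:
    """Classify every true crossover by the region transition it causes.

    A crossover toggles its own side's chromatid match state, so the
    transition type is set by the *other* side's match state at the
    crossover position: other side matching -> 1<->2, otherwise 2<->3.
    The other side's state is evaluated exactly from the crossover sets,
    independent of the variant grid.
    """
    rows = []
    other = {"pat": "mat", "mat": "pat"}
    for pair, sib, parent, chrom, bp, _ in cohort.crossovers.itertuples(index=False, name=None):
        o = other[parent]
        m1 = _label_at(cohort.crossover_sets[(pair, 0, o, chrom)], bp)
        m2 = _label_at(cohort.crossover_sets[(pair, 1, o, chrom)], bp)
        rows.append((pair, sib, parent, chrom, bp, "1-2" if m1 == m2 else "2-3"))
    return pd.DataFrame(rows, columns=["pair", "sib", "parent", "chrom", "bp", "transition"])


def _label_at(xo, bp: float) -> int:
    start = 0 if xo.start_chromatid == "a" else 1
    return (start + int(np.searchsorted(xo.positions_bp, bp, side="left"))) % 2


def trio_informative_breaks(
    father: np.ndarray,
    mother: np.ndarray,
    sib1: np.ndarray,
    sib2: np.ndarray,
    positions: np.ndarray,
    chrom: str = "chr",
    smooth_window: int = 5,
) -> dict:
    """Parent-informed break oracle from a genotyped quartet.

    At father-informative sites (father heterozygous, mother homozygous)
    the transmitted paternal allele of each sib is its dosage minus the
    mother's homozygous allele; runs of the sib1-vs-sib2 agreement
    indicator over consecutive informative sites are piecewise constant
    and toggle exactly at paternal-side breaks. Symmetrically for the
    mother. A running majority vote over ``smooth_window`` informative
    sites absorbs isolated genotyping errors; Mendelian-inconsistent
    sites are skipped and counted.

    Returns {"paternal": intervals, "maternal": intervals,
    "skipped": {...}} where intervals is a list of (left_bp, right_bp)
    0-based half-open brackets between the flanking informative sites.
    """
    father = np.asarray(father)
    mother = np.asarray(mother)
    positions = np.asarray(positions)
    out: dict = {"skipped": {}}
    for name, het, hom in (("paternal", father, mother), ("maternal", mother, father)):
        informative = (het == 1) & ((hom == 0) | (hom == 2))
        idx = np.flatnonzero(informative)
        if idx.size == 0:
            out[name] = []
            out["skipped"][name] = 0
            continue
        hom_allele = (hom[idx] // 2).astype(np.int8)
        t1 = np.asarray(sib1)[idx] - hom_allele
        t2 = np.asarray(sib2)[idx] - hom_allele
        ok = (t1 >= 0) & (t1 <= 1) & (t2 >= 0) & (t2 <= 1)
        out["skipped"][name] = int((~ok).sum())
        idx, t1, t2 = idx[ok], t1[ok], t2[ok]
        if idx.size < 2:
            out[name] = []
            continue
        agree = (t1 == t2).astype(np.int8)
        agree = _majority_smooth(agree, smooth_window)
        toggles = np.flatnonzero(np.diff(agree) != 0) + 1
        out[name] = [
            (int(positions[idx[i - 1]]), int(positions[idx[i]]) - 1)
            for i in toggles
        ]
    return out


def _majority_smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Running majority vote with window w (ties keep the current value)."""
    if w <= 1 or x.size < w:
        return x
    half = w // 2
    padded = np.pad(x, (half, half), mode="edge")
    csum = np.concatenate(([0], np.cumsum(padded)))
    window_sum = csum[w:] - csum[:-w]
    out = x.copy()
    out[window_sum * 2 > w] = 1
    out[window_sum * 2 < w] = 0
    return out
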