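"""Meiosis and sibling-cohort simulation.

This module is the ground-truth engine for the rest of the package. It
draws crossovers along a genetic map (Poisson by default, optionally a
stationary gamma-renewal process to model crossover interference),
assembles gametes from phased parental haplotypes, and produces sibling
genotypes together with full inheritance truth records, additive
polygenic scores and phenotypes under configurable assortative mating
and narrow-sense heritability.

Genetic distance conventions: map positions are 1-based base pairs;
cumulative genetic distance is in centiMorgans (cM), 100 cM = 1 Morgan =
1 expected crossover per meiosis across the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "InterferenceParams",
    "CrossoverSet",
    "MatingConfig",
    "SimulatedCohort",
    "sample_crossovers",
    "make_gamete",
    "simulate_sib_pairs",
    "SIB_METHOD_CHROMOSOME_CM",
    "default_genome_maps",
]


@dataclass(frozen=True)
class GeneticMap:
    """A monotone bp -> cumulative-cM curve for one chromosome.

    positions are 1-based and strictly increasing; cum_cM is
    non-decreasing and starts at 0.
    """

    chrom: str
    positions: np.ndarray
    cum_cM: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cum_cM, dtype=np.float64)
        if pos.size == 0:
            raise ValueError("genetic map must have at least one point")
        if pos.size != cm.size:
            raise ValueError("positions and cum_cM must have equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"map positions not strictly increasing on {self.chrom}")
        if np.any(np.diff(cm) < 0):
            bad = int(np.flatnonzero(np.diff(cm) < 0)[0]) + 1
            raise ValueError(f"cumulative cM decreases at row {bad} on {self.chrom}")
        if cm[0] != 0.0:
            raise ValueError("cumulative cM must start at 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cum_cM", cm)

    @property
    def length_cM(self) -> float:
        return float(self.cum_cM[-1])

    @property
    def length_bp(self) -> int:
        return int(self.positions[-1] - self.positions[0])

    def bp_to_cM(self, bp) -> np.ndarray:
        """Interpolate cumulative cM at physical position(s)."""
        return np.interp(bp, self.positions, self.cum_cM)

    def cM_to_bp(self, cm) -> np.ndarray:
        """Inverse interpolation: map cumulative cM back to bp.

        Flat (zero-rate) stretches invert to their left edge.
        """
        return np.interp(cm, self.cum_cM, self.positions)

    @classmethod
    def uniform(cls, chrom: str, length_bp: int, length_cM: float,
                start_bp: int = 1) -> "GeneticMap":
        """Constant recombination rate along the chromosome."""
        pos = np.array([start_bp, start_bp + length_bp], dtype=np.int64)
        return cls(chrom, pos, np.array([0.0, length_cM]))

    @classmethod
    def with_hotspot(cls, chrom: str, length_bp: int, length_cM: float,
                     hotspot_center_frac: float = 0.5,
                     hotspot_bp_frac: float = 0.01,
                     hotspot_cM_frac: float = 0.5) -> "GeneticMap":
        """Uniform background plus one hotspot interval.

        The hotspot covers ``hotspot_bp_frac`` of the physical length but
        carries ``hotspot_cM_frac`` of the genetic length.
        """
        if not 0 < hotspot_bp_frac < 1 or not 0 < hotspot_cM_frac < 1:
            raise ValueError("hotspot fractions must be in (0, 1)")
        hs_bp = hotspot_bp_frac * length_bp
        lo = hotspot_center_frac * length_bp - hs_bp / 2
        hi = lo + hs_bp
        if lo <= 0 or hi >= length_bp:
            raise ValueError("hotspot extends past chromosome ends")
        bg_cM = length_cM * (1 - hotspot_cM_frac)
        bg_bp = length_bp - hs_bp
        pos = np.array([1, 1 + lo, 1 + hi, 1 + length_bp], dtype=np.int64)
        cm = np.array([
            0.0,
            bg_cM * lo / bg_bp,
            bg_cM * lo / bg_bp + length_cM * hotspot_cM_frac,
            length_cM,
        ])
        return cls(chrom, pos, cm)


@dataclass(frozen=True)
class InterferenceParams:
    """Crossover-placement process.

    model="poisson" places crossovers independently along the genetic
    map. model="gamma_renewal" draws inter-crossover gaps (in Morgans)
    from a stationary gamma renewal process with shape ``nu`` and unit
    mean rate per Morgan; nu > 1 suppresses nearby double crossovers
    (positive interference), nu = 1 recovers the Poisson process.
    """

    model: str = "poisson"
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("poisson", "gamma_renewal"):
            raise ValueError(f"unknown crossover model {self.model!r}")
        if self.nu < 1:
            raise ValueError("interference shape nu must be >= 1")


@dataclass
class CrossoverSet:
    """Crossover positions for one meiosis on one chromosome."""

    meiosis_id: str
    chrom: str
    positions_bp: np.ndarray  # sorted, float bp within chromosome bounds
    start_chromatid: str      # "a" or "b": chromatid transmitted at the left end

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.float64)
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("crossover positions must be strictly increasing")
        if self.start_chromatid not in ("a", "b"):
            raise ValueError("start_chromatid must be 'a' or 'b'")


@dataclass(frozen=True)
class MatingConfig:
    """Cohort-level simulation parameters.

    assort_m     target spousal PGS correlation, in (-1, 1)
    h2           target narrow-sense heritability Var(PGS)/Var(y), in [0, 1]
    n_variants   total variant count across all chromosomes
    maf_range    per-variant minor-allele frequency ~ Uniform(lo, hi)
    error_rate   per-genotype error rate epsilon: the dosage is replaced
                 by a uniformly random different value
    seed         RNG seed; identical config + seed reproduces the cohort
    """

    assort_m: float = 0.0
    h2: float = 0.5
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.assort_m < 1:
            raise ValueError("assort_m must be in (-1, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_variants < 2:
            raise ValueError("need at least 2 variants")


@dataclass
class SimulatedCohort:
    """A simulated set of sibling pairs with complete truth records.

    Arrays are indexed (pair, sib, variant) or (pair, sib, parent,
    variant); parent axis order is (paternal, maternal). ``inheritance``
    holds the transmitted-chromatid label per variant (0 = a, 1 = b).
    At every non-error site the offspring genotype equals the paternal
    gamete allele plus the maternal gamete allele.
    """

    maps: list[GeneticMap]
    variant_chrom: np.ndarray       # chromosome label per variant
    variant_pos: np.ndarray         # 1-based bp per variant
    variant_maf: np.ndarray
    beta: np.ndarray                # per-allele effect sizes
    father_haps: np.ndarray         # (pair, 2 chromatids, variant) uint8
    mother_haps: np.ndarray
    inheritance: np.ndarray         # (pair, sib, parent, variant) uint8
    genotypes: np.ndarray           # observed dosages, (pair, sib, variant) int8
    true_genotypes: np.ndarray      # error-free dosages
    crossovers: "pd.DataFrame"      # pair, sib, parent, chrom, bp, start_chromatid
    crossover_sets: dict            # (pair, sib, parent, chrom) -> CrossoverSet
    true_scores: np.ndarray         # (pair, sib)
    parent_scores: np.ndarray       # (pair, 2): father, mother
    phenotypes: np.ndarray | None   # (pair, sib), None when h2 == 0
    config: MatingConfig

    @property
    def n_pairs(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[2]

    def sample_ids(self) -> list[str]:
        return [f"pair{p}_sib{s}" for p in range(self.n_pairs) for s in (1, 2)]

    def genotype_matrix(self) -> np.ndarray:
        """Observed dosages as (individual, variant), row order = sample_ids()."""
        n, _, m = self.genotypes.shape
        return self.genotypes.reshape(n * 2, m)


# Per-chromosome genetic lengths (cM) of the 22 human autosomes as
# estimated by the sibling-pair method on biobank data; they sum to
# 3338.0 cM and serve as the default genome-scale map lengths.
SIB_METHOD_CHROMOSOME_CM = {
    "1": 261.4, "2": 266.4, "3": 212.4, "4": 202.1, "5": 194.5,
    "6": 186.8, "7": 174.9, "8": 162.1, "9": 157.4, "10": 162.6,
    "11": 155.0, "12": 159.7, "13": 122.7, "14": 114.1, "15": 121.5,
    "16": 121.3, "17": 119.6, "18": 109.9, "19": 98.3, "20": 98.7,
    "21": 75.4, "22": 65.2,
}


def default_genome_maps(bp_per_cM: float = 1_000_000.0) -> list[GeneticMap]:
    """Uniform-rate maps for a 22-autosome genome totalling 3338 cM."""
    return [
        GeneticMap.uniform(c, int(round(l * bp_per_cM)), l)
        for c, l in SIB_METHOD_CHROMOSOME_CM.items()
    ]


def sample_crossovers(
    gmap: GeneticMap,
    interference: InterferenceParams | None = None,
    rng: np.random.Generator | None = None,
    meiosis_id: str = "",
) -> CrossoverSet:
    """Draw one meiosis' crossover positions along a genetic map.

    Under the Poisson model the break count is Poisson(L) for a map of
    L Morgans and positions are uniform in cumulative-cM space (then
    mapped to bp by inverse interpolation). Under the gamma-renewal
    model, inter-crossover gaps in Morgans follow a stationary gamma
    renewal with shape nu and unit mean rate per Morgan.
    """
    if interference is None:
        interference = InterferenceParams()
    if rng is None:
        rng = np.random.default_rng()
    L = gmap.length_cM / 100.0  # Morgans
    if interference.model == "poisson" or interference.nu == 1.0:
        k = rng.poisson(L)
        cm = np.sort(rng.uniform(0.0, gmap.length_cM, size=k))
    else:
        cm = _gamma_renewal_points(L, interference.nu, rng) * 100.0
    bp = gmap.cM_to_bp(cm)
    # collapse ties produced by flat map stretches
    if bp.size > 1:
        bp = bp[np.concatenate(([True], np.diff(bp) > 0))]
    start = "a" if rng.random() < 0.5 else "b"
    return CrossoverSet(meiosis_id, gmap.chrom, bp, start)


def _gamma_renewal_points(L: float, nu: float, rng: np.random.Generator) -> np.ndarray:
    """Event positions in [0, L] Morgans of a stationary gamma renewal.

    Gaps ~ Gamma(nu, scale=1/nu) (unit mean). Stationarity: the first
    event is U * G' where G' is the length-biased gap Gamma(nu+1, 1/nu).
    """
    if L <= 0:
        return np.array([])
    points = []
    t = rng.uniform() * rng.gamma(nu + 1.0, 1.0 / nu)
    while t <= L:
        points.append(t)
        t += rng.gamma(nu, 1.0 / nu)
    return np.array(points)


def make_gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    xo: CrossoverSet,
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a gamete from a parental chromatid pair and a crossover set.

    The transmitted chromatid starts at ``xo.start_chromatid`` and
    toggles a<->b at every break. Returns (alleles, labels) where
    labels[v] is 0 for chromatid a, 1 for chromatid b — the per-variant
    inheritance truth.
    """
    positions = np.asarray(positions)
    if hap_a.shape != hap_b.shape or hap_a.shape[-1] != positions.size:
        raise ValueError("haplotype/position length mismatch")
    parity = np.searchsorted(xo.positions_bp, positions, side="left") % 2
    start = 0 if xo.start_chromatid == "a" else 1
    labels = ((start + parity) % 2).astype(np.uint8)
    alleles = np.where(labels == 0, hap_a, hap_b).astype(np.uint8)
    return alleles, labels


def _allocate_variants(maps: list[GeneticMap], n_variants: int) -> tuple[np.ndarray, ...]:
    """Spread n_variants across chromosomes proportionally to genetic length.

    Within a chromosome markers are placed uniformly in genetic
    distance (equal cM per marker gap) and span the full mapped
    interval. This keeps the chance of two crossovers cancelling inside
    one marker gap uniformly small even on hotspot maps, which matters
    at scaled-down marker counts; real arrays are dense enough that the
    placement rule is immaterial.
    """
    lengths = np.array([m.length_cM for m in maps], dtype=float)
    if lengths.sum() <= 0:
        counts = np.full(len(maps), max(2, n_variants // len(maps)))
    else:
        counts = np.maximum(2, np.round(n_variants * lengths / lengths.sum()).astype(int))
    chroms, pos, final = [], [], []
    for m, k in zip(maps, counts):
        if m.length_cM > 0:
            p = m.cM_to_bp(np.linspace(0.0, m.length_cM, k))
        else:
            p = np.linspace(m.positions[0], m.positions[-1], k)
        p = np.unique(np.round(p).astype(np.int64))
        chroms.append(np.full(p.size, m.chrom, dtype=object))
        pos.append(p)
        final.append(p.size)
    return np.concatenate(chroms), np.concatenate(pos), np.array(final)


def simulate_sib_pairs(
    n_pairs: int,
    maps: GeneticMap | Sequence[GeneticMap],
    cfg: MatingConfig,
    interference: InterferenceParams | None = None,
    rng: np.random.Generator | None = None,
    share_crossovers: bool = False,
    want_phenotypes: bool = True,
) -> SimulatedCohort:
    """Simulate a cohort of sibling pairs with full truth records.

    Each pair gets fresh parents and 4 independent meioses (sperm + egg
    per sib). Parents are paired by noisy rank matching on their true
    polygenic score so that corr(father PGS, mother PGS) ~= assort_m.
    Phenotypes are y = S + e with Var(e) = V(1 - h2)/h2, giving
    Var(S)/Var(y) = h2.

    share_crossovers forces sib2 to reuse sib1's gametes (monozygotic
    twins), useful for identity checks.
    """
    import pandas as pd

    if isinstance(maps, GeneticMap):
        maps = [maps]
    maps = list(maps)
    if not maps:
        raise ValueError("at least one genetic map required")
    if interference is None:
        interference = InterferenceParams()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if want_phenotypes and cfg.h2 == 0:
        raise ValueError("phenotypes requested but h2 = 0; no additive signal")

    variant_chrom, variant_pos, counts = _allocate_variants(maps, cfg.n_variants)
    M = variant_pos.size
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=M)
    beta = rng.normal(0.0, 1.0, size=M) / np.sqrt(M)

    # Phased parental haplotypes: variants independent given haplotype
    # structure (linkage equilibrium in the parents).
    father_haps = (rng.random((n_pairs, 2, M)) < maf).astype(np.uint8)
    mother_haps = (rng.random((n_pairs, 2, M)) < maf).astype(np.uint8)

    father_scores = (father_haps.sum(axis=1) @ beta)
    mother_scores = (mother_haps.sum(axis=1) @ beta)

    # Assortative mating: comonotone (rank) matching of fathers against a
    # noisy copy of the mother score. The noise SD is set analytically so
    # the matched correlation equals assort_m: corr = V/(V + s^2) ** .5.
    m_target = cfg.assort_m
    if m_target != 0.0 and n_pairs > 2:
        # The analytic noise SD (corr = (1 + s^2/V)^-1/2) undershoots
        # slightly in finite samples, so iterate the matching until the
        # realized correlation is within 0.005 of the target.
        V_m = mother_scores.var()
        eta = rng.normal(0.0, 1.0, size=n_pairs)
        f_order = np.argsort(father_scores)
        rho = abs(m_target)
        perm = np.arange(n_pairs)
        for _ in range(12):
            s = np.sqrt(V_m * (1.0 / rho**2 - 1.0)) if rho < 1 else 0.0
            z = mother_scores + s * eta
            z_order = np.argsort(z) if m_target > 0 else np.argsort(-z)
            perm = np.empty(n_pairs, dtype=np.intp)
            perm[f_order] = z_order
            realized = np.corrcoef(father_scores, mother_scores[perm])[0, 1]
            gap = m_target - realized
            if abs(gap) <= 0.005:
                break
            rho = float(np.clip(rho + abs(gap) * np.sign(gap) * np.sign(m_target),
                                1e-3, 0.999))
        mother_haps = mother_haps[perm]
        mother_scores = mother_scores[perm]

    inheritance = np.empty((n_pairs, 2, 2, M), dtype=np.uint8)
    true_genotypes = np.empty((n_pairs, 2, M), dtype=np.int8)
    xo_rows: list[tuple] = []
    xo_sets: dict = {}

    # chromosome slices into the flat variant axis
    offsets = np.concatenate(([0], np.cumsum(counts)))
    parent_names = ("pat", "mat")

    gamete_alleles = np.zeros((n_pairs, 2, 2, M), dtype=np.uint8)
    for ci, gmap in enumerate(maps):
        sl = slice(offsets[ci], offsets[ci + 1])
        pos_c = variant_pos[sl]
        for p in range(n_pairs):
            for s in range(2):
                for par in range(2):
                    if share_crossovers and s == 1:
                        xo = xo_sets[(p, 0, parent_names[par], gmap.chrom)]
                    else:
                        xo = sample_crossovers(
                            gmap, interference, rng,
                            meiosis_id=f"pair{p}:sib{s + 1}:{parent_names[par]}:{gmap.chrom}",
                        )
                    xo_sets[(p, s, parent_names[par], gmap.chrom)] = xo
                    haps = father_haps if par == 0 else mother_haps
                    alleles, labels = make_gamete(haps[p, 0, sl], haps[p, 1, sl], xo, pos_c)
                    gamete_alleles[p, s, par, sl] = alleles
                    inheritance[p, s, par, sl] = labels
                    for bp in xo.positions_bp:
                        xo_rows.append((p, s + 1, parent_names[par], gmap.chrom,
                                        float(bp), xo.start_chromatid))

    true_genotypes[:] = (gamete_alleles[:, :, 0, :] + gamete_alleles[:, :, 1, :]).astype(np.int8)

    genotypes = true_genotypes.copy()
    if cfg.error_rate > 0:
        err = rng.random(genotypes.shape) < cfg.error_rate
        shift = rng.integers(1, 3, size=genotypes.shape).astype(np.int8)
        genotypes = np.where(err, (genotypes + shift) % 3, genotypes).astype(np.int8)

    true_scores = true_genotypes.astype(np.float64) @ beta

    phenotypes = None
    if want_phenotypes and cfg.h2 > 0:
        V = true_scores.var()
        noise_var = V * (1.0 - cfg.h2) / cfg.h2
        phenotypes = true_scores + rng.normal(0.0, np.sqrt(noise_var), size=true_scores.shape)

    crossovers = pd.DataFrame(
        xo_rows, columns=["pair", "sib", "parent", "chrom", "bp", "start_chromatid"]
    )
    return SimulatedCohort(
        maps=maps,
        variant_chrom=variant_chrom,
        variant_pos=variant_pos,
        variant_maf=maf,
        beta=beta,
        father_haps=father_haps,
        mother_haps=mother_haps,
        inheritance=inheritance,
        genotypes=genotypes,
        true_genotypes=true_genotypes,
        crossovers=crossovers,
        crossover_sets=xo_sets,
        true_scores=true_scores,
        parent_scores=np.column_stack([father_scores, mother_scores]),
        phenotypes=phenotypes,
        config=cfg,
    )
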