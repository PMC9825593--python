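"""Sibling-vs-population polygenic score statistics.

For an additive score S = sum_j G_j beta_j, classical population
genetics predicts that under random mating the variance of the score
difference between siblings is half that between random unrelated
pairs, Var(dS)/Var(dU) = 1/2, equivalently sqrt(2) * sd(dS)/sd(dU) = 1.
Spousal resemblance (assortativity m) enters the sibling covariance as
cov(S1, S2) = (V/2)(1 + m), which this module inverts to estimate m.
Narrow-sense heritability captured by a score is estimated both as
Var(S)/Var(y) and as corr(S, y)^2 and the two are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PGSModel",
    "PairSet",
    "DiffStats",
    "AssortativityEstimate",
    "HeritabilityEstimate",
    "FamilyGraph",
    "score",
    "pair_differences",
    "assortativity",
    "heritability",
    "family_closure",
    "center_scores",
    "random_pairing",
]


@dataclass(frozen=True)
class PGSModel:
    """Per-allele effect weights keyed by variant id."""

    variant_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    betas: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        b = np.asarray(self.betas, dtype=float)
        if not np.all(np.isfinite(b)):
            raise ValueError("betas must be finite")
        object.__setattr__(self, "betas", b)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PGSModel":
        return cls(
            tuple(df["variant_id"].astype(str)),
            tuple(df["effect_allele"].astype(str)),
            df["beta"].to_numpy(float),
        )


@dataclass(frozen=True)
class PairSet:
    """(id1, id2) pairs of one kind, with construction metadata."""

    pairs: tuple[tuple[str, str], ...]
    kind: str = "sibling"          # "sibling" | "random"
    seed: int | None = None
    dropped: tuple[str, ...] = ()  # leftover ids a pairing could not place

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")


@dataclass(frozen=True)
class DiffStats:
    sd_dS: float
    sd_dU: float
    ratio: float            # sqrt(2) * sd(dS) / sd(dU)
    ratio_se: float         # bootstrap SE, seeded
    var_ratio: float        # Var(dS) / Var(dU)


@dataclass(frozen=True)
class AssortativityEstimate:
    m: float
    se: float               # jackknife over pairs
    cov: float
    V: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2_ratio: float         # Var(S) / Var(y)
    h2_corr: float          # corr(S, y)^2
    h2_avg: float


@dataclass
class FamilyGraph:
    families: list[frozenset[str]]
    excluded_parent_child: int = 0

    def family_of(self) -> dict[str, int]:
        return {ind: i for i, fam in enumerate(self.families) for ind in fam}


def score(
    dosages: np.ndarray,
    variant_ids: list[str] | np.ndarray,
    model: PGSModel,
) -> tuple[np.ndarray, int]:
    """Score individuals: S_i = sum_j G_ij beta_j.

    dosages: (individuals, variants), missing < 0 replaced by the
    variant's mean observed dosage (substitution count returned).
    Model variants absent from the matrix are ignored; no overlap is an
    error.
    """
    ids = list(map(str, variant_ids))
    col = {v: j for j, v in enumerate(ids)}
    keep = [(col[v], b) for v, b in zip(model.variant_ids, model.betas) if v in col]
    if not keep:
        raise ValueError("no overlap between model variants and genotype matrix")
    cols, betas = zip(*keep)
    G = np.asarray(dosages, dtype=float)[:, list(cols)]
    missing = G < 0
    n_sub = int(missing.sum())
    if n_sub:
        with np.errstate(invalid="ignore"):
            Gm = np.where(missing, np.nan, G)
            means = np.nanmean(Gm, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        G = np.where(missing, means[None, :], G)
    return G @ np.asarray(betas), n_sub


def pair_differences(
    scores: dict[str, float] | pd.Series,
    sib_pairs: PairSet,
    random_pairs: PairSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> DiffStats:
    """SDs of signed score differences for sibling vs random pairs.

    The headline statistic sqrt(2) * sd(dS)/sd(dU) equals 1 under
    additivity and random mating; its SE is a seeded bootstrap over
    pairs.
    """
    s = pd.Series(scores)
    dS = _diffs(s, sib_pairs)
    dU = _diffs(s, random_pairs)
    if dS.size < 30 or dU.size < 30:
        raise ValueError("need at least 30 pairs of each kind")
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        rs = dS[rng.integers(0, dS.size, dS.size)]
        ru = dU[rng.integers(0, dU.size, dU.size)]
        ratios[b] = np.sqrt(2) * rs.std(ddof=1) / ru.std(ddof=1)
    sd_dS = dS.std(ddof=1)
    sd_dU = dU.std(ddof=1)
    return DiffStats(
        sd_dS=float(sd_dS),
        sd_dU=float(sd_dU),
        ratio=float(np.sqrt(2) * sd_dS / sd_dU),
        ratio_se=float(ratios.std(ddof=1)),
        var_ratio=float(dS.var(ddof=1) / dU.var(ddof=1)),
    )


def _diffs(s: pd.Series, pairs: PairSet) -> np.ndarray:
    a = s.loc[[p[0] for p in pairs.pairs]].to_numpy()
    b = s.loc[[p[1] for p in pairs.pairs]].to_numpy()
    return a - b


def assortativity(
    sib_scores: np.ndarray,
    V: float,
) -> AssortativityEstimate:
    """Invert cov(S1, S2) = (V/2)(1 + m) for the assortativity m.

    sib_scores: (n_pairs, 2) sibling score pairs; V: the population
    score variance (from an unrelated reference sample). SE by
    leave-one-pair-out jackknife.
    """
    if V <= 0:
        raise ValueError("population variance V must be positive")
    x = np.asarray(sib_scores, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("sib_scores must have shape (n_pairs, 2)")
    n = x.shape[0]
    cov = float(np.cov(x[:, 0], x[:, 1], ddof=1)[0, 1])
    m = 2.0 * cov / V - 1.0
    if n > 2:
        # leave-one-pair-out jackknife on the covariance, via sum updates
        a, b = x[:, 0], x[:, 1]
        S1, S2, Sab = a.sum(), b.sum(), (a * b).sum()
        cov_i = (Sab - a * b - (S1 - a) * (S2 - b) / (n - 1)) / (n - 2)
        jk = 2.0 * cov_i / V - 1.0
        se = float(np.sqrt((n - 1) / n * np.sum((jk - jk.mean()) ** 2)))
    else:
        se = float("nan")
    return AssortativityEstimate(m=float(m), se=se, cov=cov, V=float(V))


def heritability(scores: np.ndarray, phenotypes: np.ndarray) -> HeritabilityEstimate:
    """Two estimators of the score-captured narrow-sense heritability.

    (1) the variance ratio Var(S)/Var(y); (2) the squared correlation
    corr(S, y)^2; the average of both is the headline value.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(phenotypes, dtype=float).ravel()
    if s.size != y.size:
        raise ValueError("scores and phenotypes differ in length")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(y))):
        raise ValueError("scores and phenotypes must be finite")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("zero phenotype variance")
    h2_ratio = s.var(ddof=1) / vy
    h2_corr = float(np.corrcoef(s, y)[0, 1] ** 2)
    return HeritabilityEstimate(
        h2_ratio=float(h2_ratio),
        h2_corr=h2_corr,
        h2_avg=float((h2_ratio + h2_corr) / 2.0),
    )


def family_closure(
    sib_edges: list[tuple[str, str]],
    parent_child_edges: list[tuple[str, str]] | None = None,
) -> FamilyGraph:
    """Transitive closure of sibling edges into families.

    If A-B and B-C are sibling pairs then A-B-C is one family
    (connected component). Parent-child edges are excluded from the
    closure and counted.
    """
    pc = set(map(frozenset, parent_child_edges or []))
    g = nx.Graph()
    kept = excluded = 0
    for a, b in sib_edges:
        if frozenset((a, b)) in pc:
            excluded += 1
            continue
        g.add_edge(a, b)
        kept += 1
    fams = [frozenset(c) for c in nx.connected_components(g)]
    return FamilyGraph(families=fams, excluded_parent_child=excluded)


def center_scores(
    scores: dict[str, float] | pd.Series,
    families: FamilyGraph | list[frozenset[str]],
    mode: str = "sib_mean",
    parent_scores: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.Series, list[int]]:
    """Center each individual's score within its family.

    mode="sib_mean": subtract the family mean of the sibling scores.
    mode="midparent": subtract (mother + father)/2, with parent_scores
    keyed by family index; families missing a parent are skipped and
    their indices reported.
    """
    s = pd.Series(scores, dtype=float)
    fams = families.families if isinstance(families, FamilyGraph) else families
    out = {}
    skipped: list[int] = []
    for fi, fam in enumerate(fams):
        members = [m for m in fam if m in s.index]
        if not members:
            continue
        if mode == "sib_mean":
            center = s.loc[members].mean()
        elif mode == "midparent":
            if parent_scores is None or fi not in parent_scores:
                skipped.append(fi)
                continue
            mother, father = parent_scores[fi]
            center = (mother + father) / 2.0
        else:
            raise ValueError(f"unknown centering mode {mode!r}")
        for m in members:
            out[m] = s.loc[m] - center
    return pd.Series(out), skipped


def random_pairing(
    ids: list[str],
    sib_edges: list[tuple[str, str]] | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> PairSet:
    """Seeded random pairing with no individual matched to a known sibling.

    Shuffles and pairs consecutively, reshuffling until no pair is a
    sibling pair; an odd leftover individual is dropped and reported.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ids to pair")
    forbidden = set(map(frozenset, sib_edges or []))
    rng = np.random.default_rng(seed)
    dropped: tuple[str, ...] = ()
    for _ in range(max_tries):
        perm = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
        if len(perm) % 2:
            dropped = (perm.pop(),)
        pairs = list(zip(perm[::2], perm[1::2]))
        if all(frozenset(p) not in forbidden for p in pairs):
            return PairSet(tuple(pairs), kind="random", seed=seed, dropped=dropped)
    raise ValueError("could not build a sibling-free random pairing "
                     f"in {max_tries} attempts; constraints may be unsatisfiable")
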