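"""Mixture-model absolute disease risk and the Genetic Health Index.

Case and control polygenic scores are modeled as equal-variance
normals shifted from one another:

    phi(x) = (1 - pi) N(x; mu0, sigma) + pi N(x; mu1, sigma)

with pi the lifetime risk (an external epidemiological input, not the
cohort prevalence). Bayes' rule converts a score x into absolute risk

    r(x) = [1 + (1 - pi)/pi * N(x; mu0, sigma)/N(x; mu1, sigma)]^-1

which is strictly increasing in x when mu1 > mu0. The Genetic Health
Index aggregates risks over diseases d with lifespan weights l_d
(years) and average lifetime risks rho_d:

    I = sum_d l_d (rho_d - r_d)

so I is in life-years, zero for a population-average genome, and
decreasing in each risk score. Because r is nonlinear in x, sibling
index variance need not be half the population value even though that
holds for each underlying score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "RiskModelParams",
    "DiseaseConfig",
    "HealthIndexConfig",
    "mixture_risk",
    "fit_mixture",
    "health_index",
]


@dataclass(frozen=True)
class RiskModelParams:
    """(pi, mu0, mu1, sigma): lifetime risk, control/case mean PGS, control SD."""

    pi: float
    mu0: float
    mu1: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError("lifetime risk pi must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class DiseaseConfig:
    label: str
    lifespan_reduction: float   # l_d, years
    lifetime_risk: float        # rho_d
    params: RiskModelParams

    def __post_init__(self) -> None:
        if self.lifespan_reduction < 0:
            raise ValueError("lifespan reduction must be >= 0")
        if not 0 < self.lifetime_risk < 1:
            raise ValueError("lifetime risk must be in (0, 1)")


@dataclass(frozen=True)
class HealthIndexConfig:
    diseases: tuple[DiseaseConfig, ...]

    @classmethod
    def from_yaml(cls, path) -> "HealthIndexConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        diseases = tuple(
            DiseaseConfig(
                label=d["label"],
                lifespan_reduction=float(d["lifespan_reduction"]),
                lifetime_risk=float(d["lifetime_risk"]),
                params=RiskModelParams(
                    pi=float(d["pi"]), mu0=float(d["mu0"]),
                    mu1=float(d["mu1"]), sigma=float(d["sigma"]),
                ),
            )
            for d in raw["diseases"]
        )
        return cls(diseases)

    def to_yaml(self, path) -> None:
        raw = {"diseases": [
            {
                "label": d.label,
                "lifespan_reduction": d.lifespan_reduction,
                "lifetime_risk": d.lifetime_risk,
                "pi": d.params.pi, "mu0": d.params.mu0,
                "mu1": d.params.mu1, "sigma": d.params.sigma,
            }
            for d in self.diseases
        ]}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def mixture_risk(x, params: RiskModelParams):
    """Absolute risk r(x) under the two-component mixture model.

    Computed via the log-density difference for numerical stability far
    in the tails; returns values strictly inside (0, 1).
    """
    x = np.asarray(x, dtype=float)
    log_ratio = (
        norm.logpdf(x, params.mu0, params.sigma)
        - norm.logpdf(x, params.mu1, params.sigma)
    )
    odds = np.log((1 - params.pi) / params.pi) + log_ratio
    r = 1.0 / (1.0 + np.exp(odds))
    return float(r) if r.ndim == 0 else r


def fit_mixture(scores, case_labels, pi: float) -> RiskModelParams:
    """Fit (mu0, mu1, sigma) from labeled scores; pi is supplied externally.

    Class means are the component means; sigma is the control-group SD
    (the larger class, hence better statistics; the model assumes equal
    SDs). pi must be the lifetime risk, which in general differs from
    the cohort prevalence.
    """
    x = np.asarray(scores, dtype=float)
    lab = np.asarray(case_labels).astype(bool)
    if x.shape != lab.shape:
        raise ValueError("scores and labels differ in shape")
    n_case, n_ctrl = int(lab.sum()), int((~lab).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("each class needs at least 2 members")
    return RiskModelParams(
        pi=pi,
        mu0=float(x[~lab].mean()),
        mu1=float(x[lab].mean()),
        sigma=float(x[~lab].std(ddof=1)),
    )


def health_index(scores_by_disease: dict[str, float | np.ndarray],
                 config: HealthIndexConfig):
    """Genetic Health Index I = sum_d l_d (rho_d - r_d(x_d)), in life-years.

    Every configured disease must have a score; scores may be scalars
    or aligned arrays of individuals.
    """
    missing = [d.label for d in config.diseases if d.label not in scores_by_disease]
    if missing:
        raise ValueError(f"missing scores for diseases: {missing}")
    total = 0.0
    for d in config.diseases:
        r = mixture_risk(np.asarray(scores_by_disease[d.label], dtype=float), d.params)
        total = total + d.lifespan_reduction * (d.lifetime_risk - r)
    return total
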