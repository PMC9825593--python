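import numpy as np
import pytest

from sibkit import simulate as sim


@pytest.fixture(scope="session")
def chr100() -> sim.GeneticMap:
    """A 100 cM uniform-rate chromosome."""
    return sim.GeneticMap.uniform("1", 100_000_000, 100.0)


@pytest.fixture(scope="session")
def base_cohort(chr100) -> sim.SimulatedCohort:
    """30 error-free sibling pairs on one 100 cM chromosome."""
    cfg = sim.MatingConfig(n_variants=1500, error_rate=0.0, seed=11, h2=0.5)
    return sim.simulate_sib_pairs(30, chr100, cfg)


@pytest.fixture(scope="session")
def noisy_cohort(chr100) -> sim.SimulatedCohort:
    """Pairs with a 0.2% per-genotype error rate."""
    cfg = sim.MatingConfig(n_variants=1500, error_rate=0.002, seed=12, h2=0.5)
    return sim.simulate_sib_pairs(20, chr100, cfg)


def truth_type12_indices(cohort, pair: int, chrom: str | None = None):
    """Variant indices of true identity (type 1 <-> 2) boundaries for a pair."""
    from sibkit import regions

    if chrom is None:
        mask = np.ones(cohort.n_variants, dtype=bool)
        label = cohort.maps[0].chrom
    else:
        mask = cohort.variant_chrom == chrom
        label = chrom
    _, bounds = regions.segment_truth(
        cohort.inheritance[pair][:, :, mask], cohort.variant_pos[mask], label
    )
    return [b.index for b in bounds if b.is_type12]
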