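"""Shared fixtures: small synthetic cohorts built once per session."""

import numpy as np
import pytest

from cfmedip.simulate import SimulationParams, build_genome_model, simulate_cohort


def small_params(**overrides) -> SimulationParams:
    """A 2 x 3 Mb genome (~20k bins): fast, still rich enough to analyze."""
    base = dict(
        n_localized=8,
        n_metastatic=8,
        n_chromosomes=2,
        chrom_length=3_000_000,
        centromere_gap=300_000,
        island_spacing=30_000,
        n_hyper=40,
        n_hypo=40,
        n_ldh_bins=20,
        n_alp_bins=20,
        n_fragments=4000,
        cna_min_length=900_000,
        cna_max_length=1_500_000,
        libsize_log_mean=np.log(4e5),
    )
    base.update(overrides)
    return SimulationParams(**base)


def dmr_scale_params(**overrides) -> SimulationParams:
    """30 + 30 samples over ~2,300 bins: the differential-testing regime."""
    base = dict(
        n_localized=30,
        n_metastatic=30,
        n_chromosomes=2,
        chrom_length=350_000,
        centromere_gap=60_000,
        island_spacing=30_000,
        n_hyper=60,
        n_hypo=60,
        n_ldh_bins=30,
        n_alp_bins=30,
        n_fragments=1000,
        cna_segments_per_sample=0,
        libsize_log_mean=np.log(40_000),
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture(scope="session")
def small_cohort():
    params = small_params()
    genome = build_genome_model(params, seed=11)
    return simulate_cohort(genome, params, seed=11)


@pytest.fixture(scope="session")
def dmr_cohort():
    params = dmr_scale_params()
    genome = build_genome_model(params, seed=3)
    return simulate_cohort(genome, params, seed=3)


@pytest.fixture(scope="session")
def toy_genome():
    params = small_params()
    return build_genome_model(params, seed=11)
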