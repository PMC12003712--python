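"""Shared fixtures: small seeded cohorts used across the module test files."""

from dataclasses import replace

import numpy as np
import pytest

from cnvmetabo.simulate import (
    SimulationConfig,
    default_regions,
    simulate_cnv_truth,
    simulate_intensities,
    simulate_phenotypes,
    simulate_probe_map,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_samples=60, n_probes=400, n_metabolites=12, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One seeded cohort with four 15-probe CNV regions and one planted effect."""
    pm = simulate_probe_map(small_config)
    regions = default_regions(pm, n_probes_per_region=15, frequency=0.3)
    r0 = regions[0]
    probe_idx = int(
        np.flatnonzero((pm.chrom == r0.chrom) & (pm.pos >= r0.start) & (pm.pos <= r0.end))[7]
    )
    cfg = replace(
        small_config, regions=regions, effect_table=((probe_idx, 2, 0.8),)
    )
    truth = simulate_cnv_truth(pm, cfg)
    panel = simulate_intensities(truth, pm, cfg)
    phen = simulate_phenotypes(truth, cfg)
    return dict(
        config=cfg,
        probe_map=pm,
        truth=truth,
        panel=panel,
        phen=phen,
        regions=regions,
        effect_probe=probe_idx,
        effect_metabolite=2,
    )
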