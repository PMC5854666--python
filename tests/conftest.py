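"""Shared fixtures: small deterministic landscapes and the two expensive
session-scoped experiments (full demo pipeline run, parameter recovery)."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from nicheshift import enm, predictors, synthetic
from nicheshift.grid import make_grid
from nicheshift.pipeline import RunConfig, run_pipeline
from nicheshift.synthetic import (DEFAULT_PRIORITY, REFERENCE, NicheRanges)

logging.getLogger("nicheshift").setLevel(logging.ERROR)


@pytest.fixture
def small_grid():
    return make_grid(10, 12, 20.0)


@pytest.fixture
def noisefree_climate(small_grid):
    gradients = {
        "temp": synthetic.GradientSpec(base=-2.0, slope=1.0, noise_sd=0.0,
                                       warming_offset=3.0),
        "precip": synthetic.GradientSpec(base=900.0, slope=10.0,
                                         noise_sd=0.0, axis="col"),
    }
    return synthetic.simulate_climate(small_grid, gradients, seed=7)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full default pipeline run (the repository's demo configuration)."""
    outdir = tmp_path_factory.mktemp("demo_run")
    config = RunConfig(seed=1)
    report = run_pipeline(config, outdir)
    return config, outdir, report


@pytest.fixture(scope="session")
def recovery_experiment():
    """Niche-recovery experiment: 20 virtual species with known niches on a
    600-cell grid, sampling rate 1, default committee.

    The cohort is 10 birds and 10 other plants with niches inside the
    observed reference climate (immigrant species have empty reference
    ranges, so recovery is undefined for them). Returns per-species
    Spearman rho between consensus and true suitability, and Jaccard
    between the binarized reference range and the true suitability
    binarized by the same max-TSS rule against the species' own sampled
    occurrences.
    """
    from scipy.stats import spearmanr

    grid = make_grid(30, 20, 20.0)
    climate = synthetic.simulate_climate(
        grid, synthetic.default_gradients(3.0), seed=11)
    species, occurrences = synthetic.simulate_species(
        grid, climate, {"bird": 10, "other_plant": 10},
        niche_ranges=NicheRanges(warm_overshoot=0.0),
        sampling_rate=1.0, seed=12)
    layers = climate.frame(REFERENCE)
    rhos, jaccards = [], []
    for i, sp in enumerate(species):
        pset = predictors.select_predictors(layers, sp.taxon,
                                            priority=DEFAULT_PRIORITY)
        sub = occurrences[occurrences["species_id"] == sp.species_id]
        presence = np.zeros(grid.n_cells, dtype=np.int8)
        presence[sub["cell_id"].to_numpy()] = sub["presence"].to_numpy()
        result = enm.model_species(sp.species_id, sp.taxon, presence, grid,
                                   climate, pset, seed=100 + i)
        assert result.status == "modelled", result.reason
        true_suit = sp.true_suitability(climate, REFERENCE)
        rhos.append(spearmanr(result.maps[REFERENCE].suitability,
                              true_suit).statistic)
        true_range = true_suit >= enm.max_tss_threshold(true_suit, presence)
        model_range = result.maps[REFERENCE].presence.astype(bool)
        union = (true_range | model_range).sum()
        jaccards.append((true_range & model_range).sum() / max(1, union))
    return np.asarray(rhos), np.asarray(jaccards)
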