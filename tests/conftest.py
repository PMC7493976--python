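"""Shared fixtures: pipeline config and session-scoped synthetic scenarios."""

import numpy as np
import pandas as pd
import pytest

from ctcfrep.atlas import build_union_atlas, compute_occupancy
from ctcfrep.config import PipelineConfig
from ctcfrep.specificity import CohortDesign, compute_rpkm, quantile_normalize
from ctcfrep.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture()
def desk_cfg():
    """Pipeline config at the synthetic scenario's scale."""
    return PipelineConfig(min_peaks_per_dataset=100)


@pytest.fixture(scope="session")
def scenario():
    """The default planted scenario (2,000 sites; 8 cancer / 8 normal / 24 other)."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced scenario for end-to-end pipeline runs."""
    return ScenarioConfig(n_sites=300, chrom_length=2_000_000, n_chromosomes=1,
                          n_background_genes_per_chrom=30, seed=7)


@pytest.fixture(scope="session")
def called_scenario(scenario):
    """Atlas, normalized matrix (atlas site ids) and truth labels for seed 1."""
    pcfg = PipelineConfig(min_peaks_per_dataset=100)
    atlas = build_union_atlas(scenario.peak_datasets, pcfg)
    atlas = compute_occupancy(atlas, scenario.peak_datasets, pcfg)
    rpkm = compute_rpkm(scenario.counts, scenario.site_lengths,
                        scenario.library_sizes)
    norm = quantile_normalize(rpkm)
    arrays = atlas.chrom_arrays()
    mapping = {}
    for r in scenario.sites.itertuples(index=False):
        site = atlas.locate(r.chrom, r.center, arrays)
        if site is not None:
            mapping[r.site_id] = site.site_id
    norm_atlas = norm.loc[list(mapping)].copy()
    norm_atlas.index = [mapping[k] for k in norm_atlas.index]
    truth_class = pd.Series(
        {mapping[sid]: cls for sid, cls in scenario.truth.site_class.items()
         if sid in mapping}, name="site_class")
    design = CohortDesign(scenario.design)
    return {"pcfg": pcfg, "atlas": atlas, "norm": norm_atlas,
            "design": design, "truth_class": truth_class,
            "mapping": mapping}
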