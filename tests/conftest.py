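"""Shared fixtures: synthetic populations and fitted models.

Session-scoped fixtures hold the expensive objects (the reference
dichotomised-Gaussian population and models fitted to it) so the suite
pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import spikemaxent as sm

settings.register_profile("suite", derandomize=True, database=None, deadline=None)
settings.load_profile("suite")
from spikemaxent.synthetic import GroundTruthSpec, default_study_population, random_model


@pytest.fixture(scope="session")
def study_raster():
    """60-cell dichotomised-Gaussian population in the reference regime."""
    return default_study_population(n_cells=60, n_bins=100_000, seed=11)


@pytest.fixture(scope="session")
def study_moments(study_raster):
    return sm.compute_moments(study_raster)


@pytest.fixture(scope="session")
def gt_model_n10():
    """Random sparse k-pairwise ground-truth model, N = 10."""
    return random_model(GroundTruthSpec(n_cells=10, seed=1))


@pytest.fixture(scope="session")
def fitted_n12(study_raster):
    """k-pairwise model fitted exactly to a 12-cell subgroup."""
    mom = sm.compute_moments(study_raster.subset(np.arange(12)))
    model, report = sm.fit_maxent(mom, "k-pairwise", gradient_mode="exact", seed=3)
    return model, report, mom
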