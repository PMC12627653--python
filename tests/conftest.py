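"""Shared fixtures: one default synthetic cohort per test session."""

import numpy as np
import pytest

from fpetdyn.pipeline import AnalysisOptions, preprocess_cohort
from fpetdyn.synthio import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort (13 HC vs 14 PD, 90 one-minute frames)."""
    config = SimConfig(seed=11)
    images, table, atlas, truth = generate_cohort(config)
    return {"config": config, "images": images, "table": table,
            "atlas": atlas, "truth": truth}


@pytest.fixture(scope="session")
def options():
    return AnalysisOptions(seed=11, n_perm=200)


@pytest.fixture(scope="session")
def windowed(cohort, options):
    """Smoothed last-30-frame images, raw intensities (for the GLM)."""
    return preprocess_cohort(cohort["images"], cohort["atlas"], options, normalize=False)


@pytest.fixture(scope="session")
def normalized(cohort, options):
    """Smoothed, windowed, global-ratio-normalised images."""
    return preprocess_cohort(cohort["images"], cohort["atlas"], options, normalize=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
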