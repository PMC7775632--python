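"""Shared fixtures: small, fast simulation configurations.

Everything is generated programmatically; no fixture files.
"""

from dataclasses import replace

import numpy as np
import pytest

from steadyfield import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_params():
    """Tiny cohort: fast enough for per-test simulation."""
    return SimulationParams(
        n_per_group=3, n_trials=12, n_vertices=20, seed=11,
        epoch_start=-500.0, epoch_end=1000.0,
    )


@pytest.fixture
def clean_params(small_params):
    """Deterministic single-subject signal: no noise, no jitter, no flips."""
    return replace(
        small_params,
        noise_sd=0.0,
        assr_phase_kappa=np.inf,
        flip_fraction=0.0,
        subject_sf_amp_cv=0.0,
        subject_assr_amp_cv=0.0,
        subject_onset_jitter_sd=0.0,
        trial_sf_amp_cv=0.0,
    )
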