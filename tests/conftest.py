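"""Shared fixtures: small synthetic designs and cohorts.

Fixtures scale the study geometry down (fewer trials, small grids, short
runs) so the full simulate->fit->correlate->infer chain stays fast; the
full-scale study conditions are exercised in the acceptance tests.
"""

import numpy as np
import pytest

import dyadsync as ds


@pytest.fixture(scope="session")
def mini_design():
    """Scaled-down dyadic session: 8 trials/run, 6 runs."""
    return ds.generate_design(11, pair_id="mini", n_trials_per_run=8,
                              control_block_size=2)


@pytest.fixture(scope="session")
def mini_truth():
    return ds.default_ground_truth((8, 8, 8), n_mask_voxels=8,
                                   coupling_task=0.6, coupling_residual=0.5)


@pytest.fixture(scope="session")
def mini_sim(mini_design, mini_truth):
    """One simulated pair on the mini geometry (48 volumes, TR 2.5)."""
    return ds.simulate_pair(mini_design, mini_truth, seed=21, n_volumes=48)


@pytest.fixture(scope="session")
def small_cohort():
    """Four analyzed pairs on a 10^3 grid with injected coupling."""
    truth = ds.default_ground_truth((10, 10, 10), n_mask_voxels=27,
                                    coupling_task=0.6, coupling_residual=0.5)
    cohort = ds.simulate_cohort(4, truth, seed=31, n_volumes=96,
                                n_trials_per_run=16)
    return cohort, truth
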