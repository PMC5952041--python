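"""Shared fixtures: phantoms, tracked bundles and Monte-Carlo summaries.

Heavy artefacts (whole-brain tracking, the end-to-end dissection, the
Monte-Carlo recovery loops) are session-scoped so the expensive work runs
once and is shared between unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from smtract.config import RunConfig
from smtract.gating import sm_pipeline
from smtract.phantom import (
    PhantomSpec,
    build_phantom,
    simulate_group_table,
    simulate_rater_tables,
)
from smtract.reliability import ancova_gender, icc_two_way, partial_correlation
from smtract.tracking import TrackingParams, make_sampler, whole_brain_track


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default phantom with distractors: (spec, tensor, fod, truth)."""
    spec = PhantomSpec()
    tensor, fod, truth = build_phantom(spec)
    return spec, tensor, fod, truth


@pytest.fixture(scope="session")
def phantom_bundle_nodistr():
    spec = PhantomSpec(distractors="none")
    tensor, fod, truth = build_phantom(spec)
    return spec, tensor, fod, truth


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(phantom_bundle, run_config):
    """Full two-pass dissection on the default (distractor) phantom."""
    _, tensor, fod, truth = phantom_bundle
    low, high = run_config.tracking_params()
    return sm_pipeline(
        fod, truth.tracking_mask, truth.landmarks, low, high, tensor_field=tensor
    )


@pytest.fixture(scope="session")
def pipeline_result_nodistr(phantom_bundle_nodistr, run_config):
    _, tensor, fod, truth = phantom_bundle_nodistr
    low, high = run_config.tracking_params()
    return sm_pipeline(
        fod, truth.tracking_mask, truth.landmarks, low, high, tensor_field=tensor
    )


@pytest.fixture(scope="session")
def wb_high(phantom_bundle_nodistr):
    """High-fidelity whole-brain tractogram on the distractor-free phantom."""
    _, _, fod, truth = phantom_bundle_nodistr
    params = TrackingParams.high_fidelity(rng_seed=11)
    return whole_brain_track(fod, truth.tracking_mask, params), params


def streamline_label_fraction(points, mask, grid):
    """Fraction of a streamline's points whose nearest voxel is masked."""
    vox = np.rint(grid.world_to_voxel(points)).astype(int)
    vox = np.clip(vox, 0, np.asarray(grid.shape) - 1)
    return mask[vox[:, 0], vox[:, 1], vox[:, 2]].mean()


@pytest.fixture(scope="session")
def icc_mc():
    """2000-rep ICC recovery at generating ICC 0.9, n=50, 2 raters."""
    estimates = np.empty(2000)
    covered = np.empty(2000, dtype=bool)
    for i in range(2000):
        tab = simulate_rater_tables(
            50, 0.9, metric_means={"fa": 0.25}, rng_seed=100_000 + i
        )
        r = icc_two_way(tab, "fa")
        estimates[i] = r.icc
        covered[i] = r.ci95[0] <= 0.9 <= r.ci95[1]
    return estimates, covered


@pytest.fixture(scope="session")
def partial_mc():
    """2000-rep partial-correlation recovery at true partial r = 0.30, n=50."""
    est = np.empty(2000)
    reject = np.empty(2000, dtype=bool)
    for i in range(2000):
        tab = simulate_group_table(50, rng_seed=200_000 + i, partial_r_age=0.30)
        r, p = partial_correlation(tab, "rd")
        est[i] = r
        reject[i] = p < 0.05
    return est, reject


@pytest.fixture(scope="session")
def ancova_null_mc():
    """1000-rep ANCOVA gender test under a null gender effect."""
    reject = np.empty(1000, dtype=bool)
    for i in range(1000):
        tab = simulate_group_table(50, rng_seed=300_000 + i)
        reject[i] = ancova_gender(tab, "rd").gender_p < 0.05
    return reject
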