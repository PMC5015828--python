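"""Shared synthetic-study fixtures.

Everything is generated programmatically at collection time from fixed
seeds; the heavier session fixtures are module/session scoped so the suite
pays for them once.
"""

import numpy as np
import pytest

import decnef as dn


@pytest.fixture(scope="session")
def gt_small():
    """Compact ground truth: 24-voxel target ROI plus two silent regions."""
    return dn.make_ground_truth(
        n_other_rois=2,
        roi_voxels=20,
        target_voxels=24,
        coupling={"R01": 0.0, "R02": 0.0},
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def pool_selected(gt_small):
    pool = dn.generate_face_pool(400, gt_small, seed=1)
    return dn.select_faces(pool, seed=2)


@pytest.fixture(scope="session")
def session12(gt_small, pool_selected):
    """Full-size decoder-construction session: 12 runs x 20 trials."""
    runs, table = dn.simulate_rating_session(
        gt_small, pool_selected, n_runs=12, trials_per_run=20, seed=3
    )
    return runs, table


@pytest.fixture(scope="session")
def samples12(gt_small, session12):
    runs, _ = session12
    sm = dn.extract_session(runs, period="rating", mode="offline")
    return sm


@pytest.fixture(scope="session")
def decoder12(gt_small, session12):
    runs, _ = session12
    return dn.train_preference_decoder(runs, "CC")


@pytest.fixture(scope="session")
def noiseless_session():
    """Zero-noise subject for exact round-trip checks.

    Rating noise stays on (ratings must vary) but the voxel noise is zero,
    so extracted samples equal the embedded patterns exactly when the chain
    skips the (here degenerate) detrend/z-score stages.
    """
    gt = dn.make_ground_truth(
        n_other_rois=1, roi_voxels=12, target_voxels=16, noise_sd=0.0, seed=11
    )
    pool = dn.select_faces(dn.generate_face_pool(400, gt, seed=4), seed=5)
    runs, table = dn.simulate_rating_session(gt, pool, n_runs=4, trials_per_run=20, seed=6)
    return gt, runs, table


def rng_of(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
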