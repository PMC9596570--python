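"""Shared fixtures: small ground-truthed synthetic scenes.

Expensive renders are session-scoped so several tests can share one scene.
"""

from __future__ import annotations

import numpy as np
import pytest

import mitoflux as mf


@pytest.fixture(scope="session")
def default_scene():
    """A 512x512 scene with 10 dual, 5 GFP-only, 5 mRFP-only puncta."""
    return mf.simulate_scene(mf.SceneSpec(seed=1))


@pytest.fixture(scope="session")
def noise_only_scene():
    """A cell with diffuse fluorescence and camera noise but no puncta."""
    spec = mf.SceneSpec(seed=2, n_dual=0, n_gfp_only=0, n_rfp_only=0)
    return mf.simulate_scene(spec)


@pytest.fixture(scope="session")
def dense_scene():
    """30 dual puncta at peak SNR 5 in a large cell (detection stress case)."""
    spec = mf.SceneSpec(
        seed=1,
        n_dual=30,
        n_gfp_only=0,
        n_rfp_only=0,
        puncta_peak_snr=5.0,
        cell_axes=(130.0, 100.0),
        frac_near_mito=0.5,
    )
    return mf.simulate_scene(spec)


def match_detections(objects, truth, tol_px=3.0):
    """Greedy one-to-one matching of detected centroids to true centres.

    Returns (recall, precision, matched pairs).  Used by several tests; kept
    independent of the detection code (plain distance arithmetic).
    """
    gt = np.array([p.center for p in truth.puncta])
    det = np.array([o.centroid for o in objects])
    if len(det) == 0 or len(gt) == 0:
        return 0.0, 0.0, []
    d = np.sqrt(
        ((det[:, None, :] - gt[None, :, :]) ** 2).sum(axis=2)
    )
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_det, used_gt, pairs = set(), set(), []
    for i, j in order:
        if d[i, j] > tol_px:
            break
        if i in used_det or j in used_gt:
            continue
        used_det.add(i)
        used_gt.add(j)
        pairs.append((i, j))
    return len(used_gt) / len(gt), len(used_det) / len(det), pairs
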