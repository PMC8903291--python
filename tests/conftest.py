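import numpy as np
import pytest

from granulekit import gen_frap_trace, gen_granule_scene, gen_spot_scene


@pytest.fixture(scope="session")
def wt_frap_noiseless():
    """Noiseless complete-bleach trace at the wild-type S2R+ parameters."""
    raw, gt = gen_frap_trace(Fm=0.82, t_half_s=21.9, bleach_depth=1.0,
                             drift_per_frame=0.002, seed=0)
    return raw, gt


@pytest.fixture(scope="session")
def granule_scene_12():
    return gen_granule_scene(n_granules=12, snr=10, amorphic_fraction=0.0, seed=3)


@pytest.fixture(scope="session")
def spot_scene_20_5():
    return gen_spot_scene(n_soma=20, n_neurite=5, snr=8, seed=4)


def match_points(truth: np.ndarray, detected: np.ndarray, radius: float):
    """Greedy one-to-one matching; returns (n_matched, distances)."""
    truth = np.atleast_2d(truth).astype(float)
    detected = np.atleast_2d(detected).astype(float)
    if truth.size == 0 or detected.size == 0:
        return 0, np.array([])
    d = np.linalg.norm(truth[:, None, :] - detected[None, :, :], axis=2)
    pairs = sorted(
        (d[i, j], i, j) for i in range(len(truth)) for j in range(len(detected))
        if d[i, j] <= radius
    )
    used_t, used_d, dists = set(), set(), []
    for dist, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        dists.append(dist)
    return len(dists), np.array(dists)


def binom_ci95(p: float, n: int) -> float:
    """Half-width of the normal-approximation 95% binomial CI."""
    return 1.96 * np.sqrt(max(p * (1 - p), 1e-12) / n)
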