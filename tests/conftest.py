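import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isletquant as iq

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def clean_islet():
    """Noise-free synthetic islet in cell-staining mode with ground truth."""
    params = iq.SynthParams(seed=11, noise_sd=0.0, illumination_gradient=0.0)
    stack, islet, truth = iq.generate_islet(params)
    return params, stack, islet, truth


@pytest.fixture(scope="session")
def noisy_islet():
    """Synthetic islet at SNR 4 ((0.7-0.1)/0.15) with default illumination."""
    params = iq.SynthParams(seed=13, noise_sd=0.15)
    stack, islet, truth = iq.generate_islet(params)
    return params, stack, islet, truth


@pytest.fixture(scope="session")
def reference_cohort():
    return iq.load_reference_cohort()


def wcss_oracle_stained(channel: np.ndarray, bins: int = 256) -> np.ndarray:
    """Exhaustive optimal-threshold search minimising within-cluster SSE.

    Independent oracle for the 1-D two-cluster histogram k-means: for a
    one-dimensional two-cluster problem the globally optimal partition is
    a threshold, so scanning every histogram-bin boundary finds it.
    """
    counts, edges = np.histogram(channel.ravel(), bins=bins, range=(0.0, 1.0))
    centers = edges[:-1] + 0.5 / bins
    w = counts.astype(float)
    best = None
    best_b = None
    for b in range(1, bins):
        wl, wr = w[:b], w[b:]
        if wl.sum() == 0 or wr.sum() == 0:
            continue
        ml = np.average(centers[:b], weights=wl)
        mr = np.average(centers[b:], weights=wr)
        wcss = float((wl * (centers[:b] - ml) ** 2).sum()
                     + (wr * (centers[b:] - mr) ** 2).sum())
        if best is None or wcss < best:
            best, best_b = wcss, b
    assert best_b is not None, "oracle needs at least two occupied bins"
    return channel >= edges[best_b]


def mixture_image(seed: int, shape=(100, 200)) -> np.ndarray:
    """Seeded two-Gaussian-mixture image, clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    w_lo = rng.uniform(0.2, 0.8)
    m0, m1 = rng.uniform(0.15, 0.35), rng.uniform(0.6, 0.9)
    s0, s1 = rng.uniform(0.03, 0.08), rng.uniform(0.03, 0.08)
    n0 = int(round(w_lo * n))
    vals = np.concatenate(
        [rng.normal(m0, s0, n0), rng.normal(m1, s1, n - n0)]
    )
    return np.clip(vals, 0.0, 1.0).reshape(shape)


def match_detections(detected: np.ndarray, truth: np.ndarray, radius: float):
    """Greedy nearest matching of detected centroids to true centres.

    Returns (recall, precision, per-detection truth index or -1).
    """
    from scipy.spatial import cKDTree

    if len(detected) == 0:
        return 0.0, 0.0, np.full(0, -1)
    tree = cKDTree(truth)
    d, idx = tree.query(detected)
    assign = np.where(d <= radius, idx, -1)
    tp = len({i for i in assign if i >= 0})
    recall = tp / len(truth) if len(truth) else 1.0
    precision = tp / len(detected)
    return recall, precision, assign
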