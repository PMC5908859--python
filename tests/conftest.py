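import numpy as np
import pytest

from algacyto import PopulationSpec, SceneSpec, render_scene, sample_population


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_scene():
    """A quick-to-render field with well-separated cells and known truth."""
    spec = SceneSpec(image_shape=(256, 256), n_cells=20, seed=7)
    field, truth = render_scene(spec)
    return spec, field, truth


@pytest.fixture
def population_frame():
    from algacyto import records_to_frame

    spec = PopulationSpec(n_cells=400, seed=11)
    return records_to_frame(sample_population(spec))


def exhaustive_bcv_threshold(gray, nbins=256):
    """Independent oracle: plain-Python exhaustive between-class-variance scan."""
    g = np.asarray(gray, dtype=float).ravel()
    hist, edges = np.histogram(g, bins=nbins, range=(g.min(), g.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_k = -1.0, None
    for k in range(nbins - 1):
        n0 = int(hist[: k + 1].sum())
        n1 = int(hist[k + 1 :].sum())
        if n0 == 0 or n1 == 0:
            continue
        m0 = float((hist[: k + 1] * centers[: k + 1]).sum()) / n0
        m1 = float((hist[k + 1 :] * centers[k + 1 :]).sum()) / n1
        v = float(n0) * float(n1) * (m0 - m1) ** 2
        if v > best:
            best, best_k = v, k
    return float(centers[best_k])
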