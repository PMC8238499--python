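import numpy as np
import pytest

from multiweave import asymmetric_six, pca_embed, run_wnn, simulate_multimodal


def make_views(result, dims=(30, 18), seed=42):
    """PCA views for a two-modality simulation result."""
    mats = list(result.matrices.values())
    tags = [m.modality_tag for m in mats]
    return [
        pca_embed(m.values, d=d, modality_tag=t, seed=seed)
        for m, d, t in zip(mats, dims, tags)
    ]


@pytest.fixture(scope="session")
def small_fixture():
    """asymmetric-6 at n=400: simulation result, PCA views, and a WNN run."""
    res = simulate_multimodal(asymmetric_six(n_cells=400, seed=42))
    views = make_views(res)
    return res, views, run_wnn(views, k=20, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
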