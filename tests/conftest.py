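import warnings

import numpy as np
import pytest

from haircelltox.pipeline import benchmark_params as phantom_segmentation_params
from haircelltox.segmentation import SegmentationParams
from haircelltox.synthetic_data import StackPhantomParams, gen_neuromast_stack


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return phantom_segmentation_params()


@pytest.fixture(scope="session")
def phantom():
    """High-SNR mostly-punctate phantom shared across segmentation tests."""
    params = StackPhantomParams(seed=1, snr=30.0, diffuse_fraction=0.1)
    stack, truth = gen_neuromast_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def small_phantom_kwargs():
    """Compact geometry for Monte-Carlo style loops over many phantoms."""
    return dict(
        n_cells=6,
        cell_radius_um=3.0,
        shape_px=(32, 80, 80),
        voxel_size_um=(0.3, 0.25, 0.25),
        vesicles_per_cell=(4.0, 0.1),
        snr=20.0,
    )


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
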