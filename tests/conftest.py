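import numpy as np
import pandas as pd
import pytest

from dosiomics_ntcp import dose as dp
from dosiomics_ntcp.dose import DiscretizedVolume, DoseGrid, StructureMask
from dosiomics_ntcp.modeling import SURGERY, CohortData


def make_discrete(levels, mask=None, n_levels=None, bin_width=1.0):
    """Build a DiscretizedVolume directly from an integer level array."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    mask = StructureMask(np.asarray(mask, dtype=bool))
    if n_levels is None:
        n_levels = int(levels[mask.values].max())
    lv = np.where(mask.values, levels, 0)
    return DiscretizedVolume(lv, n_levels, bin_width, mask)


def random_discrete(rng, shape=(4, 4, 4), n_levels=5, p_mask=0.8):
    """Random small volume with a non-degenerate mask for oracle checks."""
    for _ in range(100):
        levels = rng.integers(1, n_levels + 1, size=shape)
        mask = rng.random(shape) < p_mask
        if mask.sum() < 4:
            continue
        # NGTDM needs at least one masked voxel with a masked neighbor
        from scipy import ndimage

        k = np.ones((3, 3, 3))
        k[1, 1, 1] = 0
        if (ndimage.correlate(mask.astype(float), k, mode="constant") * mask).max() > 0:
            return make_discrete(levels, mask, n_levels=n_levels)
    raise RuntimeError("could not build a random volume")


def make_tabular_cohort(
    n=400,
    n_noise=5,
    beta_true=1.5,
    beta_surgery=0.7,
    intercept=-2.0,
    seed=0,
    true_name="f_true",
):
    """Tabular synthetic cohort with one informative feature + noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_noise + 1))
    names = [true_name] + [f"noise{i}" for i in range(n_noise)]
    features = pd.DataFrame(X, columns=names)
    surgery = (rng.random(n) < 0.25).astype(int)
    from scipy.special import expit

    eta = intercept + beta_true * X[:, 0] + beta_surgery * surgery
    y = (rng.random(n) < expit(eta)).astype(int)
    cov = pd.DataFrame({SURGERY: surgery})
    return CohortData(features, cov, y)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_grid():
    """A constant 50 Gy dose on a 2 mm grid with a central box mask."""
    values = np.full((12, 10, 10), 50.0)
    mask = np.zeros((12, 10, 10), dtype=bool)
    mask[2:10, 2:8, 2:8] = True
    return DoseGrid(values, (2.0, 2.0, 2.0)), StructureMask(mask)
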