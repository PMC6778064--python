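import numpy as np
import pytest

from clustorm import laws
from clustorm.io import FieldMetadata, LocalizationField, Rect
from clustorm.synthetic import SyntheticFieldConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_field(xy, roi=None, **meta) -> LocalizationField:
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if roi is None:
        span = max(1.0, xy.max(initial=1.0) * 1.1)
        roi = Rect(min(0.0, xy.min(initial=0.0)), min(0.0, xy.min(initial=0.0)), span * 2, span * 2)
    return LocalizationField(
        x_nm=xy[:, 0],
        y_nm=xy[:, 1],
        frame=np.zeros(len(xy), dtype=int),
        roi=roi,
        metadata=FieldMetadata(**meta),
    )


def random_field(rng, n, span=2000.0):
    """Clumpy random localization field for oracle comparisons."""
    n_centers = max(1, int(rng.integers(1, 8)))
    centers = rng.uniform(0, span, size=(n_centers, 2))
    which = rng.integers(0, n_centers, size=n)
    xy = centers[which] + rng.normal(0, span / 25, size=(n, 2))
    n_uni = int(n * 0.3)
    xy[:n_uni] = rng.uniform(0, span, size=(n_uni, 2))
    return xy


@pytest.fixture
def aggregate_config():
    """Small aggregates-plus-background field with known ground truth."""
    return SyntheticFieldConfig(
        roi_width_nm=5000.0,
        roi_height_nm=5000.0,
        n_aggregates=5,
        aggregate_diameter_law=laws.uniform(60.0, 150.0),
        aggregate_density_law=laws.constant(80.0),
        n_monomers=0,
        localization_precision_nm=8.0,
        background_rate_per_um2=5.0,
        seed=11,
    )
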