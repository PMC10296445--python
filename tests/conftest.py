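import numpy as np
import pytest

from spglearn import SpatialSlide
from spglearn.attribution import ImportanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_slide(
    counts: np.ndarray,
    coords: np.ndarray | None = None,
    normalized: bool = False,
    slide_id: str = "s1",
) -> SpatialSlide:
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.arange(n, dtype=float) ** 2])
    return SpatialSlide(
        expression=counts,
        gene_ids=[f"g{j}" for j in range(g)],
        spot_ids=[f"s{i}" for i in range(n)],
        coords=np.asarray(coords, dtype=float),
        patient_id="p1",
        slide_id=slide_id,
        normalized=normalized,
    )


def make_importance(values: np.ndarray) -> ImportanceMatrix:
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ImportanceMatrix(
        values=values,
        spot_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
    )


@pytest.fixture
def planted_linear_slide():
    """Noiseless slide whose genes are exact linear functions of (x, y)."""
    rng = np.random.default_rng(7)
    side = 10
    ax = np.arange(side) * 2.0
    xx, yy = np.meshgrid(ax, ax)
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    x, y = coords[:, 0], coords[:, 1]
    X = np.column_stack([x / 18.0, y / 18.0, (x + y) / 36.0, (x - y) / 36.0])
    return SpatialSlide(
        expression=X,
        gene_ids=["gx", "gy", "gsum", "gdiff"],
        spot_ids=[f"s{i}" for i in range(len(x))],
        coords=coords,
        normalized=True,
    )
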