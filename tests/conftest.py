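import numpy as np
import pytest

from protscan.data import SpatialMap, SummaryStats, VariantTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_variants(m, maf=0.01, mac=None, pos=None, seed=0):
    rng = np.random.default_rng(seed)
    maf_arr = np.full(m, maf) if np.isscalar(maf) else np.asarray(maf, dtype=float)
    if mac is None:
        mac = np.maximum((maf_arr * 2000).astype(int), 1)
    mac = np.full(m, mac) if np.isscalar(mac) else np.asarray(mac)
    if pos is None:
        pos = np.sort(rng.choice(3000, size=m, replace=False)) + 1
    return VariantTable(
        variant_id=np.array([f"v{i + 1}" for i in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=pos,
        maf=maf_arr,
        mac=mac,
    )


def make_spatial(coords, structure="S"):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return SpatialMap(
        structure_id=np.array([structure] * coords.shape[0], dtype=object),
        coords=coords,
    )


@pytest.fixture
def twelve_point_map(rng):
    """12 points in general position: all 66 pairwise distances distinct."""
    from scipy.spatial.distance import pdist

    while True:
        coords = rng.standard_normal((12, 3))
        d = pdist(coords)
        if np.unique(np.round(d, 12)).size == 66:
            return make_spatial(coords)


@pytest.fixture
def identity_stats():
    def _make(m, U=None):
        return SummaryStats(U=np.zeros(m) if U is None else U, V=np.eye(m))

    return _make
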