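import numpy as np
import pytest

from hepazone.geometry import build_geometry, hex_full_lattice
from hepazone.io import CountMatrix, GeneSetCollection
from hepazone.scoring import NormalizedMatrix


@pytest.fixture
def lattice_7x14():
    """Full 7-row x 14-column hexagonal patch (98 spots)."""
    return hex_full_lattice(7, 14)


@pytest.fixture
def geometry_7x14(lattice_7x14):
    return build_geometry(lattice_7x14, pitch_um=100.0)


@pytest.fixture
def small_counts():
    """3 spots x 4 genes with hand-checkable totals."""
    counts = np.array(
        [
            [10, 0, 5, 5],
            [1, 2, 3, 4],
            [0, 0, 0, 8],
        ]
    )
    return CountMatrix(("s1", "s2", "s3"), ("g1", "g2", "g3", "g4"), counts)


def make_norm(values, spot_prefix="s", gene_prefix="g", gene_ids=None):
    values = np.asarray(values, dtype=float)
    spots = tuple(f"{spot_prefix}{i+1}" for i in range(values.shape[0]))
    genes = (
        tuple(gene_ids)
        if gene_ids is not None
        else tuple(f"{gene_prefix}{j+1}" for j in range(values.shape[1]))
    )
    return NormalizedMatrix(spots, genes, values)


def make_sets(**kwargs):
    return GeneSetCollection({k: tuple(v) for k, v in kwargs.items()})
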