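import numpy as np
import pytest

from zcnt.profiles import (
    ChromLayout,
    CopyNumberMatrix,
    CopyNumberProfile,
    default_bins,
)


@pytest.fixture
def chr1_layout():
    return ChromLayout(["chr1"], [4])


@pytest.fixture
def profile_factory():
    """Build a single-chromosome profile from a value list."""

    def make(values, n_chrom=1):
        values = list(values)
        if n_chrom == 1:
            return CopyNumberProfile.from_values(values)
        per = len(values) // n_chrom
        layout = ChromLayout([f"chr{i+1}" for i in range(n_chrom)], [per] * n_chrom)
        return CopyNumberProfile(values, default_bins(layout))

    return make


@pytest.fixture
def matrix_factory():
    """Build a copy number matrix from a 2-D value array and cell names."""

    def make(values, cells=None, n_chrom=1):
        values = np.asarray(values)
        if cells is None:
            cells = [f"cell_{i}" for i in range(values.shape[0])]
        per = values.shape[1] // n_chrom
        layout = ChromLayout([f"chr{i+1}" for i in range(n_chrom)], [per] * n_chrom)
        return CopyNumberMatrix(cells, values, default_bins(layout))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
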