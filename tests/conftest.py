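import numpy as np
import pandas as pd
import pytest

from panelmix import FixtureSpec, GeneticMap, HaplotypePanel, make_toy_map, simulate_mosaic_panel


@pytest.fixture
def two_knot_map():
    return GeneticMap("1", np.array([1000, 2000]), np.array([0.0, 0.1]))


@pytest.fixture
def flat_segment_map():
    return GeneticMap("1", np.array([1000, 2000, 3000]), np.array([0.0, 0.0, 0.1]))


@pytest.fixture
def megabase_map():
    """Constant-rate 1 cM map over 1 Mb (the average human rate)."""
    return make_toy_map((1, 1_000_000), 1.0, "constant")


@pytest.fixture
def hotspot_map():
    return make_toy_map((1, 1_000_000), 1.0, "hotspot")


@pytest.fixture
def small_panel():
    """50 haplotypes x 200 sites with strong block LD."""
    return simulate_mosaic_panel(FixtureSpec(n_haplotypes=50, n_sites=200, seed=42))


def make_panel(matrix, positions=None, chrom="1"):
    """Panel from an explicit (L, N) allele matrix; positions default 100, 200, ..."""
    matrix = np.asarray(matrix, dtype=np.int8)
    L, N = matrix.shape
    if positions is None:
        positions = 100 * (np.arange(L) + 1)
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
         "ref": "A", "alt": "C"}
    )
    return HaplotypePanel(
        variants=variants, matrix=matrix,
        sample_ids=[f"S{i}" for i in range(N // 2)],
    )
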