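import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mrmimpute import MethylationDataset, RBFBasis, RegionMatrix, design_matrix
from mrmimpute.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def basis():
    return RBFBasis.equally_spaced(50, 10.0)


@pytest.fixture(scope="session")
def small_basis():
    return RBFBasis.equally_spaced(10, 5.0)


def make_region(values, region_id="r0", chrom="chr1", positions=None,
                subject_ids=None):
    """RegionMatrix from an (N, I) array with NaN marking missing cells."""
    values = np.asarray(values, dtype=float)
    n, i = values.shape
    if positions is None:
        positions = 100 + 20 * np.arange(i)
    if subject_ids is None:
        subject_ids = [f"S{j}" for j in range(n)]
    return RegionMatrix(
        region_id=region_id, chrom=chrom,
        start=int(np.min(positions)), end=int(np.max(positions)),
        positions=np.asarray(positions), values=values,
        mask=~np.isnan(values), subject_ids=subject_ids,
    )


@pytest.fixture()
def two_cluster_units(basis):
    """20 flat profiles at 0.1 vs 0.9 with tiny noise; labels known."""
    rng = np.random.default_rng(7)
    units, labels = [], []
    for g, level in enumerate([0.1, 0.9]):
        for _ in range(10):
            x = np.sort(rng.uniform(-1, 1, 12))
            y = np.clip(level + rng.normal(0, 0.01, 12), 0, 1)
            units.append((x, y))
            labels.append(g)
    return units, np.asarray(labels)


@pytest.fixture(scope="session")
def small_sim():
    """3 regions x 12 subjects, 2 clusters, moderate noise, 20% missing."""
    return simulate(SimConfig(n_regions=3, n_cpg=30, n_subjects=12,
                              cluster_props=(0.5, 0.5), noise_sd=0.1,
                              missing_rate=0.2, rbf_centers=30, seed=11))
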