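import numpy as np
import pytest

from bloodbiome import synthetic as syn
from bloodbiome import profiling as pf


@pytest.fixture(scope="session")
def small_taxonomy():
    """4 phyla x 2 genera - enough structure for LCA and aggregation."""
    return syn.build_taxonomy(4, 2, seed=0)


@pytest.fixture(scope="session")
def small_markers(small_taxonomy):
    return syn.simulate_markers(small_taxonomy, markers_per_genus=2,
                                length_range=(300, 600), seed=1)


@pytest.fixture(scope="session")
def small_index(small_markers, small_taxonomy):
    return pf.build_index(small_markers, small_taxonomy, k=21)


@pytest.fixture(scope="session")
def host_ref():
    return syn.simulate_host_reference(10000, seed=2)


@pytest.fixture(scope="session")
def study_taxonomy():
    """Full-scale taxonomy (23 phyla) used by the group-structure tests."""
    return syn.build_taxonomy(23, 4, seed=0)


@pytest.fixture(scope="session")
def planted_sample(small_taxonomy, small_markers, host_ref):
    """A 20k-read sample with known per-category ground truth."""
    profiles = syn.default_group_profiles(small_taxonomy, n_phyla=4)
    design = syn.simulate_design(seed=3, sizes={g: 1 for g in syn.GROUP_ORDER})[1]
    ab = syn.draw_sample_abundances(profiles["SCZ"], seed=11, n_phyla=4)
    reads, origin = syn.simulate_sample_reads(
        design, ab, small_markers, host_ref,
        knobs={"n_reads": 20000}, seed=12)
    return reads, origin, ab


def rng_seeds(base: int, n: int) -> list[int]:
    return list(np.random.default_rng(base).integers(0, 2**31, size=n))
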