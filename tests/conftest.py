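import numpy as np
import pandas as pd
import pytest

from recphen import SimConfig, simulate_cohort
from recphen.io_formats import Family, GenotypeTable, IntervalTrack, MarkerMap, Pedigree


@pytest.fixture(scope="session")
def small_cohort():
    """10 families x 2 children, 1 chromosome, 400 markers, no error."""
    return simulate_cohort(SimConfig(n_families=10, n_markers_per_chrom=400, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Mid-size clean cohort used by calling/phenotype tests."""
    return simulate_cohort(SimConfig(n_families=60, n_markers_per_chrom=1500, seed=5))


@pytest.fixture
def tiny_track():
    return IntervalTrack("hotspot", {"1": np.array([[100, 200], [500, 700]])})


def manual_cohort():
    """A 1-family, 3-marker cohort with hand-set genotypes."""
    mmap = MarkerMap(pd.DataFrame({
        "chrom": ["1", "1", "1"], "id": ["m1", "m2", "m3"],
        "cm": [0.0, 0.0, 0.0], "bp": [1000, 2000, 3000],
        "a1": ["A", "A", "A"], "a2": ["G", "G", "G"]}))
    ped = Pedigree([Family("F1", "dad", "mum", ["c1", "c2"])],
                   {"dad": "M", "mum": "F", "c1": "M", "c2": "F"})
    genos = GenotypeTable(["dad", "mum", "c1", "c2"], mmap.ids,
                          np.array([[0, 1, 2],
                                    [1, 1, 1],
                                    [1, 1, 2],
                                    [0, 1, 1]], dtype=np.int8))
    return ped, mmap, genos
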