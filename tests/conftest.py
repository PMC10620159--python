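import numpy as np
import pandas as pd
import pytest

from fritniche.occurrences import OccurrenceSet, extract_env
from fritniche.raster import RasterGrid, RasterStack
from fritniche.sdm import fit_sre, sample_pseudo_absences
from fritniche.synth import gen_env_stack, gen_virtual_species, sample_occurrences


@pytest.fixture(scope="session")
def small_stack() -> RasterStack:
    """20x20 two-layer autocorrelated stack used across SDM tests."""
    return gen_env_stack(20, 20, 2, corr_length=2.0, means=[10.0, 500.0],
                         sds=[3.0, 100.0], seed=11, names=["bio01", "bio12"])


@pytest.fixture(scope="session")
def small_truth(small_stack):
    return gen_virtual_species(small_stack, optima=[11.0, 520.0],
                               widths=[1.5, 60.0], weights=[1.0, 1.0])


@pytest.fixture(scope="session")
def env_table(small_stack, small_truth) -> pd.DataFrame:
    """Presence/pseudo-absence environmental table on the small stack."""
    occ = sample_occurrences(small_truth, 60, duplicate_rate=0.0, seed=12)
    presence_env = extract_env(small_stack, occ)
    sre = fit_sre(presence_env)
    absences = sample_pseudo_absences(small_stack, sre, n=len(occ), seed=13,
                                      exclude=occ)
    return extract_env(small_stack, OccurrenceSet.concat([occ, absences]))


@pytest.fixture()
def unit_grid() -> RasterGrid:
    """3x3 grid with unit cells anchored at (0E, 3N) for hand arithmetic."""
    return RasterGrid(np.zeros((3, 3)), west=0.0, north=3.0, dx=1.0, dy=1.0)
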