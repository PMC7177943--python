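import numpy as np
import pytest

import koffgrid as kg
from koffgrid.probes import ProbeDefinition, default_probe_table


@pytest.fixture(scope="session")
def ligand_series():
    """Five prepared congeneric benzamide ligands (deterministic, seed 3)."""
    return kg.make_ligand_series(5, seed=3)


@pytest.fixture(scope="session")
def series_table(ligand_series):
    """Descriptor table of the ligand series (5 x 166)."""
    vectors = [kg.compute_descriptor_vector(m) for m in ligand_series]
    return kg.descriptor_table(vectors)


@pytest.fixture(scope="session")
def probe_table():
    return default_probe_table()


@pytest.fixture
def neutral_probe():
    """An uncharged, non-H-bonding probe for pure-LJ checks."""
    return ProbeDefinition("DRY", 0.0, 0.21, 3.4)


@pytest.fixture
def charged_probe():
    """A +1e probe with no LJ or H-bond terms for pure-Coulomb checks."""
    return ProbeDefinition("N3+", 1.0, 0.0, 1.0)


@pytest.fixture
def planted_split():
    """Planted 60 x 166 dataset with a 40/20 train/validation split."""
    ds = kg.make_planted_dataset(60, sigma=0.3, rho=0.3, seed=7)
    split = kg.random_split(ds.X.index, 40, seed=1)
    return ds, kg.ModelingDataset(ds.X, ds.y, split)


def synthetic_field(energies, spacing=0.5, origin=(0.0, 0.0, 0.0)):
    """Wrap a raw energy array into a MIFGrid for voxel-op tests."""
    energies = np.asarray(energies, dtype=float)
    grid = kg.GridSpec(origin=origin, spacing=spacing, dims=energies.shape)
    return kg.MIFGrid(grid=grid, probe_name="OH2", energies=energies)
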