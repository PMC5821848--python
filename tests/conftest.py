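import numpy as np
import pandas as pd
import pytest

from bioregionize import (
    IncidenceMatrix,
    full_horizontal_river,
    full_vertical_river,
    make_lattice,
    sample_environment,
    simulate_species,
)


def random_incidence(rng, n_cells, n_species, p=0.4) -> IncidenceMatrix:
    """Random 0/1 matrix with every cell guaranteed non-empty."""
    occ = (rng.random((n_cells, n_species)) < p).astype(np.int8)
    empty = occ.sum(axis=1) == 0
    occ[empty, rng.integers(0, n_species, size=int(empty.sum()))] = 1
    return IncidenceMatrix(
        pd.DataFrame(
            occ,
            index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
            columns=[f"s{j}" for j in range(n_species)],
        )
    )


def planted_landscape(seed, rows=10, cols=10, species_per_block=30,
                      crossing=0.02, range_size=("uniform", 10, 20)):
    """A 4-block river-delimited landscape with block-balanced endemic seeds."""
    lat = make_lattice(
        rows, cols,
        [full_horizontal_river(rows // 2, cols), full_vertical_river(cols // 2, rows)],
    )
    env = sample_environment(lat, seed=seed)
    n_species = species_per_block * lat.n_blocks
    incidence, truth = simulate_species(
        lat, env, n_species=n_species, range_size=range_size,
        crossing_probability=crossing,
        origin_blocks=np.arange(n_species) % lat.n_blocks, seed=seed,
    )
    return lat, env, IncidenceMatrix(incidence), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def four_block_landscape():
    return planted_landscape(seed=7)
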