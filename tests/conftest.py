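import pandas as pd
import pytest

from oceanmags.config import PipelineConfig
from oceanmags.simulate import SimulationSpec, simulate_environment, simulate_genomes


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale simulation: coarse grid, few genomes, fast everywhere."""
    return SimulationSpec(n_genomes=30, n_redundant_pairs=3, n_stations=25,
                          n_functions=100, grid_resolution_deg=10.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_world(small_spec):
    """(genomes, pairs, truth, stations, grid1, grid2) for the small spec."""
    genomes, pairs, truth = simulate_genomes(small_spec)
    stations, grid1, grid2 = simulate_environment(small_spec)
    return genomes, pairs, truth, stations, grid1, grid2


def genome_frame(rows):
    """Hand-build a genomes-schema frame from (id, length) or full tuples."""
    records = []
    for row in rows:
        gid, length = row[0], row[1]
        records.append({
            "genome_id": gid, "length": length, "completion": 50.0,
            "redundancy": 0.5, "lineage": "Stramenopiles", "source": "MAG",
            "is_phytoplankton": False,
        })
    return pd.DataFrame(records)


def pair_frame(rows):
    """Hand-build a pairs-schema frame from (a, b, ani, frac) tuples."""
    return pd.DataFrame(
        [{"genome_a": a, "genome_b": b, "ani": ani,
          "aligned_fraction_smaller": frac} for a, b, ani, frac in rows])
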