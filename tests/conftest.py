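import numpy as np
import pandas as pd
import pytest

from heterospot import (
    SimulationConfig,
    normalize_volumes,
    simulate_protein_db,
    simulate_spot_experiment,
)


def make_table(records):
    """Build a spot-volume table from (spot, stage, genotype, rep, vol) rows.

    A volume of None marks an undetected observation.
    """
    rows = []
    for spot, stage, genotype, rep, vol in records:
        rows.append(
            {
                "spot_id": spot,
                "stage": stage,
                "genotype": genotype,
                "replicate": rep,
                "volume": np.nan if vol is None else float(vol),
                "detected": vol is not None,
            }
        )
    return pd.DataFrame(rows)


def triplicate_table(stage="DS", **spot_volumes):
    """One gel per genotype x 3 replicates, identical volumes across reps.

    ``spot_volumes`` maps spot_id -> (p1, p2, h) mean volumes; None drops
    the spot from that genotype entirely.
    """
    recs = []
    for spot, (p1, p2, h) in spot_volumes.items():
        for genotype, vol in zip(("P1", "P2", "H"), (p1, p2, h)):
            for rep in (1, 2, 3):
                recs.append((spot, stage, genotype, rep, vol))
    return make_table(recs)


@pytest.fixture(scope="session")
def sim_experiment():
    """A moderate simulated experiment with dropout, shared across tests."""
    cfg = SimulationConfig(n_spots=400, seed=11, dropout_rate=0.08)
    table, truth = simulate_spot_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def sim_normalized(sim_experiment):
    _, table, _ = sim_experiment
    return normalize_volumes(table)


@pytest.fixture(scope="session")
def protein_db():
    return simulate_protein_db(30, length_range=(80, 250), seed=5)
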