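"""Shared fixtures: small hand-checked pedigrees and synthetic data sets."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ssgblup as s


@pytest.fixture
def five_animal_pedigree() -> s.PedigreeTable:
    """Two founders, two full sibs, one inbred offspring of the sibs."""
    return s.PedigreeTable.from_frame(
        pd.DataFrame(
            {
                "animal": [1, 2, 3, 4, 5],
                "sire": [0, 0, 1, 1, 3],
                "dam": [0, 0, 2, 2, 4],
            }
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small full synthetic data set shared across read-only tests."""
    cfg = s.SimulationConfig(
        n_founders=40,
        n_generations=4,
        offspring_per_mating=2.2,
        sire_fraction=0.15,
        n_herds=3,
        year_range=(2000, 2005),
        n_markers=400,
        genotyped_fraction=0.4,
        missing_call_rate=0.02,
        variance_components=(3.0, 6.0, 3.0),
        seed=11,
    )
    ped = s.simulate_pedigree(cfg)
    drop = s.gene_drop_genotypes(ped, cfg)
    records = s.simulate_phenotypes(ped, cfg, drop.true_values)
    return cfg, ped, drop, records


def random_pedigree(n: int, rng: np.random.Generator) -> s.PedigreeTable:
    """Random acyclic pedigree of ``n`` animals: each non-founder draws its
    parents uniformly among earlier animals (or stays unknown)."""
    rows = []
    for i in range(1, n + 1):
        sire = dam = 0
        if i > 2 and rng.random() < 0.8:
            sire, dam = rng.choice(np.arange(1, i), size=2, replace=False)
        rows.append((i, int(sire), int(dam)))
    return s.PedigreeTable.from_frame(
        pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    )
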