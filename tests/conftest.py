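import itertools

import numpy as np
import pandas as pd
import pytest

from aflpop import CrossTable, MarkerMatrix, SampleFrame
from aflpop.simulate import default_study_scenario, simulate_dataset

GREEN = ["Kt", "Bz", "Re", "Hw", "Bl", "U", "Wi", "Il", "Gu", "Bg", "Zi", "We", "A"]
BLUE = ["Tp", "Tb", "Pl"]
SINGLES = ["Tl", "Mu", "Mt"]
NO_FLOWER = "Gss"
ALL_POPULATIONS = GREEN + BLUE + SINGLES + [NO_FLOWER]


def crossing_polygon() -> CrossTable:
    """The interpopulation crossing outcome graph of the study design:
    thirteen mutually incompatible populations, a second incompatible trio,
    three populations compatible with everything they were crossed to, and
    one population absent because it never flowered."""
    rows = []

    def rec(mother, father, flowers, capsules, seeds):
        rows.append(
            {
                "mother_population": mother,
                "father_population": father,
                "n_flowers": flowers,
                "n_capsules": capsules,
                "n_seeds": seeds,
            }
        )

    for a, b in itertools.combinations(GREEN, 2):
        rec(a, b, 4, 1, 0)
    for a, b in itertools.combinations(BLUE, 2):
        rec(a, b, 4, 0, 0)
    # compatible crosses: singletons to members of both big groups, and a
    # green-blue bridge, so every tested population is connected by data
    for s in SINGLES:
        rec(s, GREEN[0], 3, 2, 6)
        rec(s, BLUE[0], 3, 2, 5)
    rec(GREEN[0], BLUE[0], 5, 3, 8)
    rec(SINGLES[0], SINGLES[1], 2, 1, 3)
    return CrossTable(pd.DataFrame(rows))


def make_matrix(rows: dict[str, list], locus_ids=None) -> MarkerMatrix:
    """Small matrix helper; ``None`` entries are missing."""
    sample_ids = list(rows)
    n_loci = len(next(iter(rows.values())))
    band = np.array(
        [[np.nan if v is None else float(v) for v in r] for r in rows.values()]
    )
    locus_ids = locus_ids or [f"L{k+1}" for k in range(n_loci)]
    return MarkerMatrix(sample_ids, locus_ids, band)


def random_matrix(
    rng: np.random.Generator, n_samples: int, n_loci: int, missing: float = 0.0
) -> MarkerMatrix:
    band = (rng.random((n_samples, n_loci)) < 0.4).astype(float)
    if missing > 0:
        mask = rng.random(band.shape) < missing
        # keep one scored locus per row
        mask[mask.all(axis=1), 0] = False
        band[mask] = np.nan
    return MarkerMatrix(
        [f"s{i}" for i in range(n_samples)],
        [f"L{j}" for j in range(n_loci)],
        band,
    )


def simple_samples(matrix: MarkerMatrix, population_of: dict[str, str],
                   area_of: dict[str, str] | None = None) -> SampleFrame:
    rows = [
        {
            "sample_id": s,
            "population": population_of[s],
            "region": "r",
            "area": (area_of or {}).get(s, "introduced"),
        }
        for s in matrix.sample_ids
    ]
    return SampleFrame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def scenario():
    """One default-scale simulated dataset shared across the suite."""
    return simulate_dataset(default_study_scenario(seed=1))


@pytest.fixture(scope="session")
def scenario_config():
    return default_study_scenario(seed=1)
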