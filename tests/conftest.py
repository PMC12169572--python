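from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from owaci.data import AlignedDataset, ExternalSeries, IndicatorTable
from owaci.registry import FactorDefinition, FactorRegistry, default_registry

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture54"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def toy_registry():
    """Six factors, two per dimension, mixed orientations."""
    return FactorRegistry([
        FactorDefinition("se_a", "socioeconomic protective pct",
                         "socioeconomic", "protective", "percentage"),
        FactorDefinition("se_b", "socioeconomic adverse pct",
                         "socioeconomic", "adversity_increasing", "percentage"),
        FactorDefinition("vu_a", "vulnerability adverse pct",
                         "vulnerability", "adversity_increasing", "percentage"),
        FactorDefinition("vu_b", "vulnerability protective pct",
                         "vulnerability", "protective", "percentage"),
        FactorDefinition("ri_a", "risk adverse pct",
                         "risk_insecurity", "adversity_increasing", "percentage"),
        FactorDefinition("ri_b", "risk adverse mean",
                         "risk_insecurity", "adversity_increasing", "nonneg_mean"),
    ])


def build_dataset(values: dict, external, registry,
                  continents=None) -> AlignedDataset:
    n = len(next(iter(values.values())))
    continents = continents or ["Africa", "Americas", "Asia", "Europe",
                                "Oceania"][:n] * ((n // 5) + 1)
    units = pd.DataFrame({
        "country_id": [f"C{i:02d}" for i in range(n)],
        "name": [f"Country {i:02d}" for i in range(n)],
        "continent": continents[:n],
    })
    table = IndicatorTable(units, pd.DataFrame(values, dtype=float), registry)
    return AlignedDataset(table, ExternalSeries(pd.Series(np.asarray(external,
                                                                     float))),
                          registry)


@pytest.fixture
def toy_dataset(toy_registry):
    """Five countries, six factors, hand-enterable values."""
    values = {
        "se_a": [80, 60, 40, 20, 10],   # protective: high = low adversity
        "se_b": [10, 30, 50, 70, 90],
        "vu_a": [5, 25, 45, 65, 85],
        "vu_b": [90, 70, 50, 30, 20],
        "ri_a": [12, 34, 56, 72, 95],
        "ri_b": [1, 5, 10, 15, 25],
    }
    external = [8, 22, 43, 61, 84]      # increasing with adversity
    return build_dataset(values, external, toy_registry)


@pytest.fixture(scope="session")
def fixture_dir():
    return FIXTURE_DIR
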