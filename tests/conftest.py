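"""Shared fixtures: printed-table excerpts and small synthetic datasets."""

from __future__ import annotations

import io

import pandas as pd
import pytest

from chillreq.io_phenology import BloomRecord, read_bloom_wide
from chillreq.synthetic_data import (
    ProgenySimParams,
    WeatherSimParams,
    simulate_progeny,
    simulate_weather,
)

# Published example excerpt: wide bloom table of four coded genotypes over
# eight seasons; genotype 1_1 has one season marked invalid (*).
TABLE1_CSV = """\
Genotype,BD12,BD13,BD14,BD21,BD22,BD23,BD24,BD25
1_1,*,75,69,71,81,83,80,85
1_2,70,53,53,60,63,72,59,69
1_3,72,63,62,64,72,80,75,76
1_4,72,63,63,64,67,72,68,75
"""

# Published example excerpt: the same records in long format for two genotypes.
TABLE2_ROWS = [
    ("1_1", 2012, 74), ("1_1", 2013, 69), ("1_1", 2014, 62), ("1_1", 2021, 60),
    ("1_1", 2022, 67), ("1_1", 2023, 79), ("1_1", 2024, 75), ("1_1", 2025, 83),
    ("1_4", 2012, 78), ("1_4", 2013, 65), ("1_4", 2014, 63), ("1_4", 2021, 64),
    ("1_4", 2022, 65), ("1_4", 2023, 83), ("1_4", 2024, 71), ("1_4", 2025, 74),
]

# Published example excerpt: first six days of the daily weather file.
TABLE3_CSV = """\
Day,JDay,Month,Year,Tmax,Tmin
1,1,1,2011,14.46,6.62
2,2,1,2011,15.72,6.76
3,3,1,2011,15.32,3.36
4,4,1,2011,15.17,0.42
5,5,1,2011,14.01,2.80
6,6,1,2011,20.34,3.85
"""

ORCHARD_LATITUDE = 38.11


@pytest.fixture
def table1_wide() -> pd.DataFrame:
    return read_bloom_wide(pd.read_csv(io.StringIO(TABLE1_CSV), dtype=str))


@pytest.fixture
def table1_path(tmp_path):
    path = tmp_path / "bloom_wide.csv"
    path.write_text(TABLE1_CSV)
    return path


@pytest.fixture
def table2_records() -> list[BloomRecord]:
    return [BloomRecord(*row) for row in TABLE2_ROWS]


@pytest.fixture
def table3_weather() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(TABLE3_CSV))


@pytest.fixture(scope="session")
def small_weather() -> pd.DataFrame:
    """Seven calendar years of synthetic daily weather (seasons 2012-2017)."""
    return simulate_weather(WeatherSimParams(first_year=2011, last_year=2017, seed=0))


@pytest.fixture(scope="session")
def small_progeny(small_weather):
    """Six noise-free genotypes over six seasons, with ground truth."""
    params = ProgenySimParams(n_genotypes=6, bloom_noise_sd=0.0, seed=0)
    return simulate_progeny(small_weather, params, latitude=ORCHARD_LATITUDE)
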