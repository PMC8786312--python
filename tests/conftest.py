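import numpy as np
import pandas as pd
import pytest

from numfish.choicestats import inv_logit
from numfish.stimgen import ControlCondition, Dot, DotArray, Geometry, Spatial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_array():
    """Four unit-radius dots on a 10 mm square, well inside a 30 mm field."""
    return DotArray(
        dots=(
            Dot(-5.0, -5.0, 1.0),
            Dot(5.0, -5.0, 1.0),
            Dot(5.0, 5.0, 1.0),
            Dot(-5.0, 5.0, 1.0),
        )
    )


@pytest.fixture
def area_id_condition():
    return ControlCondition(Geometry.AREA_EQ, Spatial.ID_EQ)


def make_bernoulli_table(
    n_fish: int,
    trials_per_fish: int,
    p_by_factor: dict | float,
    rng: np.random.Generator,
    fish_sd: float = 0.0,
) -> pd.DataFrame:
    """Choice table with optional per-fish random log-odds and a factor effect.

    ``p_by_factor`` is either a single success probability or a mapping
    {geometry_control level -> probability}; levels are assigned uniformly.
    """
    rows = []
    offsets = rng.normal(0.0, fish_sd, n_fish)
    if isinstance(p_by_factor, dict):
        levels = sorted(p_by_factor)
    else:
        levels = ["radius_fixed", "area_eq", "perim_eq"]
    for f in range(n_fish):
        for t in range(trials_per_fish):
            lev = levels[int(rng.integers(len(levels)))]
            p = p_by_factor[lev] if isinstance(p_by_factor, dict) else p_by_factor
            logodds = np.log(p / (1 - p)) + offsets[f]
            rows.append(
                {
                    "fish_id": f"f{f}",
                    "experiment": "exp1",
                    "phase": "test",
                    "session": 1,
                    "trial": t,
                    "geometry_control": lev,
                    "spatial_control": ["ch_eq", "id_eq"][t % 2],
                    "congruency_level": 1,
                    "comparison": "3v6",
                    "chose_target": int(rng.random() < inv_logit(logodds)),
                    "responded": 1,
                }
            )
    return pd.DataFrame(rows)
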