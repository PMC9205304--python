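import numpy as np
import pandas as pd
import pytest

import endosex as es


@pytest.fixture
def toy_separated():
    """Fully separated toy samples: all females below all males."""
    return [1.0, 2.0, 3.0, 4.0, 5.0], [10.0, 11.0, 12.0, 13.0, 14.0]


@pytest.fixture
def toy_overlapping():
    """Interleaved 3+3 toy with hand-enumerable error rates."""
    return [10.0, 20.0, 30.0], [15.0, 25.0, 35.0]


@pytest.fixture
def hormone_csv(tmp_path):
    """Well-formed 3-row hormone table on disk."""
    path = tmp_path / "hormone.csv"
    pd.DataFrame({
        "id": ["a1", "a2", "a3"],
        "age_class": ["hatchling"] * 3,
        "treatment": ["naive"] * 3,
        "testosterone": [12.5, 48.0, 300.2],
        "true_sex": ["F", "F", "M"],
    }).to_csv(path, index=False)
    return path


@pytest.fixture
def morph_csv(tmp_path):
    path = tmp_path / "morph.csv"
    pd.DataFrame({
        "id": ["a1", "a2"],
        "MCL": [50.0, 48.0],
        "SH": [30.0, 29.0],
        "CW": [40.0, 41.0],
        "PMIN": [35.0, 34.0],
        "PMAX": [45.0, 44.0],
        "true_sex": ["F", "M"],
    }).to_csv(path, index=False)
    return path


@pytest.fixture
def hatchling_sample():
    """One moderately sized draw from the hatchling scenario."""
    cfg = es.scenario_config("hatchling_naive", seed=123, n_female=120, n_male=80)
    ds = es.generate_hormone_dataset(cfg)
    return ds.hormone_values("F"), ds.hormone_values("M")


def brute_force_grid_threshold(f, m, step, objective, tie_smallest=True):
    """Independent exhaustive-search oracle for the grid threshold rules.

    Pure-Python loops over the same min->max-by-step grid, counting
    errors by direct comparison; keeps the first (smallest) optimum.
    """
    lo = min(min(f), min(m))
    hi = max(max(f), max(m))
    n_steps = int(np.floor((hi - lo) / step + 1e-9)) + 1
    best_t, best_obj, best_rates = None, None, None
    for k in range(n_steps):
        t = lo + step * k
        ef = sum(1 for v in f if v > t) / len(f)
        em = sum(1 for v in m if v < t) / len(m)
        obj = objective(ef, em)
        if best_obj is None or obj < best_obj:
            best_t, best_obj, best_rates = t, obj, (ef, em)
    return best_t, best_rates
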