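import numpy as np
import pandas as pd
import pytest

from bonemetab.study_io import BONES, PROTEINS


def make_table(n_per_cell=1, seed=0, bones=True):
    """Small valid study table: 8 factorial cells x n_per_cell records."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for animal in ("fetus", "mother"):
        for treat in ("control", "restricted"):
            for period in ("middle", "late"):
                for _ in range(n_per_cell):
                    i += 1
                    row = {"serum_id": f"S{i:03d}", "animal": animal,
                           "treat": treat, "period": period}
                    for j, p in enumerate(PROTEINS):
                        row[p] = float(rng.gamma(4.0, 2.0) + j)
                    if bones:
                        base = 10.0 if animal == "fetus" else 100.0
                        for b in BONES:
                            row[b] = base + rng.normal(0, 2.0)
                    rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def factorial_table():
    """One record per design cell (8 rows)."""
    return make_table(n_per_cell=1, seed=1)


@pytest.fixture
def small_table():
    """Three records per design cell (24 rows)."""
    return make_table(n_per_cell=3, seed=2)
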