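import numpy as np
import pandas as pd
import pytest

from twinwell.twin_data import TwinDataset


def make_cohort(rows):
    """Build a TwinDataset from (pair_id, twin_index, zyg, sex, age, traits...) dicts."""
    return TwinDataset(pd.DataFrame(rows))


@pytest.fixture
def tiny_cohort():
    rows = []
    for pid, zyg, sex, age, vals in [
        (1, "MZ", "F", 60.0, [(1.0, 2.0), (1.5, 2.5)]),
        (2, "DZ", "M", 65.0, [(0.5, 1.0), (-0.5, 0.0)]),
        (3, "MZ", "F", 58.0, [(2.0, 3.0)]),  # singleton
    ]:
        for ti, (a, b) in enumerate(vals, start=1):
            rows.append(
                dict(pair_id=pid, twin_index=ti, zygosity=zyg, sex=sex,
                     age=age, wave=1, trait_a=a, trait_b=b)
            )
    return make_cohort(rows)


def random_cohort(rng, n_pairs=10, traits=("x", "y"), singleton_prob=0.2):
    rows = []
    for pid in range(1, n_pairs + 1):
        zyg = rng.choice(["MZ", "DZ"])
        sex = rng.choice(["F", "M"])
        age = float(np.round(rng.uniform(50, 75), 1))
        n_members = 1 if rng.random() < singleton_prob else 2
        for ti in range(1, n_members + 1):
            row = dict(pair_id=pid, twin_index=ti, zygosity=zyg, sex=sex,
                       age=age, wave=1)
            for t in traits:
                row[t] = float(np.round(rng.normal(), 6))
            rows.append(row)
    return make_cohort(rows)
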