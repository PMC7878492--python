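import numpy as np
import pandas as pd
import pytest

from hmcseal import diffmod, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(12, 8, seed=101)


@pytest.fixture(scope="session")
def small_annotation():
    return synthetic.generate_annotation(60, 3, 5_000_000, seed=102)


@pytest.fixture(scope="session")
def small_counts(small_cohort, small_annotation):
    counts, truth = synthetic.generate_counts(
        small_cohort, small_annotation, n_planted=3, log2fc=1.0,
        dispersion=0.1, libsize_cv=0.3, seed=103)
    return counts, truth


@pytest.fixture(scope="session")
def table1_cohort():
    """Clinical table whose category counts match the published cohort:
    48 DLBCL (30 M, 39 EA, stage 17/20/11, LDH 25/22/1, vital 34/12/2) and
    25 FL (15 M, 19 EA, stage 5/17/3, LDH 3/21/1, vital 23/2/0)."""
    def block(subtype, n, males, ea, stage, ldh, vital):
        rows = []
        gender = ["M"] * males + ["F"] * (n - males)
        race = ["EA"] * ea + ["non-EA"] * (n - ea)
        stages = (["I/II"] * stage[0] + ["III/IV"] * stage[1]
                  + ["missing"] * stage[2])
        ldhs = (["elevated"] * ldh[0] + ["not_elevated"] * ldh[1]
                + ["missing"] * ldh[2])
        vitals = [0.0] * vital[0] + [1.0] * vital[1] + [np.nan] * vital[2]
        for i in range(n):
            rows.append({
                "sample_id": f"{subtype}_{i:03d}", "subtype": subtype,
                "age": 60.0 + i % 7, "gender": gender[i], "race": race[i],
                "stage": stages[i], "ldh": ldhs[i], "batch": "b0",
                "os_time": 24.0, "death_event": vitals[i],
                "cell_of_origin": "missing",
            })
        return rows

    rows = block("DLBCL", 48, 30, 39, (17, 20, 11), (25, 22, 1), (34, 12, 2))
    rows += block("FL", 25, 15, 19, (5, 17, 3), (3, 21, 1), (23, 2, 0))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sf(small_counts):
    counts, _ = small_counts
    return diffmod.size_factors(diffmod.filter_nonzero_variance(counts))
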