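import numpy as np
import pandas as pd
import pytest

from meltrisk.core_data import (
    Category,
    CompoundLibrary,
    CompoundRecord,
    ConcentrationTable,
)
from meltrisk.effects import BQE, BaselineModel, EffectDatabase, EffectRecord, Provenance


@pytest.fixture
def baseline_model():
    """Synthetic per-BQE coefficients; tests never rely on the packaged defaults."""
    return BaselineModel(
        slopes={BQE.FISH: -0.9, BQE.CRUSTACEAN: -0.8, BQE.ALGAE: -1.0},
        intercepts={BQE.FISH: 2.0, BQE.CRUSTACEAN: 1.8, BQE.ALGAE: 2.2},
    )


@pytest.fixture
def small_library():
    return CompoundLibrary(
        [
            CompoundRecord("tw-1", "tire compound", Category.TRAFFIC, ("tire_wear",), 4.0, 0.5),
            CompoundRecord("tw-2", "road marker", Category.TRAFFIC, (), 2.5, 1.5),
            CompoundRecord("ph-1", "pharmaceutical", Category.HUMAN_CONSUMPTION, (), 1.0, 3.0),
            CompoundRecord("pb-1", "biocide", Category.PESTICIDE_BIOCIDE, (), 3.0, None),
            CompoundRecord("ot-1", "unknown", Category.OTHER, (), None, None),
        ]
    )


@pytest.fixture
def effect_db(baseline_model):
    records = [
        EffectRecord("tw-1", BQE.FISH, 0.5, Provenance.EXPERIMENTAL),
        EffectRecord("tw-1", BQE.FISH, 1.5, Provenance.EXPERIMENTAL),
        EffectRecord("ph-1", BQE.ALGAE, 2.0, Provenance.EXPERIMENTAL),
    ]
    return EffectDatabase(records, baseline_model, cap_tolerance_log10=0.5)


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1", "s2"],
            "compound_id": ["tw-1", "tw-2", "ph-1", "tw-1"],
            "concentration_ng_L": [10.0, 20.0, 5.0, 40.0],
        }
    )
    mdl = {"tw-1": 1.0, "tw-2": 1.0, "ph-1": 1.0}
    return ConcentrationTable(df, mdl)


def rank_average(values):
    """Independent average-rank assignment (1-based), written from scratch."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    """Plain-Python Pearson correlation used as part of the Spearman oracle."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def spearman_oracle(x, y):
    """Brute-force Spearman: average ranks, then Pearson on the ranks."""
    return pearson(rank_average(x), rank_average(y))


def percentile5_oracle(values):
    """Order-statistic 5th percentile with linear interpolation, from scratch."""
    s = sorted(values)
    h = (len(s) - 1) * 0.05
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])
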