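import numpy as np
import pandas as pd
import pytest

from neosps.scoring import INDICATORS


def make_cohort(rows):
    """Build a tidy cohort frame from (id, group, timepoint, indicator-dict)."""
    records = []
    for nid, group, tp, ind in rows:
        rec = {"id": nid, "group": group, "timepoint": tp}
        for name in INDICATORS:
            rec[name] = int(ind.get(name, 0))
        rec["score"] = sum(rec[name] for name in INDICATORS)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def ten_record_cohort():
    """Ten neonates at one timepoint with hand-chosen scores.

    Scores: pos group 5, 3, 2, 0, 7; neg group 1, 3, 0, 4, 2.
    """
    def ind(k):
        return {name: 1 for name in INDICATORS[:k]}

    rows = []
    for i, (grp, k) in enumerate(
        [("pos", 5), ("pos", 3), ("pos", 2), ("pos", 0), ("pos", 7),
         ("neg", 1), ("neg", 3), ("neg", 0), ("neg", 4), ("neg", 2)]
    ):
        rows.append((f"N{i:02d}", grp, "0h", ind(k)))
    return make_cohort(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20230117)
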