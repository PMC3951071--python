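import numpy as np
import pytest
from hypothesis import settings

from hemrbe.datamodel import BloodCountRecord, GroupSummary

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_groups(means, cell_type="WBC", timepoint="d1", arm="reference", n=3, se=0.05):
    """GroupSummary list from a {dose: mean_fraction} mapping."""
    return [
        GroupSummary(arm=arm, dose=d, timepoint=timepoint, cell_type=cell_type,
                     n=n, mean_fraction=m, se_fraction=se)
        for d, m in means.items()
    ]


def make_records(fractions, cell_type="WBC", timepoint="d1", arm="test",
                 experiment_id="e1"):
    """Per-animal normalized records from a {dose: [fractions]} mapping."""
    records = []
    for dose, fracs in fractions.items():
        for i, f in enumerate(fracs):
            records.append(BloodCountRecord(
                experiment_id=experiment_id, arm=arm,
                animal_id=f"{arm}-{dose:g}-{i}", dose=dose, timepoint=timepoint,
                cell_type=cell_type, fraction_of_control=f,
            ))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def wbc_day1_means():
    # Electron WBC Day-1 group means at 5/7.5/7.7/10/15/20 Gy.
    return {5: 0.96, 7.5: 0.45, 7.7: 0.59, 10: 0.44, 15: 0.58, 20: 0.33}
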