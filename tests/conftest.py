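import numpy as np
import pytest

from epitope_audit import load_fixtures
from epitope_audit.digestion_sensitivity import ReplicateMeasurement
from epitope_audit.flow_model import (
    Condition,
    EventTable,
    Lineage,
    SampleMeta,
)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


def make_meta(**overrides) -> SampleMeta:
    defaults = dict(
        donor_id="donor1", marker="CD8a", clone="RPA-T8",
        condition=Condition.UNDIGESTED, parent_lineage=Lineage.LYMPHOID,
        experiment_day="day1",
    )
    defaults.update(overrides)
    return SampleMeta(**defaults)


def make_table(values, channel="CD8a", sample_id="s1", **meta_overrides):
    values = np.asarray(values, dtype=float)
    return EventTable(
        sample_id=sample_id, channels=[channel],
        events=values.reshape(-1, 1),
        meta=make_meta(marker=channel, **meta_overrides),
    )


def make_measurement(**overrides) -> ReplicateMeasurement:
    defaults = dict(
        marker="CD8a", clone="RPA-T8", donor_id="donor1",
        experiment_day="day1", parent_lineage=Lineage.LYMPHOID,
        pct_pos_undigested=30.0, pct_pos_digested=15.0,
        positive_detected_digested=True,
    )
    defaults.update(overrides)
    return ReplicateMeasurement(**defaults)
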