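import numpy as np
import pytest

import uqtriage as uq


@pytest.fixture
def toy_records():
    """Fixed 12-nodule cohort for hand-tally checks.

    6 benign / 6 malignant; diameters straddle the 6/8 mm boundaries;
    member vectors chosen so entropy is low for the first 8 nodules and
    high for the last 4.
    """
    low = np.full(4, 0.02)
    high = np.full(4, 0.5)
    spec = [
        # (label, diameter, type, members)
        (0, 4.0, "solid", low),
        (0, 5.9, "solid", low),
        (0, 6.0, "solid", low),
        (0, 7.5, "non_solid", low),
        (1, 8.0, "solid", 1 - low),
        (1, 12.0, "solid", 1 - low),
        (1, 9.0, "part_solid", 1 - low),
        (1, 20.0, "solid", 1 - low),
        (0, 10.0, "non_solid", high),
        (0, 14.0, "solid", high),
        (1, 6.5, "part_solid", high),
        (1, 7.999, "solid", high),
    ]
    return [
        uq.NoduleRecord(
            nodule_id=f"toy-{i:02d}",
            cohort="development",
            label=label,
            diameter_mm=diam,
            nodule_type=ntype,
            members=np.asarray(members, dtype=float),
        )
        for i, (label, diam, ntype, members) in enumerate(spec)
    ]


@pytest.fixture
def dev_scores():
    """Scored screening-like development cohort (883 nodules, seeded)."""
    records = uq.generate_cohort(uq.development_config(seed=7))
    return uq.score_records(records)
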