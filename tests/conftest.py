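import numpy as np
import pandas as pd
import pytest

from lncmeth import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (140 tumors, fixed seed) with its raw
    Ct table; shared across tests that only read it."""
    frame, ct = simulate_cohort(CohortSpec(seed=20240), make_ct=True)
    return frame, ct


@pytest.fixture(scope="session")
def cohort_frame(default_cohort):
    return default_cohort[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_ct_rows(entries, replicates=1, offsets=(0.0,)):
    """Build a long-format Ct table from {(sample, assay): ct} entries."""
    rows = []
    for (sample, assay), ct in entries.items():
        offs = offsets if replicates == len(offsets) else (0.0,) * replicates
        for r, off in enumerate(offs, start=1):
            rows.append(
                (sample, assay, r, ct + off if ct == ct and ct is not None else np.nan)
            )
    return pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"])
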