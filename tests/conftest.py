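import warnings

import numpy as np
import pytest

from myeloflow import gating
from myeloflow.positivity import GatedSample
from myeloflow.synthetic_data import CaseProfile, generate_combined, profile_from_table_row


@pytest.fixture(scope="session")
def nm_case():
    """A mid-size non-malignant case (fixture row 2) with its gating."""
    profile = profile_from_table_row("non_malignant", 2, n_events=20_000)
    table, gt = generate_combined(profile, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        masks = gating.gate_all(table)
    return profile, table, gt, masks


@pytest.fixture(scope="session")
def nm_sample(nm_case):
    _, table, _, masks = nm_case
    return GatedSample(table=table, masks=masks)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_profile(n_events=20_000, cohort="non_malignant", **fracs) -> CaseProfile:
    """Hand-built profile with explicit population fractions."""
    base = {"blast": 1.0, "erythroid": 15.0, "myeloid": 45.0, "monocytic": 3.0}
    base.update(fracs)
    return CaseProfile(
        case_id="test", cohort=cohort, target_fractions=base, n_events=n_events
    )
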