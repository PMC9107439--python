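import numpy as np
import pandas as pd
import pytest

from ieco import (
    CnnSpec,
    SplitSpec,
    make_atlas,
    scale_features,
    simulate_cohort,
    study_cohort_spec,
    encode_all,
)
from ieco.encoding import METRICS, FeatureTable
from ieco.pipeline import cohort_feature_table


@pytest.fixture(scope="session")
def atlas14():
    return make_atlas(14, (12, 12, 14), seed=0)


@pytest.fixture(scope="session")
def atlas6():
    """Small 6-network atlas for fast cohort-level tests."""
    return make_atlas(6, (9, 9, 6), seed=0)


@pytest.fixture(scope="session")
def study_cohort(atlas14):
    """The full four-group study cohort with 2x injected effects,
    n=40/group, T=128, TR=2 s: simulated once per session and shared by
    the cohort-level and classification tests."""
    spec = study_cohort_spec(effect=2.0, n_per_group=40, seed=0)
    subjects = simulate_cohort(spec, atlas14)
    table, qc = cohort_feature_table(subjects, atlas14, spec)
    return spec, subjects, table, qc


@pytest.fixture(scope="session")
def study_images(study_cohort):
    _, _, table, _ = study_cohort
    return encode_all(scale_features(table))


def random_feature_table(rng, n_per_group=6, groups=("TYP", "SCH"), networks=None):
    """A small random FeatureTable for encoding/stats unit tests."""
    networks = networks or [f"Net{i}" for i in range(1, 6)]
    rows = []
    sids, glist = [], []
    i = 0
    for g in groups:
        for _ in range(n_per_group):
            rows.append(
                {f"{m}_{n}": float(rng.uniform(0, 1)) for m in METRICS for n in networks}
            )
            sids.append(f"sub-{i:03d}")
            glist.append(g)
            i += 1
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", sids)
    df.insert(1, "group", glist)
    return FeatureTable(data=df, network_names=networks)
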