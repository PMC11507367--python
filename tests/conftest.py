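"""Shared fixtures: published reference rows, bundled proteins, synthetic tables."""

import numpy as np
import pandas as pd
import pytest

import spoilmark as sm


@pytest.fixture(scope="session")
def milk_proteins():
    return sm.load_milk_proteins()


@pytest.fixture(scope="session")
def alpha_s1(milk_proteins):
    return next(p for p in milk_proteins if p.accession == sm.CASEIN_ALPHA_S1)


@pytest.fixture(scope="session")
def default_timecourse():
    """Default synthetic study (seed 1): table plus ground truth."""
    return sm.generate_timecourse(sm.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def top10_table():
    """The published top-10 in-solution features as a coordinate FeatureTable."""
    records = [(r.feature_id, r.mz, r.rt, int(r.charge))
               for r in sm.TOP10_FEATURES.itertuples()]
    return sm.table_from_records(records)


@pytest.fixture(scope="session")
def band8_table():
    """Synthetic stand-in for the band-8 in-gel table.

    The study reports which band-8 features partner the selected in-solution
    features, but prints no coordinates for them; this synthetic table places
    each partner at the published in-solution coordinates offset by amounts
    inside the cross-match tolerances (0.01 Th, 5 s), plus distant decoys.
    """
    published = sm.TOP10_FEATURES
    records = []
    for r in published.itertuples():
        if r.sds_partner is not None:
            records.append((r.sds_partner, r.mz + 0.004, r.rt + 3.0, int(r.charge)))
    # decoys well outside the tolerances
    records += [("sdsFT9001", 700.7007, 100.0, 1), ("sdsFT9002", 800.8008, 850.0, 2)]
    return sm.table_from_records(records)
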