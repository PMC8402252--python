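"""Shared fixtures: small synthetic recordings and cohorts.

Walk lengths are kept short (tens of metres, a few passes) so the whole
suite generates its data at test time in seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitclass import (
    EffectSizes,
    GaitParams,
    apply_severity,
    generate_cohort,
    generate_recording,
)
from gaitclass.preprocess import (
    detect_foot_contacts,
    detect_turns,
    segment_straight_walks,
)


SMALL_PARAMS = GaitParams(walk_length=30.0, n_passes=3)
NOISEFREE_PARAMS = GaitParams(
    walk_length=30.0, n_passes=3, step_length_sd=0.0, tremor_amplitude=0.0
)


@pytest.fixture(scope="session")
def small_recording():
    return generate_recording(SMALL_PARAMS, "H01", seed=11)


@pytest.fixture(scope="session")
def noisefree_recording():
    return generate_recording(NOISEFREE_PARAMS, "H02", seed=12)


@pytest.fixture(scope="session")
def ataxic_recording():
    params = apply_severity(SMALL_PARAMS, 1.0, EffectSizes())
    return generate_recording(params, "A01", seed=13, label="ataxic")


@pytest.fixture(scope="session")
def small_segments(small_recording):
    rec, _ = small_recording
    contacts = detect_foot_contacts(rec)
    turns = detect_turns(rec)
    return segment_straight_walks(rec, turns, contacts)


@pytest.fixture(scope="session")
def small_cohort():
    """8 healthy + 8 ataxic short walks with ground truth."""
    return generate_cohort(
        8, 8, base_params=SMALL_PARAMS, seed=21
    )


def segments_of(recording):
    contacts = detect_foot_contacts(recording)
    turns = detect_turns(recording)
    return segment_straight_walks(recording, turns, contacts)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from gaitclass import features_table

    segs = []
    for rec, _ in small_cohort:
        segs.extend(segments_of(rec))
    return features_table(segs)
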