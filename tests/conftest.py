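"""Shared fixtures.

The session-scoped fixtures hold the desk-scale six-sample study (15
genera per sample, 5,000 molecules each) that the end-to-end recovery
tests share; they are expensive and computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pollenpipe.evaluation import (
    NOISY_RATES,
    RELAXED_IDENTITY,
    build_study,
    run_long_arm,
    run_short_arm,
)
from pollenpipe.reference_db import ReferenceDatabase, ReferenceRecord
from pollenpipe.synthetic_data import ErrorModel, generate_reference_set

STUDY_SEED = 101


@pytest.fixture(scope="session")
def small_records() -> list[ReferenceRecord]:
    """10 records across 5 genera, 2 species each."""
    return generate_reference_set(5, 2, seed=7)


@pytest.fixture(scope="session")
def small_db(small_records) -> ReferenceDatabase:
    return ReferenceDatabase(small_records)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(424242)


# --- the six-sample study -------------------------------------------------


@pytest.fixture(scope="session")
def study():
    return build_study(STUDY_SEED)


@pytest.fixture(scope="session")
def truth_profiles(study):
    return {sid: study.truth_profile(sid) for sid in study.sample_ids}


@pytest.fixture(scope="session")
def errorfree_long(study):
    """Error-free long reads, end-trim variant, strict identity."""
    error = ErrorModel.long_single(
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0, concatemer_prob=0.0,
        flank_q_penalty=0.0,
    )
    return run_long_arm(study, error, seed=STUDY_SEED + 50, mode="trim", min_identity=0.98)


@pytest.fixture(scope="session")
def noisy_error_model():
    return ErrorModel.long_single(concatemer_prob=0.01, **NOISY_RATES)


@pytest.fixture(scope="session")
def noisy_long_trim(study, noisy_error_model):
    """3%/3%/3% sub/ins/del long reads, end-trim variant, identity 0.80."""
    return run_long_arm(
        study, noisy_error_model, seed=STUDY_SEED + 60, mode="trim",
        min_identity=RELAXED_IDENTITY,
    )


@pytest.fixture(scope="session")
def noisy_long_extract(study, noisy_error_model):
    """Same reads as noisy_long_trim, strict amplicon-extraction variant."""
    return run_long_arm(
        study, noisy_error_model, seed=STUDY_SEED + 60, mode="extract",
        min_identity=RELAXED_IDENTITY,
    )


@pytest.fixture(scope="session")
def short_profiles(study):
    """2x150 ~Q30 paired-end arm at the strict paired rule."""
    return run_short_arm(study, seed=STUDY_SEED + 70)
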