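import warnings

import pandas as pd
import pytest

from armcompare.synthetic_data import GeneratorParams, generate_database, make_fixture


@pytest.fixture(scope="session")
def minimal_db():
    return make_fixture("minimal_two_arm")


@pytest.fixture(scope="session")
def six_study_db():
    return make_fixture("six_study_multilevel")


@pytest.fixture(scope="session")
def paper_db():
    return make_fixture("paper_scale_default")


@pytest.fixture(scope="session")
def small_db():
    """A 12-study database with all reporting complete (no missingness),
    cheap enough for property tests."""
    p = GeneratorParams(seed=5)
    p.n_studies = {"medication": 5, "psychotherapy": 7}
    p.missing_post_sd = 0.0
    p.missing_post_mean = 0.0
    p.missing_sites = {"medication": 0.0, "psychotherapy": 0.0}
    p.missing_age = {"medication": 0.0, "psychotherapy": 0.0}
    p.missing_female = {"medication": 0.0, "psychotherapy": 0.0}
    return generate_database(p)


def assert_frames_value_equal(a: pd.DataFrame, b: pd.DataFrame) -> None:
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
    )
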