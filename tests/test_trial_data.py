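"""Data model, CSV round-trips, validation, and sensitivity filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from armcompare.errors import (
    ConfigError,
    DuplicateError,
    ScaleLookupError,
    SchemaError,
)
from armcompare.trial_data import (
    FilterSpec,
    ScaleSpec,
    TrialDatabase,
    apply_filter,
    load_trials,
)


def _write_csvs(tmp_path, arms_rows, study_rows):
    arms = pd.DataFrame(arms_rows)
    studies = pd.DataFrame(study_rows)
    arms.to_csv(tmp_path / "arms.csv", index=False)
    studies.to_csv(tmp_path / "studies.csv", index=False)
    pd.DataFrame(
        [
            {"name": "CDRS-R", "min_score": 17, "max_score": 113},
            {"name": "HAM-D", "min_score": 0, "max_score": 52},
        ]
    ).to_csv(tmp_path / "scales.csv", index=False)
    return tmp_path


MINIMAL_ARMS = [
    {"study_id": "s1", "arm_id": "c0", "role": "control",
     "control_type": "pill_placebo", "n": 50, "scale": "CDRS-R",
     "baseline_mean": 55.0, "baseline_sd": 9.0, "post_mean": 40.0,
     "post_sd": 10.0},
    {"study_id": "s1", "arm_id": "a1", "role": "active",
     "control_type": "none", "n": 50, "scale": "CDRS-R",
     "baseline_mean": 54.0, "baseline_sd": 8.5, "post_mean": 35.0,
     "post_sd": 9.0},
]
MINIMAL_STUDY = [{"study_id": "s1", "modality": "medication", "n_sites": 4,
                  "subclinical": False, "percent_female": 48.0,
                  "mean_age": 14.1, "sd_age": 1.4, "n_total": 100}]


def test_empty_arms_file_loads_with_warning(tmp_path):
    d = _write_csvs(
        tmp_path,
        pd.DataFrame(columns=list(MINIMAL_ARMS[0].keys())),
        pd.DataFrame(columns=list(MINIMAL_STUDY[0].keys())),
    )
    with pytest.warns(UserWarning, match="empty arms"):
        db = load_trials(d)
    assert db.n_studies == 0 and db.n_arms == 0


def test_minimal_two_row_file(tmp_path):
    d = _write_csvs(tmp_path, MINIMAL_ARMS, MINIMAL_STUDY)
    db = load_trials(d)
    assert db.n_studies == 1
    assert db.n_arms == 2
    assert db.report["n_arms"]["medication_active"] == 1
    assert db.report["n_arms"]["medication_control"] == 1


def test_synthetic_database_roundtrips(tmp_path, paper_db):
    paper_db.save(tmp_path)
    back = load_trials(tmp_path)
    pd.testing.assert_frame_equal(paper_db.arms, back.arms, check_dtype=False)
    pd.testing.assert_frame_equal(
        paper_db.studies, back.studies, check_dtype=False
    )
    assert set(back.scales) == set(paper_db.scales)
    # save(load(x)) identity: a second round-trip is byte-identical
    back.save(tmp_path / "again")
    for name in ("arms.csv", "studies.csv", "scales.csv"):
        assert (tmp_path / name).read_bytes() == \
            (tmp_path / "again" / name).read_bytes()


@pytest.mark.parametrize(
    "mutate, err",
    [
        (lambda a, s: s[0].update(modality="homeopathy"), SchemaError),
        (lambda a, s: a[1].update(arm_id="c0"), DuplicateError),
        (lambda a, s: a[0].update(scale="PHQ-9"), ScaleLookupError),
        (lambda a, s: a[1].update(control_type="waitlist"), SchemaError),
        (lambda a, s: a[0].update(baseline_sd=-1.0), SchemaError),
        (lambda a, s: a[0].update(post_mean=np.nan), SchemaError),
    ],
)
def test_validation_rejects_bad_records(mutate, err):
    arms = [dict(r) for r in MINIMAL_ARMS]
    studies = [dict(r) for r in MINIMAL_STUDY]
    mutate(arms, studies)
    with pytest.raises(err):
        TrialDatabase(pd.DataFrame(studies), pd.DataFrame(arms))


def test_pill_placebo_forbidden_outside_medication():
    studies = [dict(MINIMAL_STUDY[0], modality="psychotherapy")]
    with pytest.raises(SchemaError, match="pill_placebo"):
        TrialDatabase(pd.DataFrame(studies), pd.DataFrame(MINIMAL_ARMS))


def test_unknown_filter_criterion():
    with pytest.raises(ConfigError, match="bogus"):
        FilterSpec.from_dict({"bogus": True})


def test_waitlist_filter_noop_without_waitlists(minimal_db):
    out = apply_filter(minimal_db, {"exclude_waitlist": True})
    pd.testing.assert_frame_equal(out.arms, minimal_db.arms)


def test_waitlist_filter_drops_whole_studies(paper_db):
    arms = paper_db.arms_with_modality()
    is_ctl = arms["role"] == "control"
    wl_studies = set(arms.loc[arms["control_type"] == "waitlist", "study_id"])
    # studies where every control arm is waitlist disappear entirely
    all_wl = {
        sid for sid in wl_studies
        if (arms.loc[(arms["study_id"] == sid) & is_ctl, "control_type"]
            == "waitlist").all()
    }
    out = apply_filter(paper_db, {"exclude_waitlist": True})
    assert all_wl.isdisjoint(set(out.studies["study_id"]))
    assert not (out.arms["control_type"] == "waitlist").any()
    # mixed-control studies survive minus their waitlist arms
    mixed = wl_studies - all_wl
    assert mixed <= set(out.studies["study_id"])


def test_variance_filter_is_strict():
    # three arms engineered to SMD variances 0.01, 0.02, 0.05 at r=0.675:
    # with smd=0 (post=baseline, Hedges J irrelevant), var = 2(1-r)/n = 0.65/n
    studies = [dict(MINIMAL_STUDY[0])]
    arms = []
    for i, n in enumerate([65, 33, 13]):  # -> 0.01, ~0.0197, 0.05
        arms.append({
            "study_id": "s1", "arm_id": f"x{i}",
            "role": "active" if i else "control",
            "control_type": "none" if i else "pill_placebo",
            "n": n, "scale": "CDRS-R", "baseline_mean": 50.0,
            "baseline_sd": 10.0, "post_mean": 50.0, "post_sd": 10.0,
        })
    db = TrialDatabase(pd.DataFrame(studies), pd.DataFrame(arms))
    out = apply_filter(db, {"max_effect_variance": 0.02})
    kept = set(out.arms["arm_id"])
    assert kept == {"x0", "x1"}  # 0.05 removed; 0.0197 < 0.02 kept
    # threshold exactly equal to an arm's variance: strict < excludes it
    thr = 2 * (1 - 0.675) / 65
    out2 = apply_filter(db, {"max_effect_variance": thr})
    assert "x0" not in set(out2.arms["arm_id"])


FILTERS = [
    {"exclude_waitlist": True},
    {"exclude_subclinical": True},
    {"scale_in": ["CDRS-R"]},
    {"require_post_sd": True},
    {"max_effect_variance": 0.03},
    {"all_female_excluded": True},
]


@pytest.mark.parametrize("crit", FILTERS)
def test_filters_idempotent(paper_db, crit):
    once = apply_filter(paper_db, crit)
    twice = apply_filter(once, crit)
    pd.testing.assert_frame_equal(
        once.arms.reset_index(drop=True), twice.arms.reset_index(drop=True)
    )


@pytest.mark.parametrize(
    "c1, c2", list(itertools.combinations(range(len(FILTERS)), 2))
)
def test_filters_commute(paper_db, c1, c2):
    a = apply_filter(apply_filter(paper_db, FILTERS[c1]), FILTERS[c2])
    b = apply_filter(apply_filter(paper_db, FILTERS[c2]), FILTERS[c1])
    pd.testing.assert_frame_equal(
        a.arms.reset_index(drop=True), b.arms.reset_index(drop=True)
    )
    pd.testing.assert_frame_equal(
        a.studies.reset_index(drop=True), b.studies.reset_index(drop=True)
    )


def test_filters_leave_original_untouched(paper_db):
    before = paper_db.arms.copy()
    apply_filter(paper_db, {"exclude_waitlist": True, "require_post_sd": True})
    pd.testing.assert_frame_equal(paper_db.arms, before)


def test_scale_spec_invariants():
    with pytest.raises(SchemaError):
        ScaleSpec("bad", 10.0, 10.0)
    assert ScaleSpec("CDRS-R", 17, 113).range == 96
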