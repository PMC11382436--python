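import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carpalign.axes import AxisVariant
from carpalign.drr import RotationLog
from carpalign.observers import (
    AnnotationLine,
    MeasurementTable,
    ObserverProfile,
    annotation_to_angle,
    make_observer_pool,
    radiocarpal_from_annotations,
    simulate_session,
)
from carpalign.phantom import sample_cohort
from carpalign.volume import BoneLabel

ZERO_NOISE = {
    kind: {b: 0.0 for b in BoneLabel} for kind in ("summation", "stripped")
}


def _line(p1, p2):
    return AnnotationLine(endpoints=(p1, p2), bone=BoneLabel.RADIUS)


def test_annotation_angle_closed_forms():
    assert annotation_to_angle(_line((5.0, 0.0), (5.0, 9.0))) == pytest.approx(0.0)
    assert annotation_to_angle(_line((0.0, 0.0), (1.0, 1.0))) == pytest.approx(45.0)


@given(
    st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
    st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
)
@settings(derandomize=True, max_examples=50)
def test_annotation_angle_ignores_endpoint_order(p1, p2):
    if abs(p1[0] - p2[0]) < 1e-6 and abs(p1[1] - p2[1]) < 1e-6:
        return
    a = annotation_to_angle(_line(p1, p2))
    b = annotation_to_angle(_line(p2, p1))
    assert a == pytest.approx(b, abs=1e-9)
    assert -90.0 < a <= 90.0


def test_coincident_endpoints_rejected():
    with pytest.raises(ValueError, match="distinct"):
        _line((1.0, 1.0), (1.0, 1.0))


def test_radiocarpal_composition():
    assert radiocarpal_from_annotations(54.0, 7.0) == pytest.approx(47.0)
    assert radiocarpal_from_annotations(7.0, 7.0) == pytest.approx(0.0)


def test_zero_noise_session_equals_truth():
    cohort = sample_cohort(5, seed=3)
    pool = make_observer_pool(2, 2, seed=0, noise_sd=ZERO_NOISE)
    log = RotationLog(rotations={ph.wrist_id: 4.0 + i for i, ph in enumerate(cohort)}, seed=0)
    table = simulate_session(cohort, None, pool, session=1, seed=7, rotation_log=log)
    rc = table.radiocarpal()
    for row in rc.itertuples():
        wrist = next(p for p in cohort if p.wrist_id == row.wrist_id)
        expected = wrist.truth_angle(BoneLabel[row.bone.upper()], row.variant)
        assert row.radiocarpal_deg == pytest.approx(expected, abs=1e-9)
    # angle-vs-vertical rows carry the wrist's applied rotation
    radius_rows = table.df[table.df["bone"] == "radius"]
    for row in radius_rows.itertuples():
        assert row.angle_deg == pytest.approx(log.rotation_for(row.wrist_id))


def test_vectorized_radiocarpal_matches_per_pair_loop():
    cohort = sample_cohort(4, seed=1)
    pool = make_observer_pool(1, 1, seed=2)
    table = simulate_session(cohort, None, pool, session=1, seed=5)
    rc = table.radiocarpal()
    df = table.df
    for row in rc.sample(20, random_state=0).itertuples():
        radius = df[
            (df["wrist_id"] == row.wrist_id)
            & (df["observer_id"] == row.observer_id)
            & (df["image_kind"] == row.image_kind)
            & (df["bone"] == "radius")
        ]["angle_deg"].iloc[0]
        assert row.radiocarpal_deg == pytest.approx(
            radiocarpal_from_annotations(row.angle_deg, radius)
        )


def test_noise_sd_is_reproduced_in_the_large():
    """Empirical SD of (drawn - truth) matches the configured noise SD
    within 3 Monte-Carlo standard errors."""
    n = 2500
    cohort = sample_cohort(n, seed=4)
    sd_target = 3.0
    noise = {k: {b: (sd_target if b == BoneLabel.SCAPHOID else 0.0) for b in BoneLabel} for k in ("summation", "stripped")}
    profile = ObserverProfile("obs", instructed=True, noise_sd=noise)
    table = simulate_session(cohort, None, [profile], session=1, seed=11)
    df = table.df
    sub = df[(df["bone"] == "scaphoid") & (df["variant"] == "axial")]
    truth = {ph.wrist_id: ph.truth_angle(BoneLabel.SCAPHOID, "axial") for ph in cohort}
    err = sub["angle_deg"].to_numpy() - sub["wrist_id"].map(truth).to_numpy()
    se = sd_target / np.sqrt(2 * len(err))
    assert abs(err.std(ddof=1) - sd_target) < 3 * se


def test_sessions_draw_independent_errors():
    cohort = sample_cohort(400, seed=6)
    pool = [ObserverProfile("obs", instructed=True)]
    t1 = simulate_session(cohort, None, pool, session=1, seed=13)
    t2 = simulate_session(cohort, None, pool, session=2, seed=13)
    truth = {ph.wrist_id: ph.truth_angle(BoneLabel.CAPITATE, "axial") for ph in cohort}

    def errors(t):
        sub = t.df[(t.df["bone"] == "capitate") & (t.df["variant"] == "axial") & (t.df["image_kind"] == "summation")]
        sub = sub.sort_values("wrist_id")
        return sub["angle_deg"].to_numpy() - sub["wrist_id"].map(truth).to_numpy()

    r = np.corrcoef(errors(t1), errors(t2))[0, 1]
    assert abs(r) < 3.0 / np.sqrt(400)


def test_session_reproducibility():
    cohort = sample_cohort(3, seed=2)
    pool = make_observer_pool(2, 1, seed=5)
    a = simulate_session(cohort, None, pool, session=1, seed=21)
    b = simulate_session(cohort, None, pool, session=1, seed=21)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_uninstructed_observers_cannot_request_stripped_images():
    with pytest.raises(ValueError, match="summation"):
        ObserverProfile("obs", instructed=False, requested_kinds=("summation", "stripped"))


def test_instructed_observer_needs_both_image_kinds():
    cohort = sample_cohort(2, seed=8)
    pool = [ObserverProfile("obs", instructed=True)]
    images = {ph.wrist_id: {"summation"} for ph in cohort}
    with pytest.raises(ValueError, match="stripped"):
        simulate_session(cohort, images, pool, session=1, seed=1)


def test_pool_shape_matches_study_design():
    pool = make_observer_pool(7, 6, seed=0)
    uninstructed = [p for p in pool if not p.instructed]
    assert len(uninstructed) == 7 and len(pool) == 13
    tangential_pref = [
        p
        for p in uninstructed
        if p.preferred_variant.get(BoneLabel.SCAPHOID) == AxisVariant.TANGENTIAL
    ]
    assert len(tangential_pref) == 1


def test_measurement_table_roundtrip_and_validation(tmp_path):
    cohort = sample_cohort(2, seed=9)
    pool = make_observer_pool(1, 1, seed=3)
    table = simulate_session(cohort, None, pool, session=1, seed=2)
    path = table.to_csv(tmp_path / "meas.csv")
    back = MeasurementTable.from_csv(path)
    assert np.allclose(back.df["angle_deg"], table.df["angle_deg"].round(4))
    dup = pd.concat([table.df, table.df.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        MeasurementTable(dup)
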