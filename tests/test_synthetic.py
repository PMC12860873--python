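"""synthetic_data: phantom ground-truth contract and cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from edgescore.metrics import FeatureManifest
from edgescore.spatial import compute_spatial_features
from edgescore.synthetic import (CohortSpec, PhantomSpec, SpecError,
                                 candidate_feature_columns, make_cohort,
                                 make_phantom)


# ------------------------------------------------------------------ phantoms

def test_phantom_hotspot_voxel_is_exact_suvmax(sphere_phantom):
    vol, msk, truth = sphere_phantom
    hotspot = tuple(truth["hotspot_index"])
    assert vol.values[hotspot] == pytest.approx(PhantomSpec().peak_suv)
    assert vol.values.max() == vol.values[hotspot]
    assert msk.values[hotspot]


def test_phantom_truth_matches_spec_geometry():
    spec = PhantomSpec(hotspot_fraction=0.25)
    _, _, truth = make_phantom(spec)
    assert truth["nDmaxC"] == pytest.approx(0.25)
    assert truth["nDmaxP"] == pytest.approx(0.75)
    assert truth["EPS"] == pytest.approx(2 * 0.25 - 1)


def test_phantom_is_deterministic():
    a_vol, a_msk, a_truth = make_phantom(PhantomSpec(noise_sigma=0.1, seed=3))
    b_vol, b_msk, b_truth = make_phantom(PhantomSpec(noise_sigma=0.1, seed=3))
    np.testing.assert_array_equal(a_vol.values, b_vol.values)
    np.testing.assert_array_equal(a_msk.values, b_msk.values)
    assert a_truth == b_truth


def test_phantom_noise_seed_changes_values():
    a, _, _ = make_phantom(PhantomSpec(noise_sigma=0.1, seed=3))
    b, _, _ = make_phantom(PhantomSpec(noise_sigma=0.1, seed=4))
    assert not np.array_equal(a.values, b.values)


def test_phantom_spatial_features_track_truth_center():
    """At f=0 the hotspot sits on the centroid: EPS = -1 exactly."""
    vol, msk, truth = make_phantom(PhantomSpec(hotspot_fraction=0.0))
    feats = compute_spatial_features(vol, msk)
    assert feats.hotspot_index == tuple(truth["hotspot_index"])
    assert feats.DmaxC == pytest.approx(0.0, abs=1e-9)
    assert feats.EPS == pytest.approx(-1.0)


def test_phantom_ellipsoid_mask_shape():
    spec = PhantomSpec(shape="ellipsoid", radius_vox=(16.0, 10.0, 8.0))
    _, msk, _ = make_phantom(spec)
    expected = 4.0 / 3.0 * np.pi * 16 * 10 * 8
    assert msk.voxel_count == pytest.approx(expected, rel=0.05)


def test_phantom_validation():
    with pytest.raises(SpecError):
        PhantomSpec(hotspot_fraction=1.5)
    with pytest.raises(SpecError):
        PhantomSpec(radius_vox=2.0)
    with pytest.raises(SpecError):
        PhantomSpec(shape="cube")


# ------------------------------------------------------------------ cohorts

def test_cohort_shape_and_columns(cohort244):
    df = cohort244
    assert len(df) == 244
    for col in ["age", "sex_female", "stage", "stage_advanced", "MTV_ml",
                "SUVmax", "SUVmean", "TLG", "nDmaxC", "nDmaxP", "EPS",
                "eps_group", "LVI", "VPI", "STAS", "pfs_months", "pfs_event"]:
        assert col in df.columns, col
    for col in candidate_feature_columns():
        assert col in df.columns, col
    assert df.notna().all().all()


def test_cohort_eps_satisfies_score_formula(cohort244):
    df = cohort244
    expected = (df["nDmaxC"] - df["nDmaxP"]) / (df["nDmaxC"] + df["nDmaxP"])
    np.testing.assert_allclose(df["EPS"], expected, rtol=1e-12)
    np.testing.assert_array_equal(df["eps_group"], (df["EPS"] > 0).astype(int))


def test_cohort_is_deterministic_and_seed_sensitive():
    a = make_cohort(CohortSpec(n=100, seed=5))
    b = make_cohort(CohortSpec(n=100, seed=5))
    c = make_cohort(CohortSpec(n=100, seed=6))
    pd.testing.assert_frame_equal(a, b)
    assert not a["age"].equals(c["age"])


def test_cohort_marginals_match_spec_at_large_n(cohort_large):
    df = cohort_large
    spec = CohortSpec()
    assert df["age"].median() == pytest.approx(spec.age_median, rel=0.05)
    assert df["MTV_ml"].median() == pytest.approx(spec.mtv_median, rel=0.15)
    assert df["SUVmax"].median() == pytest.approx(spec.suvmax_median, rel=0.15)
    assert df["nDmaxC"].median() == pytest.approx(spec.ndmaxc_median, rel=0.15)
    assert df["nDmaxP"].median() == pytest.approx(spec.ndmaxp_median, rel=0.15)


def test_cohort_event_rate_and_prevalence(cohort_large):
    df = cohort_large
    spec = CohortSpec()
    assert df["pfs_event"].mean() == pytest.approx(spec.event_rate, abs=0.05)
    for label, p in spec.label_prevalence.items():
        assert df[label].mean() == pytest.approx(p, abs=0.05)


def test_cohort_high_eps_group_has_worse_outcomes(cohort_large):
    df = cohort_large
    high = df[df["eps_group"] == 1]
    low = df[df["eps_group"] == 0]
    assert high["pfs_event"].mean() > low["pfs_event"].mean()
    assert high["LVI"].mean() > low["LVI"].mean()


def test_cohort_null_eps_effect_removes_association():
    null = {ep: {"EPS": 0.0} for ep in ("LVI", "VPI", "STAS")}
    spec = CohortSpec(n=2000, seed=9, label_log_odds=null,
                      hr_eps_group=1.0, hr_stage=1.0, hr_vpi=1.0,
                      hr_age_per_year=1.0, hr_mtv_per_ml=1.0)
    df = make_cohort(spec)
    from scipy import stats
    r, p = stats.pointbiserialr(df["LVI"], df["EPS"])
    assert abs(r) < 0.08
    # survival no longer differs between EPS groups
    high = df.loc[df.eps_group == 1, "pfs_event"].mean()
    low = df.loc[df.eps_group == 0, "pfs_event"].mean()
    assert abs(high - low) < 0.06


def test_cohort_feature_count_is_full_manifest(cohort244):
    manifest = FeatureManifest.default()
    feature_cols = candidate_feature_columns()
    assert len(feature_cols) == 7 + len(manifest) == 122
    assert len([c for c in cohort244.columns if c in feature_cols]) == 122


def test_cohort_rejects_bad_specs():
    with pytest.raises(SpecError):
        CohortSpec(n=5)
    with pytest.raises(SpecError):
        CohortSpec(event_rate=1.5)
    with pytest.raises(SpecError):
        CohortSpec(stage_probs=(0.5, 0.5, 0.5))
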