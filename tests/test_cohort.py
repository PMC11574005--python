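"""Cohort generator, stage bookkeeping, matching, and thickness simulation."""

import numpy as np
import pandas as pd
import pytest

from shapestage.cohort import (
    EffectSpec,
    StageBump,
    default_effect_spec,
    group_stages,
    match_controls,
    regroup_stage,
    simulate_cohort,
    simulate_thickness,
)
from shapestage.errors import MatchingError, ParameterError, ValidationError


def test_empty_cohort():
    df = simulate_cohort({"control": 0, 1: 0}, seed=0)
    assert len(df) == 0


def test_cohort_reproducible_and_controls_have_no_stage():
    a = simulate_cohort({"control": 30, 1: 10, 2.5: 10}, n_cohorts=3, seed=5)
    b = simulate_cohort({"control": 30, 1: 10, 2.5: 10}, n_cohorts=3, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert a.loc[a.group == "control", "hy_stage"].isna().all()
    assert set(a.loc[a.group == "PD", "hy_stage"]) == {1.0, 2.5}
    assert (a.age > 0).all() and (a.icv > 0).all()
    moca = a.moca.dropna()
    assert ((moca >= 0) & (moca <= 30)).all()


def test_negative_group_size_raises():
    with pytest.raises(ParameterError):
        simulate_cohort({"control": -1}, seed=0)


def test_clinical_gradient_is_monotone_across_stages():
    # Monte-Carlo check of the generator's monotone parameterization
    df = simulate_cohort({1: 500, 2: 500, 3: 500, 4: 500, 5: 500}, seed=11)
    g = df.groupby("hy_stage")
    moca = g["moca"].mean()
    assert moca.is_monotonic_decreasing
    assert g["time_since_diagnosis"].mean().is_monotonic_increasing
    assert g["updrs3"].mean().is_monotonic_increasing


@pytest.mark.parametrize(
    "raw,expected", [(1, 1), (1.5, 2), (2, 2), (2.5, 2), (3, 3), (4, 4), (5, 5)]
)
def test_regroup_stage(raw, expected):
    assert regroup_stage(raw) == expected


def test_regroup_rejects_unknown_stage():
    with pytest.raises(ValidationError):
        regroup_stage(0.5)


def test_group_stages_schemes():
    stages = [1, 1.5, 2, 2.5, 3, 4, 5]
    assert list(group_stages(stages, "HY45")) == ["1", "2", "2", "2", "3", "45", "45"]
    assert list(group_stages(stages, "HY345")) == ["1", "2", "2", "2", "345", "345", "345"]


def _subjects(rows):
    df = pd.DataFrame(rows, columns=["age", "sex"])
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(df))])
    return df


def test_match_identical_control_selected():
    cases = _subjects([(65.0, 1)])
    controls = _subjects([(65.0, 1), (40.0, 1), (65.0, 0)])
    out = match_controls(cases, controls, ratio=1, seed=0)
    assert list(out.subject_id) == ["s0"]


def test_match_two_cases_equals_bruteforce_minimum():
    cases = _subjects([(60.0, 1), (70.0, 1)])
    controls = _subjects([(59.0, 1), (66.0, 1), (71.0, 1)])
    out = match_controls(cases, controls, ratio=1, seed=0)
    # exhaustive enumeration of one-to-one assignments
    import itertools

    best, best_cost = None, np.inf
    ca = cases.age.to_numpy()
    co = controls.age.to_numpy()
    scale = pd.concat([cases.age, controls.age]).std(ddof=0)
    for pair in itertools.permutations(range(3), 2):
        cost = sum(abs(ca[i] - co[j]) / scale for i, j in enumerate(pair))
        if cost < best_cost:
            best, best_cost = set(pair), cost
    assert set(controls.index[controls.subject_id.isin(out.subject_id)]) == best


def test_match_ratio_two_takes_two_nearest():
    cases = _subjects([(60.0, 1)])
    controls = _subjects([(58.0, 1), (61.0, 1), (70.0, 1), (80.0, 1), (59.5, 1)])
    out = match_controls(cases, controls, ratio=2, seed=0)
    assert set(out.subject_id) == {"s1", "s4"}  # distances 1 and 0.5


def test_match_sex_is_exact_by_default():
    cases = _subjects([(60.0, 1)])
    controls = _subjects([(60.0, 0), (75.0, 1)])
    out = match_controls(cases, controls, ratio=1, seed=0)
    assert list(out.subject_id) == ["s1"]


def test_match_empty_pool_raises():
    cases = _subjects([(60.0, 1)])
    with pytest.raises(MatchingError):
        match_controls(cases, cases.iloc[:0], seed=0)


def test_matching_reduces_age_gap():
    rng_cases = simulate_cohort({3: 60}, seed=1)
    controls = simulate_cohort({"control": 300}, seed=2)
    out = match_controls(rng_cases, controls, ratio=2, seed=3)
    gap_matched = abs(out.age.mean() - rng_cases.age.mean())
    gap_pool = abs(controls.age.mean() - rng_cases.age.mean())
    assert gap_matched < gap_pool


# ---------------------------------------------------------------------------
# thickness simulation


def test_zero_noise_zero_effects_equals_baseline(toy_atlas):
    cohort = simulate_cohort({"control": 4, 2: 3}, seed=0)
    spec = EffectSpec(bumps=[], beta_age=0, beta_sex=0, beta_icv=0, cohort_sd=0, residual_sd=0)
    tm = simulate_thickness(toy_atlas, cohort, spec, seed=0)
    assert np.allclose(tm.values, tm.values[0])  # every subject identical
    assert (tm.values > 0).all()


def test_planted_bump_exact_at_center_with_zero_noise(toy_atlas):
    cohort = simulate_cohort({"control": 5, 2: 5}, seed=1)
    bump = StageBump("putamen_left", 10, radius=3, amplitude=-0.3, stages=(2.0,))
    spec = EffectSpec(bumps=[bump], beta_age=0, beta_sex=0, beta_icv=0, cohort_sd=0, residual_sd=0)
    tm = simulate_thickness(toy_atlas, cohort, spec, seed=1)
    start, _ = toy_atlas.vertex_offsets["putamen_left"]
    v = start + 10
    pd_mask = (cohort.group == "PD").to_numpy()
    diff = tm.values[pd_mask, v].mean() - tm.values[~pd_mask, v].mean()
    assert diff == pytest.approx(-0.3, abs=1e-12)


def test_planted_bump_recovered_within_3se_under_noise(toy_atlas):
    n = 200
    cohort = simulate_cohort({"control": n, 2: n}, seed=2)
    bump = StageBump("putamen_left", 10, radius=3, amplitude=-0.3, stages=(2.0,))
    spec = EffectSpec(bumps=[bump], beta_age=0, beta_sex=0, beta_icv=0, cohort_sd=0, residual_sd=0.2)
    tm = simulate_thickness(toy_atlas, cohort, spec, seed=2)
    start, _ = toy_atlas.vertex_offsets["putamen_left"]
    v = start + 10
    pd_mask = (cohort.group == "PD").to_numpy()
    diff = tm.values[pd_mask, v].mean() - tm.values[~pd_mask, v].mean()
    se = 0.2 * np.sqrt(2 / n)
    assert abs(diff - (-0.3)) < 3 * se


def test_thickness_reproducible(toy_atlas):
    cohort = simulate_cohort({"control": 6, 1: 6}, seed=3)
    spec = default_effect_spec(toy_atlas)
    a = simulate_thickness(toy_atlas, cohort, spec, seed=9)
    b = simulate_thickness(toy_atlas, cohort, spec, seed=9)
    np.testing.assert_array_equal(a.values, b.values)


def test_ols_recovers_planted_covariate_effects(toy_atlas):
    # regression of simulated thickness on the generating design, one cohort
    n = 800
    cohort = simulate_cohort({"control": n}, n_cohorts=1, seed=4)
    spec = EffectSpec(bumps=[], beta_age=-0.01, beta_sex=0.2, beta_icv=0.0, cohort_sd=0.0, residual_sd=0.1)
    tm = simulate_thickness(toy_atlas, cohort, spec, seed=4)
    X = np.column_stack([np.ones(n), cohort.age, cohort.sex])
    v = 5
    beta, *_ = np.linalg.lstsq(X, tm.values[:, v], rcond=None)
    assert beta[1] == pytest.approx(-0.01, abs=2e-3)
    assert beta[2] == pytest.approx(0.2, abs=3e-2)


def test_bump_center_out_of_range_raises(toy_atlas):
    cohort = simulate_cohort({2: 3}, seed=0)
    bump = StageBump("putamen_left", 10_000, radius=3, amplitude=-0.3, stages=(2.0,))
    with pytest.raises(ValidationError):
        simulate_thickness(toy_atlas, cohort, EffectSpec(bumps=[bump], residual_sd=0.0), seed=0)
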