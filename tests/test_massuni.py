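"""Vertex-wise effect maps and the searchlight FDR procedure."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from shapestage.cohort import ThicknessMatrix
from shapestage.errors import AlignmentError, DesignMatrixError
from shapestage.massuni import (
    DesignSpec,
    EffectMap,
    fit_vertex_lmm,
    map_effects,
    searchlight_fdr,
    summarize_map,
)


def _cohort_frame(rng, n=120, n_cohorts=4):
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "is_pd": rng.integers(0, 2, n),
            "age": rng.normal(62, 9, n),
            "sex": rng.integers(0, 2, n),
            "icv": rng.normal(1.5e6, 1.5e5, n),
            "cohort_id": rng.integers(0, n_cohorts, n).astype(str),
        }
    )
    return df


def _thickness(rng, df, V=10, effect=0.0):
    base = 3.0 + rng.normal(0, 0.2, (len(df), V))
    base[:, 0] += effect * df["is_pd"].to_numpy()
    return ThicknessMatrix(base, df["subject_id"].to_numpy())


def test_map_effects_equals_per_vertex_fits(rng):
    df = _cohort_frame(rng)
    tm = _thickness(rng, df, V=10, effect=-0.3)
    design = DesignSpec(predictor="is_pd")
    emap = map_effects(tm, design, df)
    for v in [0, 3, 9]:
        b, se, p = fit_vertex_lmm(tm.values[:, v], design, df)
        assert emap.beta[v] == pytest.approx(b, abs=1e-12)
        assert emap.p[v] == pytest.approx(p, abs=1e-12)


def test_consistent_row_permutation_leaves_map_unchanged(rng):
    df = _cohort_frame(rng)
    tm = _thickness(rng, df, V=6, effect=-0.2)
    emap = map_effects(tm, DesignSpec(predictor="is_pd"), df)
    perm = rng.permutation(len(df))
    df2 = df.iloc[perm].reset_index(drop=True)
    tm2 = ThicknessMatrix(tm.values[perm], df2["subject_id"].to_numpy())
    emap2 = map_effects(tm2, DesignSpec(predictor="is_pd"), df2)
    np.testing.assert_allclose(emap2.beta, emap.beta, atol=1e-10)


def test_nuisance_rescaling_leaves_beta_unchanged(rng):
    df = _cohort_frame(rng)
    tm = _thickness(rng, df, V=4, effect=-0.25)
    emap = map_effects(tm, DesignSpec(predictor="is_pd"), df)
    df2 = df.copy()
    df2["age"] = (df2["age"] - 60.0) / 10.0
    df2["icv"] = df2["icv"] / 1e6
    emap2 = map_effects(tm, DesignSpec(predictor="is_pd"), df2)
    np.testing.assert_allclose(emap2.beta, emap.beta, atol=1e-6)


def test_misaligned_subjects_raise(rng):
    df = _cohort_frame(rng)
    tm = _thickness(rng, df)
    df2 = df.iloc[::-1].reset_index(drop=True)
    with pytest.raises(AlignmentError):
        map_effects(tm, DesignSpec(predictor="is_pd"), df2)


def test_constant_predictor_raises(rng):
    df = _cohort_frame(rng)
    df["is_pd"] = 1
    tm = _thickness(rng, df)
    with pytest.raises(DesignMatrixError):
        map_effects(tm, DesignSpec(predictor="is_pd"), df)


def test_planted_bump_beta_peaks_at_center(rng):
    df = _cohort_frame(rng, n=400)
    V = 30
    base = 3.0 + rng.normal(0, 0.2, (len(df), V))
    profile = np.exp(-np.arange(V) / 2.0) * -0.3  # decays away from vertex 0
    base += np.outer(df["is_pd"].to_numpy(), profile)
    tm = ThicknessMatrix(base, df["subject_id"].to_numpy())
    emap = map_effects(tm, DesignSpec(predictor="is_pd"), df)
    assert np.argmax(np.abs(emap.beta)) == 0


# ---------------------------------------------------------------------------
# searchlight FDR


def _ring_edges(n):
    return np.array([(i, (i + 1) % n) for i in range(n)])


def test_all_null_and_all_signal_masks():
    edges = _ring_edges(50)
    assert not searchlight_fdr(np.ones(50), edges, 3, 0.05).any()
    assert searchlight_fdr(np.full(50, 1e-12), edges, 3, 0.05).all()


def test_searchlight_matches_bruteforce_neighborhood_bh(rng):
    n = 200
    edges = _ring_edges(n)
    p = np.concatenate([rng.uniform(0, 1, n - 20), rng.uniform(0, 1e-4, 20)])
    rng.shuffle(p)
    mask = searchlight_fdr(p, edges, 3, 0.05)
    # independent re-computation per vertex
    for v in range(n):
        hood = [(v + k) % n for k in range(-3, 4)]
        ps = np.sort(p[hood])
        crit = 0.05 * np.arange(1, len(ps) + 1) / len(ps)
        passing = ps[ps <= crit]
        thr = passing[-1] if len(passing) else -1.0
        assert mask[v] == (p[v] <= thr)


def test_radius_infinity_equals_global_bh(rng):
    n = 300
    edges = _ring_edges(n)
    for _ in range(5):
        p = np.concatenate([rng.uniform(0, 1, n - 30), rng.uniform(0, 1e-3, 30)])
        rng.shuffle(p)
        mask = searchlight_fdr(p, edges, None, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(mask, ref)


def test_radius_zero_is_single_test_rule(rng):
    n = 40
    p = rng.uniform(0, 1, n)
    mask = searchlight_fdr(p, _ring_edges(n), 0, 0.05)
    np.testing.assert_array_equal(mask, p <= 0.05)


def test_summarize_map_counts(toy_atlas):
    V = toy_atlas.n_vertices
    beta = np.zeros(V)
    p = np.ones(V)
    sl = toy_atlas.structure_slice("putamen_left")
    beta[sl] = -0.2
    mask = np.zeros(V, dtype=bool)
    mask[sl.start : sl.start + 10] = True
    beta[sl.start] = -0.4  # peak
    emap = EffectMap(beta, np.ones(V), p, sig_mask=mask, q_level=0.05)
    out = summarize_map(emap, toy_atlas).set_index("structure")
    npl = sl.stop - sl.start
    assert out.loc["putamen_left", "pct_significant"] == pytest.approx(100 * 10 / npl)
    assert out.loc["putamen_left", "peak_beta"] == pytest.approx(-0.4)
    assert out.loc["pallidum_right", "pct_significant"] == 0
    assert out.loc["pallidum_right", "peak_beta"] == 0
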