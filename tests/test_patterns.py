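"""Ordination and model-profile clustering, against hand-computed and
brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirnaome import patterns
from mirnaome.patterns import (
    average_linkage,
    hcluster_libraries,
    pca_libraries,
    run_stem,
    stem_assign,
    stem_enumerate,
    stem_select,
    stem_significance,
    trajectory_transform,
    zscore,
)

# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------


def test_zscore_rows_standardised_and_roundtrip():
    df = pd.DataFrame(
        {"L1": [1.0, 5.0], "L2": [2.0, 6.0], "L3": [3.0, 10.0]},
        index=["a", "b"],
    )
    z = zscore(df)
    assert np.allclose(z.mean(axis=1), 0.0)
    assert np.allclose(z.std(axis=1, ddof=1), 1.0)
    restored = z.mul(df.std(axis=1, ddof=1), axis=0).add(df.mean(axis=1), axis=0)
    assert np.allclose(restored.to_numpy(), df.to_numpy(), atol=1e-10)


def test_zscore_drops_constant_rows_with_warning():
    df = pd.DataFrame({"L1": [1.0, 4.0], "L2": [1.0, 5.0]}, index=["flat", "var"])
    with pytest.warns(UserWarning, match="constant"):
        z = zscore(df)
    assert list(z.index) == ["var"]
    with pytest.raises(ValueError):
        zscore(pd.DataFrame({"L1": [1.0], "L2": [1.0]}, index=["flat"]))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_duplicate_libraries_share_scores():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(30, 5))
    data[:, 3] = data[:, 1]  # two identical libraries
    df = pd.DataFrame(data, columns=[f"L{i}" for i in range(5)])
    df.index = [f"m{i}" for i in range(30)]
    res = pca_libraries(zscore(df))
    assert np.allclose(res.scores.loc["L1"], res.scores.loc["L3"], atol=1e-8)


def test_pca_variance_fractions_match_direct_eigendecomposition():
    toy = pd.DataFrame(
        [[2.0, 0.5, 1.0], [0.0, 1.5, -1.0], [1.0, -1.0, 0.5], [-3.0, -1.0, -0.5]],
        index=["m1", "m2", "m3", "m4"],
        columns=["L1", "L2", "L3"],
    )
    res = pca_libraries(toy)
    obs = toy.T.to_numpy()
    centered = obs - obs.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    expected = sv**2 / (sv**2).sum()
    assert np.allclose(
        res.variance_ratio.to_numpy(), expected[: len(res.variance_ratio)]
    )
    assert (res.variance_ratio.to_numpy() >= 0).all()
    assert res.variance_ratio.sum() <= 1 + 1e-9


def test_pca_orders_stages_along_first_component_for_pure_gradient():
    """A single planted gradient across stages must appear as a monotone
    PC1 ordering of the libraries."""
    stages = np.arange(5, dtype=float)
    rng = np.random.default_rng(1)
    loadings = rng.normal(size=40)
    data = np.outer(loadings, stages)  # rank-one stage gradient
    df = pd.DataFrame(
        data, index=[f"m{i}" for i in range(40)],
        columns=[f"L{s}" for s in range(5)],
    )
    res = pca_libraries(zscore(df))
    pc1 = res.scores["PC1"].to_numpy()
    diffs = np.diff(pc1)
    assert (diffs > 0).all() or (diffs < 0).all()


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def test_identical_libraries_merge_first_at_height_zero():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(25, 4))
    data[:, 2] = data[:, 0]
    df = pd.DataFrame(
        data, index=[f"m{i}" for i in range(25)], columns=list("ABCD")
    )
    res = hcluster_libraries(zscore(df))
    first = res.linkage_matrix[0]
    assert first[2] == pytest.approx(0.0, abs=1e-10)
    merged = {res.labels[int(first[0])], res.labels[int(first[1])]}
    assert merged == {"A", "C"}


def test_three_leaf_average_linkage_matches_hand_computation():
    # distances: d(A,B)=0.1, d(A,C)=0.5, d(B,C)=0.6
    d = pd.DataFrame(
        [[0.0, 0.1, 0.5], [0.1, 0.0, 0.6], [0.5, 0.6, 0.0]],
        index=list("ABC"),
        columns=list("ABC"),
    )
    z = average_linkage(d)
    assert z[0][2] == pytest.approx(0.1)  # A+B first
    assert {int(z[0][0]), int(z[0][1])} == {0, 1}
    assert z[1][2] == pytest.approx((0.5 + 0.6) / 2)  # average to C


def test_same_stage_libraries_pair_when_no_breed_effect(small_config):
    """With no planted breed effect the two breeds' same-stage libraries are
    each other's nearest neighbours under noise-free counts."""
    from mirnaome import SimConfig, generate_dataset, run_on_dataset

    cfg = SimConfig(
        **{
            **small_config.__dict__,
            "n_breed_de": 0,
            "n_true_targets": 0,
            "n_decoy_targets": 0,
        }
    )
    res = run_on_dataset(generate_dataset(cfg))
    z = patterns.zscore(res.filtered.tpm)
    d = patterns.correlation_distance_matrix(z)
    for stage in cfg.stages:
        a, b = f"TC{stage}", f"YK{stage}"
        others = [c for c in d.columns if c != a]
        assert d.loc[a, b] == min(d.loc[a, others])


# ---------------------------------------------------------------------------
# model profiles
# ---------------------------------------------------------------------------


def test_enumeration_count_and_distinctness():
    c5 = stem_enumerate(5)
    assert len(c5) == 81  # 3^4
    assert len({values for _, values in c5}) == 81
    assert len(stem_enumerate(2)) == 3
    with pytest.raises(ValueError):
        stem_enumerate(1)


def test_select_all_returns_every_candidate():
    candidates = stem_enumerate(3)
    profiles = stem_select(candidates, len(candidates))
    assert {p.values for p in profiles} == {v for _, v in candidates}
    with pytest.raises(ValueError):
        stem_select(candidates, len(candidates) + 1)


def test_select_two_from_three_takes_the_monotone_extremes():
    candidates = stem_enumerate(2)  # steps -1, 0, +1
    profiles = stem_select(candidates, 2)
    assert {p.steps for p in profiles} == {(-1,), (1,)}


def test_selection_is_deterministic_and_includes_flat_profile():
    a = stem_select(stem_enumerate(5), 20)
    b = stem_select(stem_enumerate(5), 20)
    assert [p.values for p in a] == [p.values for p in b]
    assert any(p.is_flat for p in a)
    # profile 0 is the monotone decline (largest total change, lex tie-break)
    assert a[0].steps == (-1, -1, -1, -1)


def _default_profiles():
    return stem_select(stem_enumerate(5), 20)


def test_trajectory_equal_to_profile_assigns_with_correlation_one():
    profiles = _default_profiles()
    target = profiles[5]
    tpm = pd.DataFrame(
        [np.exp2(np.asarray(target.values)) * 100.0],
        index=["m"],
        columns=[40, 55, 63, 70, 90],
    )
    assigned = stem_assign(tpm, profiles)
    assert "m" in assigned[5].assigned


def test_strictly_decreasing_trajectory_goes_to_decline_profile():
    profiles = _default_profiles()
    tpm = pd.DataFrame(
        [[1000.0, 400.0, 150.0, 60.0, 20.0]], index=["m"],
        columns=[40, 55, 63, 70, 90],
    )
    assigned = stem_assign(tpm, profiles)
    decline = next(p for p in assigned if p.steps == (-1, -1, -1, -1))
    assert decline.assigned == ["m"]


def test_constant_trajectory_goes_to_flat_profile():
    profiles = _default_profiles()
    tpm = pd.DataFrame(
        [[5.0, 5.0, 5.0, 5.0, 5.0]], index=["m"], columns=[40, 55, 63, 70, 90]
    )
    assigned = stem_assign(tpm, profiles)
    flat = next(p for p in assigned if p.is_flat)
    assert flat.assigned == ["m"]


def test_assignment_matches_exhaustive_argmax_oracle():
    profiles = _default_profiles()
    rng = np.random.default_rng(3)
    tpm = pd.DataFrame(
        np.exp2(rng.normal(size=(50, 5))) * 50,
        index=[f"m{i}" for i in range(50)],
        columns=[40, 55, 63, 70, 90],
    )
    assigned = stem_assign(tpm, profiles)
    traj = trajectory_transform(tpm)
    vecs = {p.profile_id: np.asarray(p.values) for p in profiles}
    for mir in tpm.index:
        t = traj.loc[mir].to_numpy()
        corrs = {}
        for pid, v in vecs.items():
            if np.ptp(v) == 0 or np.ptp(t) == 0:
                corrs[pid] = 0.0
            else:
                corrs[pid] = np.corrcoef(t, v)[0, 1]
        best = min(corrs, key=lambda pid: (-corrs[pid], pid))
        actual = next(p.profile_id for p in assigned if mir in p.assigned)
        assert actual == best


def test_every_mirna_assigned_to_exactly_one_profile(pipeline_result):
    for breed, profiles in pipeline_result.profiles.items():
        assigned = [m for p in profiles for m in p.assigned]
        assert len(assigned) == len(set(assigned))
        assert set(assigned) == set(pipeline_result.filtered.tpm.index)


def test_flat_profile_expectation_invariant_under_permutation_symmetry():
    """Under exchangeable stage labels, a constant trajectory lands on the
    flat profile for every permutation, so its expected count is exact."""
    profiles = _default_profiles()
    tpm = pd.DataFrame(
        [[7.0] * 5, [1000.0, 400.0, 150.0, 60.0, 20.0]],
        index=["flat", "down"],
        columns=[40, 55, 63, 70, 90],
    )
    assigned = stem_assign(tpm, profiles)
    scored = stem_significance(assigned, tpm)
    flat = next(p for p in scored if p.is_flat)
    assert flat.expected == pytest.approx(1.0)


def test_observed_equal_expected_is_not_significant():
    profiles = _default_profiles()
    tpm = pd.DataFrame(
        [[7.0] * 5], index=["flat"], columns=[40, 55, 63, 70, 90]
    )
    scored = stem_significance(stem_assign(tpm, profiles), tpm)
    flat = next(p for p in scored if p.is_flat)
    assert flat.expected == pytest.approx(1.0)
    assert flat.p_value >= 0.5
    assert not flat.significant


def test_planted_decline_cluster_recovered_and_significant(
    pipeline_result, dataset
):
    for breed, profiles in pipeline_result.profiles.items():
        decline = next(p for p in profiles if p.steps == (-1, -1, -1, -1))
        assert set(dataset.truth.declining) <= set(decline.assigned)
        assert decline.significant


def test_dominant_decline_plant_makes_decline_profile_most_significant(
    small_config,
):
    """With >= 80% of miRNAs planted on the declining trend (noise-free),
    the decline profile collects exactly the planted set and is the most
    significant profile."""
    from mirnaome import SimConfig, generate_dataset, run_on_dataset

    cfg = SimConfig(
        **{
            **small_config.__dict__,
            "n_decline": 25,  # 25 of 30 miRNAs decline
            "n_breed_de": 0,
            "n_true_targets": 0,
            "n_decoy_targets": 0,
        }
    )
    res = run_on_dataset(generate_dataset(cfg))
    ds_truth = generate_dataset(cfg).truth
    for breed, profiles in res.profiles.items():
        decline = next(p for p in profiles if p.steps == (-1, -1, -1, -1))
        assert set(decline.assigned) == set(ds_truth.declining)
        best = min(profiles, key=lambda p: p.p_value)
        assert best.profile_id == decline.profile_id


def test_stem_pipeline_is_bit_reproducible(dataset, pipeline_result):
    breed = "TC"
    tpm = pipeline_result.filtered.stage_matrix(breed)
    again = run_stem(tpm)
    for p, q in zip(pipeline_result.profiles[breed], again):
        assert p.values == q.values
        assert p.assigned == q.assigned
        assert p.expected == q.expected
        assert p.p_value == q.p_value
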