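"""Permutation machinery: exactness by enumeration, NPC synchronization,
Shaffer logic, eye-position classification, and whole-study invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cytolaminar.inference import (
    ModelSpec,
    build_scheme,
    classify_eye_position,
    npc_fisher_combine,
    pairwise_tests,
    permutation_test,
    possible_true_null_counts,
    run_grouping_analysis,
    shaffer_adjust,
    shaffer_multipliers,
)
from cytolaminar.pipeline import measure_study, summarize_study
from cytolaminar.synthetic import GroupEffect, generate_group_study
from tests.conftest import SMALL_LAYERS

# ---------------------------------------------------------------------------
# univariate permutation test


def test_constant_observations_give_p_one():
    res = permutation_test(np.full(12, 3.7), np.repeat(["a", "b"], 6), 999)
    assert res.p_value == 1.0


def test_small_groups_are_enumerated_exhaustively():
    res = permutation_test(
        [1.0, 2.0, 3.0, 10.0, 11.0, 12.0], np.repeat(["a", "b"], 3), 999
    )
    assert res.exhaustive
    assert res.scheme.n_perms == 20  # C(6,3) distinct splits
    assert res.p_value >= 1 / 20


def test_exhaustive_p_matches_monte_carlo_within_002():
    v = np.array([1.2, 0.3, 0.5, 2.1, 2.5, 1.9])
    g = np.repeat(["a", "b"], 3)
    p_exact = permutation_test(v, g, 10_000).p_value
    p_mc = permutation_test(v, g, 10_000, seed=4, force_monte_carlo=True).p_value
    assert abs(p_exact - p_mc) < 0.02


def test_p_floor_and_ceiling(rng):
    for _ in range(10):
        v = rng.normal(size=14)
        res = permutation_test(v, np.repeat(["a", "b"], 7), 499, seed=rng)
        assert 1 / (499 + 1) <= res.p_value <= 1.0


def test_single_group_rejected():
    with pytest.raises(ValueError):
        permutation_test([1.0, 2.0, 3.0], ["a", "a", "a"], 999)


def test_location_only_statistic_ignores_pure_scale_effect(rng):
    # same means, very different dispersions: the scale-sensitive statistic
    # should reject far more often than location-only
    hits_ls, hits_loc = 0, 0
    for i in range(60):
        r = np.random.default_rng(i)
        a = r.normal(0, 0.2, 8)
        b = r.normal(0, 3.0, 8)
        v = np.concatenate([a, b - b.mean() + a.mean()])
        g = np.repeat(["a", "b"], 8)
        hits_ls += permutation_test(v, g, 299, seed=1).p_value <= 0.05
        hits_loc += permutation_test(v, g, 299, seed=1, statistic="location").p_value <= 0.05
    assert hits_ls > hits_loc + 20


# ---------------------------------------------------------------------------
# NPC combination


def test_single_variable_combination_is_identity(rng):
    v = rng.normal(size=16)
    res = permutation_test(v, np.repeat(["a", "b"], 8), 999, seed=3)
    p_comb, _ = npc_fisher_combine([res])
    assert p_comb == res.p_value


def test_duplicated_variable_combined_p_equals_partial(rng):
    v = rng.normal(size=16)
    v[:8] += 1.0
    res = permutation_test(v, np.repeat(["a", "b"], 8), 999, seed=5)
    p_comb, _ = npc_fisher_combine([res, res])
    assert p_comb == res.p_value  # perfect dependence handled by permutation


def test_broken_synchronization_is_detectable(rng):
    # negative control: combining two *independently permuted* copies of the
    # same variable behaves like independent evidence and diverges from the
    # partial p — the duplication oracle catches the broken NPC contract
    v = rng.normal(size=16)
    v[:8] += 0.8
    g = np.repeat(["a", "b"], 8)
    r1 = permutation_test(v, g, 999, seed=11)
    r2 = permutation_test(v, g, 999, seed=12, force_monte_carlo=True)
    p_desync, _ = npc_fisher_combine([r1.statistics, r2.statistics])
    assert abs(p_desync - r1.p_value) > 0.01


def test_unsynchronized_lengths_raise(rng):
    v = rng.normal(size=16)
    g = np.repeat(["a", "b"], 8)
    r1 = permutation_test(v, g, 999, seed=1)
    r2 = permutation_test(v, g, 499, seed=1)
    with pytest.raises(ValueError, match="synchronized"):
        npc_fisher_combine([r1.statistics, r2.statistics])


def test_independent_variables_fisher_statistic_matches_chi2():
    from scipy import stats as st

    rng = np.random.default_rng(0)
    k = 3
    g = np.repeat(["a", "b"], 12)
    scheme = build_scheme(g, 2000, rng)
    from cytolaminar.inference import _fisher_stat, _variable_statistic

    parts = [
        _variable_statistic(rng.normal(size=24), scheme, "location") for _ in range(k)
    ]
    T = _fisher_stat(parts)
    ks = st.kstest(T, st.chi2(2 * k).cdf).statistic
    assert ks < 0.05


# ---------------------------------------------------------------------------
# pairwise tests and Shaffer


def test_pairwise_equals_two_group_test_alone():
    rng = np.random.default_rng(2)
    v = rng.normal(size=9)
    g = np.repeat(["a", "b", "c"], 3)
    pw = pairwise_tests(v, g, 999)  # 3+3 pairs are enumerated -> seed-free
    sel = (g == "a") | (g == "c")
    alone = permutation_test(v[sel], g[sel], 999).p_value
    assert pw[("a", "c")] == alone


def test_three_identical_groups_all_p_one():
    v = np.tile([1.0, 2.0, 3.0, 4.0], 3)
    g = np.repeat(["a", "b", "c"], 4)
    pw = pairwise_tests(v, g, 999)
    assert all(p == 1.0 for p in pw.values())


def test_shifted_group_power_pattern():
    # one group shifted by 5 within-group sds: both of its pairs reject at
    # alpha=0.05 in >=95% of runs; the remaining null pair keeps its level
    hits_shift, hits_null = 0, 0
    reps = 200
    for i in range(reps):
        r = np.random.default_rng(1000 + i)
        v = np.concatenate([r.normal(0, 1, 6), r.normal(0, 1, 6), r.normal(5, 1, 6)])
        g = np.repeat(["a", "b", "c"], 6)
        pw = pairwise_tests(v, g, 999, seed=i)
        hits_shift += (pw[("a", "c")] <= 0.05) and (pw[("b", "c")] <= 0.05)
        hits_null += pw[("a", "b")] <= 0.05
    assert hits_shift / reps >= 0.95
    assert hits_null / reps <= 0.10


def test_shaffer_k3_worked_example():
    adj = shaffer_adjust([0.01, 0.02, 0.03], k=3)
    assert np.allclose(adj, [0.03, 0.03, 0.03])
    assert shaffer_multipliers(3) == [3, 1, 1]
    assert possible_true_null_counts(3) == [0, 1, 3]


def test_shaffer_k2_is_identity():
    assert shaffer_adjust([0.04], k=2).tolist() == [0.04]


def test_shaffer_k4_multiplier_sequence():
    # enumeration of equality patterns for k=4: achievable true-null counts
    # {0,1,2,3,6} give the classical step-down sequence
    assert possible_true_null_counts(4) == [0, 1, 2, 3, 6]
    assert shaffer_multipliers(4) == [6, 3, 3, 3, 2, 1]


def test_shaffer_incomplete_pair_set_rejected():
    with pytest.raises(ValueError):
        shaffer_adjust([0.01, 0.02], k=3)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    hst.lists(hst.floats(0.0001, 1.0), min_size=6, max_size=6),
)
def test_shaffer_adjusted_at_least_raw_and_monotone(raw):
    adj = shaffer_adjust(raw, k=4)
    assert np.all(adj >= np.asarray(raw) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(raw)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# eye-position classification


@pytest.mark.parametrize(
    "angle,expected",
    [
        (20.0, "frontal-eyed"),
        (60.0, "frontal-eyed"),
        (120.0, "wide-field"),
        (150.0, "wide-field"),
        (170.0, "lateral-eyed"),
        (180.0, "lateral-eyed"),
    ],
)
def test_classify_eye_position(angle, expected):
    assert classify_eye_position(angle) == expected


@pytest.mark.parametrize("angle", [-1.0, 180.5, 400.0])
def test_eye_position_angle_out_of_range(angle):
    with pytest.raises(ValueError):
        classify_eye_position(angle)


# ---------------------------------------------------------------------------
# full grouping analysis


def _small_study(seed, effects=None):
    effects = effects or [GroupEffect("a"), GroupEffect("b"), GroupEffect("c")]
    study = generate_group_study(
        effects, 3, seed=seed, layer_params=SMALL_LAYERS, strip_width_um=1000.0
    )
    cells = measure_study(study)
    return summarize_study(cells), study.design


def test_row_order_invariance(rng):
    medians, design = _small_study(33)
    spec = ModelSpec(grouping="group", n_permutations=199, seed=9)
    r1 = run_grouping_analysis(medians, design, spec)
    shuffled = medians.sample(frac=1.0, random_state=5).reset_index(drop=True)
    r2 = run_grouping_analysis(shuffled, design.sample(frac=1.0, random_state=6), spec)
    pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())


def test_identical_seed_identical_results():
    medians, design = _small_study(34)
    spec = ModelSpec(grouping="group", n_permutations=199, seed=4)
    r1 = run_grouping_analysis(medians, design, spec).to_frame()
    r2 = run_grouping_analysis(medians, design, spec).to_frame()
    pd.testing.assert_frame_equal(r1, r2)


def test_missing_grouping_column_and_group_rejected():
    medians, design = _small_study(35)
    spec = ModelSpec(grouping="habitat", n_permutations=199, seed=1)
    with pytest.raises(ValueError, match="grouping column"):
        run_grouping_analysis(medians, design, spec)
    spec2 = ModelSpec(grouping="group", n_permutations=199, seed=1)
    with pytest.raises(ValueError, match="without metadata"):
        run_grouping_analysis(
            medians, design[design["specimen_id"] != "c_01"], spec2
        )
    with pytest.raises(ValueError, match="observations"):
        run_grouping_analysis(
            medians[medians["specimen_id"] != "c_01"].query(
                "~(specimen_id in ['c_02','c_03'] and layer=='L1')"
            ),
            design,
            spec2,
        )


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(n_permutations=50)
    with pytest.raises(ValueError):
        ModelSpec(domains={"size": ("x",), "shape": ("x",)})
    with pytest.raises(ValueError):
        ModelSpec(statistic="median")


def test_null_study_global_p_uniform():
    # exchangeable groups: the global combined p must be uniform
    from scipy import stats as st

    ps = []
    for rep in range(300):
        medians, design = _small_study(10_000 + rep)
        res = run_grouping_analysis(
            medians, design, ModelSpec(grouping="group", n_permutations=199, seed=rep)
        )
        ps.append(res.layers["L1"].global_p)
    assert st.kstest(ps, "uniform").pvalue > 0.01


def test_power_monotone_in_effect_size():
    rates = []
    for mult in (1.0, 0.75, 0.5):
        hits = 0
        for rep in range(200):
            study = generate_group_study(
                [GroupEffect("a"), GroupEffect("b", density_multiplier=mult)],
                4,
                seed=50_000 + rep,
                layer_params=SMALL_LAYERS[:1],
                strip_width_um=1000.0,
            )
            med = summarize_study(measure_study(study))
            v = med["density_50um"].to_numpy()
            g = med["specimen_id"].str.split("_").str[0].to_numpy()
            hits += permutation_test(v, g, 999).p_value <= 0.05
        rates.append(hits / 200)
    assert rates[0] <= rates[1] + 0.05  # null level
    assert rates[1] <= rates[2] + 0.05
    assert rates[2] > rates[0]
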