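"""SAM statistic, fudge factor, permutation null and calling machinery.

Hand-computed values and the pooled-t equivalence serve as independent
oracles for the statistic; permutation counts are checked against their
closed forms.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tsc2sig.io import ExpressionMatrix, ValidationError, LOG2P1
from tsc2sig.sam import (
    SamConfig,
    SamDE,
    call_significant,
    differential_expression,
    estimate_s0,
    log_transform,
    paired_sign_patterns,
    permutation_null_paired,
    permutation_null_unpaired,
    resolve_s0,
    sam_statistic_paired,
    sam_statistic_unpaired,
    unpaired_permutations,
)
from tsc2sig.simulate import FibroblastSimParams, simulate_fibroblast_experiment


def log_matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        scale=LOG2P1,
    )


# ---------------------------------------------------------------------------
# log transform

def test_log_transform_exact_values():
    m = ExpressionMatrix(["g"], ["a", "b", "c", "d"], np.array([[0.0, 1.0, 3.0, 7.0]]))
    y = log_transform(m)
    np.testing.assert_allclose(y.values, [[0.0, 1.0, 2.0, 3.0]])
    assert y.scale == LOG2P1


def test_log_transform_guards_idempotence():
    m = ExpressionMatrix(["g"], ["a"], np.array([[1.0]]))
    with pytest.raises(ValidationError, match="already"):
        log_transform(log_transform(m))


# ---------------------------------------------------------------------------
# statistics: hand-computed oracles

def test_unpaired_statistic_hand_value():
    # class1 = (0, 1), class2 = (2, 3): num = 2, s = sqrt(((1/2+1/2)/2) * 1) = 0.7071
    values = np.array([[0.0, 1.0, 2.0, 3.0]])
    d, s = sam_statistic_unpaired(values, np.array([0, 1]), np.array([2, 3]), s0=0.0)
    assert d[0] == pytest.approx(2.8284, abs=1e-4)
    assert s[0] == pytest.approx(0.7071, abs=1e-4)


def test_unpaired_identical_classes_give_zero():
    rng = np.random.default_rng(0)
    block = rng.normal(size=(10, 3))
    values = np.hstack([block, block])
    d, _ = sam_statistic_unpaired(values, np.arange(3), np.arange(3, 6), s0=0.3)
    np.testing.assert_allclose(d, 0.0, atol=1e-12)


def test_unpaired_equals_pooled_t_at_s0_zero():
    rng = np.random.default_rng(42)
    values = rng.normal(size=(200, 6))
    idx1, idx2 = np.arange(3), np.arange(3, 6)
    d, _ = sam_statistic_unpaired(values, idx1, idx2, s0=0.0)
    t = sps.ttest_ind(values[:, idx2], values[:, idx1], axis=1, equal_var=True).statistic
    np.testing.assert_allclose(d, t, atol=1e-12)


def test_unpaired_label_swap_negates_d():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(50, 7))
    idx1, idx2 = np.arange(3), np.arange(3, 7)
    d_fwd, _ = sam_statistic_unpaired(values, idx1, idx2, s0=0.2)
    d_rev, _ = sam_statistic_unpaired(values, idx2, idx1, s0=0.2)
    np.testing.assert_allclose(d_fwd, -d_rev, atol=1e-12)


def test_paired_statistic_hand_values():
    # differences (0,1,2): mean 1, s = sqrt(2/6) = 0.5774 -> d = 1.7321
    d, s = sam_statistic_paired(np.array([[0.0, 1.0, 2.0]]), s0=0.0)
    assert d[0] == pytest.approx(1.7321, abs=1e-4)
    assert s[0] == pytest.approx(0.5774, abs=1e-4)
    # all-zero differences -> 0
    d0, _ = sam_statistic_paired(np.zeros((1, 3)), s0=0.0)
    assert d0[0] == 0.0
    # constant differences (1,1,1) with s0 = 0.5: s = 0 -> d = 1/0.5 = 2
    dc, _ = sam_statistic_paired(np.ones((1, 3)), s0=0.5)
    assert dc[0] == pytest.approx(2.0)


def test_paired_sign_flip_negates_d():
    rng = np.random.default_rng(2)
    diffs = rng.normal(size=(40, 4))
    d_fwd, _ = sam_statistic_paired(diffs, s0=0.1)
    d_rev, _ = sam_statistic_paired(-diffs, s0=0.1)
    np.testing.assert_allclose(d_fwd, -d_rev, atol=1e-12)


def test_zero_se_with_zero_s0_flags_infinite():
    values = np.array([[0.0, 0.0, 1.0, 1.0]])
    d, _ = sam_statistic_unpaired(values, np.array([0, 1]), np.array([2, 3]), s0=0.0)
    assert np.isinf(d[0]) and d[0] > 0


def test_class_size_validation():
    with pytest.raises(ValidationError, match=">= 2"):
        sam_statistic_unpaired(np.ones((1, 3)), np.array([0]), np.array([1, 2]), 0.0)


# ---------------------------------------------------------------------------
# fudge factor

def test_s0_fixed_passthrough():
    num, s = np.ones(10), np.ones(10)
    assert resolve_s0(SamConfig(s0_mode="fixed", s0_fixed=0.3), num, s) == 0.3


def test_s0_percentile_mode():
    s = np.linspace(0.0, 1.0, 200)
    num = np.ones(200)
    got = resolve_s0(SamConfig(s0_mode="percentile", s0_percentile=50.0), num, s)
    assert got == pytest.approx(np.percentile(s, 50))


def test_s0_degenerate_tie_returns_common_value():
    # every s equal: all candidates tie and the smallest (the common value) wins
    s = np.full(150, 0.7)
    num = np.random.default_rng(3).normal(size=150)
    assert estimate_s0(num, s) == pytest.approx(0.7)


def test_s0_small_input_falls_back_to_fifth_percentile(caplog):
    rng = np.random.default_rng(4)
    s = rng.gamma(2.0, 1.0, size=50)
    with caplog.at_level("WARNING"):
        got = estimate_s0(rng.normal(size=50), s)
    assert got == pytest.approx(np.percentile(s, 5.0))


def test_s0_auto_matches_bruteforce_grid():
    """Independent re-implementation of the CV-of-window-MADs grid search."""
    rng = np.random.default_rng(5)
    m = 400
    s = rng.gamma(2.0, 0.5, size=m) + 0.05
    num = rng.normal(size=m) * (s + 0.2)

    candidates = np.percentile(s, np.arange(0, 101, 5))
    edges = np.quantile(s, np.linspace(0, 1, 101))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best, best_cv = None, np.inf
    for cand in candidates:
        d = num / (s + cand)
        mads = []
        for w in range(100):
            dw = d[window == w]
            if len(dw) >= 2:
                mads.append(sps.median_abs_deviation(dw, scale="normal"))
        mads = np.asarray(mads)
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best = cv, float(cand)
    assert estimate_s0(num, s) == pytest.approx(best)


# ---------------------------------------------------------------------------
# permutation null

@pytest.mark.parametrize("n1,n2,expected", [(3, 3, 20), (2, 2, 6)])
def test_unpaired_permutation_counts(n1, n2, expected):
    perms = unpaired_permutations(n1, n2, 5000, 1000, np.random.default_rng(0))
    assert len(perms) == expected == math.comb(n1 + n2, n1)


def test_paired_sign_pattern_count():
    patterns = paired_sign_patterns(3, 5000, 1000, np.random.default_rng(0))
    assert patterns.shape == (8, 3)  # 2^3


def test_sampled_permutations_when_exhaustive_too_large():
    perms = unpaired_permutations(10, 10, max_exhaustive=100, n_sampled=37, rng=np.random.default_rng(1))
    assert len(perms) == 37
    np.testing.assert_array_equal(perms[0], np.arange(10))  # observed assignment included


def test_null_rows_are_sorted():
    rng = np.random.default_rng(6)
    values = rng.normal(size=(30, 6))
    null = permutation_null_unpaired(values, 3, 3, s0=0.1, config=SamConfig())
    assert null.shape == (20, 30)
    assert (np.diff(null, axis=1) >= 0).all()
    null_p = permutation_null_paired(rng.normal(size=(30, 3)), s0=0.1, config=SamConfig())
    assert null_p.shape == (8, 30)


# ---------------------------------------------------------------------------
# calling

def test_call_significant_empty_call_set_is_well_defined():
    rng = np.random.default_rng(7)
    d = rng.normal(size=100) * 0.1
    null = np.sort(rng.normal(size=(20, 100)) * 0.1, axis=1)
    cfg = SamConfig(delta_grid=np.array([50.0]))
    res = call_significant(d, null, [f"g{i}" for i in range(100)], cfg, s0_used=0.1)
    assert res.n_called == 0
    assert ((res.table["q"] >= 0) & (res.table["q"] <= 1)).all()


def test_planted_genes_all_called_with_correct_direction():
    rng = np.random.default_rng(8)
    noise_sd = 1.0
    values = rng.normal(0.0, noise_sd, size=(200, 6))
    planted = np.arange(20)
    values[planted[:10], 3:] += 5.0 * noise_sd   # up in class 2
    values[planted[10:], 3:] -= 5.0 * noise_sd   # down in class 2
    d, s = sam_statistic_unpaired(values, np.arange(3), np.arange(3, 6), s0=0.0)
    s0 = estimate_s0(values[:, 3:].mean(axis=1) - values[:, :3].mean(axis=1), s)
    d, _ = sam_statistic_unpaired(values, np.arange(3), np.arange(3, 6), s0=s0)
    null = permutation_null_unpaired(values, 3, 3, s0, SamConfig())
    res = call_significant(d, null, [f"g{i}" for i in range(200)], SamConfig(), s0)
    table = res.table.set_index("gene_id")
    for i in planted[:10]:
        assert table.loc[f"g{i}", "called"] and table.loc[f"g{i}", "direction"] == 1
    for i in planted[10:]:
        assert table.loc[f"g{i}", "called"] and table.loc[f"g{i}", "direction"] == -1


def test_q_monotone_in_excursion_and_called_below_target():
    m, samples, _ = simulate_fibroblast_experiment(FibroblastSimParams(n_genes=300, seed=21))
    res = differential_expression(m, samples, "ko_vs_wt_vehicle", SamConfig(seed=21))
    t = res.table
    absdiff = (t["d"] - t["d_expected"]).abs().to_numpy()
    q = t["q"].to_numpy()
    order = np.argsort(absdiff)
    assert (np.diff(q[order]) <= 1e-12).all()
    assert (t.loc[t["called"], "q"] <= res.fdr_target + 1e-12).all()


# ---------------------------------------------------------------------------
# model orchestration

@pytest.fixture(scope="module")
def small_experiment():
    return simulate_fibroblast_experiment(FibroblastSimParams(n_genes=300, seed=10))


def test_differential_expression_deterministic(small_experiment):
    matrix, samples, _ = small_experiment
    r1 = differential_expression(matrix, samples, "ko_vs_wt_vehicle", SamConfig(seed=5))
    r2 = differential_expression(matrix, samples, "ko_vs_wt_vehicle", SamConfig(seed=5))
    pd.testing.assert_frame_equal(r1.table, r2.table)
    assert r1.s0_used == r2.s0_used and r1.delta_used == r2.delta_used


def test_paired_comparison_runs(small_experiment):
    matrix, samples, truth = small_experiment
    res = differential_expression(matrix, samples, "sir_vs_veh_in_ko", SamConfig(seed=5))
    assert res.n_permutations == 8
    # reversed up-genes move down under sirolimus in KO
    down = set(res.called_by_direction(-1))
    hits = len(down & set(truth.reversed_up))
    assert hits > 0.5 * len(truth.reversed_up)


def test_design_mismatch_errors(small_experiment):
    matrix, samples, _ = small_experiment
    wt_only = samples[samples["genotype"] == "WT"]
    with pytest.raises(ValidationError, match="KO=0"):
        SamDE(matrix, wt_only, "ko_vs_wt_vehicle").fit()
    with pytest.raises(ValidationError, match="unknown comparison"):
        SamDE(matrix, samples, "ko_vs_wt")


def test_incomplete_pair_named(small_experiment):
    matrix, samples, _ = small_experiment
    broken = samples[samples["sample_id"] != "L2_KO_sir"]
    with pytest.raises(ValidationError, match="L2_KO"):
        SamDE(matrix, broken, "sir_vs_veh_in_ko").fit()


def test_zero_variance_genes_never_called(small_experiment):
    matrix, samples, _ = small_experiment
    values = matrix.values.copy()
    values[0, :] = 5.0  # flat gene
    flat = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, values)
    res = differential_expression(flat, samples, "ko_vs_wt_vehicle", SamConfig(seed=5))
    row = res.table.iloc[0]
    assert row["d"] == 0.0 and not row["called"]
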