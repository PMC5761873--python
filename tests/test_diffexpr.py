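"""Normalization, no-replicate NB testing, DE calls, matrix DE, BH."""

import numpy as np
import pandas as pd
import pytest

from pirome import diffexpr as de


def counts_df(data, samples=("s1", "s2")):
    return pd.DataFrame(data, columns=list(samples))


COND = {"s1": "control", "s2": "case"}


# ---------------------------------------------------------------- size factors

def test_identical_columns_get_unit_factors():
    c = counts_df([[10, 10], [40, 40], [7, 7]])
    assert np.allclose(de.size_factors(c), [1.0, 1.0])


def test_doubled_column_gets_doubled_factor():
    c = counts_df([[10, 20], [20, 40]])
    f = de.size_factors(c)
    assert f["s2"] / f["s1"] == pytest.approx(2.0)


def test_single_sample_factor_is_one():
    c = pd.DataFrame({"only": [5, 9, 3]})
    assert de.size_factors(c)["only"] == pytest.approx(1.0)


def test_factor_invariance_and_scaling():
    rng = np.random.default_rng(0)
    c = pd.DataFrame(rng.integers(1, 500, size=(40, 3)), columns=list("abc"))
    f = de.size_factors(c)
    shuffled = c.sample(frac=1.0, random_state=1)
    assert np.allclose(de.size_factors(shuffled), f)
    # scaling one sample's counts by c scales its factor by c, relative
    # to the others (factors are defined up to a common constant)
    scaled = c.copy()
    scaled["b"] = scaled["b"] * 3
    f2 = de.size_factors(scaled)
    assert f2["b"] / f2["a"] == pytest.approx(3 * f["b"] / f["a"])


def test_no_common_nonzero_feature_is_an_error():
    c = counts_df([[5, 0], [0, 7]])
    with pytest.raises(ValueError, match="pseudocount"):
        de.size_factors(c)


# ------------------------------------------------------------------ NB test

def simulate_null(n_features=400, mean=200.0, disp=0.05, seed=0):
    rng = np.random.default_rng(seed)
    size = 1.0 / disp
    mu = rng.lognormal(np.log(mean), 0.5, size=n_features)
    draw = lambda: rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame({"s1": draw(), "s2": draw()})


def test_balanced_feature_has_large_pvalue():
    c = counts_df([[200, 200]] * 30 + [[50, 50]] * 30)
    f = de.size_factors(c)
    res = de.nb_test_noreplicates(c, f, COND)
    assert res["p_value"].min() > 0.5


def test_planted_fold_change_detected_among_nulls():
    c = simulate_null(200, seed=3)
    c.iloc[0] = [150, 1300]   # ~8-fold
    f = de.size_factors(c)
    res = de.nb_test_noreplicates(c, f, COND)
    assert res["p_value"].iloc[0] <= 0.05
    assert res["fold_change"].iloc[0] > 4


def test_all_zero_feature_gets_p_one_and_unchanged():
    c = simulate_null(50, seed=4)
    c.iloc[10] = [0, 0]
    f = de.size_factors(c)
    res = de.call_de(de.nb_test_noreplicates(c, f, COND))
    assert res["p_value"].iloc[10] == 1.0
    assert res["status"].iloc[10] == "unchanged"


def test_null_simulation_is_calibrated_or_conservative():
    c = simulate_null(n_features=2000, seed=9)
    f = de.size_factors(c)
    res = de.nb_test_noreplicates(c, f, COND)
    frac = float((res["p_value"] <= 0.05).mean())
    assert frac <= 0.10


# ------------------------------------------------------------------- call_de

def de_row(fc, p, mean_control=100.0, mean_case=None):
    mean_case = fc * mean_control if mean_case is None else mean_case
    return pd.DataFrame({
        "base_mean": [(mean_control + mean_case) / 2],
        "base_mean_control": [mean_control],
        "base_mean_case": [mean_case],
        "fold_change": [np.inf if mean_control == 0 else mean_case / mean_control],
        "log2fc": [np.nan],
        "p_value": [p],
    })


def test_boundaries_inclusive_and_statuses():
    assert de.call_de(de_row(1.5, 0.05))["status"].iloc[0] == "up"
    assert de.call_de(de_row(3.0, 0.2))["status"].iloc[0] == "unchanged"
    assert de.call_de(de_row(1 / 1.5, 0.05))["status"].iloc[0] == "down"
    anomalous = de_row(np.inf, 1e-9, mean_control=0.0, mean_case=50.0)
    assert de.call_de(anomalous)["status"].iloc[0] == "anomalous"


# ------------------------------------------------------------------ BH

def test_bh_matches_hand_computed_step_up():
    p = [0.005, 0.009, 0.05, 0.1, 0.9]
    expected = [0.0225, 0.0225, 0.05 * 5 / 3, 0.125, 0.9]
    assert np.allclose(de.bh_adjust(p), expected)
    # order-independence
    perm = [0.9, 0.05, 0.005, 0.1, 0.009]
    assert np.allclose(de.bh_adjust(perm),
                       [expected[4], expected[2], expected[0],
                        expected[3], expected[1]])


# ------------------------------------------------- expression-matrix DE

def expr_matrix(n_genes=200, n=5, seed=1, planted=None):
    rng = np.random.default_rng(seed)
    cols = [f"N{i}" for i in range(n)] + [f"T{i}" for i in range(n)]
    base = rng.uniform(6, 12, size=n_genes)
    mat = base[:, None] + rng.normal(0, 0.25, size=(n_genes, 2 * n))
    for idx, shift in (planted or {}).items():
        mat[idx, n:] += shift
    groups = {c: ("control" if c.startswith("N") else "case") for c in cols}
    return pd.DataFrame(mat, columns=cols,
                        index=[f"g{i}" for i in range(n_genes)]), groups


def test_constant_feature_is_not_de():
    m, groups = expr_matrix(planted=None)
    m.iloc[5] = 10.0
    res = de.de_genes_expression_matrix(m, groups)
    if "g5" in res.index:
        assert res.loc["g5", "status"] == "unchanged"


def test_planted_four_fold_shift_is_called():
    m, groups = expr_matrix(planted={0: +2.0, 1: -2.0}, seed=2)
    m.iloc[0, :] += 2     # keep the shifted gene above the intensity floor
    m.iloc[1, :] += 2
    res = de.de_genes_expression_matrix(m, groups)
    assert res.loc["g0", "status"] == "up"
    assert res.loc["g1", "status"] == "down"


def test_percentile_filter_removes_twenty_percent():
    m, groups = expr_matrix(n_genes=500, seed=5)
    res = de.de_genes_expression_matrix(m, groups)
    assert len(res) == 400


def test_small_group_is_an_error():
    m, _ = expr_matrix()
    groups = {"N0": "control", "T0": "case", "T1": "case"}
    with pytest.raises(ValueError, match="2 samples"):
        de.de_genes_expression_matrix(m[["N0", "T0", "T1"]], groups)


# ------------------------------------------------- planted-truth recovery

def test_planted_pirna_fold_changes_recovered(pipeline_run):
    """>= 90% of planted |log2FC| >= 2 piRNAs are called DE at the
    FC >= 1.5, p <= 0.05 thresholds."""
    _cfg, _m, truth, results = pipeline_run
    table = pd.read_csv(results / "de_pirnas.tsv", sep="\t", index_col=0)
    planted = [pid for pid, p in truth.pirnas.items()
               if p.de_status in ("up", "down")
               and abs(np.log2(p.fold_change)) >= 2]
    hits = sum(
        table.loc[pid, "status"] == truth.pirnas[pid].de_status
        for pid in planted if pid in table.index
    )
    assert hits / len(planted) >= 0.9
    anomalous = [pid for pid, p in truth.pirnas.items()
                 if p.de_status == "anomalous"]
    for pid in anomalous:
        assert table.loc[pid, "status"] == "anomalous"
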