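import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hugescreen as hs
from hugescreen.multiple_testing import local_fdr


def result_table(pvalues, groups, deltas=None):
    p = np.asarray(pvalues, dtype=float)
    return pd.DataFrame(
        {
            "knockout_id": [f"K{i}" for i in range(len(p))],
            "biomarker_id": list(groups),
            "p_value": p,
            "delta": np.zeros(len(p)) if deltas is None else np.asarray(deltas),
            "group_id": list(groups),
            "skipped": False,
        }
    )


# ---------------------------------------------------------------------------
# estimate_pi0


def test_pi0_near_one_on_uniform_grid():
    p = np.arange(1, 10001) / 10001.0
    assert 0.95 <= hs.estimate_pi0(p) <= 1.0


def test_pi0_recovers_known_mixture():
    # Beta(0.1,1) alternatives leave density 0.1 at p=1, so any tail-based
    # estimator carries a +0.05 asymptotic bias here; 15% relative tolerance
    rng = np.random.default_rng(0)
    p = np.concatenate([rng.random(5000), rng.beta(0.1, 1, 5000)])
    assert hs.estimate_pi0(p) == pytest.approx(0.5, rel=0.15)


def test_pi0_clamps_when_all_pvalues_tiny():
    p = np.full(100, 1e-4)
    with pytest.warns(UserWarning, match="clamp"):
        pi0 = hs.estimate_pi0(p, method="fixed_lambda")
    assert pi0 == pytest.approx(1.0 / 100)


def test_pi0_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        hs.estimate_pi0(np.array([0.5, 1.5]))


def test_pi0_small_sample_falls_back_with_warning():
    with pytest.warns(UserWarning, match="fixed_lambda"):
        pi0 = hs.estimate_pi0(np.linspace(0.01, 0.99, 10))
    assert 0 < pi0 <= 1


# ---------------------------------------------------------------------------
# local_fdr


def test_lfdr_near_one_under_uniform_null():
    rng = np.random.default_rng(0)
    p = rng.random(10000)
    model = local_fdr(p, hs.estimate_pi0(p))
    assert model.lfdr.min() >= 0.9
    assert model.lfdr.max() <= 1.0


def test_lfdr_matches_analytic_mixture_curve():
    """pi0=0.8 with Beta(0.2,1) alternatives: closed-form lfdr oracle."""
    rng = np.random.default_rng(1)
    pi0, a = 0.8, 0.2
    p = np.concatenate([rng.random(8000), rng.beta(a, 1, 2000)])
    model = local_fdr(p, pi0)
    f_true = pi0 + (1 - pi0) * a * np.power(p, a - 1.0)
    lfdr_true = np.clip(pi0 / f_true, 0, 1)
    lo, hi = np.quantile(p, [0.05, 0.95])
    sel = (p >= lo) & (p <= hi)
    mae = np.mean(np.abs(model.lfdr[sel] - lfdr_true[sel]))
    assert mae <= 0.05


def test_lfdr_capped_at_one_and_monotone():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.beta(0.3, 1, 500), rng.random(500)])
    model = local_fdr(p, hs.estimate_pi0(p))
    assert model.lfdr.max() <= 1.0
    order = np.argsort(p)
    assert (np.diff(model.lfdr[order]) >= -1e-12).all()


def test_lfdr_density_integrates_to_one():
    rng = np.random.default_rng(3)
    p = np.concatenate([rng.beta(0.2, 1, 2000), rng.random(8000)])
    model = local_fdr(p, 0.8)
    integral = np.sum(model.density_f * np.diff(model.density_x))
    assert integral == pytest.approx(1.0, abs=1e-2)


def test_lfdr_degenerate_identical_pvalues():
    with pytest.warns(UserWarning, match="degenerate"):
        model = local_fdr(np.full(50, 0.2), pi0=0.7)
    np.testing.assert_allclose(model.lfdr, 0.7)


# ---------------------------------------------------------------------------
# grouped_local_fdr


def test_single_large_group_reduces_to_ungrouped():
    rng = np.random.default_rng(4)
    p = rng.random(500)
    table = result_table(p, ["B1"] * 500)
    grouped = hs.grouped_local_fdr(table)
    pooled = local_fdr(p, hs.estimate_pi0(p))
    np.testing.assert_allclose(grouped["lfdr"].to_numpy(), pooled.lfdr)


def test_grouping_sharpens_signal_group_lfdr():
    """Hub group B gains, all-null group A yields ~no calls at lfdr<=0.6."""
    rng = np.random.default_rng(5)
    p_a = rng.random(5000)
    p_b = np.concatenate([rng.beta(0.05, 1, 2500), rng.random(2500)])
    is_alt = np.concatenate([np.zeros(5000, bool), np.ones(2500, bool), np.zeros(2500, bool)])
    table = result_table(np.concatenate([p_a, p_b]), ["A"] * 5000 + ["B"] * 5000)
    grouped = hs.grouped_local_fdr(table)

    pooled_model = local_fdr(table["p_value"].to_numpy(),
                             hs.estimate_pi0(table["p_value"].to_numpy()))
    med_grouped = np.median(grouped["lfdr"].to_numpy()[is_alt])
    med_pooled = np.median(pooled_model.lfdr[is_alt])
    assert med_grouped < med_pooled
    lfdr_a = grouped.loc[grouped["group_id"] == "A", "lfdr"]
    assert (lfdr_a <= 0.6).mean() < 0.01


def test_small_groups_fall_back_to_pooled_model():
    rng = np.random.default_rng(6)
    p = rng.random(120)
    table = result_table(p, ["big"] * 100 + ["small"] * 20)
    out = hs.grouped_local_fdr(table, min_group_tests=50)
    assert out.loc[out["group_id"] == "small", "lfdr_pooled_fallback"].all()
    assert not out.loc[out["group_id"] == "big", "lfdr_pooled_fallback"].any()


def test_lfdr_invariant_to_row_permutation():
    rng = np.random.default_rng(7)
    p = rng.random(300)
    table = result_table(p, ["A"] * 150 + ["B"] * 150)
    out = hs.grouped_local_fdr(table)
    perm = rng.permutation(len(table))
    out_perm = hs.grouped_local_fdr(table.iloc[perm].reset_index(drop=True))
    merged = out.merge(out_perm, on="knockout_id", suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["lfdr_a"], merged["lfdr_b"])


# ---------------------------------------------------------------------------
# storey_qvalues


def test_qvalues_with_pi0_one_equal_bh():
    rng = np.random.default_rng(8)
    p = rng.random(200)
    q = hs.storey_qvalues(p, pi0=1.0)
    bh = hs.classical_corrections(p, "bh").adjusted
    np.testing.assert_allclose(q, bh)


def test_qvalues_hand_computed_example():
    q = hs.storey_qvalues(np.array([0.01, 0.02, 0.03]), pi0=0.5)
    np.testing.assert_allclose(q, [0.015, 0.015, 0.015])


def test_qvalues_constant_vector_ties():
    q = hs.storey_qvalues(np.full(5, 0.3), pi0=0.6)
    np.testing.assert_allclose(q, 0.6 * 0.3)


pvalue_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40
)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(pvalue_vectors, st.floats(min_value=0.01, max_value=1.0))
def test_qvalue_properties_hold_for_arbitrary_inputs(p, pi0):
    p = np.asarray(p)
    q = hs.storey_qvalues(p, pi0=pi0)
    assert ((q >= 0) & (q <= 1)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()  # monotone in p
    bh = hs.classical_corrections(p, "bh").adjusted
    np.testing.assert_allclose(q, np.minimum(pi0 * bh, 1.0), atol=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(pvalue_vectors)
def test_adjusted_pvalue_orderings_hold_for_arbitrary_inputs(p):
    p = np.asarray(p)
    bh = hs.classical_corrections(p, "bh").adjusted
    holm = hs.classical_corrections(p, "holm").adjusted
    bonf = hs.classical_corrections(p, "bonferroni").adjusted
    assert (bh <= bonf + 1e-12).all()  # BH is never more conservative
    assert (holm <= bonf + 1e-12).all()
    for adj in (bh, holm, bonf):
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(9)
    p = rng.random(500)
    q = hs.storey_qvalues(p, pi0=0.8)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# classical corrections


def brute_force_adjust(p, method):
    """Textbook definitions applied literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return np.minimum(m * p, 1.0)
    order = np.argsort(p)
    out = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            out[i] = min(running, 1.0)
    else:  # bh
        running = np.inf
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, m * p[i] / (rank + 1))
            out[i] = min(running, 1.0)
    return out


@pytest.mark.parametrize("method", ["bh", "bonferroni", "holm"])
def test_corrections_match_brute_force(method):
    rng = np.random.default_rng(10)
    for p in ([0.04], [0.01, 0.02, 0.03], rng.random(37), [1.0] * 4):
        got = hs.classical_corrections(np.asarray(p), method).adjusted
        np.testing.assert_allclose(got, brute_force_adjust(p, method))


def test_corrections_worked_example():
    p = np.array([0.01, 0.02, 0.03])
    np.testing.assert_allclose(
        hs.classical_corrections(p, "bonferroni").adjusted, [0.03, 0.06, 0.09]
    )
    np.testing.assert_allclose(hs.classical_corrections(p, "holm").adjusted, [0.03, 0.04, 0.04])
    np.testing.assert_allclose(hs.classical_corrections(p, "bh").adjusted, [0.03, 0.03, 0.03])


def test_adjusted_never_below_raw():
    rng = np.random.default_rng(11)
    p = rng.random(100)
    for method in ("bh", "bonferroni", "holm"):
        assert (hs.classical_corrections(p, method).adjusted >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# covariate_bh


def test_uninformative_grouping_reduces_to_plain_bh():
    rng = np.random.default_rng(12)
    p = rng.random(2000)
    table = result_table(p, [f"G{i % 10}" for i in range(2000)])
    cov = hs.covariate_bh(table, alpha=0.20)
    bh = hs.classical_corrections(p, "bh")
    assert cov.n_significant_at[0.20] == bh.n_significant(0.20)
    np.testing.assert_allclose(cov.adjusted, bh.adjusted)


def test_hub_structure_boosts_discoveries_over_plain_bh():
    screen = hs.simulate_screen(hs.SimulationConfig(seed=13, effect_size=1.5))
    res = hs.moderated_t_test(screen.essentiality, screen.mutations)
    p = res["p_value"].to_numpy()
    cov = hs.covariate_bh(res, alpha=0.20)
    bh = hs.classical_corrections(p, "bh")
    assert cov.n_significant_at[0.20] >= bh.n_significant(0.20)


def test_empty_group_gets_unit_weight_with_warning():
    table = result_table([0.5, 0.6, 0.7], ["A", "A", "A"])
    extra = pd.DataFrame(
        {
            "knockout_id": ["K9"], "biomarker_id": ["B"], "p_value": [np.nan],
            "delta": [0.0], "group_id": ["B"], "skipped": [True],
        }
    )
    table = pd.concat([table, extra], ignore_index=True)
    with pytest.warns(UserWarning, match="empty group"):
        cov = hs.covariate_bh(table, alpha=0.2)
    assert np.isnan(cov.adjusted[-1])


def test_covariate_bh_rejects_bad_alpha(hub_results):
    with pytest.raises(ValueError, match="alpha"):
        hs.covariate_bh(hub_results, alpha=1.5)


# ---------------------------------------------------------------------------
# diagnostics


def test_group_diagnostics_flags_hub_histogram(hub_results, hub_screen):
    diag = hs.group_diagnostics(hub_results)
    hubs = sorted({b for b, _, _ in hub_screen.truth})
    hub_rows = diag[diag["group_id"].isin(hubs)]
    null_rows = diag[~diag["group_id"].isin(hubs)]
    # hub groups show a tall excess of small p-values; null groups stay flat
    assert hub_rows["frac_p_below_05"].min() > 0.30
    assert null_rows["frac_p_below_05"].median() < 0.15
    assert (hub_rows["pi0"] < 0.8).all()
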