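import dataclasses

import numpy as np
import pytest
from scipy import stats

from gslond.metrics import DecisionLedger
from gslond.simulate import (
    NotApplicableError,
    SimScenario,
    _draw_trial_data,
    generate_trial,
    run_budget_mode,
    run_replicates,
    saved_sample_size,
)

BASE = SimScenario(K=10, n=50, n1=25, n_delta=20, pi0=1.0, controls="CC",
                   alpha=0.025, n_reps=10, seed=123)


def _collect_pvalues(scenario, n_reps, seed):
    ss = np.random.SeedSequence(seed)
    p1, pf = [], []
    for child in ss.spawn(n_reps):
        data = _draw_trial_data(scenario, np.random.default_rng(child))
        p1.append(data.p_interim)
        pf.append(data.p_final)
    return np.concatenate(p1), np.concatenate(pf)


def test_null_pvalues_uniform():
    p1, pf = _collect_pvalues(BASE, 500, 42)  # 5000 arms
    assert stats.kstest(p1, "uniform").pvalue > 0.01
    assert stats.kstest(pf, "uniform").pvalue > 0.01


def test_interim_final_correlation_sqrt_t1():
    p1, pf = _collect_pvalues(BASE, 1000, 7)  # 10^4 pairs
    z1 = stats.norm.ppf(1 - p1)
    zf = stats.norm.ppf(1 - pf)
    corr = np.corrcoef(z1, zf)[0, 1]
    assert abs(corr - np.sqrt(0.5)) < 0.02


def test_ncc_uses_more_controls_and_same_treatment_data():
    cc = dataclasses.replace(BASE, controls="CC")
    ncc = dataclasses.replace(BASE, controls="NCC_CC")
    d_cc = _draw_trial_data(cc, np.random.default_rng(99))
    d_ncc = _draw_trial_data(ncc, np.random.default_rng(99))
    # identical draws: only the analysis window differs
    np.testing.assert_array_equal(d_cc.treatment, d_ncc.treatment)
    np.testing.assert_array_equal(d_cc.controls, d_ncc.controls)
    np.testing.assert_array_equal(d_cc.is_null, d_ncc.is_null)
    # arm 1 has no non-concurrent controls: identical p-values
    assert d_cc.p_interim[0] == pytest.approx(d_ncc.p_interim[0])
    assert d_cc.p_final[0] == pytest.approx(d_ncc.p_final[0])
    # later arms use strictly more controls, so p-values differ
    assert not np.allclose(d_cc.p_final[1:], d_ncc.p_final[1:])


def test_single_arm_cc_equals_ncc():
    one = dataclasses.replace(BASE, K=1)
    d_cc = _draw_trial_data(one, np.random.default_rng(5))
    d_ncc = _draw_trial_data(
        dataclasses.replace(one, controls="NCC_CC"), np.random.default_rng(5)
    )
    assert d_cc.p_interim[0] == pytest.approx(d_ncc.p_interim[0])
    assert d_cc.p_final[0] == pytest.approx(d_ncc.p_final[0])


def test_truth_order_blocks():
    sc_first = dataclasses.replace(BASE, pi0=0.8, order="alternatives_first")
    sc_last = dataclasses.replace(BASE, pi0=0.8, order="alternatives_last")
    d1 = _draw_trial_data(sc_first, np.random.default_rng(1))
    d2 = _draw_trial_data(sc_last, np.random.default_rng(1))
    assert d1.is_null.tolist() == [False, False] + [True] * 8
    assert d2.is_null.tolist() == [True] * 8 + [False, False]


def test_generate_trial_event_stream():
    events, is_null = generate_trial(BASE, np.random.default_rng(3))
    assert len(events) == 2 * BASE.K
    assert is_null.all()
    times = [e.time for e in events]
    assert all(t1 < t2 for t1, t2 in zip(times, times[1:]))
    # each arm has one interim before its final
    for i in range(1, BASE.K + 1):
        stages = [e.stage for e in events if e.hypothesis == i]
        assert stages == ["interim", "final"]


def test_run_replicates_determinism():
    sc = dataclasses.replace(BASE, pi0=0.5, n_reps=50)
    r1 = run_replicates(sc)
    r2 = run_replicates(sc)
    assert r1.fdr == r2.fdr
    assert r1.power == r2.power
    assert r1.saved_pct == r2.saved_pct


def test_common_random_numbers_across_variants():
    sc = dataclasses.replace(BASE, pi0=0.5, n_reps=30)
    res = run_replicates(sc, variants=["gsLOND", "gsLOND.II", "LOND"])
    assert set(res) == {"gsLOND", "gsLOND.II", "LOND"}
    # same generated data: identical truth labels per replicate
    for a, b in [("gsLOND", "gsLOND.II"), ("gsLOND", "LOND")]:
        assert res[a].n_reps == res[b].n_reps == 30
    # the exhausting variant can only add rejections on shared data
    assert res["gsLOND.II"].per_rep["rejected_alternatives"].sum() >= (
        res["gsLOND"].per_rep["rejected_alternatives"].sum()
    )


def test_saved_sample_size_denominators():
    sc = dataclasses.replace(BASE, n_reps=4)
    res = run_replicates(sc)
    # fabricate known stop counts: every arm stops at interim
    res.per_rep["interim_stops"] = np.full(4, sc.K)
    assert saved_sample_size(res, denominator="stage2") == pytest.approx(100.0)
    assert saved_sample_size(res, denominator="total") == pytest.approx(
        100.0 * sc.n2 / sc.n
    )
    res.per_rep["interim_stops"] = np.zeros(4)
    assert saved_sample_size(res) == pytest.approx(0.0)


def test_saved_sample_size_undefined_for_fixed_sample():
    sc = dataclasses.replace(BASE, variant="LOND", n_reps=5)
    res = run_replicates(sc)
    with pytest.raises(NotApplicableError):
        saved_sample_size(res)


def test_budget_mode_conservation():
    sc = dataclasses.replace(
        BASE, pi0=0.5, n_reps=50, budget_mode=1, K0=10, controls="NCC_CC"
    )
    res = run_budget_mode(sc)
    used = res.per_rep["observations_used"]
    budget = res.per_rep["budget"]
    assert budget == 10 * 50 + (9 * 20 + 50)
    assert np.all(used <= budget)
    assert np.all(res.per_rep["n_arms"] >= 10)


def test_budget_mode_no_stops_no_replacement():
    # without futility stopping and with a near-unspendable level, no arm
    # stops early, so no replacement arm can be funded
    sc = dataclasses.replace(
        BASE, pi0=1.0, n_reps=40, budget_mode=1, K0=10,
        futility=None, alpha=1e-6,
    )
    res = run_budget_mode(sc)
    assert np.all(res.per_rep["n_arms"] == 10)
    assert np.all(res.per_rep["observations_used"] == res.per_rep["budget"])


def test_budget_mode_added_arm_effects():
    # scenario 4: added alternatives get effect size 1, so with heavy
    # futility stopping arms get replaced
    sc = dataclasses.replace(
        BASE, pi0=0.9, n_reps=40, budget_mode=4, K0=10, delta=0.6,
    )
    res = run_budget_mode(sc)
    assert np.any(res.per_rep["n_arms"] > 10)


def test_scenario_validation():
    with pytest.raises(ValueError):
        SimScenario(n1=50, n=50)
    with pytest.raises(ValueError):
        SimScenario(pi0=1.5)
    with pytest.raises(ValueError):
        SimScenario(order="sorted")
    with pytest.raises(ValueError):
        SimScenario(controls="NCC")
    with pytest.raises(ValueError):
        SimScenario(variant="gsLORD")
    with pytest.raises(ValueError):
        SimScenario(budget_mode=7)


def test_scenario_roundtrip():
    sc = dataclasses.replace(BASE, delta=[0.4, 0.8])
    assert SimScenario.from_dict(sc.to_dict()) == sc
    assert SimScenario.from_dict(BASE.to_dict()) == BASE
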