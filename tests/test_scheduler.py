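import numpy as np
import pytest

from gslond.alpha_spending import spend_obf, spend_pocock, two_stage_boundaries
from gslond.beta_sequences import BetaSequence
from gslond.fixtures import OUTCOMES, toy_events, toy_sequence
from gslond.scheduler import (
    COMPARATORS,
    GS_VARIANTS,
    AnalysisEvent,
    SequencingError,
    comparator_levels,
    run_schedule,
)

SEQ = toy_sequence()  # equal budgets 0.05/3, N = 3


def run_toy(outcomes, variant, spending="PO", futility=None):
    return run_schedule(
        toy_events(outcomes),
        seq=SEQ,
        spending=spending,
        variant=variant,
        futility=futility,
        t1=0.5,
    )


# H2 stage-1 / stage-2 boundaries (Pocock) for every (H1, H3) outcome pair,
# all four scheduling rules; rounded to 4 decimals.  Regression values,
# hand-checked against the two-stage plans at levels 0.0167/0.0333/0.05.
H2_TABLE = {
    # (H1, H3): (stage1, gsLOND, gsLOND.II, gsLOND.III, gsLOND.II.III)
    ("retain", "retain"): (0.0103, 0.0089, 0.0089, 0.0089, 0.0089),
    ("retain", "reject_interim"): (0.0103, 0.0089, 0.0089, 0.0190, 0.0190),
    ("retain", "reject_final"): (0.0103, 0.0089, 0.0089, 0.0089, 0.0089),
    ("reject_interim", "retain"): (0.0207, 0.0190, 0.0190, 0.0190, 0.0190),
    ("reject_interim", "reject_interim"): (0.0207, 0.0190, 0.0190, 0.0297, 0.0297),
    ("reject_interim", "reject_final"): (0.0207, 0.0190, 0.0190, 0.0190, 0.0190),
    ("reject_final", "retain"): (0.0103, 0.0190, 0.0279, 0.0190, 0.0279),
    ("reject_final", "reject_interim"): (0.0103, 0.0190, 0.0279, 0.0297, 0.0459),
    ("reject_final", "reject_final"): (0.0103, 0.0190, 0.0279, 0.0190, 0.0279),
}

# H3 boundaries (Pocock) under gsLOND and gsLOND.II; H1 is decided entirely
# before H3's interim, H2's final analysis falls in between H3's two looks.
H3_TABLE = {
    # (H1, H2): (stage1, gsLOND stage2, gsLOND.II stage2)
    ("retain", "retain"): (0.0103, 0.0089, 0.0089),
    ("retain", "reject_interim"): (0.0207, 0.0190, 0.0190),
    ("retain", "reject_final"): (0.0103, 0.0190, 0.0279),
    ("reject_interim", "retain"): (0.0207, 0.0190, 0.0190),
    ("reject_interim", "reject_interim"): (0.0310, 0.0297, 0.0297),
    ("reject_interim", "reject_final"): (0.0207, 0.0297, 0.0389),
}


@pytest.mark.parametrize("combo", sorted(H2_TABLE))
def test_h2_boundaries_all_variants(combo):
    h1, h3 = combo
    stage1, *stage2 = H2_TABLE[combo]
    for variant, expected in zip(GS_VARIANTS, stage2):
        res = run_toy({1: h1, 2: "retain", 3: h3}, variant)
        assert round(res.boundary(2, "interim"), 4) == pytest.approx(stage1)
        assert round(res.boundary(2, "final"), 4) == pytest.approx(expected)


@pytest.mark.parametrize("combo", sorted(H3_TABLE))
def test_h3_boundaries_base_and_exhausting(combo):
    h1, h2 = combo
    stage1, base, exhausting = H3_TABLE[combo]
    res = run_toy({1: h1, 2: h2, 3: "retain"}, "gsLOND")
    assert round(res.boundary(3, "interim"), 4) == pytest.approx(stage1)
    assert round(res.boundary(3, "final"), 4) == pytest.approx(base)
    res2 = run_toy({1: h1, 2: h2, 3: "retain"}, "gsLOND.II")
    assert round(res2.boundary(3, "final"), 4) == pytest.approx(exhausting)


def test_variant_final_boundary_dominance():
    # the exhausting and all-index variants can only relax the final boundary
    for h1 in OUTCOMES:
        for h3 in OUTCOMES:
            outcomes = {1: h1, 2: "retain", 3: h3}
            a2 = {
                v: run_toy(outcomes, v).boundary(2, "final") for v in GS_VARIANTS
            }
            assert a2["gsLOND.II"] >= a2["gsLOND"] - 1e-12
            assert a2["gsLOND.III"] >= a2["gsLOND"] - 1e-12
            assert a2["gsLOND.II.III"] >= max(a2["gsLOND.II"], a2["gsLOND.III"]) - 1e-12


def test_interim_boundary_is_spend_of_level():
    res = run_toy({1: "reject_interim", 2: "retain", 3: "retain"}, "gsLOND")
    level = res.level(2, "interim")
    assert level == pytest.approx(2 * 0.05 / 3)
    assert res.boundary(2, "interim") == pytest.approx(spend_pocock(0.5, level))
    res_obf = run_toy({1: "reject_interim", 2: "retain", 3: "retain"}, "gsLOND",
                      spending="OBF")
    assert res_obf.boundary(2, "interim") == pytest.approx(spend_obf(0.5, level))


def test_online_property_future_events_irrelevant():
    # H2's boundaries under gsLOND / gsLOND.II never depend on H3
    for h3_a, h3_b in [("retain", "reject_interim"), ("retain", "reject_final")]:
        for variant in ("gsLOND", "gsLOND.II"):
            a = run_toy({1: "reject_final", 2: "retain", 3: h3_a}, variant)
            b = run_toy({1: "reject_final", 2: "retain", 3: h3_b}, variant)
            for stage in ("interim", "final"):
                assert a.boundary(2, stage) == pytest.approx(b.boundary(2, stage))


def _random_events(rng, K=6):
    """Random staggered two-stage event stream (interleaved chronology)."""
    raw = []
    for i in range(1, K + 1):
        start = (i - 1) * 2.0
        raw.append((start + 1.5, i, "interim", float(rng.uniform(1e-4, 1.0))))
        raw.append((start + 3.0, i, "final", float(rng.uniform(1e-4, 1.0))))
    raw.sort()
    return [
        AnalysisEvent(time=t + k * 1e-9, hypothesis=h, stage=s, p_value=p)
        for k, (t, h, s, p) in enumerate(raw)
    ]


def _run_stream(events, variant, seq):
    """Drive a potential-event stream, dropping finals of resolved arms."""
    from gslond.scheduler import ScheduleRunner

    runner = ScheduleRunner(seq=seq, spending="PO", variant=variant,
                            futility=None, t1=0.5)
    for ev in events:
        st = runner.states.get(ev.hypothesis)
        if ev.stage == "final" and st is not None and st.resolved:
            continue
        runner.process(ev)
    return runner.rejections()


def test_rejection_monotonicity_across_variants(rng):
    seq = BetaSequence.descending_truncated(0.4, 6)  # high level: many rejections
    for _ in range(50):
        events = _random_events(rng)
        base = _run_stream(events, "gsLOND", seq)
        assert base <= _run_stream(events, "gsLOND.II", seq)


def test_futility_stop():
    # continue-p-value 0.4 >= futility bound 0.3: every arm stops at interim,
    # so no final analysis takes place (the caller drops those events)
    events = toy_events({1: "retain", 2: "retain", 3: "retain"})
    interims = [e for e in events if e.stage == "interim"]
    res = run_schedule(interims, seq=SEQ, spending="PO", variant="gsLOND",
                       futility=0.3, t1=0.5)
    assert all(s == "stopped_futility" for s in res.statuses.values())
    assert res.rejected == set()
    # feeding the final event of a futility-stopped arm is a sequencing error
    with pytest.raises(SequencingError):
        run_schedule(events, seq=SEQ, spending="PO", variant="gsLOND",
                     futility=0.3, t1=0.5)


def test_comparator_levels():
    assert comparator_levels(5, "level_alpha", 0.025) == 0.025
    assert comparator_levels(5, "bonferroni", 0.025, K=10) == pytest.approx(0.0025)
    with pytest.raises(ValueError):
        comparator_levels(1, "bonferroni", 0.025)
    with pytest.raises(ValueError):
        comparator_levels(1, "holm", 0.025)


def test_comparator_schedule_constant_levels():
    events = toy_events({1: "retain", 2: "retain", 3: "retain"})
    res = run_schedule(events, spending="PO", variant="level_alpha",
                       futility=None, t1=0.5, alpha=0.025)
    assert set(np.round(res.log["level"], 12)) == {0.025}
    res_b = run_schedule(events, spending="PO", variant="bonferroni",
                         futility=None, t1=0.5, alpha=0.025, K=3)
    assert set(np.round(res_b.log["level"], 12)) == {round(0.025 / 3, 12)}


def test_single_hypothesis_matches_plan():
    events = [
        AnalysisEvent(1.0, 1, "interim", 0.4),
        AnalysisEvent(2.0, 1, "final", 0.9),
    ]
    res = run_schedule(events, seq=SEQ, spending="PO", variant="gsLOND",
                       futility=None, t1=0.5)
    plan = two_stage_boundaries(0.05 / 3, t1=0.5, spending="PO")
    assert res.boundary(1, "interim") == pytest.approx(plan.a1)
    assert res.boundary(1, "final") == pytest.approx(plan.a2)


def test_sequencing_errors():
    seq = SEQ
    ev = lambda t, h, s, p=0.4: AnalysisEvent(t, h, s, p)
    with pytest.raises(SequencingError):  # non-increasing times
        run_schedule([ev(2.0, 1, "interim"), ev(1.0, 2, "interim")], seq=seq)
    with pytest.raises(SequencingError):  # duplicate interim
        run_schedule([ev(1.0, 1, "interim"), ev(2.0, 1, "interim")], seq=seq)
    with pytest.raises(SequencingError):  # final without interim
        run_schedule([ev(1.0, 1, "final")], seq=seq)
    with pytest.raises(SequencingError):  # final after interim rejection
        run_schedule([ev(1.0, 1, "interim", 1e-6), ev(2.0, 1, "final")], seq=seq)


def test_event_validation():
    with pytest.raises(ValueError):
        AnalysisEvent(1.0, 0, "interim", 0.5)
    with pytest.raises(ValueError):
        AnalysisEvent(1.0, 1, "midterm", 0.5)
    with pytest.raises(ValueError):
        AnalysisEvent(1.0, 1, "interim", 0.0)
    with pytest.raises(ValueError):
        AnalysisEvent(1.0, 1, "interim", 1.5)


def test_log_frame_columns():
    res = run_toy({1: "retain", 2: "retain", 3: "retain"}, "gsLOND")
    assert list(res.log.columns) == [
        "time", "hypothesis", "stage", "variant", "n_rejections",
        "level", "boundary", "p_value", "decision",
    ]
    assert len(res.log) == 6
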