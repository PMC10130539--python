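"""Deterministic worked example: three overlapping hypotheses.

A minimal platform trial with N = K = 3 hypotheses at one-sided alpha = 0.05
split equally (beta_i = 0.05/3), Pocock or OBF spending at information
fraction 0.5, and the interleaved chronology

    H1 interim < H2 interim < H1 final < H3 interim < H2 final < H3 final

(the ordering produced by staggered entry with overlapping stage timings).
Driving this chronology through every combination of outcomes enumerates all
boundary updates of the four scheduling rules; the resulting tables double as
regression fixtures.

P-values are only used here to force outcomes: a value far below every
boundary forces a rejection, a mid-range value continues past the interim,
and a large value retains.  No futility bound is applied, so "retain" means
retained at the final analysis.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .alpha_spending import two_stage_boundaries
from .beta_sequences import BetaSequence
from .lond import lond_level
from .scheduler import GS_VARIANTS, AnalysisEvent, run_schedule

TOY_ALPHA = 0.05
TOY_N = 3
TOY_T1 = 0.5

#: event times of the interleaved chronology
TOY_TIMES = {
    (1, "interim"): 1.0,
    (2, "interim"): 2.0,
    (1, "final"): 3.0,
    (3, "interim"): 4.0,
    (2, "final"): 5.0,
    (3, "final"): 6.0,
}

#: forcing p-values
P_REJECT = 1e-4     # below every boundary in the example
P_CONTINUE = 0.4    # above every interim boundary (no futility bound used)
P_RETAIN = 0.9

OUTCOMES = ("retain", "reject_interim", "reject_final")


def toy_sequence() -> BetaSequence:
    return BetaSequence.equal(TOY_ALPHA, TOY_N)


def toy_events(outcomes: dict[int, str]) -> list[AnalysisEvent]:
    """Event stream of the toy chronology forcing the given outcomes.

    ``outcomes`` maps hypothesis index to one of ``retain``,
    ``reject_interim`` or ``reject_final``.  A hypothesis rejected at interim
    has no final event.
    """
    events = []
    for i in (1, 2, 3):
        out = outcomes[i]
        if out not in OUTCOMES:
            raise ValueError(f"unknown outcome {out!r} for H{i}")
        if out == "reject_interim":
            events.append(
                AnalysisEvent(TOY_TIMES[(i, "interim")], i, "interim", P_REJECT)
            )
            continue
        events.append(
            AnalysisEvent(TOY_TIMES[(i, "interim")], i, "interim", P_CONTINUE)
        )
        p_final = P_REJECT if out == "reject_final" else P_RETAIN
        events.append(AnalysisEvent(TOY_TIMES[(i, "final")], i, "final", p_final))
    events.sort(key=lambda e: e.time)
    return events


def _run_toy(outcomes, variant, spending="PO"):
    return run_schedule(
        toy_events(outcomes),
        seq=toy_sequence(),
        spending=spending,
        variant=variant,
        futility=None,  # the example has no futility bound
        t1=TOY_T1,
    )


def reproduce_table1() -> pd.DataFrame:
    """Nominal levels and two-stage boundaries after 0, 1 or 2 rejections.

    Columns: the fixed-sample LOND level beta*(r+1) and the Pocock / OBF
    stage-1 and stage-2 boundaries of the group-sequential design at that
    level (t1 = 0.5).
    """
    beta = TOY_ALPHA / TOY_N
    rows = []
    for r in (0, 1, 2):
        level = lond_level(beta, r)
        po = two_stage_boundaries(level, t1=TOY_T1, spending="PO")
        obf = two_stage_boundaries(level, t1=TOY_T1, spending="OBF")
        rows.append(
            {
                "n_rejections": r,
                "lond_level": level,
                "po_stage1": po.a1,
                "po_stage2": po.a2,
                "obf_stage1": obf.a1,
                "obf_stage2": obf.a2,
            }
        )
    return pd.DataFrame(rows)


def reproduce_table2(spending: str = "PO") -> pd.DataFrame:
    """Boundaries for H2 under every (H1, H3) outcome combination.

    H2 continues past its interim and is retained at the final analysis, so
    the logged boundaries are the thresholds it was actually tested against.
    The stage-1 boundary is identical across the four rules here (only H1's
    interim decision precedes H2's interim); the stage-2 boundary is reported
    per rule.
    """
    rows = []
    for h1 in OUTCOMES:
        for h3 in OUTCOMES:
            row = {"H1": h1, "H3": h3}
            for variant in GS_VARIANTS:
                res = _run_toy({1: h1, 2: "retain", 3: h3}, variant, spending)
                if variant == "gsLOND":
                    row["stage1"] = res.boundary(2, "interim")
                row[f"{variant}_stage2"] = res.boundary(2, "final")
            rows.append(row)
    return pd.DataFrame(rows)


def reproduce_table3(spending: str = "PO") -> pd.DataFrame:
    """Boundaries for H3 under every (H1, H2) outcome combination.

    Both analyses of H1 precede H3's interim, so only whether H1 was rejected
    matters; H2's final analysis falls between H3's interim and final, which
    is the configuration where the increment-exhausting rule differs from the
    base rule.
    """
    rows = []
    for h1 in ("retain", "reject_interim"):
        for h2 in OUTCOMES:
            row = {"H1": "reject" if h1 != "retain" else "retain", "H2": h2}
            for variant in ("gsLOND", "gsLOND.II"):
                res = _run_toy({1: h1, 2: h2, 3: "retain"}, variant, spending)
                if variant == "gsLOND":
                    row["stage1"] = res.boundary(3, "interim")
                    row["gsLOND_stage2"] = res.boundary(3, "final")
                else:
                    row["gsLOND.II_stage2"] = res.boundary(3, "final")
            rows.append(row)
    return pd.DataFrame(rows)


def make_toy_fixtures(outdir) -> list[Path]:
    """Write the toy event streams and boundary tables as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    _write(reproduce_table1(), "table1_boundaries.csv")
    _write(reproduce_table2(), "table2_H2_boundaries.csv")
    _write(reproduce_table3(), "table3_H3_boundaries.csv")
    for h1 in OUTCOMES:
        for h3 in OUTCOMES:
            events = toy_events({1: h1, 2: "retain", 3: h3})
            df = pd.DataFrame(
                [
                    {
                        "hypothesis": e.hypothesis,
                        "stage": e.stage,
                        "time": e.time,
                        "p_value": e.p_value,
                    }
                    for e in events
                ]
            )
            _write(df, f"toy_events_H1-{h1}_H3-{h3}.csv")
    return written
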