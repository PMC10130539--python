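"""Event-driven group-sequential LOND over overlapping hypotheses.

In a platform trial the interim and final analyses of different treatment
arms interleave in calendar time, so the rejection count feeding the LOND
level of a hypothesis can change between its own interim and final look.
This module executes one of four scheduling rules over a chronologically
ordered stream of analysis events:

``gsLOND``
    The level for H_i at each of its analyses is ``beta_i * (r + 1)`` where
    ``r`` counts rejections among *earlier-entering* hypotheses (j < i) whose
    test happened strictly before the current analysis.  Boundaries always
    come from the initially chosen spending function at the (possibly
    increased) nominal level.

``gsLOND.II``
    As gsLOND, but when the nominal level rose between interim and final
    (because some H_j, j < i, was rejected in between), the final boundary is
    recomputed to spend the increment ``level_final - a1_actually_used`` in
    full, exhausting the updated level exactly.  This can only add
    rejections.

``gsLOND.III``
    As gsLOND, but the rejection count also includes later-entering
    hypotheses (j > i) decided before the current analysis.  This variant
    deliberately leaves the pre-fixed LOND order and carries no formal
    online-FDR guarantee; it never re-decides a completed test.

``gsLOND.II.III``
    Combination: the count is taken over all j != i (as in III) and, whenever
    the j < i count grew between interim and final, the boundary exhausts the
    increment of the (III-updated) nominal level (as in II).

Two comparator rules are available: ``level_alpha`` (no multiplicity
adjustment, constant nominal level alpha) and ``bonferroni`` (constant
``alpha / K``).

At an interim event the hypothesis is rejected if ``p <= a1``, stopped for
futility without rejection if ``p >= futility_bound`` (non-binding bound),
and continues to its final analysis otherwise.  Decisions are never revised:
a rejection counts from its timestamp onward, a futility stop contributes a
permanent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alpha_spending import (
    SpendingFunction,
    exhaust_increment_boundary,
    spending_function,
    two_stage_boundaries,
)
from .beta_sequences import BetaSequence

GS_VARIANTS = ("gsLOND", "gsLOND.II", "gsLOND.III", "gsLOND.II.III")
COMPARATORS = ("level_alpha", "bonferroni")

INTERIM = "interim"
FINAL = "final"


class SequencingError(ValueError):
    """Event stream violates the required chronology."""


@dataclass(frozen=True, order=True)
class AnalysisEvent:
    """One analysis of one hypothesis: (time, hypothesis, stage, p-value)."""

    time: float
    hypothesis: int
    stage: str = field(compare=False)
    p_value: float = field(compare=False)

    def __post_init__(self):
        if self.hypothesis < 1:
            raise ValueError("hypothesis index must be >= 1")
        if self.stage not in (INTERIM, FINAL):
            raise ValueError(f"stage must be 'interim' or 'final', got {self.stage!r}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value must lie in (0, 1], got {self.p_value}")


def comparator_levels(i: int, mode: str, alpha: float, K: int | None = None) -> float:
    """Constant nominal level of the comparator procedures."""
    if mode == "level_alpha":
        return alpha
    if mode == "bonferroni":
        if K is None or K < 1:
            raise ValueError("bonferroni requires the number of hypotheses K >= 1")
        return alpha / K
    raise ValueError(f"unknown comparator {mode!r}; expected one of {COMPARATORS}")


@dataclass
class HypothesisState:
    status: str = "pending"  # pending/in_stage2/rejected_interim/rejected_final/retained/stopped_futility
    interim_time: float | None = None
    interim_level: float | None = None
    a1_used: float | None = None
    interim_count_lower: int | None = None  # rejected j < i at interim
    interim_count_all: int | None = None  # rejected j != i at interim
    decision_time: float | None = None

    @property
    def rejected(self) -> bool:
        return self.status in ("rejected_interim", "rejected_final")

    @property
    def resolved(self) -> bool:
        return self.status not in ("pending", "in_stage2")


class ScheduleRunner:
    """Incremental executor of a group-sequential LOND (or comparator) rule.

    Feed events strictly in time order through :meth:`process`; each call
    returns the log row of that analysis (level, boundary, rejection count
    used, decision).  The runner owns the trial state, so the platform
    simulator can interleave event generation with decisions (needed for
    fixed-budget arm replacement).
    """

    def __init__(
        self,
        seq: BetaSequence | None = None,
        spending: SpendingFunction | str = "OBF",
        variant: str = "gsLOND",
        futility: float | None = 0.5,
        t1: float = 0.5,
        alpha: float | None = None,
        K: int | None = None,
    ):
        if variant not in GS_VARIANTS + COMPARATORS:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {GS_VARIANTS + COMPARATORS}"
            )
        if variant in GS_VARIANTS and seq is None:
            raise ValueError(f"variant {variant!r} requires a BetaSequence")
        if variant in COMPARATORS and alpha is None:
            raise ValueError(f"comparator {variant!r} requires alpha")
        self.seq = seq
        self.spending = spending_function(spending)
        self.variant = variant
        self.futility = futility
        self.t1 = t1
        self.alpha = alpha
        self.K = K
        self.states: dict[int, HypothesisState] = {}
        self.rejected_lower: list[int] = []  # rejected hypothesis indices, any order
        self._last_time: float | None = None
        self.log: list[dict] = []

    # -- level rules -------------------------------------------------------

    def _count_rejected(self, i: int, include_later: bool) -> int:
        if include_later:
            return sum(1 for j in self.rejected_lower if j != i)
        return sum(1 for j in self.rejected_lower if j < i)

    def _nominal_level(self, i: int, include_later: bool) -> tuple[float, int]:
        if self.variant in COMPARATORS:
            return comparator_levels(i, self.variant, self.alpha, self.K), 0
        count = self._count_rejected(i, include_later)
        beta_i = float(self.seq.values(i))
        return beta_i * (count + 1), count

    def interim_level(self, i: int) -> float:
        """Nominal level for the interim analysis of H_i given current state."""
        include_later = self.variant in ("gsLOND.III", "gsLOND.II.III")
        return self._nominal_level(i, include_later)[0]

    def final_level_and_boundary(self, i: int) -> tuple[float, float]:
        """Nominal level and final boundary a2 for H_i given current state."""
        st = self.states.get(i)
        if st is None or st.status != "in_stage2":
            raise SequencingError(
                f"final boundary requested for H{i} which is not awaiting its final analysis"
            )
        include_later = self.variant in ("gsLOND.III", "gsLOND.II.III")
        level, _ = self._nominal_level(i, include_later)
        count_lower = self._count_rejected(i, include_later=False)
        exhaust = (
            self.variant in ("gsLOND.II", "gsLOND.II.III")
            and count_lower > st.interim_count_lower
        )
        if exhaust:
            a2 = exhaust_increment_boundary(level, st.a1_used, self.t1)
        else:
            a2 = two_stage_boundaries(level, t1=self.t1, spending=self.spending).a2
        return level, a2

    # -- event processing ----------------------------------------------------

    def process(self, event: AnalysisEvent) -> dict:
        if self._last_time is not None and event.time <= self._last_time:
            raise SequencingError(
                f"events must have strictly increasing times (got {event.time} "
                f"after {self._last_time}); break ties upstream by hypothesis index"
            )
        i = event.hypothesis
        st = self.states.setdefault(i, HypothesisState())
        if event.stage == INTERIM:
            row = self._process_interim(event, st)
        else:
            row = self._process_final(event, st)
        self._last_time = event.time
        self.log.append(row)
        return row

    def _process_interim(self, event: AnalysisEvent, st: HypothesisState) -> dict:
        i = event.hypothesis
        if st.status != "pending":
            raise SequencingError(f"duplicate interim analysis for H{i}")
        include_later = self.variant in ("gsLOND.III", "gsLOND.II.III")
        level, count = self._nominal_level(i, include_later)
        a1 = self.spending(self.t1, level)
        st.interim_time = event.time
        st.interim_level = level
        st.a1_used = a1
        st.interim_count_lower = self._count_rejected(i, include_later=False)
        st.interim_count_all = self._count_rejected(i, include_later=True)
        if event.p_value <= a1:
            st.status = "rejected_interim"
            st.decision_time = event.time
            self.rejected_lower.append(i)
            decision = "reject"
        elif self.futility is not None and event.p_value >= self.futility:
            st.status = "stopped_futility"
            st.decision_time = event.time
            decision = "stop_futility"
        else:
            st.status = "in_stage2"
            decision = "continue"
        return {
            "time": event.time,
            "hypothesis": i,
            "stage": INTERIM,
            "variant": self.variant,
            "n_rejections": count,
            "level": level,
            "boundary": a1,
            "p_value": event.p_value,
            "decision": decision,
        }

    def _process_final(self, event: AnalysisEvent, st: HypothesisState) -> dict:
        i = event.hypothesis
        if st.status == "pending":
            raise SequencingError(f"final analysis for H{i} without a preceding interim")
        if st.status != "in_stage2":
            raise SequencingError(
                f"final analysis for H{i} which was already resolved ({st.status})"
            )
        include_later = self.variant in ("gsLOND.III", "gsLOND.II.III")
        level, count = self._nominal_level(i, include_later)
        _, a2 = self.final_level_and_boundary(i)
        if event.p_value <= a2:
            st.status = "rejected_final"
            self.rejected_lower.append(i)
            decision = "reject"
        else:
            st.status = "retained"
            decision = "retain"
        st.decision_time = event.time
        return {
            "time": event.time,
            "hypothesis": i,
            "stage": FINAL,
            "variant": self.variant,
            "n_rejections": count,
            "level": level,
            "boundary": a2,
            "p_value": event.p_value,
            "decision": decision,
        }

    # -- summaries ----------------------------------------------------------

    def rejections(self) -> set[int]:
        return {i for i, st in self.states.items() if st.rejected}

    def statuses(self) -> dict[int, str]:
        return {i: st.status for i, st in self.states.items()}

    def log_frame(self) -> pd.DataFrame:
        cols = [
            "time",
            "hypothesis",
            "stage",
            "variant",
            "n_rejections",
            "level",
            "boundary",
            "p_value",
            "decision",
        ]
        return pd.DataFrame(self.log, columns=cols)


@dataclass
class ScheduleResult:
    """Decision log plus terminal per-hypothesis statuses."""

    log: pd.DataFrame
    statuses: dict[int, str]
    rejected: set[int]

    def boundary(self, hypothesis: int, stage: str) -> float:
        sub = self.log[
            (self.log["hypothesis"] == hypothesis) & (self.log["stage"] == stage)
        ]
        if sub.empty:
            raise KeyError(f"no {stage} analysis logged for H{hypothesis}")
        return float(sub["boundary"].iloc[0])

    def level(self, hypothesis: int, stage: str) -> float:
        sub = self.log[
            (self.log["hypothesis"] == hypothesis) & (self.log["stage"] == stage)
        ]
        if sub.empty:
            raise KeyError(f"no {stage} analysis logged for H{hypothesis}")
        return float(sub["level"].iloc[0])


def run_schedule(
    events,
    seq: BetaSequence | None = None,
    spending: SpendingFunction | str = "OBF",
    variant: str = "gsLOND",
    futility: float | None = 0.5,
    t1: float = 0.5,
    alpha: float | None = None,
    K: int | None = None,
) -> ScheduleResult:
    """Execute a full, pre-sorted event stream.

    The stream must be chronologically sorted with strictly increasing
    timestamps, each hypothesis's interim must precede its final, and no
    final event may follow an interim rejection or futility stop (the caller
    decides which events actually happen).
    """
    events = list(events)
    if any(
        events[k].time >= events[k + 1].time for k in range(len(events) - 1)
    ):
        raise SequencingError("events must be sorted with strictly increasing times")
    runner = ScheduleRunner(
        seq=seq,
        spending=spending,
        variant=variant,
        futility=futility,
        t1=t1,
        alpha=alpha,
        K=K,
    )
    for ev in events:
        runner.process(ev)
    return ScheduleResult(
        log=runner.log_frame(),
        statuses=runner.statuses(),
        rejected=runner.rejections(),
    )
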