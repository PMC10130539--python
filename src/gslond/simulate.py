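"""Monte-Carlo simulator of platform trials with a shared control arm.

The generative model follows the standard staggered-entry platform design:
control patients accrue one at a time and their running index is the clock.
A new treatment arm opens every ``n_delta`` control patients; while an arm is
open it accrues one observation per control patient (1:1:...:1 allocation),
so arm i reaches its interim after ``n1`` further control patients and its
final analysis after ``n``.  Observations are N(delta_i, 1) with delta_i = 0
for controls and true nulls and delta_i = Delta for alternatives.  Each
analysis performs a pooled-variance one-sided two-sample t-test of
H0: mu_i <= 0 against the configured control set:

* ``CC``      - concurrent controls only (accrued in parallel with the arm,
                equal sample size),
* ``NCC_CC``  - all control observations accrued so far (non-concurrent plus
                concurrent), which inflates the control sample for late arms.

Treatment-arm data are identical under both control configurations at the
same seed, so CC-vs-NCC comparisons are paired by construction; the same
holds for comparisons across spending functions, procedure variants and
budget bounds N.

The information fraction of every interim is fixed at t1 = n1/n for both
control configurations (the boundaries do not exploit the larger NCC control
sample; a deliberate, mildly conservative choice).

Fixed-budget mode (:func:`run_budget_mode`) replaces early-stopped arms: the
platform's budget is B = K0*n + C with C the pre-planned control count; every
interim stop frees the arm's stage-2 allocation ``n2``, and a new arm opens
immediately once a full ``n`` fits into the freed pool.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .beta_sequences import BetaSequence
from .lond import run_fixed_sample
from .metrics import DecisionLedger, average_power, fdr_curve, mc_standard_error
from .scheduler import FINAL, INTERIM, AnalysisEvent, ScheduleRunner

GS_PROCEDURES = ("gsLOND", "gsLOND.II", "gsLOND.III", "gsLOND.II.III",
                 "level_alpha", "bonferroni")
ALL_PROCEDURES = ("LOND",) + GS_PROCEDURES

ORDERS = ("random", "alternatives_first", "alternatives_last")
CONTROL_MODES = ("CC", "NCC_CC")


class NotApplicableError(ValueError):
    """Requested metric is undefined for this design."""


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one simulated platform trial."""

    K: int = 10                      # number of treatment arms (K0 in budget mode)
    n: int = 50                      # per-arm treatment sample size
    n1: int = 25                     # stage-1 treatment sample size
    n_delta: int = 20                # control patients between arm entries
    delta: float | Sequence[float] = 0.6
    pi0: float = 0.5                 # proportion of true nulls
    order: str = "random"
    controls: str = "NCC_CC"
    alpha: float = 0.025             # one-sided overall FDR level
    futility: float | None = 0.5     # non-binding interim futility bound
    spending: str = "OBF"
    variant: str = "gsLOND"
    beta_kind: str = "descending_truncated"
    N: int | None = 100              # budget-sequence bound (None = unbounded)
    n_reps: int = 5000
    seed: int = 20221003
    budget_mode: int | None = None   # None or budget scenario 1..4
    K0: int | None = None            # initially planned arms in budget mode

    def __post_init__(self):
        if not 0 < self.n1 < self.n:
            raise ValueError("need 0 < n1 < n")
        if self.n_delta < 1:
            raise ValueError("n_delta must be >= 1")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if self.order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}")
        if self.controls not in CONTROL_MODES:
            raise ValueError(f"controls must be one of {CONTROL_MODES}")
        if self.variant not in ALL_PROCEDURES:
            raise ValueError(f"variant must be one of {ALL_PROCEDURES}")
        if self.budget_mode is not None and self.budget_mode not in (1, 2, 3, 4):
            raise ValueError("budget_mode must be None or one of 1..4")

    @property
    def n2(self) -> int:
        return self.n - self.n1

    @property
    def t1(self) -> float:
        return self.n1 / self.n

    def beta_sequence(self) -> BetaSequence | None:
        if self.variant in ("level_alpha", "bonferroni"):
            return None
        if self.beta_kind == "descending":
            return BetaSequence.descending(self.alpha)
        if self.beta_kind == "descending_truncated":
            if self.N is None:
                return BetaSequence.descending(self.alpha)
            return BetaSequence.descending_truncated(self.alpha, self.N)
        if self.beta_kind == "equal":
            if self.N is None:
                raise ValueError("equal beta sequence requires a bound N")
            return BetaSequence.equal(self.alpha, self.N)
        raise ValueError(f"unknown beta_kind {self.beta_kind!r}")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if isinstance(d["delta"], (tuple, list, np.ndarray)):
            d["delta"] = [float(x) for x in d["delta"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        return cls(**d)


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def _draw_truth(K: int, pi0: float, order: str, rng) -> np.ndarray:
    """is_null labels per arm, in entry order."""
    if order == "random":
        return rng.random(K) < pi0
    m1 = int(round(K * (1.0 - pi0)))  # number of alternatives
    is_null = np.ones(K, dtype=bool)
    if order == "alternatives_first":
        is_null[:m1] = False
    else:  # alternatives_last
        is_null[K - m1:] = False
    return is_null


def _draw_delta(delta_spec, rng) -> float:
    if np.ndim(delta_spec) == 0:
        return float(delta_spec)
    return float(rng.choice(np.asarray(delta_spec, dtype=float)))


def _one_sided_t_p(m1, v1, k1, m0, v0, k0):
    """One-sided (greater) pooled-variance two-sample t-test, vectorized."""
    df = k1 + k0 - 2
    sp2 = ((k1 - 1) * v1 + (k0 - 1) * v0) / df
    t = (m1 - m0) / np.sqrt(sp2 * (1.0 / k1 + 1.0 / k0))
    return stats.t.sf(t, df)


def _segment_stats(csum, csq, a, b):
    """Mean and ddof-1 variance of stream[a:b] from cumulative sums."""
    k = b - a
    m = (csum[b] - csum[a]) / k
    v = (csq[b] - csq[a] - k * m * m) / (k - 1)
    return m, v, k


@dataclass
class TrialData:
    """Raw replicate data plus per-arm p-values under one control mode."""

    is_null: np.ndarray
    deltas: np.ndarray
    p_interim: np.ndarray
    p_final: np.ndarray
    interim_times: np.ndarray
    final_times: np.ndarray
    controls: np.ndarray
    treatment: np.ndarray  # shape (K, n)


def _draw_trial_data(scenario: SimScenario, rng) -> TrialData:
    K, n, n1, nd = scenario.K, scenario.n, scenario.n1, scenario.n_delta
    is_null = _draw_truth(K, scenario.pi0, scenario.order, rng)
    deltas = np.array(
        [0.0 if is_null[i] else _draw_delta(scenario.delta, rng) for i in range(K)]
    )
    T = (K - 1) * nd + n
    controls = rng.standard_normal(T)
    treat = rng.standard_normal((K, n)) + deltas[:, None]

    csum = np.concatenate([[0.0], np.cumsum(controls)])
    csq = np.concatenate([[0.0], np.cumsum(controls * controls)])
    starts = nd * np.arange(K)

    mt1 = treat[:, :n1].mean(axis=1)
    vt1 = treat[:, :n1].var(axis=1, ddof=1)
    mt = treat.mean(axis=1)
    vt = treat.var(axis=1, ddof=1)

    if scenario.controls == "CC":
        a1, b1 = starts, starts + n1
        a2, b2 = starts, starts + n
    else:  # NCC_CC: everything accrued so far
        a1, b1 = np.zeros(K, dtype=int), starts + n1
        a2, b2 = np.zeros(K, dtype=int), starts + n
    mc1, vc1, k1 = _segment_stats(csum, csq, a1, b1)
    mc2, vc2, k2 = _segment_stats(csum, csq, a2, b2)

    p_interim = _one_sided_t_p(mt1, vt1, n1, mc1, vc1, k1)
    p_final = _one_sided_t_p(mt, vt, n, mc2, vc2, k2)
    return TrialData(
        is_null=is_null,
        deltas=deltas,
        p_interim=np.clip(p_interim, np.nextafter(0, 1), 1.0),
        p_final=np.clip(p_final, np.nextafter(0, 1), 1.0),
        interim_times=(starts + n1).astype(float),
        final_times=(starts + n).astype(float),
        controls=controls,
        treatment=treat,
    )


def generate_trial(scenario: SimScenario, rng):
    """One replicate: chronologically ordered potential events + truth labels.

    The stream contains the interim *and* final event of every arm; whether a
    final analysis actually takes place depends on the interim decision and is
    resolved by the scheduling rule at run time.
    """
    data = _draw_trial_data(scenario, rng)
    events = _potential_events(data)
    return events, data.is_null


def _potential_events(data: TrialData) -> list[AnalysisEvent]:
    K = data.is_null.size
    raw = []
    for i in range(K):
        raw.append((data.interim_times[i], i + 1, INTERIM, data.p_interim[i]))
        raw.append((data.final_times[i], i + 1, FINAL, data.p_final[i]))
    # simultaneous analyses are ordered by hypothesis index (order of entry)
    raw.sort(key=lambda r: (r[0], r[1]))
    events = []
    eps_rank = {}
    for t, h, s, p in raw:
        # enforce strictly increasing times by an infinitesimal index offset
        k = eps_rank.get(t, 0)
        eps_rank[t] = k + 1
        events.append(AnalysisEvent(time=t + k * 1e-9, hypothesis=h, stage=s, p_value=p))
    return events


# ---------------------------------------------------------------------------
# running replicates
# ---------------------------------------------------------------------------

def _run_one_gs(scenario: SimScenario, variant: str, data: TrialData, seq):
    runner = ScheduleRunner(
        seq=seq,
        spending=scenario.spending,
        variant=variant,
        futility=scenario.futility,
        t1=scenario.t1,
        alpha=scenario.alpha,
        K=scenario.K,
    )
    for ev in _potential_events(data):
        st = runner.states.get(ev.hypothesis)
        if ev.stage == FINAL and st is not None and st.resolved:
            continue  # stopped at interim: the final analysis never happens
        runner.process(ev)
    statuses = runner.statuses()
    K = data.is_null.size
    rejected = np.array(
        [statuses[i + 1] in ("rejected_interim", "rejected_final") for i in range(K)]
    )
    stopped = sum(
        1 for i in range(K) if statuses[i + 1] in ("rejected_interim", "stopped_futility")
    )
    return rejected, stopped


def _run_one(scenario: SimScenario, variant: str, data: TrialData, seq):
    """Terminal rejections (index order) and number of interim stops."""
    if variant == "LOND":
        rec = run_fixed_sample(data.p_final, seq)
        return rec.rejections, None
    return _run_one_gs(scenario, variant, data, seq)


@dataclass
class SimResult:
    """Aggregated operating characteristics of one scenario x procedure."""

    scenario: SimScenario
    variant: str
    n_reps: int
    fdr: float
    fdr_se: float
    power: float
    power_se: float
    saved_pct: float | None
    saved_pct_se: float | None
    fdr_by_step: np.ndarray | None
    rejected_alternatives: float
    rejected_alternatives_se: float
    per_rep: dict = field(repr=False, default_factory=dict)

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "n_reps": self.n_reps,
            "fdr": self.fdr,
            "fdr_se": self.fdr_se,
            "power": self.power,
            "power_se": self.power_se,
            "saved_pct": self.saved_pct,
            "saved_pct_se": self.saved_pct_se,
            "rejected_alternatives": self.rejected_alternatives,
            "rejected_alternatives_se": self.rejected_alternatives_se,
        }


def _aggregate(scenario, variant, ledgers, stops, n_reps, equal_len=True) -> SimResult:
    fdp = np.array([led.fdp_at_step(len(led)) for led in ledgers])
    power_rep = np.array(
        [
            (np.sum(led.rejected & ~led.is_null) / max(np.sum(~led.is_null), 1))
            if np.any(~led.is_null)
            else np.nan
            for led in ledgers
        ]
    )
    rej_alt = np.array([float(np.sum(led.rejected & ~led.is_null)) for led in ledgers])
    has_alt = ~np.isnan(power_rep)
    power = float(np.mean(power_rep[has_alt])) if has_alt.any() else float("nan")
    power_se = mc_standard_error(power_rep[has_alt]) if has_alt.any() else float("nan")
    if stops is None:
        saved = saved_se = None
        saved_rep = None
    else:
        saved_rep = 100.0 * np.asarray(stops, dtype=float) * scenario.n2 / (
            scenario.K * scenario.n
        )
        saved = float(np.mean(saved_rep))
        saved_se = mc_standard_error(saved_rep)
    return SimResult(
        scenario=scenario,
        variant=variant,
        n_reps=n_reps,
        fdr=float(np.mean(fdp)),
        fdr_se=mc_standard_error(fdp),
        power=power,
        power_se=power_se,
        saved_pct=saved,
        saved_pct_se=saved_se,
        fdr_by_step=fdr_curve(ledgers) if equal_len else None,
        rejected_alternatives=float(np.mean(rej_alt)),
        rejected_alternatives_se=mc_standard_error(rej_alt),
        per_rep={
            "fdp": fdp,
            "power": power_rep,
            "saved": saved_rep,
            "rejected_alternatives": rej_alt,
            "interim_stops": None if stops is None else np.asarray(stops),
        },
    )


def run_replicates(scenario: SimScenario, variants=None):
    """Simulate ``scenario.n_reps`` replicates and aggregate the metrics.

    ``variants``: optional list of procedures to evaluate on the *same*
    generated data (common random numbers); returns a dict keyed by variant.
    With the default (None) a single :class:`SimResult` for
    ``scenario.variant`` is returned.
    """
    if scenario.budget_mode is not None:
        raise ValueError("use run_budget_mode for budget scenarios")
    single = variants is None
    vlist = [scenario.variant] if single else list(variants)
    seqs = {
        v: replace(scenario, variant=v).beta_sequence() if v not in
        ("level_alpha", "bonferroni") else None
        for v in vlist
    }
    ledgers = {v: [] for v in vlist}
    stops = {v: [] for v in vlist}
    ss = np.random.SeedSequence(scenario.seed)
    for child in ss.spawn(scenario.n_reps):
        rng = np.random.default_rng(child)
        data = _draw_trial_data(scenario, rng)
        for v in vlist:
            rejected, nstop = _run_one(scenario, v, data, seqs[v])
            ledgers[v].append(DecisionLedger(rejected=rejected, is_null=data.is_null))
            if nstop is not None:
                stops[v].append(nstop)
    results = {
        v: _aggregate(
            scenario, v, ledgers[v], stops[v] if stops[v] else None, scenario.n_reps
        )
        for v in vlist
    }
    return results[vlist[0]] if single else results


def saved_sample_size(result: SimResult, denominator: str = "total") -> float:
    """Average % of treatment observations saved by interim stopping.

    ``denominator="total"`` divides the saved stage-2 observations by the
    total planned treatment observations K*n (the scale of the reported
    headline figures); ``"stage2"`` divides by the maximum stage-2 total
    K*n2.  Undefined for the fixed-sample design.
    """
    stops = result.per_rep.get("interim_stops")
    if stops is None:
        raise NotApplicableError(
            "saved sample size is undefined for the fixed-sample design"
        )
    sc = result.scenario
    denom = sc.K * (sc.n if denominator == "total" else sc.n2)
    return float(np.mean(100.0 * stops * sc.n2 / denom))


# ---------------------------------------------------------------------------
# fixed-budget mode with arm replacement
# ---------------------------------------------------------------------------

def _budget_truth_and_delta(scenario: SimScenario, rng, added_index: int | None):
    """Truth label and effect for one arm; added_index is 1-based for
    replacement arms and None for initially planned ones."""
    mode = scenario.budget_mode
    pi0 = scenario.pi0
    if mode == 3 and added_index is not None:
        pi0 = max(pi0 - added_index / 80.0, 0.0)
    is_null = bool(rng.random() < pi0)
    if is_null:
        return True, 0.0
    if mode == 2:
        return False, float(rng.choice([0.4, 0.8, 1.2]))
    if mode == 4 and added_index is not None:
        return False, 1.0
    return False, _draw_delta(scenario.delta, rng)


class _ControlStream:
    """Lazily extended N(0,1) control stream (the platform clock)."""

    def __init__(self, rng, chunk: int = 256):
        self.rng = rng
        self.chunk = chunk
        self.values = np.empty(0)

    def upto(self, idx: int) -> np.ndarray:
        while self.values.size < idx:
            self.values = np.concatenate(
                [self.values, self.rng.standard_normal(self.chunk)]
            )
        return self.values

    def segment(self, a: int, b: int):
        v = self.upto(b)[a:b]
        return float(v.mean()), float(v.var(ddof=1)), b - a


def _budget_replicate(scenario: SimScenario, rng):
    K0 = scenario.K0 or scenario.K
    n, n1, n2, nd = scenario.n, scenario.n1, scenario.n2, scenario.n_delta
    planned_controls = (K0 - 1) * nd + n
    budget = K0 * n + planned_controls

    controls = _ControlStream(rng)
    arms = []  # dicts: start, is_null, delta, treat
    heap: list[tuple[float, int, int]] = []  # (time, hyp 1-based, stage 0=interim 1=final)

    def open_arm(start: int, added_index: int | None):
        is_null, delta = _budget_truth_and_delta(scenario, rng, added_index)
        treat = rng.standard_normal(n) + delta
        arms.append({"start": start, "is_null": is_null, "delta": delta, "treat": treat})
        heapq.heappush(heap, (float(start + n1), len(arms), 0))

    for i in range(K0):
        open_arm(i * nd, None)

    variant = scenario.variant
    seq = scenario.beta_sequence()
    if variant == "LOND":
        # no interim analyses: no early stopping, hence no replacements
        p_final = np.empty(K0)
        for i, arm in enumerate(arms):
            s = arm["start"]
            a = s if scenario.controls == "CC" else 0
            mc, vc, kc = controls.segment(a, s + n)
            x = arm["treat"]
            p_final[i] = _one_sided_t_p(
                x.mean(), x.var(ddof=1), n, mc, vc, kc
            )
        rec = run_fixed_sample(np.clip(p_final, np.nextafter(0, 1), 1.0), seq)
        rejected = rec.rejections
        is_null = np.array([a["is_null"] for a in arms])
        used = K0 * n + planned_controls
        return DecisionLedger(rejected=rejected, is_null=is_null), used, budget, K0

    runner = ScheduleRunner(
        seq=seq,
        spending=scenario.spending,
        variant=variant,
        futility=scenario.futility,
        t1=scenario.t1,
        alpha=scenario.alpha,
        K=K0,
    )
    freed = 0
    n_added = 0
    tie_eps = {}
    while heap:
        time, hyp, stage = heapq.heappop(heap)
        arm = arms[hyp - 1]
        s = arm["start"]
        a = s if scenario.controls == "CC" else 0
        if stage == 0:
            mc, vc, kc = controls.segment(a, s + n1)
            x = arm["treat"][:n1]
        else:
            mc, vc, kc = controls.segment(a, s + n)
            x = arm["treat"]
        p = float(
            np.clip(
                _one_sided_t_p(x.mean(), x.var(ddof=1), x.size, mc, vc, kc),
                np.nextafter(0, 1),
                1.0,
            )
        )
        k = tie_eps.get(time, 0)
        tie_eps[time] = k + 1
        ev = AnalysisEvent(
            time=time + k * 1e-9,
            hypothesis=hyp,
            stage=INTERIM if stage == 0 else FINAL,
            p_value=p,
        )
        row = runner.process(ev)
        if stage == 0:
            if row["decision"] == "continue":
                heapq.heappush(heap, (float(s + n), hyp, 1))
            else:
                freed += n2
                if freed >= n:
                    n_added += 1
                    freed -= n
                    open_arm(int(round(time)), n_added)

    statuses = runner.statuses()
    K_total = len(arms)
    rejected = np.array(
        [statuses[i + 1] in ("rejected_interim", "rejected_final") for i in range(K_total)]
    )
    is_null = np.array([a["is_null"] for a in arms])
    treatment_used = sum(
        n1 if statuses[i + 1] in ("rejected_interim", "stopped_futility") else n
        for i in range(K_total)
    )
    used = treatment_used + planned_controls
    return DecisionLedger(rejected=rejected, is_null=is_null), used, budget, K_total


def run_budget_mode(scenario: SimScenario):
    """Simulate the fixed-budget platform with immediate arm replacement."""
    if scenario.budget_mode not in (1, 2, 3, 4):
        raise ValueError("scenario.budget_mode must be one of 1..4")
    K0 = scenario.K0 or scenario.K
    if K0 < 1:
        raise ValueError("budget must cover at least one arm")
    ledgers, used_list, n_arms = [], [], []
    budget = None
    ss = np.random.SeedSequence(scenario.seed)
    for child in ss.spawn(scenario.n_reps):
        rng = np.random.default_rng(child)
        led, used, budget, k_tot = _budget_replicate(scenario, rng)
        ledgers.append(led)
        used_list.append(used)
        n_arms.append(k_tot)
    result = _aggregate(
        scenario, scenario.variant, ledgers, None, scenario.n_reps, equal_len=False
    )
    result.per_rep["observations_used"] = np.asarray(used_list)
    result.per_rep["budget"] = budget
    result.per_rep["n_arms"] = np.asarray(n_arms)
    return result
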