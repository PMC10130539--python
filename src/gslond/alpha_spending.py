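"""Alpha-spending functions and two-stage group-sequential boundaries.

A group-sequential test of a single one-sided hypothesis at nominal level
``alpha_i`` with one interim look at information fraction ``t1`` is specified
by two critical boundaries on the nominal p-value scale: ``a1`` for the
interim analysis and ``a2`` for the final analysis.  ``a1`` is set by a
Lan-DeMets spending function evaluated at ``t1``; ``a2`` is then the solution
of

    P(p1 > a1, p <= a2 | H0) = alpha_i - a1,

where the interim and final z-statistics are bivariate standard normal with
correlation ``sqrt(t1)`` (pooled final analysis with proportional per-stage
allocation).  The bivariate normal rectangle probability is evaluated in
closed form through Owen's T function, and ``a2`` is found by bracketed
root-finding, so each plan is exact to ~1e-12 and is cached.

Two spending shapes are provided (one-sided):

* approximate O'Brien-Fleming: ``2 * (1 - Phi(Phi^{-1}(1 - alpha/2) / sqrt(t)))``
* approximate Pocock: ``alpha * ln(1 + (e - 1) * t)``

OBF spends almost nothing at the interim and nearly the full level at the
final analysis; Pocock splits the level roughly evenly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm


class InfeasiblePlanError(ValueError):
    """No level is left for the second stage."""


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen's T closed form)
# ---------------------------------------------------------------------------

def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Closed form through Owen's T function (Owen 1956), accurate to ~1e-15
    and far faster than numerical integration, which matters because the
    boundary root-finder evaluates it repeatedly.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if math.isinf(h) or math.isinf(k):
        if h == -math.inf or k == -math.inf:
            return 0.0
        return float(norm.cdf(k)) if math.isinf(h) else float(norm.cdf(h))
    if rho == 0.0:
        return float(norm.cdf(h) * norm.cdf(k))
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    if h == 0.0 or k == 0.0:
        # Owen's formula has removable singularities here; defer to the
        # generic integrator for these measure-zero arguments.
        from scipy.stats import multivariate_normal

        cov = [[1.0, rho], [rho, 1.0]]
        return float(multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([h, k]))
    s = math.sqrt(1.0 - rho * rho)
    delta = 0.0 if h * k > 0 else 0.5
    t_h = float(owens_t(h, (k - rho * h) / (h * s)))
    t_k = float(owens_t(k, (h - rho * k) / (k * s)))
    return 0.5 * (float(norm.cdf(h)) + float(norm.cdf(k))) - t_h - t_k - delta


# ---------------------------------------------------------------------------
# spending functions
# ---------------------------------------------------------------------------

def _check_spend_args(t_star: float, alpha_i: float) -> None:
    if not 0.0 <= t_star <= 1.0:
        raise ValueError(f"information fraction must lie in [0, 1], got {t_star}")
    if not 0.0 < alpha_i < 1.0:
        raise ValueError(f"nominal level must lie in (0, 1), got {alpha_i}")


def spend_obf(t_star: float, alpha_i: float) -> float:
    """Cumulative alpha spent by the approximate O'Brien-Fleming shape."""
    _check_spend_args(t_star, alpha_i)
    if t_star == 0.0:
        return 0.0
    return float(2.0 * (1.0 - norm.cdf(norm.ppf(1.0 - alpha_i / 2.0) / math.sqrt(t_star))))


def spend_pocock(t_star: float, alpha_i: float) -> float:
    """Cumulative alpha spent by the approximate Pocock shape."""
    _check_spend_args(t_star, alpha_i)
    return float(alpha_i * math.log(1.0 + (math.e - 1.0) * t_star))


@dataclass(frozen=True)
class SpendingFunction:
    """A named one-sided alpha-spending shape (``"OBF"`` or ``"PO"``)."""

    kind: str

    def __post_init__(self):
        if self.kind not in ("OBF", "PO"):
            raise ValueError(f"unknown spending kind {self.kind!r}; expected 'OBF' or 'PO'")

    def __call__(self, t_star: float, alpha_i: float) -> float:
        if self.kind == "OBF":
            return spend_obf(t_star, alpha_i)
        return spend_pocock(t_star, alpha_i)


OBF = SpendingFunction("OBF")
PO = SpendingFunction("PO")


def spending_function(spec) -> SpendingFunction:
    """Coerce a string ('obf'/'po') or SpendingFunction to a SpendingFunction."""
    if isinstance(spec, SpendingFunction):
        return spec
    key = str(spec).upper()
    if key in ("OBF", "O'BRIEN-FLEMING", "OBRIEN-FLEMING"):
        return OBF
    if key in ("PO", "POCOCK"):
        return PO
    raise ValueError(f"unknown spending function {spec!r}")


# ---------------------------------------------------------------------------
# two-stage plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStagePlan:
    """Critical boundaries of a one-sided two-stage group-sequential test.

    All boundaries live on the nominal p-value scale.  ``futility`` is a
    non-binding interim stopping bound: the efficacy boundaries ``a1``/``a2``
    are computed ignoring it.
    """

    nominal_alpha: float
    t1: float
    a1: float
    a2: float
    spending: SpendingFunction
    futility: float | None = None

    @property
    def correlation(self) -> float:
        """corr(Z_interim, Z_final) = sqrt(t1) under pooled final analysis."""
        return math.sqrt(self.t1)


def _second_stage_probability(a1: float, a2: float, rho: float) -> float:
    """P(p1 > a1, p <= a2) under H0 = P(Z1 < z_{a1}, Zf >= z_{a2})."""
    z1 = float(norm.ppf(1.0 - a1))
    z2 = float(norm.ppf(1.0 - a2))
    return float(norm.cdf(z1)) - bvn_cdf(z1, z2, rho)


def _solve_second_stage(target: float, a1: float, rho: float) -> float:
    """Find a2 with P(p1 > a1, p <= a2 | H0) = target."""
    if target <= 0.0:
        raise InfeasiblePlanError(
            f"no level left for the second stage (target increment {target})"
        )
    f = lambda a2: _second_stage_probability(a1, a2, rho) - target
    return float(brentq(f, 1e-14, 1.0 - 1e-12, xtol=1e-15, rtol=8.9e-16))


@lru_cache(maxsize=None)
def _plan_cached(nominal_alpha: float, t1: float, kind: str) -> tuple[float, float]:
    spending = SpendingFunction(kind)
    a1 = spending(t1, nominal_alpha)
    if a1 >= nominal_alpha:
        raise InfeasiblePlanError(
            f"spending exhausts the level at the interim (a1={a1} >= alpha={nominal_alpha})"
        )
    a2 = _solve_second_stage(nominal_alpha - a1, a1, math.sqrt(t1))
    return a1, a2


def two_stage_boundaries(
    nominal_alpha: float,
    t1: float = 0.5,
    spending: SpendingFunction | str = OBF,
    futility: float | None = None,
) -> TwoStagePlan:
    """Boundaries of a two-stage design exhausting ``nominal_alpha``.

    ``a1`` is the spend at ``t1``; ``a2`` solves the bivariate-normal
    continuation equation so the overall null rejection probability equals
    ``nominal_alpha`` (futility, if any, is non-binding and ignored here).
    """
    if not 0.0 < nominal_alpha < 1.0:
        raise ValueError(f"nominal level must lie in (0, 1), got {nominal_alpha}")
    if not 0.0 < t1 < 1.0:
        raise ValueError(f"t1 must lie in (0, 1), got {t1}")
    spending = spending_function(spending)
    a1, a2 = _plan_cached(float(nominal_alpha), float(t1), spending.kind)
    return TwoStagePlan(
        nominal_alpha=nominal_alpha,
        t1=t1,
        a1=a1,
        a2=a2,
        spending=spending,
        futility=futility,
    )


@lru_cache(maxsize=None)
def exhaust_increment_boundary(
    nominal_final: float, a1_spent: float, t1: float = 0.5
) -> float:
    """Final boundary spending the increment ``nominal_final - a1_spent``.

    Used when the nominal level of a hypothesis rose between its interim and
    final analysis: the interim was already tested at ``a1_spent``, and the
    remaining level is spent entirely at the final look so the updated
    nominal level is exhausted exactly.
    """
    if not 0.0 < t1 < 1.0:
        raise ValueError(f"t1 must lie in (0, 1), got {t1}")
    if nominal_final <= a1_spent:
        raise InfeasiblePlanError(
            f"updated level {nominal_final} does not exceed the interim spend {a1_spent}"
        )
    return _solve_second_stage(nominal_final - a1_spent, a1_spent, math.sqrt(t1))


def boundary_table(alphas, t1: float = 0.5, spendings=("PO", "OBF")):
    """Tabulate (nominal_alpha, spending, t1, a1, a2) for a list of levels."""
    import pandas as pd

    rows = []
    for a in alphas:
        for sp in spendings:
            plan = two_stage_boundaries(a, t1=t1, spending=sp)
            rows.append(
                {
                    "nominal_alpha": a,
                    "spending": spending_function(sp).kind,
                    "t1": t1,
                    "a1": plan.a1,
                    "a2": plan.a2,
                }
            )
    return pd.DataFrame(rows)
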