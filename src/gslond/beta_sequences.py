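"""Budget sequences for online FDR control.

The LOND procedure splits the overall one-sided FDR level ``alpha`` into a
pre-specified sequence of non-negative budgets ``beta_i`` with
``sum_i beta_i <= alpha``.  Four constructions are supported:

``descending``
    The slowly decaying series ``beta_j = C * alpha * log(max(j, 2)) /
    (j * exp(sqrt(log j)))`` (natural logarithms), suitable for an unbounded
    hypothesis stream.  ``C`` defaults to the conventional constant
    0.07720838; with that value the infinite sum is slightly below ``alpha``
    (about ``0.976 * alpha``), which keeps the procedure (mildly
    conservatively) valid.  :func:`normalizing_constant` recomputes the exact
    normalizer from the series for users who prefer self-consistency.

``descending_truncated``
    The same series rescaled so that the first ``N`` terms sum exactly to
    ``alpha`` (and ``beta_i = 0`` beyond ``N``) when an a-priori upper bound
    ``N`` on the number of hypotheses is acceptable.  Bounding ``N`` raises
    every budget and hence power.

``equal``
    ``beta_i = alpha / N`` for ``i <= N``: the level is split equally among
    all potential hypotheses.

``dependent_adjusted``
    Any base sequence divided by the harmonic number ``H_i = sum_{j<=i} 1/j``,
    which restores FDR control under arbitrary dependence (the online
    analogue of the Benjamini-Yekutieli correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma, gammaincc

#: Conventional normalizing constant for the descending series.
JM_CONSTANT = 0.07720838

#: Euler-Mascheroni constant, used for harmonic numbers.
_EULER_GAMMA = 0.5772156649015328606

KINDS = ("descending", "descending_truncated", "equal", "dependent_adjusted")


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")


def _check_index(j) -> np.ndarray:
    j = np.asarray(j)
    if not np.issubdtype(j.dtype, np.integer) and not np.all(j == np.floor(j)):
        raise ValueError("hypothesis index must be a positive integer")
    if np.any(j < 1):
        raise ValueError("hypothesis index must be >= 1")
    return j.astype(float)


def _series_term(j) -> np.ndarray:
    """log(max(j,2)) / (j * exp(sqrt(log j))), elementwise."""
    j = np.asarray(j, dtype=float)
    return np.log(np.maximum(j, 2.0)) / (j * np.exp(np.sqrt(np.log(j))))


def beta_descending(j, alpha: float, C: float = JM_CONSTANT):
    """Budget ``beta_j`` of the descending sequence.

    Parameters
    ----------
    j : int or array of int
        Hypothesis index (1-based).
    alpha : float
        Overall one-sided FDR level in (0, 1).
    C : float
        Normalizing constant (> 0).

    Returns
    -------
    float or ndarray
    """
    _check_alpha(alpha)
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    jf = _check_index(j)
    out = C * alpha * _series_term(jf)
    return float(out) if np.isscalar(j) or np.ndim(j) == 0 else out


def _series_tail(m: float) -> float:
    """Analytic integral tail ``int_m^inf log(x)/(x exp(sqrt(log x))) dx``.

    Substituting ``t = sqrt(log x)`` turns the integral into
    ``2 * Gamma(4, sqrt(log m))`` (upper incomplete gamma).
    """
    t = math.sqrt(math.log(m))
    return 2.0 * 6.0 * float(gammaincc(4, t))  # Gamma(4) = 6


def series_total(n_terms: int = 10**6) -> float:
    """Full sum of the unnormalized descending series.

    Exact partial sum of the first ``n_terms`` terms plus the analytic
    integral tail (midpoint-corrected).  The series converges extremely
    slowly, so the tail term is essential: the first 1e6 terms cover only
    about half of the total.
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    partial = float(_series_term(np.arange(1, n_terms + 1)).sum())
    return partial + _series_tail(n_terms + 0.5)


def normalizing_constant(n_terms: int = 10**6) -> float:
    """Constant ``C`` that makes the descending budgets sum exactly to alpha.

    Computed as the reciprocal of :func:`series_total`.  Note this exact
    normalizer (~0.079082) is a little larger than the conventional
    :data:`JM_CONSTANT`; using the conventional constant under-spends the
    level slightly and is therefore conservative.
    """
    return 1.0 / series_total(n_terms)


def harmonic_number(i) -> np.ndarray:
    """``H_i = sum_{j=1}^{i} 1/j`` via the digamma identity."""
    ifl = _check_index(i)
    out = digamma(ifl + 1.0) + _EULER_GAMMA
    return float(out) if np.ndim(i) == 0 else out


@dataclass(frozen=True)
class BetaSequence:
    """Per-hypothesis budgets ``beta_i`` with ``sum_i beta_i <= alpha``.

    Construct through the classmethods :meth:`descending`,
    :meth:`descending_truncated` and :meth:`equal`, or adjust an existing
    sequence for general dependence with :meth:`adjusted_for_dependence`.
    """

    alpha: float
    kind: str
    N: int | None = None
    C: float = JM_CONSTANT
    _scale: float = field(default=1.0, repr=False)
    _base_kind: str | None = field(default=None, repr=False)

    def __post_init__(self):
        _check_alpha(self.alpha)
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if self.kind in ("descending_truncated", "equal") and (
            self.N is None or self.N < 1
        ):
            raise ValueError(f"kind {self.kind!r} requires a bound N >= 1")

    # -- constructors -----------------------------------------------------

    @classmethod
    def descending(cls, alpha: float, C: float = JM_CONSTANT) -> "BetaSequence":
        return cls(alpha=alpha, kind="descending", C=C)

    @classmethod
    def descending_truncated(
        cls, alpha: float, N: int, C: float = JM_CONSTANT
    ) -> "BetaSequence":
        return rescale_to_bound(cls.descending(alpha, C=C), N)

    @classmethod
    def equal(cls, alpha: float, N: int) -> "BetaSequence":
        if N < 1:
            raise ValueError(f"N must be >= 1, got {N}")
        return cls(alpha=alpha, kind="equal", N=int(N))

    # -- evaluation -------------------------------------------------------

    def values(self, i):
        """Budget ``beta_i`` for 1-based index ``i`` (scalar or array)."""
        ifl = _check_index(i)
        kind = self._base_kind or self.kind
        if kind == "equal":
            vals = np.full_like(ifl, self.alpha / self.N)
        else:
            vals = self.C * self.alpha * _series_term(ifl) * self._scale
        if self.N is not None:
            vals = np.where(ifl > self.N, 0.0, vals)
        if self.kind == "dependent_adjusted":
            vals = vals / harmonic_number(np.asarray(i))
        return float(vals) if np.ndim(i) == 0 else vals

    def partial_sum(self, n: int) -> float:
        """``sum_{i=1}^{n} beta_i`` by direct term-by-term summation."""
        return float(np.sum(self.values(np.arange(1, n + 1))))

    def adjusted_for_dependence(self) -> "BetaSequence":
        """Divide every budget by the harmonic number ``H_i``.

        The resulting sequence keeps FDR control under arbitrary dependence
        between the p-values.
        """
        if self.kind == "dependent_adjusted":
            return self
        return replace(self, kind="dependent_adjusted", _base_kind=self.kind)

    # -- export -----------------------------------------------------------

    def to_frame(self, n: int):
        """First ``n`` budgets as a two-column DataFrame (index, beta)."""
        import pandas as pd

        idx = np.arange(1, n + 1)
        return pd.DataFrame({"index": idx, "beta": self.values(idx)})


def rescale_to_bound(seq: BetaSequence, N: int) -> BetaSequence:
    """Rescale a descending sequence so the first ``N`` budgets sum to alpha.

    ``beta_i' = beta_i * alpha / sum_{j<=N} beta_j`` for ``i <= N`` and zero
    beyond; the rescale factor is >= 1, so every retained budget grows.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if seq.kind != "descending":
        raise ValueError("rescale_to_bound expects a descending sequence")
    total = seq.partial_sum(int(N))
    return replace(
        seq,
        kind="descending_truncated",
        N=int(N),
        _scale=seq._scale * seq.alpha / total,
    )


def dependent_adjustment(seq: BetaSequence, i: int) -> float:
    """Budget ``beta_i / H_i`` restoring FDR control under dependence."""
    return float(seq.values(i) / harmonic_number(i))
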