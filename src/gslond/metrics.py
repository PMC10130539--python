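"""Error-rate and efficiency metrics over decision records.

The online FDR after the i-th decision is

    FDR_i = E[ V(i) / max(sum_{j<=i} R_j, 1) ]

with V(i) the number of falsely rejected hypotheses among the first i.  The
expectation is estimated by averaging the false discovery proportion (FDP)
over simulation replicates; a replicate without rejections contributes zero
(the clamped denominator).  Average power is the proportion of rejected
alternatives among all alternatives, averaged over replicates that contain at
least one alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DecisionLedger:
    """Decisions of one replicate in hypothesis-index order.

    ``rejected[j]`` is the terminal decision for H_{j+1} and ``is_null[j]``
    its truth label (True = null hypothesis, i.e. a rejection is false).
    """

    rejected: np.ndarray
    is_null: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rejected, dtype=bool)
        t = np.asarray(self.is_null, dtype=bool)
        if r.shape != t.shape or r.ndim != 1:
            raise ValueError("rejected and is_null must be 1-d arrays of equal length")
        object.__setattr__(self, "rejected", r)
        object.__setattr__(self, "is_null", t)

    def __len__(self) -> int:
        return self.rejected.size

    def fdp_at_step(self, i: int) -> float:
        """V(i) / max(R(i), 1) for this replicate."""
        if not 1 <= i <= len(self):
            raise ValueError(f"step i must lie in 1..{len(self)}, got {i}")
        r = self.rejected[:i]
        v = int(np.sum(r & self.is_null[:i]))
        return v / max(int(r.sum()), 1)

    def fdp_curve(self) -> np.ndarray:
        """FDP after each decision step."""
        v = np.cumsum(self.rejected & self.is_null)
        r = np.cumsum(self.rejected)
        return v / np.maximum(r, 1)


def fdr_at_step(ledgers, i: int) -> float:
    """Empirical online FDR at decision step i across replicates."""
    ledgers = list(ledgers)
    if not ledgers:
        raise ValueError("at least one replicate is required")
    return float(np.mean([led.fdp_at_step(i) for led in ledgers]))


def fdr_curve(ledgers) -> np.ndarray:
    """Empirical FDR after every decision step (replicates of equal length)."""
    ledgers = list(ledgers)
    if not ledgers:
        raise ValueError("at least one replicate is required")
    return np.mean([led.fdp_curve() for led in ledgers], axis=0)


def average_power(ledgers) -> float:
    """Mean proportion of rejected alternatives among all alternatives.

    Replicates without any alternative carry no information about power and
    are excluded (relevant for randomly drawn truth labels).
    """
    fractions = []
    for led in ledgers:
        alts = ~led.is_null
        n_alt = int(alts.sum())
        if n_alt:
            fractions.append(int(np.sum(led.rejected & alts)) / n_alt)
    if not fractions:
        raise ValueError("no replicate contains an alternative hypothesis")
    return float(np.mean(fractions))


def mc_standard_error(samples) -> float:
    """Monte-Carlo standard error of a per-replicate sample mean."""
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))
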