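"""Fixed-sample-size online LOND.

LOND ("significance Levels based On Number of Discoveries") tests a stream of
hypotheses H_1, H_2, ... in a pre-specified, data-independent order.  The
nominal level for H_i is its budget beta_i inflated by the number of
discoveries made so far:

    alpha_i = beta_i * (1 + number of rejections among H_1 .. H_{i-1})

which controls the online FDR at level alpha = sum_i beta_i after every
decision, for independent or positively dependent (PRDS) p-values.  The
"updated" variant uses ``beta_i * max(R, 1)`` instead, which carries the
positive-dependence proof.

P-values exactly on the boundary are rejected (p <= alpha_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta_sequences import BetaSequence

VARIANTS = ("standard", "updated")


def lond_level(beta_i: float, n_rejections: int) -> float:
    """Nominal level ``beta_i * (n_rejections + 1)``."""
    if beta_i < 0:
        raise ValueError(f"beta_i must be non-negative, got {beta_i}")
    if n_rejections < 0:
        raise ValueError(f"rejection count must be non-negative, got {n_rejections}")
    return beta_i * (n_rejections + 1)


def lond_level_updated(beta_i: float, n_rejections: int) -> float:
    """Nominal level ``beta_i * max(n_rejections, 1)`` (updated LOND)."""
    if beta_i < 0:
        raise ValueError(f"beta_i must be non-negative, got {beta_i}")
    if n_rejections < 0:
        raise ValueError(f"rejection count must be non-negative, got {n_rejections}")
    return beta_i * max(n_rejections, 1)


@dataclass
class DecisionRecord:
    """Outcome of a fixed-sample LOND run."""

    table: pd.DataFrame  # columns: index, beta, level, p_value, reject
    variant: str

    @property
    def rejections(self) -> np.ndarray:
        return self.table["reject"].to_numpy()

    @property
    def n_rejections(self) -> int:
        return int(self.table["reject"].sum())


def run_fixed_sample(
    pvalues, seq: BetaSequence, variant: str = "standard"
) -> DecisionRecord:
    """Run LOND over an ordered p-value stream.

    The i-th p-value is tested at a level computed from the decisions on the
    first i-1 hypotheses only (the online property).  Returns the full
    decision record with per-hypothesis budget, level and decision.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rule = lond_level if variant == "standard" else lond_level_updated
    n = p.size
    betas = seq.values(np.arange(1, n + 1)) if n else np.empty(0)
    levels = np.empty(n)
    reject = np.zeros(n, dtype=bool)
    n_rej = 0
    for i in range(n):
        levels[i] = rule(float(betas[i]), n_rej)
        reject[i] = p[i] <= levels[i]
        n_rej += int(reject[i])
    table = pd.DataFrame(
        {
            "index": np.arange(1, n + 1),
            "beta": betas,
            "level": levels,
            "p_value": p,
            "reject": reject,
        }
    )
    return DecisionRecord(table=table, variant=variant)
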