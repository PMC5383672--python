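"""Signal-detection scoring of the oddball vigilance task.

Sensitivity is the yes/no d' = Phi^-1(H) - Phi^-1(F), with H the hit rate
over oddball blocks and F the false-alarm rate over standard blocks.
Participants whose d' falls more than k standard deviations below the group
mean are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DetectionOutcome",
    "DPrimeResult",
    "ExtremeRateError",
    "dprime",
    "exclude_low_performers",
    "condition_hit_rates",
]


class ExtremeRateError(ValueError):
    """A hit or false-alarm rate of exactly 0 or 1 under the 'error' policy."""


@dataclass(frozen=True)
class DetectionOutcome:
    """Counts from a yes/no detection task."""

    hits: int
    n_signal: int
    false_alarms: int
    n_noise: int

    def __post_init__(self) -> None:
        if self.n_signal < 1 or self.n_noise < 1:
            raise ValueError("denominators must be >= 1")
        if not 0 <= self.hits <= self.n_signal:
            raise ValueError("hits must lie in [0, n_signal]")
        if not 0 <= self.false_alarms <= self.n_noise:
            raise ValueError("false_alarms must lie in [0, n_noise]")


@dataclass(frozen=True)
class DPrimeResult:
    d_prime: float
    hit_rate: float
    fa_rate: float
    correction_applied: bool


def dprime(outcome: DetectionOutcome, extreme_rate_policy: str = "error") -> DPrimeResult:
    """d' = Phi^-1(H) - Phi^-1(F).

    extreme_rate_policy:
      * ``"error"`` (default) — raise :class:`ExtremeRateError` if H or F is
        exactly 0 or 1 (the normal quantile is infinite there).
      * ``"loglinear"`` — when any rate is extreme, replace both rates with
        (x + 0.5) / (n + 1) before taking quantiles.
    """
    if extreme_rate_policy not in ("error", "loglinear"):
        raise ValueError(f"unknown extreme_rate_policy {extreme_rate_policy!r}")
    h = outcome.hits / outcome.n_signal
    f = outcome.false_alarms / outcome.n_noise
    corrected = False
    if h in (0.0, 1.0) or f in (0.0, 1.0):
        if extreme_rate_policy == "error":
            bad = "hit rate" if h in (0.0, 1.0) else "false-alarm rate"
            raise ExtremeRateError(
                f"{bad} is extreme (H={h}, F={f}); use the 'loglinear' policy"
            )
        h = (outcome.hits + 0.5) / (outcome.n_signal + 1)
        f = (outcome.false_alarms + 0.5) / (outcome.n_noise + 1)
        corrected = True
    return DPrimeResult(
        d_prime=float(norm.ppf(h) - norm.ppf(f)),
        hit_rate=h,
        fa_rate=f,
        correction_applied=corrected,
    )


def exclude_low_performers(
    d_primes: Sequence[float], k_sd: float = 1.5, ddof: int = 1
) -> np.ndarray:
    """Flag subjects with d' below ``mean - k_sd * sd`` of the full group.

    The mean and (sample, ddof=1 by default) standard deviation are taken
    over all subjects, candidates included. Returns a boolean exclusion
    mask aligned with the input order.
    """
    d = np.asarray(d_primes, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 subjects for the exclusion rule")
    cutoff = d.mean() - k_sd * d.std(ddof=ddof)
    return d < cutoff


def condition_hit_rates(
    outcomes: Mapping[str, DetectionOutcome],
    conditions: Iterable[str] = ("A", "V", "AV", "R", "G"),
) -> pd.DataFrame:
    """Per-condition hit rate H for condition-specific oddballs."""
    rows = []
    for cond in conditions:
        if cond not in outcomes:
            raise ValueError(f"missing condition {cond!r}")
        o = outcomes[cond]
        rows.append({"condition": cond, "hits": o.hits, "n_signal": o.n_signal,
                     "hit_rate": o.hits / o.n_signal})
    return pd.DataFrame(rows)
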