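"""First-level design construction and Least-Squares-Separate (LS-S) estimation.

Block-design BOLD runs are modeled with HRF-convolved boxcar regressors.
Per-block activation is estimated with LS-S: one ordinary-least-squares fit
per block, whose design contains a single regressor of interest for that
block, one nuisance regressor for the remaining blocks of the same
condition, one nuisance regressor per other condition, and run-level
baseline plus polynomial drift. Volumes flagged by motion / outlier
censoring are dropped from every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "HRFParams",
    "BlockEvent",
    "TimeSeries",
    "CensorMask",
    "DesignError",
    "RankDeficientError",
    "double_gamma_hrf",
    "hrf_regressor",
    "censor_timepoints",
    "build_lss_design",
    "lss_estimate",
    "legendre_drift",
]


class DesignError(ValueError):
    """Invalid design: overlapping/duplicate blocks, missing metadata, ..."""


class RankDeficientError(ValueError):
    """LS-S design became rank deficient (e.g., after censoring)."""


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Double-gamma canonical HRF, normalized to unit peak.

    The response is ``g(peak) - ratio * g(undershoot)`` where each ``g`` is a
    gamma density with the given shape/scale (seconds). Defaults peak near
    5 s with an undershoot near 15 s.
    """

    peak_shape: float = 6.0
    peak_scale: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


def double_gamma_hrf(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Evaluate the unit-peak double-gamma HRF at times ``t`` (seconds)."""
    p = params or HRFParams()
    t = np.asarray(t, dtype=float)
    h = (
        _gamma_dist.pdf(t, p.peak_shape, scale=p.peak_scale)
        - p.undershoot_ratio * _gamma_dist.pdf(t, p.undershoot_shape, scale=p.undershoot_scale)
    )
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    if peak <= 0:
        raise ValueError("HRF has non-positive peak; check parameters")
    return h / peak


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockEvent:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class TimeSeries:
    """One run of per-voxel (or per-ROI) BOLD samples with block metadata.

    nuisance holds per-volume censoring metrics: ``enorm`` (Euclidean norm of
    motion derivatives) and ``outlier_frac`` (fraction of in-brain voxels
    flagged as outliers).
    """

    samples: np.ndarray
    tr_s: float
    run_id: int
    block_events: list[BlockEvent]
    nuisance: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array (one series per run)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        run_end = len(self.samples) * self.tr_s
        for ev in self.block_events:
            if ev.onset_s < 0 or ev.onset_s >= run_end:
                raise DesignError(f"block onset {ev.onset_s} s outside run [0, {run_end}) s")

    @property
    def n_volumes(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass
class CensorMask:
    """Per-volume keep flags with reason codes ('' where kept)."""

    keep: np.ndarray
    reasons: list[str]

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.keep) != len(self.reasons):
            raise ValueError("keep and reasons must have equal length")

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------

def censor_timepoints(
    ts: TimeSeries,
    outlier_frac_threshold: float = 0.10,
    enorm_threshold: float = 0.4,
) -> CensorMask:
    """Censor volumes with too many outlier voxels or excess motion.

    A volume is censored iff its outlier-voxel fraction strictly exceeds
    ``outlier_frac_threshold`` or the Euclidean norm of the motion
    derivatives strictly exceeds ``enorm_threshold``.
    """
    if ts.nuisance is None:
        raise ValueError("time series carries no nuisance metrics; cannot censor")
    for col in ("outlier_frac", "enorm"):
        if col not in ts.nuisance.columns:
            raise ValueError(f"nuisance metrics missing column {col!r}")
    if len(ts.nuisance) != ts.n_volumes:
        raise ValueError("nuisance metrics length does not match volume count")

    out = ts.nuisance["outlier_frac"].to_numpy() > outlier_frac_threshold
    mot = ts.nuisance["enorm"].to_numpy() > enorm_threshold
    keep = ~(out | mot)
    reasons = []
    for o, m in zip(out, mot):
        r = []
        if o:
            r.append("outlier_frac")
        if m:
            r.append("enorm")
        reasons.append("+".join(r))
    return CensorMask(keep=keep, reasons=reasons)


# ---------------------------------------------------------------------------
# Regressors
# ---------------------------------------------------------------------------

_FINE_DT = 0.1  # fine-grid convolution step, seconds


def hrf_regressor(
    events: Sequence[BlockEvent],
    n_volumes: int,
    tr_s: float,
    hrf: HRFParams | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar for a set of blocks, sampled at the TR grid.

    Convolution runs on a 0.1-s grid to control discretization error, then
    is sampled at volume acquisition times k*TR.
    """
    p = hrf or HRFParams()
    run_len = n_volumes * tr_s
    n_fine = int(np.ceil(run_len / _FINE_DT)) + 1
    box = np.zeros(n_fine)
    t_fine = np.arange(n_fine) * _FINE_DT
    for ev in events:
        box[(t_fine >= ev.onset_s) & (t_fine < ev.onset_s + ev.duration_s)] = 1.0
    kernel = double_gamma_hrf(np.arange(0, p.duration_s + _FINE_DT, _FINE_DT), p)
    conv = np.convolve(box, kernel)[:n_fine] * _FINE_DT
    # rescale so an isolated block of this duration has unit peak response
    if events:
        dur = events[0].duration_s
        ref_box = np.zeros(n_fine)
        ref_box[t_fine < dur] = 1.0
        ref_peak = (np.convolve(ref_box, kernel)[:n_fine] * _FINE_DT).max()
        if ref_peak > 0:
            conv = conv / ref_peak
    sample_idx = np.round(np.arange(n_volumes) * tr_s / _FINE_DT).astype(int)
    return conv[sample_idx]


def legendre_drift(n_volumes: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns of order 1..order on [-1, 1]."""
    if order < 1:
        return np.empty((n_volumes, 0))
    x = np.linspace(-1.0, 1.0, n_volumes)
    cols = [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, order + 1)]
    return np.column_stack(cols)


def _check_events(events: Sequence[BlockEvent]) -> None:
    seen = set()
    for ev in events:
        key = (ev.condition, ev.onset_s)
        if key in seen:
            raise DesignError(f"duplicate block: condition={ev.condition} onset={ev.onset_s}")
        seen.add(key)
    ordered = sorted(events, key=lambda e: e.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset_s < a.onset_s + a.duration_s:
            raise DesignError(
                f"overlapping blocks at onsets {a.onset_s} and {b.onset_s} s"
            )


def build_lss_design(
    ts: TimeSeries,
    target: int,
    hrf: HRFParams | None = None,
    drift_order: int = 2,
    confounds: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """LS-S design matrix for one target block.

    Columns: ``target`` (the block of interest), ``nuis:<cond>`` for the
    remaining blocks of the target's condition and for every other
    condition, ``baseline``, ``drift1..driftK``, and optional user-supplied
    confound columns.
    """
    events = ts.block_events
    if not 0 <= target < len(events):
        raise DesignError(f"target block {target} does not exist (have {len(events)})")
    _check_events(events)

    cols: dict[str, np.ndarray] = {}
    tgt = events[target]
    cols["target"] = hrf_regressor([tgt], ts.n_volumes, ts.tr_s, hrf)
    if not np.any(cols["target"] != 0):
        raise DesignError(f"target block {target} produces an all-zero regressor")

    same = [e for i, e in enumerate(events) if i != target and e.condition == tgt.condition]
    if same:
        cols[f"nuis:{tgt.condition}"] = hrf_regressor(same, ts.n_volumes, ts.tr_s, hrf)
    for cond in dict.fromkeys(e.condition for e in events):  # stable order
        if cond == tgt.condition:
            continue
        others = [e for e in events if e.condition == cond]
        cols[f"nuis:{cond}"] = hrf_regressor(others, ts.n_volumes, ts.tr_s, hrf)

    cols["baseline"] = np.ones(ts.n_volumes)
    drift = legendre_drift(ts.n_volumes, drift_order)
    for k in range(drift.shape[1]):
        cols[f"drift{k + 1}"] = drift[:, k]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != ts.n_volumes:
            confounds = confounds.T
        if confounds.shape[0] != ts.n_volumes:
            raise ValueError("confounds rows must match volume count")
        for k in range(confounds.shape[1]):
            cols[f"confound{k + 1}"] = confounds[:, k]
    return pd.DataFrame(cols)


def lss_estimate(
    ts: TimeSeries,
    hrf: HRFParams | None = None,
    drift_order: int = 2,
    censor: Optional[CensorMask] = None,
    confounds: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-block LS-S activation estimates for one run.

    Fits one OLS model per block (censored volumes dropped) and records the
    target-column coefficient. Returns a table with one row per block:
    run_id, block_index, condition, onset_s, duration_s, beta.
    """
    if not ts.block_events:
        raise DesignError("time series has no block events")
    keep = np.ones(ts.n_volumes, dtype=bool) if censor is None else censor.keep
    if len(keep) != ts.n_volumes:
        raise ValueError("censor mask length does not match volume count")

    rows = []
    y = ts.samples[keep]
    for i, ev in enumerate(ts.block_events):
        design = build_lss_design(ts, i, hrf=hrf, drift_order=drift_order, confounds=confounds)
        X = design.to_numpy()[keep]
        if not np.any(X[:, 0] != 0):
            raise RankDeficientError(
                f"block {i} ({ev.condition} @ {ev.onset_s}s): target regressor fully censored"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficientError(
                f"block {i} ({ev.condition} @ {ev.onset_s}s): design rank deficient after censoring"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rows.append(
            {
                "run_id": ts.run_id,
                "block_index": i,
                "condition": ev.condition,
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "beta": beta[0],
            }
        )
    return pd.DataFrame(rows)
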