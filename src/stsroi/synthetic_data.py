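"""Synthetic inputs for every stage of the pipeline.

Emulates the study's block design: five conditions (A, V, AV, R, G) shown in
12-s blocks, three blocks per condition in each of ten runs, TR 2.5 s.
Generates (a) block-level percent-signal-change tables following the additive
auditory/visual/speech (AP/VP/SP) model with per-subject random effects,
(b) HRF-convolved BOLD time series with drift and nuisance metrics,
(c) blocks-by-voxels pattern matrices for MVPA, (d) grayscale frame stacks
with known object motion, and (e) binomial oddball detection outcomes.
All generators are reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import DetectionOutcome
from .block_estimation import BlockEvent, HRFParams, TimeSeries, hrf_regressor

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "ObjectSpec",
    "CorrelationMatrixError",
    "gen_block_psc",
    "gen_bold_timeseries",
    "gen_pattern_dataset",
    "gen_frames",
    "gen_oddball_outcomes",
    "write_block_table",
    "read_block_table",
    "CONDITIONS",
]

CONDITIONS = ("A", "V", "AV", "R", "G")

# AP/VP/SP stimulus-content coding of the five conditions (auditory present,
# visual-motion present, speech present).
_CODING = {
    "A": (1, 0, 1),
    "V": (0, 1, 1),
    "AV": (1, 1, 1),
    "R": (1, 0, 0),
    "G": (0, 1, 0),
}


class CorrelationMatrixError(ValueError):
    """Random-effect correlation matrix is not symmetric positive semi-definite."""


@dataclass(frozen=True)
class DesignSpec:
    """Block-design layout of the experiment."""

    n_subjects: int = 18
    n_runs: int = 10
    blocks_per_condition_per_run: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    block_duration_s: float = 12.0
    inter_block_interval_s: float = 0.5
    tr_s: float = 2.5
    volumes_per_run: int = 109
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "blocks_per_condition_per_run", "volumes_per_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        n_blocks = len(self.conditions) * self.blocks_per_condition_per_run
        needed = n_blocks * (self.block_duration_s + self.inter_block_interval_s)
        run_len = self.volumes_per_run * self.tr_s
        if needed > run_len:
            raise ValueError(
                f"{n_blocks} blocks need {needed:.1f} s but the run is {run_len:.1f} s"
            )

    @property
    def blocks_per_condition(self) -> int:
        return self.n_runs * self.blocks_per_condition_per_run


@dataclass(frozen=True)
class EffectSpec:
    """Additive fixed effects (PSC units) plus per-subject random structure.

    random_effect_sd holds standard deviations for (intercept, AP, VP, SP)
    random terms; random_effect_corr is their 4x4 correlation matrix.
    """

    intercept: float = 0.0
    beta_AP: float = 0.0
    beta_VP: float = 0.0
    beta_SP: float = 0.0
    random_effect_sd: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    random_effect_corr: Optional[np.ndarray] = None
    noise_sd: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.random_effect_sd):
            raise ValueError("random-effect sds must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")

    def covariance(self) -> np.ndarray:
        sd = np.asarray(self.random_effect_sd, dtype=float)
        corr = self.random_effect_corr
        if corr is None:
            corr = np.eye(4)
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (4, 4):
            raise CorrelationMatrixError("correlation matrix must be 4x4")
        if not np.allclose(corr, corr.T):
            raise CorrelationMatrixError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0) or np.abs(corr).max() > 1 + 1e-12:
            raise CorrelationMatrixError(
                "correlation matrix needs a unit diagonal and entries in [-1, 1]"
            )
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise CorrelationMatrixError("correlation matrix must be positive semi-definite")
        return corr * np.outer(sd, sd)


# ---------------------------------------------------------------------------
# (a) block-level percent signal change
# ---------------------------------------------------------------------------

def gen_block_psc(
    design: DesignSpec,
    effects: Sequence[EffectSpec] | EffectSpec,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long-format block table following the additive AP/VP/SP model.

    psc = intercept + AP*(beta_AP + b_AP,s) + VP*(beta_VP + b_VP,s)
          + SP*(beta_SP + b_SP,s) + b0,s + noise (+ occasional outlier shift),
    with AP/VP/SP the 0/1 stimulus-content coding of the condition and the
    b terms per-subject Gaussian random effects (drawn independently per
    subregion). One row per subject x run x condition x block x subregion.
    """
    if isinstance(effects, EffectSpec):
        effects = [effects]
    for cond in design.conditions:
        if cond not in _CODING:
            raise ValueError(f"no AP/VP/SP coding for condition {cond!r}")
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    frames = []
    for sub_id, eff in enumerate(effects, start=1):
        cov = eff.covariance()  # validates the correlation matrix
        # eigen-based factor keeps zero-variance terms exactly zero
        w, V = np.linalg.eigh(cov)
        factor = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        b = rng.standard_normal((design.n_subjects, 4)) @ factor.T

        rows_per_subject = (
            design.n_runs * len(design.conditions) * design.blocks_per_condition_per_run
        )
        subj = np.repeat(np.arange(1, design.n_subjects + 1), rows_per_subject)
        run = np.tile(
            np.repeat(
                np.arange(1, design.n_runs + 1),
                len(design.conditions) * design.blocks_per_condition_per_run,
            ),
            design.n_subjects,
        )
        cond = np.tile(
            np.repeat(list(design.conditions), design.blocks_per_condition_per_run),
            design.n_subjects * design.n_runs,
        )
        block = np.tile(
            np.arange(1, design.blocks_per_condition_per_run + 1),
            design.n_subjects * design.n_runs * len(design.conditions),
        )
        code = np.array([_CODING[c] for c in cond], dtype=float)
        ap, vp, sp = code[:, 0], code[:, 1], code[:, 2]
        bs = b[subj - 1]
        psc = (
            eff.intercept
            + bs[:, 0]
            + ap * (eff.beta_AP + bs[:, 1])
            + vp * (eff.beta_VP + bs[:, 2])
            + sp * (eff.beta_SP + bs[:, 3])
        )
        if eff.noise_sd > 0:
            psc = psc + rng.normal(0.0, eff.noise_sd, size=psc.shape)
        if eff.outlier_rate > 0:
            hit = rng.random(psc.shape) < eff.outlier_rate
            sign = rng.choice([-1.0, 1.0], size=psc.shape)
            psc = psc + hit * sign * eff.outlier_magnitude
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subj,
                    "run_id": run,
                    "condition": cond,
                    "block_index": block,
                    "subregion_id": sub_id,
                    "psc": psc,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_block_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_block_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# (b) voxel-level BOLD time series
# ---------------------------------------------------------------------------

def _run_schedule(
    design: DesignSpec, rng: np.random.Generator, randomize_order: bool
) -> list[BlockEvent]:
    conds = [
        c for c in design.conditions for _ in range(design.blocks_per_condition_per_run)
    ]
    order = rng.permutation(len(conds)) if randomize_order else np.arange(len(conds))
    events = []
    step = design.block_duration_s + design.inter_block_interval_s
    for slot, idx in enumerate(order):
        events.append(
            BlockEvent(
                condition=conds[idx],
                onset_s=slot * step,
                duration_s=design.block_duration_s,
            )
        )
    return events


def gen_bold_timeseries(
    design: DesignSpec,
    block_amplitudes: Mapping[str, float] | Sequence[float],
    drift_coefs: Sequence[float] = (),
    noise_sd: float = 0.0,
    hrf: HRFParams | None = None,
    rng: Optional[np.random.Generator] = None,
    randomize_order: bool = True,
    nuisance_enorm_sd: float = 0.05,
    nuisance_outlier_frac_mean: float = 0.02,
) -> list[TimeSeries]:
    """Simulate one BOLD series per run under the block design.

    Each run is sum(block amplitude x HRF-convolved boxcar) + polynomial
    drift + white noise, sampled at the TR. ``block_amplitudes`` is either a
    mapping condition -> amplitude or a flat sequence covering every block of
    every run in schedule order. Synthetic per-volume nuisance metrics
    (motion-derivative Euclidean norm, outlier-voxel fraction) are attached.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    n_blocks_per_run = len(design.conditions) * design.blocks_per_condition_per_run
    flat: Optional[np.ndarray] = None
    if not isinstance(block_amplitudes, Mapping):
        flat = np.asarray(list(block_amplitudes), dtype=float)
        if flat.size != n_blocks_per_run * design.n_runs:
            raise ValueError(
                f"need {n_blocks_per_run * design.n_runs} block amplitudes, got {flat.size}"
            )

    runs = []
    for r in range(1, design.n_runs + 1):
        events = _run_schedule(design, rng, randomize_order)
        if flat is None:
            amps = np.array([block_amplitudes[e.condition] for e in events])  # type: ignore[index]
        else:
            amps = flat[(r - 1) * n_blocks_per_run : r * n_blocks_per_run]
        y = np.zeros(design.volumes_per_run)
        for ev, a in zip(events, amps):
            if a != 0:
                y = y + a * hrf_regressor([ev], design.volumes_per_run, design.tr_s, hrf)
        if drift_coefs:
            x = np.linspace(-1.0, 1.0, design.volumes_per_run)
            for k, c in enumerate(drift_coefs):
                y = y + c * x**k
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        nuis = pd.DataFrame(
            {
                "enorm": np.abs(rng.normal(0.0, nuisance_enorm_sd, design.volumes_per_run)),
                "outlier_frac": np.clip(
                    rng.exponential(nuisance_outlier_frac_mean, design.volumes_per_run), 0, 1
                ),
            }
        )
        runs.append(
            TimeSeries(samples=y, tr_s=design.tr_s, run_id=r, block_events=events, nuisance=nuis)
        )
    return runs


# ---------------------------------------------------------------------------
# (c) blocks x voxels pattern matrices
# ---------------------------------------------------------------------------

@dataclass
class PatternData:
    """Blocks x voxels activation patterns with run/condition labels."""

    X: np.ndarray
    runs: np.ndarray
    conditions: np.ndarray
    subject_id: int = 1


def gen_pattern_dataset(
    n_voxels: int,
    class_means: Mapping[str, np.ndarray],
    noise_sd: float,
    design: DesignSpec,
    rng: Optional[np.random.Generator] = None,
    subject_id: int = 1,
) -> PatternData:
    """Per-block pattern = condition mean + isotropic Gaussian noise."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    for cond, mu in class_means.items():
        if len(np.atleast_1d(mu)) != n_voxels:
            raise ValueError(f"class mean for {cond!r} has wrong length")
    conds = list(class_means)
    rows, runs, labels = [], [], []
    for r in range(1, design.n_runs + 1):
        for cond in conds:
            mu = np.asarray(class_means[cond], dtype=float)
            for _ in range(design.blocks_per_condition_per_run):
                rows.append(mu + rng.normal(0.0, noise_sd, size=n_voxels))
                runs.append(r)
                labels.append(cond)
    return PatternData(
        X=np.asarray(rows),
        runs=np.asarray(runs),
        conditions=np.asarray(labels),
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# (d) grayscale frame stacks with known motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectSpec:
    """Moving object rendered into a frame stack.

    shape: ``"gaussian"`` (smooth blob), ``"rect"``, or ``"texture"`` (a
    full-field smooth periodic texture shifted with wrap-around; useful for
    optical-flow ground truth). size is the blob sigma / rectangle half-width
    in pixels; ignored for texture. displacement is (dx, dy) pixels per frame
    or a per-frame sequence of such pairs.
    """

    shape: str = "gaussian"
    intensity: float = 1.0
    size: float = 5.0
    start_xy: tuple[float, float] = (0.0, 0.0)
    displacement: tuple[float, float] | Sequence[tuple[float, float]] = (1.0, 0.0)


def _displacements(spec: ObjectSpec, n_frames: int) -> np.ndarray:
    d = np.asarray(spec.displacement, dtype=float)
    if d.ndim == 1:
        d = np.tile(d, (n_frames - 1, 1))
    if d.shape != (n_frames - 1, 2):
        raise ValueError("displacement must be (dx, dy) or a list of n_frames-1 pairs")
    return d


def gen_frames(
    width: int,
    height: int,
    n_frames: int,
    object_spec: ObjectSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an (n_frames, height, width) grayscale stack plus ground truth.

    Returns (stack, displacements) where displacements[i] is the (dx, dy)
    motion between frames i and i+1.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    disp = _displacements(object_spec, n_frames) if n_frames > 1 else np.zeros((0, 2))
    cum = np.vstack([np.zeros((1, 2)), np.cumsum(disp, axis=0)]) if n_frames > 1 else np.zeros((1, 2))
    positions = np.asarray(object_spec.start_xy, dtype=float) + cum

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    stack = np.zeros((n_frames, height, width))

    if object_spec.shape == "texture":
        rng = np.random.default_rng(seed)
        phase_x = rng.uniform(0, 2 * np.pi, 3)
        phase_y = rng.uniform(0, 2 * np.pi, 3)
        freqs = (1, 2, 3)
        for i, (cx, cy) in enumerate(positions):
            img = np.zeros((height, width))
            for f, px, py in zip(freqs, phase_x, phase_y):
                img += np.sin(2 * np.pi * f * (xx - cx) / width + px)
                img += np.sin(2 * np.pi * f * (yy - cy) / height + py)
            stack[i] = object_spec.intensity * (img - img.min()) / (img.max() - img.min())
        return stack, disp

    for i, (cx, cy) in enumerate(positions):
        margin = object_spec.size
        if not (margin <= cx <= width - 1 - margin and margin <= cy <= height - 1 - margin):
            raise ValueError(
                f"object at ({cx:.1f}, {cy:.1f}) leaves the {width}x{height} frame at step {i}"
            )
        if object_spec.shape == "gaussian":
            stack[i] = object_spec.intensity * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * object_spec.size**2)
            )
        elif object_spec.shape == "rect":
            stack[i] = object_spec.intensity * (
                (np.abs(xx - cx) <= object_spec.size) & (np.abs(yy - cy) <= object_spec.size)
            )
        else:
            raise ValueError(f"unknown object shape {object_spec.shape!r}")
    return stack, disp


# ---------------------------------------------------------------------------
# (e) oddball detection outcomes
# ---------------------------------------------------------------------------

def gen_oddball_outcomes(
    p_hit: float,
    p_fa: float,
    n_oddball: int = 30,
    n_standard: int = 150,
    seed: int = 0,
) -> DetectionOutcome:
    """Binomial hits over oddball blocks and false alarms over standards."""
    if not (0 <= p_hit <= 1 and 0 <= p_fa <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return DetectionOutcome(
        hits=int(rng.binomial(n_oddball, p_hit)),
        n_signal=n_oddball,
        false_alarms=int(rng.binomial(n_standard, p_fa)),
        n_noise=n_standard,
    )
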