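"""Motion energy of dynamic visual stimuli via Horn-Schunck optical flow.

For each consecutive frame pair, horizontal (u) and vertical (v) velocity
fields are estimated by the Horn-Schunck algorithm (brightness constancy
plus a global smoothness penalty, solved by Jacobi iteration). A clip's
total motion energy is the root-mean-square flow velocity pooled over both
flow components, all pixels, and all frame pairs; condition-level energy is
the sum over the condition's clips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve as _ndconvolve

__all__ = [
    "FlowField",
    "MotionEnergySummary",
    "horn_schunck",
    "clip_flows",
    "flow_energy",
    "clip_motion_energy",
    "condition_motion_energy",
]

# Jacobi neighbourhood-average kernel from the original Horn-Schunck scheme.
_AVG_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12],
     [1 / 6, 0.0, 1 / 6],
     [1 / 12, 1 / 6, 1 / 12]]
)

_LUMA = np.array([0.2126, 0.7152, 0.0722])  # Rec. 709 luminance weights


@dataclass
class FlowField:
    """Per-pixel velocities (pixels/frame) for one consecutive frame pair."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow fields must be finite")


@dataclass
class MotionEnergySummary:
    per_clip_energy: list[float]
    condition_energy: float
    clip_ids: list


def _to_intensity(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to double-precision grayscale intensities in [0, 1]."""
    f = np.asarray(frame)
    if f.ndim == 3 and f.shape[-1] == 3:  # RGB -> luminance
        f = f @ _LUMA
    elif f.ndim != 2:
        raise ValueError("frames must be 2-D grayscale or (H, W, 3) RGB")
    if not np.all(np.isfinite(np.asarray(f, dtype=float))):
        raise ValueError("frame intensities must be finite")
    if np.issubdtype(np.asarray(frame).dtype, np.integer):
        return f.astype(float) / np.iinfo(np.asarray(frame).dtype).max
    return f.astype(float)


def _avg(x: np.ndarray) -> np.ndarray:
    return _ndconvolve(x, _AVG_KERNEL, mode="nearest")


def horn_schunck(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    smoothness_weight: float = 1.0,
    n_iterations: int = 100,
    tol: float = 1e-6,
) -> FlowField:
    """Estimate optical flow between two frames.

    Iterates the classic update u = ubar - Ex*(Ex*ubar + Ey*vbar + Et)/
    (alpha^2 + Ex^2 + Ey^2) (and likewise for v), where the derivative
    estimates use the original 2x2x2 stencils with replicate padding and the
    bars denote the Jacobi neighbourhood average. Stops early when the mean
    update magnitude falls below ``tol``. Deterministic for fixed parameters.
    """
    a = _to_intensity(frame_a)
    b = _to_intensity(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")

    def shift(x, dy, dx):
        # replicate-padded shift
        pad = np.pad(x, 1, mode="edge")
        return pad[1 + dy : 1 + dy + x.shape[0], 1 + dx : 1 + dx + x.shape[1]]

    # Horn-Schunck derivative stencils (averages over the 2x2x2 cube).
    ex = 0.25 * (
        (shift(a, 0, 1) - a) + (shift(a, 1, 1) - shift(a, 1, 0))
        + (shift(b, 0, 1) - b) + (shift(b, 1, 1) - shift(b, 1, 0))
    )
    ey = 0.25 * (
        (shift(a, 1, 0) - a) + (shift(a, 1, 1) - shift(a, 0, 1))
        + (shift(b, 1, 0) - b) + (shift(b, 1, 1) - shift(b, 0, 1))
    )
    et = 0.25 * (
        (b - a) + (shift(b, 1, 0) - shift(a, 1, 0))
        + (shift(b, 0, 1) - shift(a, 0, 1)) + (shift(b, 1, 1) - shift(a, 1, 1))
    )

    alpha2 = float(smoothness_weight) ** 2
    denom = alpha2 + ex**2 + ey**2
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    for _ in range(n_iterations):
        ubar, vbar = _avg(u), _avg(v)
        t = (ex * ubar + ey * vbar + et) / denom
        u_new = ubar - ex * t
        v_new = vbar - ey * t
        delta = np.mean(np.abs(u_new - u) + np.abs(v_new - v))
        u, v = u_new, v_new
        if delta < tol:
            break
    return FlowField(u=u, v=v)


def clip_flows(
    frames: np.ndarray | Sequence[np.ndarray],
    smoothness_weight: float = 1.0,
    n_iterations: int = 100,
    tol: float = 1e-6,
) -> list[FlowField]:
    """Flow fields for every consecutive frame pair of a clip."""
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("a clip needs at least two frames")
    return [
        horn_schunck(frames[i], frames[i + 1], smoothness_weight, n_iterations, tol)
        for i in range(len(frames) - 1)
    ]


def flow_energy(flows: Sequence[FlowField], method: str = "components") -> float:
    """RMS velocity pooled over all flow fields of a clip.

    method ``"components"`` (default) pools the u and v values into one set
    before the RMS, so a field with |u| = |v| = c has energy c;
    ``"magnitude"`` takes the RMS of the per-pixel speed sqrt(u^2 + v^2).
    """
    if not flows:
        raise ValueError("no flow fields given")
    sq_u = np.concatenate([f.u.ravel() ** 2 for f in flows])
    sq_v = np.concatenate([f.v.ravel() ** 2 for f in flows])
    if method == "components":
        return float(np.sqrt(np.concatenate([sq_u, sq_v]).mean()))
    if method == "magnitude":
        return float(np.sqrt((sq_u + sq_v).mean()))
    raise ValueError(f"unknown method {method!r}")


def clip_motion_energy(
    frames: np.ndarray | Sequence[np.ndarray],
    smoothness_weight: float = 1.0,
    n_iterations: int = 100,
    tol: float = 1e-6,
    method: str = "components",
) -> float:
    """Total motion energy of one clip (RMS flow velocity, pixels/frame)."""
    return flow_energy(
        clip_flows(frames, smoothness_weight, n_iterations, tol), method=method
    )


def condition_motion_energy(
    clips: Sequence[np.ndarray],
    clip_ids: Sequence | None = None,
    **flow_params,
) -> MotionEnergySummary:
    """Per-clip energies and their sum for one stimulus condition."""
    if len(clips) < 1:
        raise ValueError("need at least one clip")
    ids = list(clip_ids) if clip_ids is not None else list(range(len(clips)))
    energies = [clip_motion_energy(c, **flow_params) for c in clips]
    return MotionEnergySummary(
        per_clip_energy=energies,
        condition_energy=float(np.sum(energies)),
        clip_ids=ids,
    )
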