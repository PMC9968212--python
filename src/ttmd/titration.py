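"""Temperature-ramp scheduling and the titration run loop.

A titration is a chain of constant-temperature simulation windows over an
increasing ramp (default 300→450 K in 10 K steps of 10 ns).  Each window is
produced by a dynamics backend, every frame is scored against the reference
fingerprint, and the run terminates early after the first window whose mean
IFP_CS is exactly zero — the native binding mode was absent for the whole
window.  Windows are chained: the end state of one seeds the next.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .complex_model import ComplexModel, Frame
from .fingerprint import (
    FrameScore,
    InteractionFingerprint,
    InteractionGeometryConfig,
    fingerprint_frame,
    ifp_cs_score,
    window_mean_ifpcs,
)
from .geometry import superpose_kabsch

__all__ = [
    "TemperatureRamp",
    "WindowResult",
    "TitrationRun",
    "DynamicsBackend",
    "build_ramp",
    "compute_reference_fp",
    "check_termination",
    "run_titration",
]

log = logging.getLogger(__name__)

DEFAULT_STRIDE_PS = 100.0  # frame save interval; 100 frames per 10 ns window


@dataclass(frozen=True)
class TemperatureRamp:
    """Ordered temperature windows with per-window durations (ns)."""

    t_start: float
    t_end: float
    increment: float
    window_durations: tuple

    @property
    def window_temperatures(self) -> tuple:
        n = self.n_windows
        return tuple(self.t_start + i * self.increment for i in range(n))

    @property
    def n_windows(self) -> int:
        return int(round((self.t_end - self.t_start) / self.increment)) + 1

    def to_dict(self) -> dict:
        return {
            "t_start": self.t_start,
            "t_end": self.t_end,
            "increment": self.increment,
            "window_durations": list(self.window_durations),
        }


def build_ramp(t_start: float, t_end: float, increment: float, durations) -> TemperatureRamp:
    """Build the temperature ramp; a scalar duration is broadcast to all windows."""
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    if increment <= 0:
        raise ValueError("increment must be positive")
    span = t_end - t_start
    n = int(round(span / increment)) + 1
    if abs((n - 1) * increment - span) > 1e-6:
        raise ValueError("ramp span must be an integer multiple of the increment")
    if np.isscalar(durations):
        durations = [float(durations)] * n
    durations = [float(d) for d in durations]
    if len(durations) != n:
        raise ValueError(f"expected {n} window durations, got {len(durations)}")
    if any(d <= 0 for d in durations):
        raise ValueError("window durations must be positive")
    return TemperatureRamp(float(t_start), float(t_end), float(increment), tuple(durations))


DEFAULT_RAMP = build_ramp(300.0, 450.0, 10.0, 10.0)


@dataclass
class WindowResult:
    """Frames and scores of one TTMD step, plus its termination decision."""

    temperature: float
    frames: list
    frame_scores: list
    mean_ifpcs: float
    terminated_here: bool
    backbone_rmsd_mean: float | None = None


@dataclass
class TitrationRun:
    """One complete titration: reference fingerprint and scored windows."""

    reference_fp: InteractionFingerprint
    windows: list
    ramp: TemperatureRamp
    seed: int
    model: ComplexModel | None = None
    reference_frame: Frame | None = None

    @property
    def last_temperature(self) -> float:
        return self.windows[-1].temperature

    @property
    def completed_full_ramp(self) -> bool:
        return not any(w.terminated_here for w in self.windows)

    def window_means(self) -> list:
        return [w.mean_ifpcs for w in self.windows]

    def iter_frames(self):
        for w in self.windows:
            yield from w.frames

    def manifest(self, cfg: InteractionGeometryConfig | None = None) -> dict:
        cfg = cfg or InteractionGeometryConfig()
        cfg_hash = hashlib.sha256(
            json.dumps({**self.ramp.to_dict(), "geometry": str(cfg)}, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {
            "ramp": self.ramp.to_dict(),
            "seed": self.seed,
            "config_hash": cfg_hash,
            "window_temperatures": [w.temperature for w in self.windows],
            "window_means": self.window_means(),
            "terminated": not self.completed_full_ramp,
            "last_temperature": self.last_temperature,
        }


class DynamicsBackend(Protocol):
    """Contract for per-window dynamics engines (synthetic or file-backed)."""

    def run_window(self, state, temperature: float, duration_ns: float,
                   stride_ps: float, seed: int):  # -> (frames, end_state)
        ...


def compute_reference_fp(
    model: ComplexModel,
    reference_frame: Frame,
    cfg: InteractionGeometryConfig | None = None,
) -> InteractionFingerprint:
    """Fingerprint of the reference (equilibrated native) complex; must be non-zero."""
    fp = fingerprint_frame(model, reference_frame, cfg)
    if not fp.counts.any():
        raise ValueError("pose has no detectable native interactions")
    return fp


def check_termination(window: WindowResult) -> bool:
    """True iff the window mean IFP_CS is exactly zero.

    Exact equality is correct here: integer fingerprints make every frame
    score zero iff it shares no feature with the reference, so the mean is
    zero iff the native binding mode was never sampled in the window.
    """
    if window.frame_scores is None or len(window.frame_scores) == 0:
        raise ValueError("window has not been scored")
    return window.mean_ifpcs == 0.0


def _derive_window_seed(seed: int, window_index: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(window_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _backbone_indices(model: ComplexModel) -> np.ndarray:
    names = {"N", "CA", "C", "O"}
    return np.array(
        [i for i, a in enumerate(model.protein_atoms)
         if a.name.upper() in names and not a.is_metal],
        dtype=int,
    )


def run_titration(
    model: ComplexModel,
    pose_frame: Frame,
    ramp: TemperatureRamp,
    backend: DynamicsBackend,
    cfg: InteractionGeometryConfig | None = None,
    seed: int = 0,
    stride_ps: float = DEFAULT_STRIDE_PS,
    rmsd_warn_threshold: float = 5.0,
) -> TitrationRun:
    """Run the full titration protocol for one pose.

    Iterates windows in ramp order, chaining each window's end state into
    the next, scoring every frame with IFP_CS against the reference
    fingerprint of ``pose_frame``, and stopping after the first window whose
    mean score is zero.  Deterministic given (backend, seed).  Backbone RMSD
    to the reference is monitored per window as a fold-integrity check and
    logged — it never terminates the run.
    """
    cfg = cfg or InteractionGeometryConfig()
    reference_fp = compute_reference_fp(model, pose_frame, cfg)
    bb_idx = _backbone_indices(model)

    windows = []
    state = pose_frame
    for w_i, (temperature, duration) in enumerate(
        zip(ramp.window_temperatures, ramp.window_durations)
    ):
        w_seed = _derive_window_seed(seed, w_i)
        try:
            frames, state = backend.run_window(state, temperature, duration, stride_ps, w_seed)
        except Exception as exc:
            raise RuntimeError(
                f"dynamics backend failed in window {w_i} at {temperature:g} K"
            ) from exc
        if not frames:
            raise RuntimeError(f"backend returned no frames for window {w_i} at {temperature:g} K")

        scores = []
        for frame in frames:
            fp = fingerprint_frame(model, frame, cfg)
            scores.append(
                FrameScore(
                    ifp_cs=ifp_cs_score(reference_fp, fp),
                    frame_index=frame.index,
                    temperature=temperature,
                )
            )
        mean = window_mean_ifpcs(scores)

        bb_rmsd = None
        if len(bb_idx) >= 3:
            ref_bb = pose_frame.coords_protein[bb_idx]
            rmsds = [
                superpose_kabsch(f.coords_protein[bb_idx], ref_bb)[2] for f in frames
            ]
            bb_rmsd = float(np.mean(rmsds))
            if bb_rmsd > rmsd_warn_threshold:
                log.warning(
                    "window %d (%g K): mean backbone RMSD %.2f Å exceeds %.1f Å — "
                    "the ramp may be denaturing the protein fold",
                    w_i, temperature, bb_rmsd, rmsd_warn_threshold,
                )

        window = WindowResult(
            temperature=temperature,
            frames=frames,
            frame_scores=scores,
            mean_ifpcs=mean,
            terminated_here=False,
            backbone_rmsd_mean=bb_rmsd,
        )
        window.terminated_here = check_termination(window)
        windows.append(window)
        log.info(
            "window %d: T=%g K, mean IFP_CS=%.4f, %s",
            w_i, temperature, mean, "TERMINATE" if window.terminated_here else "continue",
        )
        if window.terminated_here:
            break

    return TitrationRun(
        reference_fp=reference_fp,
        windows=windows,
        ramp=ramp,
        seed=seed,
        model=model,
        reference_frame=pose_frame,
    )
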