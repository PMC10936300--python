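"""Stance-phase detection and segmentation from vertical ground reaction force.

Heel-strike and toe-off are located by thresholding the vertical GRF at 5%
of body weight (0.05 * mass * g): heel-strike is the upward crossing,
toe-off the subsequent downward crossing.  Runs shorter than a debounce
length are discarded.  Each detected window then cuts synchronized
image-frame, moment, sEMG and GRF segments into one StanceCycle, and traces
can be resampled onto a percent-stance axis (0% heel-strike, 100% toe-off).

Conventions: 0-based sample indices; stance windows are half-open
[heel_strike, toe_off); all streams share the 1 kHz analog timebase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRAVITY",
    "ForceTrace",
    "GaitEvents",
    "StanceCycle",
    "stance_threshold_newtons",
    "detect_stance",
    "segment_stance_cycles",
    "normalize_stance_percent",
    "resample_to_rate",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class ForceTrace:
    """Vertical GRF in newtons sampled at ``fs`` Hz starting at ``t0`` s."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if v.ndim != 1:
            raise ValueError("GRF trace must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite GRF samples")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class GaitEvents:
    """(heel_strike_index, toe_off_index) pairs, half-open windows."""

    pairs: tuple[tuple[int, int], ...]
    threshold_newtons: float

    def __post_init__(self) -> None:
        prev_end = -1
        for hs, to in self.pairs:
            if not hs < to:
                raise ValueError(f"heel-strike {hs} not before toe-off {to}")
            if hs <= prev_end:
                raise ValueError("stance windows overlap or are out of order")
            prev_end = to

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class StanceCycle:
    """One heel-strike-to-toe-off segment bundling all synchronized streams.

    ``frames`` is (n, H, W) image data (may be empty for signal-only use);
    ``moment`` (n,), ``grf`` (n,), ``semg`` (channels, n); ``frame_indices``
    index into the parent image sequence.
    """

    speed: float
    cycle_id: int
    frame_indices: np.ndarray
    moment: np.ndarray
    grf: np.ndarray
    semg: np.ndarray
    frames: np.ndarray | None = None
    fs: float = 1000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.moment.shape[0]
        if self.grf.shape[0] != n:
            raise ValueError("GRF segment does not cover the stance window")
        if self.semg.size and self.semg.shape[-1] != n:
            raise ValueError("sEMG segment does not cover the stance window")
        if self.frame_indices.shape[0] != n:
            raise ValueError("frame count != moment sample count")
        if self.frames is not None and self.frames.shape[0] != n:
            raise ValueError("image stack does not cover the stance window")

    @property
    def n_samples(self) -> int:
        return int(self.moment.shape[0])


def stance_threshold_newtons(body_mass: float) -> float:
    """5% body-mass threshold expressed as force: 0.05 * mass * g newtons."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    return 0.05 * body_mass * GRAVITY


def detect_stance(
    grf: ForceTrace, body_mass: float, min_stance: float = 0.2
) -> GaitEvents:
    """Threshold the GRF at 5% body weight and pair up the crossings.

    Heel-strike is the first sample of a super-threshold run, toe-off the
    first sample after it drops back below; runs shorter than ``min_stance``
    seconds are treated as chatter and discarded.  A run still above
    threshold at the end of the trace is dropped (incomplete stance).
    """
    thr = stance_threshold_newtons(body_mass)
    above = grf.values > thr
    if not above.any():
        return GaitEvents((), thr)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:  # incomplete trailing stance
        starts = starts[: len(ends)]
    min_samples = int(round(min_stance * grf.fs))
    pairs = tuple(
        (int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_samples
    )
    return GaitEvents(pairs, thr)


def segment_stance_cycles(
    events: GaitEvents,
    moment: np.ndarray,
    grf: ForceTrace,
    semg: np.ndarray,
    frame_times: np.ndarray,
    frames: np.ndarray | None = None,
    speed: float = float("nan"),
) -> list[StanceCycle]:
    """Cut every synchronized stream to the detected stance windows.

    ``frame_times`` are the image timestamps in seconds on the same clock as
    the GRF trace; frames are selected by timestamp membership in the
    half-open window.  All 1 kHz streams are indexed directly.
    """
    moment = np.asarray(moment, dtype=float)
    semg = np.asarray(semg, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    cycles = []
    for k, (hs, to) in enumerate(events.pairs):
        for name, stream_len in (
            ("moment", moment.shape[0]),
            ("grf", grf.values.shape[0]),
            ("semg", semg.shape[-1] if semg.size else to),
        ):
            if stream_len < to:
                raise ValueError(
                    f"stream '{name}' (length {stream_len}) shorter than stance "
                    f"window ending at sample {to}"
                )
        t_hs = grf.t0 + hs / grf.fs
        t_to = grf.t0 + to / grf.fs
        in_window = np.flatnonzero((frame_times >= t_hs) & (frame_times < t_to))
        cycles.append(
            StanceCycle(
                speed=speed,
                cycle_id=k,
                frame_indices=in_window,
                moment=moment[hs:to],
                grf=grf.values[hs:to],
                semg=semg[..., hs:to] if semg.size else semg,
                frames=frames[in_window] if frames is not None else None,
                fs=grf.fs,
            )
        )
    return cycles


def normalize_stance_percent(trace: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Resample a stance-cycle trace onto [0, 100]% by linear interpolation.

    The output has ``n_points`` equally spaced percent values with the
    original endpoints preserved exactly.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("trace must be 1-D with length >= 2")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if trace.size == n_points:
        return trace.copy()
    src = np.linspace(0.0, 100.0, trace.size)
    dst = np.linspace(0.0, 100.0, n_points)
    out = np.interp(dst, src, trace)
    out[0], out[-1] = trace[0], trace[-1]
    return out


def resample_to_rate(
    values: np.ndarray, fs_in: float, fs_out: float
) -> np.ndarray:
    """Linear-interpolation resampling (e.g. 100 Hz kinematics to 1 kHz)."""
    values = np.asarray(values, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    duration = (values.shape[-1] - 1) / fs_in
    t_out = np.arange(0.0, duration + 0.5 / fs_out, 1.0 / fs_out)
    t_in = np.arange(values.shape[-1]) / fs_in
    return np.interp(t_out, t_in, values)
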