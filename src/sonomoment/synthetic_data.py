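"""Seeded synthetic treadmill-walking datasets for end-to-end pipeline tests.

No recordings were deposited with the study this pipeline reproduces, so
this module generates synchronized multi-speed walking data with the
statistical structure the pipeline assumes: five treadmill speeds
(0.50–1.50 m/s), eight stance cycles per speed, trigger-synchronized image
frames and 1 kHz analog channels, a net plantarflexion moment trace that is
zero at heel-strike and toe-off with a single push-off peak that grows with
speed, a double-bumped vertical GRF, electromechanically leading sEMG, and
muscle-image texture whose fascicle-band geometry is a deterministic
monotone function of the instantaneous moment.

All randomness flows from one root seed split into named substreams, so any
modality can be regenerated independently and bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, sosfiltfilt

from .beamforming import TransducerGeometry
from .gait_events import GRAVITY, StanceCycle

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "substream",
    "gen_moment_profile",
    "gen_grf",
    "gen_semg",
    "gen_us_sequence",
    "point_scatterer_rf",
    "gen_walking_dataset",
]

GENERATOR_VERSION = "1.0"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic participant.

    Defaults mirror the emulated protocol: speeds 0.50–1.50 m/s, eight
    stance cycles per speed, 1,000 Hz analog channels trigger-synchronized
    with 1,000 FPS imaging.  The moment peak follows
    ``peak_moment_base + peak_moment_per_speed * speed`` (plantarflexion
    peaks of roughly 80–120 Nm for a 70 kg adult across the speed range),
    perturbed per cycle by ``cycle_noise_sd`` (fractional sd; within-subject
    variability is not reported for the emulated protocol, so it is exposed
    here rather than asserted).
    """

    speeds: tuple[float, ...] = (0.50, 0.75, 1.00, 1.25, 1.50)
    cycles_per_speed: int = 8
    fs_analog: float = 1000.0
    fps_us: float = 1000.0
    body_mass: float = 70.0
    peak_moment_base: float = 60.0
    peak_moment_per_speed: float = 40.0
    cycle_noise_sd: float = 0.03
    semg_lead_ms: float = 50.0
    image_height_px: int = 100
    image_width_px: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.speeds) == 0 or len(set(self.speeds)) != len(self.speeds):
            raise ValueError("speeds must be distinct")
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be strictly positive")
        if self.fs_analog != self.fps_us:
            raise ValueError(
                "fs_analog must equal fps_us (frame trigger is the analog clock)"
            )
        if self.cycles_per_speed < 2:
            raise ValueError("cycles_per_speed must be >= 2")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["speeds"] = list(self.speeds)
        return d


@dataclass
class SyntheticDataset:
    """Per-speed stance cycles plus the raw synchronized traces."""

    cycles: dict[float, list[StanceCycle]]
    traces: dict[float, dict]
    config: SyntheticConfig
    peak_moment: float
    meta: dict = field(default_factory=dict)

    def all_cycles(self) -> list[StanceCycle]:
        return [c for speed in self.config.speeds for c in self.cycles[speed]]

    @property
    def n_cycles(self) -> int:
        return sum(len(v) for v in self.cycles.values())


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Named child RNG: one root seed, independent streams per modality."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# Moment
# ---------------------------------------------------------------------------

_PUSHOFF_FRACTION = 0.75
# sin^2(pi * u^a) peaks where u^a = 1/2, i.e. at u = 0.5^(1/a)
_PUSHOFF_EXPONENT = float(np.log(0.5) / np.log(_PUSHOFF_FRACTION))


def gen_moment_profile(
    speed: float,
    stance_duration: float,
    fs: float,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Net plantarflexion moment over one stance, zero at both ends.

    The trace is ``peak * sin^2(pi * u^a)`` on u in [0, 1] with the
    exponent chosen so the single smooth maximum falls at 75% of stance
    (push-off).  peak = peak_moment_base + peak_moment_per_speed * speed,
    perturbed multiplicatively by a seeded cycle-to-cycle factor when an
    rng is supplied.
    """
    if stance_duration <= 0:
        raise ValueError("stance_duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    cfg = config or SyntheticConfig()
    n = int(round(stance_duration * fs))
    u = np.linspace(0.0, 1.0, n)
    peak = cfg.peak_moment_base + cfg.peak_moment_per_speed * speed
    if rng is not None and cfg.cycle_noise_sd > 0:
        peak *= 1.0 + cfg.cycle_noise_sd * rng.standard_normal()
    trace = peak * np.sin(np.pi * u**_PUSHOFF_EXPONENT) ** 2
    trace[0] = 0.0
    trace[-1] = 0.0
    return trace


# ---------------------------------------------------------------------------
# GRF
# ---------------------------------------------------------------------------


def _grf_shape(u: np.ndarray) -> np.ndarray:
    """Double-peaked unit stance shape: loading and push-off bumps with a
    mid-stance valley; steep shoulders so the 5% body-weight crossing sits
    within ~1 sample of the window edge."""
    s = np.sqrt(np.clip(np.sin(np.pi * u), 0.0, None))
    valley = 1.0 - 0.3 * np.exp(-(((u - 0.5) / 0.15) ** 2))
    return s * valley


def gen_grf(
    stance_schedule: list[tuple[float, float]],
    body_mass: float,
    fs: float,
    rng: np.random.Generator | None = None,
    noise_sd_fraction: float = 0.0,
    tail: float = 0.3,
) -> np.ndarray:
    """Vertical GRF trace: double-bumped force inside each stance window
    (peak 1.1x body weight), identically zero outside.

    ``stance_schedule`` lists non-overlapping (start_s, duration_s)
    windows.  Optional additive noise (fraction of body weight) only
    perturbs within-stance samples so the zero baseline stays exact.
    """
    if body_mass <= 0 or fs <= 0:
        raise ValueError("body_mass and fs must be positive")
    schedule = sorted(stance_schedule)
    for (s0, d0), (s1, _) in zip(schedule, schedule[1:]):
        if s0 + d0 > s1:
            raise ValueError(f"stance windows overlap near t={s1:.3f}s")
    if any(d <= 0 for _, d in schedule):
        raise ValueError("stance durations must be positive")
    bw = body_mass * GRAVITY
    end = max(s + d for s, d in schedule) + tail
    trace = np.zeros(int(np.ceil(end * fs)))
    for start, dur in schedule:
        i0 = int(round(start * fs))
        n = int(round(dur * fs))
        u = np.arange(n) / n
        shape = _grf_shape(u)
        bump = 1.1 * bw * shape / shape.max()
        if rng is not None and noise_sd_fraction > 0:
            interior = shape > 0.05
            bump[interior] += (
                noise_sd_fraction * bw * rng.standard_normal(interior.sum())
            )
        trace[i0 : i0 + n] = np.clip(bump, 0.0, None)
    return trace


# ---------------------------------------------------------------------------
# sEMG
# ---------------------------------------------------------------------------


def gen_semg(
    moment: np.ndarray,
    channels: int = 3,
    lead_ms: float = 50.0,
    fs: float = 1000.0,
    rng: np.random.Generator | None = None,
    amplitude_mv: float = 1.0,
    baseline_fraction: float = 0.05,
) -> np.ndarray:
    """Multi-channel sEMG: band-limited noise amplitude-modulated by the
    moment envelope advanced by the electromechanical lead.

    Muscle electrical activity precedes mechanical output by 30–150 ms, so
    the modulation envelope is the normalized moment shifted ``lead_ms``
    earlier in time.  Each channel is zero-mean noise band-limited to
    20–450 Hz (band top capped below Nyquist for low-rate runs), unit-RMS
    normalized, scaled by a seeded per-channel gain in (0.6, 1.0] and by
    ``baseline + (1 - baseline) * envelope``.
    """
    if not (0.0 <= lead_ms <= 150.0):
        raise ValueError("electromechanical lead must be within [0, 150] ms")
    moment = np.asarray(moment, dtype=float)
    rng = rng or np.random.default_rng(0)
    n = moment.size
    peak = np.max(np.abs(moment))
    m_hat = moment / peak if peak > 0 else np.zeros(n)
    shift = int(round(lead_ms * 1e-3 * fs))
    env = np.zeros(n)
    env[: n - shift if shift else n] = m_hat[shift:]
    high = min(450.0, 0.45 * fs)
    sos = butter(4, [min(20.0, 0.5 * high), high], btype="bandpass", fs=fs, output="sos")
    gains = 0.6 + 0.4 * rng.random(channels)
    out = np.empty((channels, n))
    for c in range(channels):
        noise = rng.standard_normal(n)
        noise = sosfiltfilt(sos, noise)
        noise /= np.sqrt(np.mean(noise**2))
        out[c] = (
            gains[c]
            * amplitude_mv
            * (baseline_fraction + (1 - baseline_fraction) * env)
            * noise
        )
    return out


# ---------------------------------------------------------------------------
# Ultrasound image / RF texture
# ---------------------------------------------------------------------------

# Fascicle-band encoding: inclination, spacing and band contrast are each a
# monotone affine function of the moment normalized by the dataset peak.
_BAND_ANGLE_BASE_DEG = 8.0
_BAND_ANGLE_SPAN_DEG = 14.0
_BAND_SPACING_BASE_PX = 12.0
_BAND_SPACING_SPAN_PX = 4.0
_BAND_WEIGHT_BASE = 0.35
_BAND_WEIGHT_SPAN = 0.25
_SPECKLE_SIGMA = 0.4


def _fascicle_frame(
    m_hat: float, height: int, width: int, speckle: np.ndarray | None
) -> np.ndarray:
    """One frame: speckle background + oriented fascicle grating at the
    geometry encoded by the normalized moment ``m_hat``."""
    theta = np.deg2rad(_BAND_ANGLE_BASE_DEG + _BAND_ANGLE_SPAN_DEG * m_hat)
    spacing = _BAND_SPACING_BASE_PX - _BAND_SPACING_SPAN_PX * m_hat
    weight = _BAND_WEIGHT_BASE + _BAND_WEIGHT_SPAN * m_hat
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    phase = 2 * np.pi * (cols * np.sin(theta) + rows * np.cos(theta)) / spacing
    grating = 0.5 + 0.5 * np.cos(phase)
    background = speckle if speckle is not None else np.full((height, width), 0.5)
    return (1.0 - weight) * background + weight * grating


def _speckle_field(
    height: int, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Exponentiated smoothed Gaussian field, rescaled into [0, 1]."""
    g = gaussian_filter(rng.standard_normal((height, width)), sigma=1.5)
    g /= max(g.std(), 1e-12)
    s = np.exp(_SPECKLE_SIGMA * g)
    return (s - s.min()) / max(s.max() - s.min(), 1e-12)


def point_scatterer_rf(
    scatterers_mm: list[tuple[float, float]],
    geometry: TransducerGeometry | None = None,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Plane-wave RF channel data for ideal point scatterers.

    For a scatterer at (lateral x, depth z) the echo reaches element e at
    t = (z + ||p - e||)/c; each echo is a Gaussian-windowed tone burst at
    the transducer center frequency.  Returns an element_count x n_samples
    matrix sized to cover the two-way imaging depth.
    """
    geo = geometry or TransducerGeometry()
    c = geo.speed_of_sound
    fs = geo.sampling_rate_mhz * 1e6
    f0 = geo.center_frequency_mhz * 1e6
    sigma_t = 1.0 / f0  # ~1-period Gaussian envelope
    xe = geo.element_x_mm * 1e-3
    depth = geo.imaging_depth_mm * 1e-3
    half_ap = geo.aperture_width_mm * 1e-3 / 2
    t_max = (depth + np.hypot(depth, 2 * half_ap)) / c + 8 * sigma_t
    n_t = int(np.ceil(t_max * fs))
    t = np.arange(n_t) / fs
    amps = (
        np.ones(len(scatterers_mm)) if amplitudes is None else np.asarray(amplitudes)
    )
    rf = np.zeros((geo.element_count, n_t))
    for (x_mm, z_mm), a in zip(scatterers_mm, amps):
        x, z = x_mm * 1e-3, z_mm * 1e-3
        tau = (z + np.hypot(x - xe, z)) / c  # (elements,)
        dt = t[None, :] - tau[:, None]
        rf += a * np.exp(-(dt**2) / (2 * sigma_t**2)) * np.cos(2 * np.pi * f0 * dt)
    return rf


def gen_us_sequence(
    moment: np.ndarray,
    height: int = 100,
    width: int = 100,
    peak_norm: float | None = None,
    rng: np.random.Generator | None = None,
    rf_mode: bool = False,
    geometry: TransducerGeometry | None = None,
) -> np.ndarray:
    """One muscle image (or RF frame) per moment sample.

    B-mode mode: multiplicative-style speckle background (one field per
    call, i.e. frozen tissue texture) plus bright oblique fascicle-like
    bands whose inclination, spacing and contrast are deterministic
    monotone functions of moment / peak_norm.  With ``rng`` None the
    background is flat, so equal moments give identical frames.

    RF mode: emits point-scatterer plane-wave channel data instead, with
    the central scatterer's depth shifted in proportion to the normalized
    moment, for beamformer integration tests.
    """
    moment = np.asarray(moment, dtype=float)
    if moment.size == 0:
        raise ValueError("moment trace is empty")
    peak = peak_norm if peak_norm is not None else max(np.max(np.abs(moment)), 1e-12)
    m_hat = np.clip(moment / peak, 0.0, 1.0)
    if rf_mode:
        frames = []
        for m in m_hat:
            scat = [(-5.0, 20.0), (0.0, 20.0 + 5.0 * m), (5.0, 20.0)]
            frames.append(point_scatterer_rf(scat, geometry))
        return np.stack(frames)
    speckle = _speckle_field(height, width, rng) if rng is not None else None
    out = np.empty((moment.size, height, width), dtype=np.float32)
    for i, m in enumerate(m_hat):
        out[i] = _fascicle_frame(float(m), height, width, speckle)
    return out


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def stance_duration_for_speed(speed: float) -> float:
    """Linear stance-time model: 0.80 s at 0.50 m/s down to 0.55 s at 1.50 m/s."""
    return 0.8 - 0.25 * (speed - 0.5)


def gen_walking_dataset(
    config: SyntheticConfig | None = None, with_images: bool = True
) -> SyntheticDataset:
    """Generate the full multi-speed dataset of synchronized stance cycles.

    For each speed, ``cycles_per_speed`` stances are scheduled with swing
    gaps between them; stance duration decreases linearly with speed with a
    small seeded jitter per cycle.  Moment, GRF, sEMG and (optionally)
    image frames are sample-aligned on the shared analog/frame clock, and
    fascicle texture is normalized by the dataset-wide peak moment so the
    image encoding is consistent across speeds.
    """
    cfg = config or SyntheticConfig()
    fs = cfg.fs_analog
    moments: dict[float, list[np.ndarray]] = {}
    schedules: dict[float, list[tuple[float, float]]] = {}
    for speed in cfg.speeds:
        rng_sched = substream(cfg.seed, "schedule", f"{speed:.4f}")
        t = 0.2
        sched, mom = [], []
        for k in range(cfg.cycles_per_speed):
            dur = stance_duration_for_speed(speed)
            if cfg.cycle_noise_sd > 0:
                dur *= 1.0 + 0.02 * rng_sched.standard_normal()
            dur = round(dur * fs) / fs  # snap to the sample grid
            sched.append((t, dur))
            rng_mom = substream(cfg.seed, "moment", f"{speed:.4f}", str(k))
            mom.append(
                gen_moment_profile(
                    speed, dur, fs, cfg, rng_mom if cfg.cycle_noise_sd > 0 else None
                )
            )
            t += dur + 0.35 * dur  # swing gap
        schedules[speed] = sched
        moments[speed] = mom
    peak_moment = max(float(np.max(m)) for ms in moments.values() for m in ms)

    cycles: dict[float, list[StanceCycle]] = {}
    traces: dict[float, dict] = {}
    for speed in cfg.speeds:
        sched = schedules[speed]
        grf = gen_grf(sched, cfg.body_mass, fs)
        n_total = grf.size
        moment_full = np.zeros(n_total)
        for (start, dur), m in zip(sched, moments[speed]):
            i0 = int(round(start * fs))
            moment_full[i0 : i0 + m.size] = m
        rng_emg = substream(cfg.seed, "semg", f"{speed:.4f}")
        semg = gen_semg(
            moment_full, channels=3, lead_ms=cfg.semg_lead_ms, fs=fs, rng=rng_emg
        )
        frame_times = np.arange(n_total) / cfg.fps_us
        traces[speed] = {
            "grf": grf,
            "moment": moment_full,
            "semg": semg,
            "frame_times": frame_times,
        }
        cyc_list = []
        for k, ((start, dur), m) in enumerate(zip(sched, moments[speed])):
            i0 = int(round(start * fs))
            idx = np.arange(i0, i0 + m.size)
            frames = None
            if with_images:
                rng_img = substream(cfg.seed, "us", f"{speed:.4f}", str(k))
                frames = gen_us_sequence(
                    m,
                    cfg.image_height_px,
                    cfg.image_width_px,
                    peak_norm=peak_moment,
                    rng=rng_img if cfg.cycle_noise_sd > 0 else None,
                )
            cyc_list.append(
                StanceCycle(
                    speed=speed,
                    cycle_id=k,
                    frame_indices=idx,
                    moment=m,
                    grf=grf[i0 : i0 + m.size],
                    semg=semg[:, i0 : i0 + m.size],
                    frames=frames,
                    fs=fs,
                )
            )
        cycles[speed] = cyc_list

    return SyntheticDataset(
        cycles=cycles,
        traces=traces,
        config=cfg,
        peak_moment=peak_moment,
        meta={"seed": cfg.seed, "generator_version": GENERATOR_VERSION},
    )
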