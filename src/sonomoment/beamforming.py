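"""Plane-wave delay-and-sum beamforming, B-mode conversion, and ROI cropping.

A single zero-angle plane-wave transmit insonifies the whole field of view,
so one RF acquisition per frame suffices for kHz frame rates.  For a pixel
p at depth z and lateral position x, the echo from p arrives at element e
after the transmit delay z/c plus the receive delay ||p - e||/c; DAS sums
every element's RF sample at that per-pixel time of flight (linear
interpolation between time samples, no apodization, full aperture).

The beamformed field is envelope-detected with the axial analytic signal,
log-compressed to a fixed dynamic range, and normalized to [0, 1].  Image
coordinates: axial depth increases downward from the skin (row 0), lateral
0 mm is the transducer's longitudinal center; the default grid is isotropic
0.1 mm/px, i.e. 500 rows x 380 cols for a 50 mm depth, 38 mm aperture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "TransducerGeometry",
    "RFFrame",
    "PixelGrid",
    "BModeImage",
    "RoiSpec",
    "das_beamform",
    "das_beamform_reference",
    "envelope_logcompress",
    "crop_roi",
    "mm_to_px",
]


@dataclass(frozen=True)
class TransducerGeometry:
    """Linear-array geometry and acquisition constants.

    Defaults follow a 38 mm, 6.4 MHz linear probe imaging to 50 mm depth in
    soft tissue (c = 1540 m/s); RF sampling defaults to 4x the center
    frequency.
    """

    element_count: int = 128
    pitch_mm: float = 38.0 / 128
    aperture_width_mm: float = 38.0
    center_frequency_mhz: float = 6.4
    sampling_rate_mhz: float = 25.6
    speed_of_sound: float = 1540.0  # m/s
    imaging_depth_mm: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "element_count",
            "pitch_mm",
            "aperture_width_mm",
            "center_frequency_mhz",
            "sampling_rate_mhz",
            "speed_of_sound",
            "imaging_depth_mm",
        ):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"geometry field {name} must be positive, got {v!r}")
        if not np.isclose(
            self.aperture_width_mm, self.element_count * self.pitch_mm, rtol=0.05
        ):
            raise ValueError("aperture_width must be ~ element_count * pitch")

    @property
    def element_x_mm(self) -> np.ndarray:
        """Lateral element-center positions, 0 at the array center."""
        return (np.arange(self.element_count) - (self.element_count - 1) / 2) * self.pitch_mm

    def to_dict(self) -> dict:
        return {
            "element_count": self.element_count,
            "pitch_mm": self.pitch_mm,
            "aperture_width_mm": self.aperture_width_mm,
            "center_frequency_mhz": self.center_frequency_mhz,
            "sampling_rate_mhz": self.sampling_rate_mhz,
            "speed_of_sound": self.speed_of_sound,
            "imaging_depth_mm": self.imaging_depth_mm,
        }


@dataclass(frozen=True)
class RFFrame:
    """One plane-wave acquisition: element_count x time-sample RF matrix."""

    samples: np.ndarray
    geometry: TransducerGeometry
    t0: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[0] != self.geometry.element_count:
            raise ValueError(
                f"RF matrix must be {self.geometry.element_count} x n_samples, "
                f"got {s.shape}"
            )
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite RF samples")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class PixelGrid:
    """Reconstruction grid in physical mm coordinates.

    Row r sits at depth r * pitch_axial from the skin; column c sits at
    lateral (c - n_cols // 2) * pitch_lateral from the array center, so
    column n_cols // 2 is exactly lateral 0.
    """

    n_rows: int = 500
    n_cols: int = 380
    pitch_axial_mm: float = 0.1
    pitch_lateral_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have positive size")
        if self.pitch_axial_mm <= 0 or self.pitch_lateral_mm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def depths_mm(self) -> np.ndarray:
        return np.arange(self.n_rows) * self.pitch_axial_mm

    @property
    def laterals_mm(self) -> np.ndarray:
        return (np.arange(self.n_cols) - self.n_cols // 2) * self.pitch_lateral_mm


@dataclass(frozen=True)
class BModeImage:
    """Log-compressed intensity image in [0, 1] on a physical mm grid."""

    pixels: np.ndarray
    grid: PixelGrid
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("B-mode image must be 2-D")
        if p.min() < 0 or p.max() > 1 + 1e-9:
            raise ValueError("B-mode intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class RoiSpec:
    """A crop window: size in pixels, center in physical mm coordinates."""

    size_px: tuple[int, int]
    center_lateral_mm: float = 0.0
    center_depth_mm: float = 20.0

    def __post_init__(self) -> None:
        h, w = self.size_px
        if h < 1 or w < 1:
            raise ValueError("ROI size must be positive")


def mm_to_px(value_mm: float, pitch_mm: float) -> int:
    """Nearest pixel index with half-sample ties broken toward the smaller index."""
    return int(np.ceil(value_mm / pitch_mm - 0.5))


def _delay_samples(
    grid: PixelGrid, geometry: TransducerGeometry
) -> np.ndarray:
    """Per (element, row, col) time-of-flight in RF sample units."""
    z = grid.depths_mm[:, None] * 1e-3  # m, (rows, 1)
    x = grid.laterals_mm[None, :] * 1e-3  # m, (1, cols)
    xe = geometry.element_x_mm * 1e-3  # (elements,)
    c = geometry.speed_of_sound
    fs = geometry.sampling_rate_mhz * 1e6
    tx = z / c  # plane-wave transmit delay, (rows, 1)
    rx = (
        np.sqrt((x[None, :, :] - xe[:, None, None]) ** 2 + z[None, :, :] ** 2) / c
    )  # (elements, rows, cols)
    return (tx[None, :, :] + rx) * fs


def das_beamform(rf: RFFrame, grid: PixelGrid | None = None) -> np.ndarray:
    """Vectorized delay-and-sum of one RF frame onto the pixel grid.

    Sub-sample delays are linearly interpolated; delays falling outside the
    recorded samples contribute zero.  Returns the pre-envelope real matrix
    (rows x cols).
    """
    if grid is None:
        grid = PixelGrid()
    if grid.depths_mm[-1] > rf.geometry.imaging_depth_mm + grid.pitch_axial_mm:
        raise ValueError("grid extends beyond the imaging depth")
    delays = _delay_samples(grid, rf.geometry)  # (elements, rows, cols)
    n_t = rf.samples.shape[1]
    i0 = np.floor(delays).astype(np.int64)
    frac = delays - i0
    valid = (i0 >= 0) & (i0 < n_t - 1)
    i0c = np.clip(i0, 0, n_t - 2)
    out = np.zeros((grid.n_rows, grid.n_cols))
    for e in range(rf.geometry.element_count):
        s = rf.samples[e]
        contrib = s[i0c[e]] * (1 - frac[e]) + s[i0c[e] + 1] * frac[e]
        out += np.where(valid[e], contrib, 0.0)
    return out


def das_beamform_reference(rf: RFFrame, grid: PixelGrid) -> np.ndarray:
    """Brute-force per-pixel delay loop; slow, kept as the plain statement
    of the DAS sum for cross-checking the vectorized path."""
    geometry = rf.geometry
    c = geometry.speed_of_sound
    fs = geometry.sampling_rate_mhz * 1e6
    xe = geometry.element_x_mm * 1e-3
    n_t = rf.samples.shape[1]
    out = np.zeros((grid.n_rows, grid.n_cols))
    for r in range(grid.n_rows):
        z = grid.depths_mm[r] * 1e-3
        for col in range(grid.n_cols):
            x = grid.laterals_mm[col] * 1e-3
            acc = 0.0
            for e in range(geometry.element_count):
                tau = (z + np.hypot(x - xe[e], z)) / c
                s = tau * fs
                k = int(np.floor(s))
                if 0 <= k < n_t - 1:
                    f = s - k
                    acc += rf.samples[e, k] * (1 - f) + rf.samples[e, k + 1] * f
            out[r, col] = acc
    return out


def envelope_logcompress(
    beamformed: np.ndarray,
    grid: PixelGrid | None = None,
    dynamic_range_db: float = 60.0,
    timestamp: float = 0.0,
) -> BModeImage:
    """Axial analytic-signal envelope, then log compression to [0, 1].

    Pixel value = clamp(1 + 20 log10(env / env_max) / DR, 0, 1); an
    all-zero field maps to an all-zero image.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive")
    if grid is None:
        grid = PixelGrid(n_rows=beamformed.shape[0], n_cols=beamformed.shape[1])
    env = np.abs(hilbert(beamformed, axis=0))
    env_max = env.max()
    if env_max == 0:
        return BModeImage(np.zeros_like(env), grid, timestamp)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / env_max)
    pixels = np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0)
    return BModeImage(pixels, grid, timestamp)


def crop_roi(image: BModeImage, roi: RoiSpec) -> np.ndarray:
    """Window the ROI out of a B-mode image (pure crop, no resampling).

    The ROI center in mm is snapped to the nearest pixel (ties toward the
    smaller index); the window of exactly ``size_px`` is placed so its
    center pixel is at index size // 2 within the patch.
    """
    grid = image.grid
    h, w = roi.size_px
    center_row = mm_to_px(roi.center_depth_mm, grid.pitch_axial_mm)
    center_col = grid.n_cols // 2 + mm_to_px(
        roi.center_lateral_mm, grid.pitch_lateral_mm
    )
    r0, c0 = center_row - h // 2, center_col - w // 2
    r1, c1 = r0 + h, c0 + w
    n_rows, n_cols = image.pixels.shape
    if r0 < 0:
        raise IndexError(f"ROI top edge at row {r0} is above the image")
    if c0 < 0:
        raise IndexError(f"ROI left edge at col {c0} is outside the image")
    if r1 > n_rows:
        raise IndexError(
            f"ROI bottom edge at row {r1} exceeds {n_rows} image rows"
        )
    if c1 > n_cols:
        raise IndexError(
            f"ROI right edge at col {c1} exceeds {n_cols} image cols"
        )
    return image.pixels[r0:r1, c0:c1]
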