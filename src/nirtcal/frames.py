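"""Frame sequences, regions of interest, and the temporal-spatial
aggregation protocol.

Frames are 2-D grids of apparent temperature in degrees Celsius under the
emissivity-1.0 convention: the camera reports the blackbody-equivalent
temperature of the *total* detected radiance, so the radiance is recovered
exactly as sigma * (T + 273.15)^4.

Aggregation follows the acquisition protocol of a 20-minute, 1 Hz capture:
within each frame the top and bottom 10% of ROI pixel values are discarded
and the rest averaged (a two-sided trimmed mean), giving one value per
frame; per-condition summaries are plain means over the per-frame series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .radiometry import CELSIUS_ZERO, DEFAULT_CONSTANTS, RadiometricConstants

__all__ = [
    "FrameSequence",
    "rect_mask",
    "trimmed_mean",
    "extract_roi_series",
    "aggregate_condition",
    "apparent_temperature_to_radiance_series",
    "read_thermistor_log",
    "write_thermistor_log",
]

DEFAULT_TRIM_FRACTION = 0.10


def rect_mask(shape: tuple[int, int], rect: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean mask for a half-open rectangle (row0, row1, col0, col1), 0-based."""
    r0, r1, c0, c1 = rect
    rows, cols = shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"rectangle {rect} out of bounds for frame shape {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def pixel_mask(shape: tuple[int, int], pixels) -> np.ndarray:
    """Boolean mask from an explicit list of (row, col) pixels."""
    mask = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"pixel ({r}, {c}) out of bounds for shape {shape}")
        mask[r, c] = True
    return mask


@dataclass
class FrameSequence:
    """Ordered apparent-temperature frames with named ROI masks.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Apparent temperature, degrees Celsius, emissivity-1.0 convention.
    timestamps : ndarray, shape (n_frames,)
        Seconds from condition start, strictly increasing.
    rois : dict of str -> bool ndarray (rows, cols)
        Named pixel masks, e.g. "object" (furnace trace area) and
        "reference" (in-scene blackbody trace area).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        n = self.frames.shape[0]
        if self.timestamps.shape != (n,):
            raise ValueError("timestamps must have one entry per frame")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        shape = self.frames.shape[1:]
        for name, mask in self.rois.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError(f"ROI {name!r} mask shape {mask.shape} != frame shape {shape}")
            if not mask.any():
                raise ValueError(f"ROI {name!r} is empty")
            self.rois[name] = mask

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path) -> None:
        """Write frames as a multi-page 32-bit float TIFF plus a timestamp sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")
        pd.DataFrame({"time_s": self.timestamps}).to_csv(
            path.with_suffix(".timestamps.csv"), index=False
        )

    @classmethod
    def from_tiff(
        cls,
        path,
        rois: dict[str, np.ndarray] | None = None,
        timestamps=None,
        frame_rate_hz: float = 1.0,
    ) -> "FrameSequence":
        path = Path(path)
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if timestamps is None:
            sidecar = path.with_suffix(".timestamps.csv")
            if sidecar.exists():
                timestamps = pd.read_csv(sidecar)["time_s"].to_numpy()
            else:
                timestamps = np.arange(frames.shape[0]) / frame_rate_hz
        return cls(frames=frames, timestamps=np.asarray(timestamps), rois=rois or {})

    def to_csv_dir(self, directory) -> None:
        """Write one CSV matrix per frame (filename-ordered) plus timestamps.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = max(6, len(str(self.n_frames)))
        for i, frame in enumerate(self.frames):
            np.savetxt(directory / f"frame_{i:0{width}d}.csv", frame, delimiter=",", fmt="%.6f")
        pd.DataFrame({"time_s": self.timestamps}).to_csv(
            directory / "timestamps.csv", index=False
        )

    @classmethod
    def from_csv_dir(
        cls,
        directory,
        rois: dict[str, np.ndarray] | None = None,
        frame_rate_hz: float = 1.0,
    ) -> "FrameSequence":
        directory = Path(directory)
        paths = sorted(directory.glob("frame_*.csv"))
        if not paths:
            raise FileNotFoundError(f"no frame_*.csv files in {directory}")
        frames = np.stack([np.loadtxt(p, delimiter=",", ndmin=2) for p in paths])
        ts_path = directory / "timestamps.csv"
        if ts_path.exists():
            timestamps = pd.read_csv(ts_path)["time_s"].to_numpy()
        else:
            timestamps = np.arange(frames.shape[0]) / frame_rate_hz
        return cls(frames=frames, timestamps=timestamps, rois=rois or {})


# ------------------------------------------------------------- aggregation


def trimmed_mean(values, trim_fraction: float = DEFAULT_TRIM_FRACTION) -> float:
    """Two-sided trimmed mean: drop floor(n * trim_fraction) values per tail.

    Matches the image-level protocol of discarding the top and bottom 10%
    of ROI pixel values before averaging.  ``trim_fraction`` is the
    fraction removed from *each* tail and must satisfy 0 <= f < 0.5.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot take the trimmed mean of an empty sequence")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = math.floor(v.size * trim_fraction + 1e-12)
    if 2 * k >= v.size:
        raise ValueError("trimming would remove all values")
    if k == 0:
        return float(v.mean())
    return float(np.sort(v)[k:-k].mean())


def extract_roi_series(
    seq: FrameSequence,
    roi_name: str,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> np.ndarray:
    """Per-frame trimmed-mean apparent temperature of a named ROI.

    One value per frame, frame order preserved; trimming acts spatially
    within each frame.
    """
    if roi_name not in seq.rois:
        raise KeyError(f"unknown ROI {roi_name!r}; have {sorted(seq.rois)}")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    pixels = seq.frames[:, seq.rois[roi_name]]  # (n_frames, n_pixels)
    n_px = pixels.shape[1]
    k = math.floor(n_px * trim_fraction + 1e-12)
    if 2 * k >= n_px:
        raise ValueError("trimming would remove all ROI pixels")
    if k == 0:
        return pixels.mean(axis=1)
    return np.sort(pixels, axis=1)[:, k : n_px - k].mean(axis=1)


def aggregate_condition(series) -> float:
    """Per-condition summary: arithmetic mean over the per-frame series."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("cannot aggregate an empty series")
    return float(s.mean())


def apparent_temperature_to_radiance_series(
    series_c,
    constants: RadiometricConstants = DEFAULT_CONSTANTS,
):
    """Detected radiance from apparent temperature: sigma * (T + 273.15)^4.

    Under the emissivity-1.0 export convention the apparent temperature
    encodes total detected radiance, so this recovers W_det exactly.
    """
    t = np.asarray(series_c, dtype=float) + CELSIUS_ZERO
    if np.any(t <= 0):
        raise ValueError("apparent temperature below absolute zero")
    w = constants.sigma * t**4
    return float(w) if w.ndim == 0 else w


# --------------------------------------------------------- thermistor log


def write_thermistor_log(path, time_s, temperature_c) -> None:
    """CSV time series of the reference blackbody's internal temperature."""
    pd.DataFrame({"time_s": time_s, "temperature_C": temperature_c}).to_csv(
        path, index=False
    )


def read_thermistor_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_s", "temperature_C"} - set(df.columns)
    if missing:
        raise ValueError(f"thermistor log missing columns: {sorted(missing)}")
    return df
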