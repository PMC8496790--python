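"""Movie preprocessing: spatial binning, temporal filtering, drift
correction + normalization, and signal-to-noise masking.

The stage converts a raw voltage-sensitive-dye movie into a filtered,
per-pixel normalized movie with an analysis mask, ready for activation
detection.  All operations are per-frame or per-pixel-trace and preserve
the movie geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "VoltageMovie",
    "PixelMask",
    "load_movie",
    "save_movie",
    "spatial_bin",
    "temporal_filter",
    "drift_correct_normalize",
    "snr_mask",
    "preprocess_movie",
]

#: SNR assigned to pixels whose noise estimate is numerically zero.
SNR_CAP = 1e9


@dataclass
class VoltageMovie:
    """Fluorescence time series with acquisition geometry.

    Parameters
    ----------
    data
        ``(n_frames, rows, cols)`` float array, arbitrary fluorescence units.
    frame_rate_hz
        Acquisition rate in frames per second.
    pixel_size_mm
        Edge length of one pixel on the tissue, in mm.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (frames, rows, cols)")
        if self.data.shape[0] < 3:
            raise ValueError("movie must have at least 3 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.frame_rate_hz

    def times_ms(self) -> np.ndarray:
        """Frame timestamps in ms (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate_hz


@dataclass
class PixelMask:
    """Boolean analysis mask; ``True`` marks pixels that are analyzed."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("empty mask")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def save_movie(movie: VoltageMovie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF (with JSON sidecar) or ``.npz``."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, movie.data.astype(np.float32))
        sidecar = {
            "frame_rate_hz": movie.frame_rate_hz,
            "pixel_size_mm": movie.pixel_size_mm,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(
            path,
            data=movie.data.astype(np.float32),
            frame_rate_hz=movie.frame_rate_hz,
            pixel_size_mm=movie.pixel_size_mm,
        )
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")


def load_movie(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_mm: float | None = None,
) -> VoltageMovie:
    """Read a movie written by :func:`save_movie`.

    Explicit ``frame_rate_hz`` / ``pixel_size_mm`` override any metadata
    stored alongside the pixels.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        try:
            data = tifffile.imread(path)
        except Exception as exc:  # corrupt / unreadable stack
            raise OSError(f"TIFF reader failed on {path}: {exc}") from exc
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    elif path.suffix.lower() == ".npz":
        with np.load(path) as npz:
            data = npz["data"]
            meta = {
                "frame_rate_hz": float(npz["frame_rate_hz"]),
                "pixel_size_mm": float(npz["pixel_size_mm"]),
            }
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")
    fr = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    px = pixel_size_mm if pixel_size_mm is not None else meta.get("pixel_size_mm")
    if fr is None or px is None:
        raise ValueError("frame rate / pixel size not in metadata; pass explicitly")
    return VoltageMovie(np.asarray(data, dtype=float), float(fr), float(px))


def _gaussian_kernel(kernel_size: int) -> np.ndarray:
    """Normalized 2-D Gaussian, sigma = kernel_size / 4, truncated to
    kernel_size x kernel_size."""
    sigma = kernel_size / 4.0
    half = kernel_size // 2
    x = np.arange(-half, half + 1)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g1, g1)
    return k / k.sum()


def spatial_bin(movie: VoltageMovie, kernel_size: int = 3) -> VoltageMovie:
    """Gaussian spatial binning of every frame.

    Each frame is convolved with a normalized Gaussian kernel of the given
    size (3 or 5); borders are handled by edge replication, so a spatially
    constant frame passes through unchanged.
    """
    if kernel_size not in (3, 5):
        raise ValueError("kernel_size must be 3 or 5")
    kernel = _gaussian_kernel(kernel_size)
    out = ndimage.convolve(movie.data, kernel[np.newaxis, :, :], mode="nearest")
    return replace(movie, data=out)


def temporal_filter(
    movie: VoltageMovie,
    low_hz: float = 0.0,
    high_hz: float = 100.0,
    order: int = 4,
) -> VoltageMovie:
    """Zero-phase Butterworth band-pass of every pixel trace.

    A low edge of 0 Hz reduces the filter to a low-pass at ``high_hz`` (DC
    gain 1); forward-backward application (``sosfiltfilt``) keeps upstrokes
    at their original times.
    """
    nyq = movie.frame_rate_hz / 2.0
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz must be below Nyquist ({nyq:g} Hz)")
    if low_hz == 0:
        sos = signal.butter(order, high_hz, btype="low", fs=movie.frame_rate_hz, output="sos")
    else:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="band", fs=movie.frame_rate_hz, output="sos"
        )
    out = signal.sosfiltfilt(sos, movie.data, axis=0)
    return replace(movie, data=out)


def _baseline_fit(data2d: np.ndarray, t: np.ndarray, order: int, window_frames: int) -> np.ndarray:
    """Per-pixel polynomial baseline robust to action potentials.

    A grayscale opening (running minimum then maximum) with a window wider
    than one action potential erases the upstroke/plateau humps and leaves
    the slow baseline; the polynomial is then an ordinary least-squares fit
    to that opened trace.  Columns of ``data2d`` are pixel traces.
    """
    w = int(np.clip(window_frames, 3, data2d.shape[0]))
    eroded = ndimage.minimum_filter1d(data2d, w, axis=0, mode="nearest")
    opened = ndimage.maximum_filter1d(eroded, w, axis=0, mode="nearest")
    vand = np.polynomial.polynomial.polyvander(t, order)  # (T, K)
    coef, *_ = np.linalg.lstsq(vand, opened, rcond=None)
    return vand @ coef


def drift_correct_normalize(
    movie: VoltageMovie, poly_order: int = 2, baseline_window_ms: float = 200.0
) -> VoltageMovie:
    """Subtract a slow per-pixel baseline, then map each trace to [0, 1].

    The baseline is a low-order polynomial fitted to a morphologically
    opened copy of the trace (window ``baseline_window_ms``), so action
    potentials do not drag it upward.  After subtraction each trace is
    affinely rescaled min -> 0, max -> 1; constant traces become all zeros
    instead of dividing by zero.
    """
    n_frames, rows, cols = movie.data.shape
    flat = movie.data.reshape(n_frames, rows * cols)
    t = np.linspace(-1.0, 1.0, n_frames)  # scaled abscissa for conditioning
    win = int(round(baseline_window_ms * movie.frame_rate_hz / 1000.0))
    baseline = _baseline_fit(flat, t, poly_order, win)
    detr = flat - baseline
    lo = detr.min(axis=0)
    rng = detr.max(axis=0) - lo
    tiny = 1e-12 * max(1.0, np.abs(movie.data).max())
    safe = np.where(rng > tiny, rng, 1.0)
    norm = np.where(rng > tiny, (detr - lo) / safe, 0.0)
    return replace(movie, data=norm.reshape(n_frames, rows, cols))


def snr_mask(
    movie: VoltageMovie,
    snr_threshold: float = 3.0,
    smooth_ms: float = 20.0,
) -> PixelMask:
    """Mask pixels whose signal-to-noise ratio falls below ``snr_threshold``.

    SNR per pixel = (peak-to-peak range of the smoothed trace) / (robust
    noise sigma from the high-frequency residual).  The noise sigma is the
    median-absolute successive difference of trace minus its running mean,
    scaled to a Gaussian sigma; noise-free pixels get a large capped SNR.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    win = max(3, int(round(smooth_ms * movie.frame_rate_hz / 1000.0)))
    win = min(win, movie.n_frames // 2)
    smooth = ndimage.uniform_filter1d(movie.data, size=win, axis=0, mode="nearest")
    # drop the half-window at each end: there the running mean leans on
    # replicated samples and its noise floor is inflated
    core = smooth[win // 2 : movie.n_frames - win // 2]
    amp = core.max(axis=0) - core.min(axis=0)
    resid = movie.data - smooth
    d = np.diff(resid, axis=0)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d, axis=0)), axis=0) / np.sqrt(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sigma > 0, amp / sigma, SNR_CAP)
    snr = np.minimum(snr, SNR_CAP)
    keep = snr >= snr_threshold
    if not keep.any():
        raise ValueError("empty mask: no pixel reaches the SNR threshold")
    return PixelMask(keep)


def preprocess_movie(
    movie: VoltageMovie,
    kernel_size: int = 3,
    filter_low_hz: float = 0.0,
    filter_high_hz: float = 100.0,
    filter_order: int = 4,
    drift_poly_order: int = 2,
    drift_window_ms: float = 200.0,
    snr_threshold: float = 3.0,
    snr_smooth_ms: float = 20.0,
) -> tuple[VoltageMovie, PixelMask]:
    """Full preprocessing chain: bin -> band-pass -> drift/normalize -> mask."""
    out = spatial_bin(movie, kernel_size)
    out = temporal_filter(out, filter_low_hz, filter_high_hz, filter_order)
    out = drift_correct_normalize(out, drift_poly_order, drift_window_ms)
    mask = snr_mask(out, snr_threshold, snr_smooth_ms)
    return out, mask
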