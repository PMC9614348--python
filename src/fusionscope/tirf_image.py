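"""Image-stack processing for the single-vesicle TIRF fusion assay.

The raw observable is a movie of diffraction-limited spots: each docked
vesicle produces a step increase in local fluorescence, and each fusion event
a transient spike.  The processing chain is: temporal moving-average filter,
per-pixel maximum projection over the stack, single-particle detection on the
projection, and extraction of per-particle intensity traces (the central-pixel
"peak" series and the mean of the 5x5 pixel area around each detected center
of mass).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)

__all__ = [
    "MovieStack",
    "ParticleTrace",
    "moving_average_filter",
    "max_projection",
    "detect_particles",
    "extract_traces",
    "read_movie",
    "traces_to_frame",
]

ROI_HALF = 2  # 5x5 pixel^2 analysis area around each center


@dataclass
class MovieStack:
    """A fluorescence movie: (frames, rows, cols) with its frame interval."""

    data: np.ndarray
    frame_interval: float = 0.020
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie must be a (frames, rows, cols) array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ParticleTrace:
    """Per-particle intensity time series at an integer pixel center."""

    particle_id: int
    center: tuple[int, int]  # (row, col), 0-based
    peak_series: np.ndarray  # central pixel per frame
    mean_series: np.ndarray  # 5x5 mean per frame

    def __post_init__(self) -> None:
        self.peak_series = np.asarray(self.peak_series, dtype=float)
        self.mean_series = np.asarray(self.mean_series, dtype=float)
        if self.peak_series.shape != self.mean_series.shape:
            raise ValueError("peak and mean series must have equal length")


def read_movie(path, frame_interval: float = 0.020) -> MovieStack:
    """Load a grayscale TIFF stack (ImageJ-compatible) as a MovieStack."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return MovieStack(np.asarray(data, dtype=float), frame_interval)


def moving_average_filter(stack: MovieStack, window: int = 3) -> MovieStack:
    """Temporal moving average with a centered, edge-truncated window.

    Each output frame t averages the input frames within the window centered
    at t, truncated at the first/last frame, so the output has the same length
    and events are not shifted in time.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    window = min(int(window), stack.n_frames)
    if window == 1:
        return MovieStack(stack.data.copy(), stack.frame_interval, stack.pixel_size)
    dtype = stack.data.dtype if np.issubdtype(stack.data.dtype, np.floating) else np.float64
    data = stack.data.astype(dtype, copy=False)
    # Truncated centered mean: ratio of windowed sums to windowed counts.
    csum = ndimage.uniform_filter1d(data, size=window, axis=0, mode="constant") * window
    counts = ndimage.uniform_filter1d(
        np.ones(stack.n_frames), size=window, mode="constant"
    ) * window
    out = csum / counts[:, None, None].astype(dtype)
    return MovieStack(out, stack.frame_interval, stack.pixel_size)


def max_projection(stack: MovieStack) -> np.ndarray:
    """Per-pixel maximum over all frames, projected onto a single image."""
    return stack.data.max(axis=0)


def detect_particles(
    image: np.ndarray,
    min_separation: int = 5,
    threshold_sd: float = 5.0,
    psf_sigma: float = 1.0,
) -> list[tuple[int, int]]:
    """Locate diffraction-limited particles in a (projected) image.

    Laplacian-of-Gaussian response at the PSF scale, local-maximum selection
    with a robust (MAD-based) background threshold: a pixel is a detection if
    its LoG amplitude exceeds ``threshold_sd`` times the robust SD of the LoG
    image, maxima are at least ``min_separation`` pixels apart, and every
    detection is >= 2 px from the border so the 5x5 analysis area fits.
    The center of mass is refined as the intensity-weighted centroid in the
    5x5 neighbourhood, then rounded to the nearest integer pixel.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 5:
        raise ValueError("image must be 2-D and at least 5x5")
    # -LoG is positive on bright blobs; scale-normalised response
    log_resp = -(psf_sigma**2) * ndimage.gaussian_laplace(image, sigma=psf_sigma)
    med = np.median(log_resp)
    mad = np.median(np.abs(log_resp - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = log_resp.std() or np.inf
    thr = med + threshold_sd * robust_sd
    peaks = peak_local_max(
        log_resp,
        min_distance=int(min_separation),
        threshold_abs=thr,
        exclude_border=ROI_HALF,
    )
    centers: list[tuple[int, int]] = []
    bg = float(np.median(image))
    for r, c in peaks:
        patch = image[r - ROI_HALF : r + ROI_HALF + 1, c - ROI_HALF : c + ROI_HALF + 1]
        w = np.clip(patch - bg, 0, None)
        if w.sum() > 0:
            rr, cc = np.mgrid[r - ROI_HALF : r + ROI_HALF + 1, c - ROI_HALF : c + ROI_HALF + 1]
            r = int(round((w * rr).sum() / w.sum()))
            c = int(round((w * cc).sum() / w.sum()))
        r = int(np.clip(r, ROI_HALF, image.shape[0] - 1 - ROI_HALF))
        c = int(np.clip(c, ROI_HALF, image.shape[1] - 1 - ROI_HALF))
        centers.append((r, c))
    # centroiding can merge neighbours onto one pixel; deduplicate
    return list(dict.fromkeys(centers))


def extract_traces(
    stack: MovieStack, centers: "list[tuple[int, int]]"
) -> list[ParticleTrace]:
    """Peak (central-pixel) and 5x5-mean intensity traces at each center.

    Centers whose 5x5 area does not fit inside the image are rejected with a
    warning rather than raising, so one bad detection does not abort a run.
    """
    n_rows, n_cols = stack.shape
    traces: list[ParticleTrace] = []
    for pid, (r, c) in enumerate(centers):
        if not (ROI_HALF <= r < n_rows - ROI_HALF and ROI_HALF <= c < n_cols - ROI_HALF):
            warnings.warn(
                f"center ({r}, {c}) too close to border for a 5x5 area; skipped",
                stacklevel=2,
            )
            continue
        peak = stack.data[:, r, c].astype(float)
        roi = stack.data[:, r - ROI_HALF : r + ROI_HALF + 1, c - ROI_HALF : c + ROI_HALF + 1]
        mean = roi.mean(axis=(1, 2)).astype(float)
        traces.append(ParticleTrace(pid, (r, c), peak, mean))
    return traces


def traces_to_frame(traces: "list[ParticleTrace]") -> pd.DataFrame:
    """Long-format trace table: particle_id, frame, peak, mean (CSV-ready)."""
    parts = []
    for t in traces:
        n = t.peak_series.size
        parts.append(
            pd.DataFrame(
                {
                    "particle_id": t.particle_id,
                    "frame": np.arange(n),
                    "row": t.center[0],
                    "col": t.center[1],
                    "peak": t.peak_series,
                    "mean": t.mean_series,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["particle_id", "frame", "row", "col", "peak", "mean"])
    return pd.concat(parts, ignore_index=True)
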