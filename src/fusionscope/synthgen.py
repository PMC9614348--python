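"""Synthetic data generators for every assay in the package.

Each generator emits data with the statistical structure its assay assumes,
together with the exact ground truth, so the downstream analysis can be
validated end-to-end without any recorded data:

* TIRF fusion movies — diffraction-limited Gaussian spots on an EMCCD-like
  Gaussian-noise background; docking is a step to a plateau, fusion a spike of
  factor ``spike_gain`` (the dequenching gain, observed value 2) followed by
  exponential decay as labeled lipids spread away.  3000 frames at 20 ms by
  default.
* Binding time courses — first-order saturation of the field-mean intensity,
  sampled every 30 s, with the dequenching mixture of fused/unfused liposomes.
* FLIC terrace sets — 16 intensities per set from the five-layer interference
  model at a known dye height, with multiplicative noise; 100 sets per image
  by default.
* Planar-bilayer current traces — Poisson-timed abrupt conductance spikes
  with exponential decay on a noisy baseline, 3.5 min segments by default.

All randomness flows from one seeded NumPy generator per call, so every
output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .docking_binding import BindingTimeCourse, observed_intensity
from .blm_electro import CurrentTrace
from .flic_optics import FlicMeasurement, FlicOpticsParams, _forward_matrix, default_oxide_thicknesses
from .tirf_image import MovieStack

__all__ = [
    "TirfSimConfig",
    "BindingSimConfig",
    "FlicSimConfig",
    "BlmSimConfig",
    "SimulatedVesicle",
    "simulate_tirf_movie",
    "simulate_binding_series",
    "simulate_flic_sets",
    "simulate_current_trace",
]


# --------------------------------------------------------------------------
# TIRF fusion movies


@dataclass(frozen=True)
class TirfSimConfig:
    """Conditions of a simulated single-vesicle fusion movie.

    ``docking_rate`` is in expected events per frame over the whole movie;
    docking times are kept ``start_margin``..``end_margin`` frames away from
    the movie edges so that every event has a pre-dock baseline and a full
    1 s post-dock observation window.  ``spot_amplitude`` is the central-pixel
    intensity of a docked vesicle above background, so the spot SNR is
    spot_amplitude / background_sd.  The dock-to-fusion delay is a truncated
    exponential (mean ``fusion_delay_mean``, ceiling ``fusion_delay_max``)
    calibrated so that about 65% of fusing vesicles fuse within 250 ms; the
    1 s ceiling keeps every simulated fusion inside the classification cutoff.
    """

    n_frames: int = 3000
    frame_interval: float = 0.020
    image_shape: tuple[int, int] = (140, 140)
    psf_sigma: float = 1.0
    docking_rate: float = 200 / 3000  # events per frame; ~200 events per movie
    fusion_probability: float = 0.34
    fusion_delay_mean: float = 0.24  # s; ~65% of delays fall below 250 ms
    fusion_delay_max: float = 1.0  # s
    fusion_delay_min: float = 0.04  # s; docking and fusion on distinct frames
    spike_gain: float = 2.0
    decay_tau: float = 0.10  # s, post-fusion lipid-spread decay
    spot_amplitude: float = 20.0
    background_mean: float = 100.0
    background_sd: float = 2.0
    min_separation: int = 6  # px between docking sites
    start_margin: int = 25  # frames
    end_margin: int = 75  # frames
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape", tuple(self.image_shape))
        if not 0.0 <= self.fusion_probability <= 1.0:
            raise ValueError("fusion_probability must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if min(self.image_shape) < 5:
            raise ValueError("image_shape too small to hold a 5x5 analysis area")


@dataclass
class SimulatedVesicle:
    """Ground truth for one simulated docking event."""

    particle_id: int
    row: int
    col: int
    dock_frame: int
    fusion_frame: int | None
    plateau: float  # noiseless central-pixel amplitude above background

    @property
    def fused(self) -> bool:
        return self.fusion_frame is not None


def _sample_positions(
    rng: np.random.Generator, n: int, shape: tuple[int, int], min_sep: int, margin: int
) -> list[tuple[int, int]]:
    """Rejection-sample up to n integer positions with a minimum separation."""
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n and tries < 500 * n:
        tries += 1
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
            placed.append((r, c))
    if len(placed) < n:
        warnings.warn(
            f"placed only {len(placed)} of {n} docking sites at the requested "
            "separation; increase image_shape or lower docking_rate",
            stacklevel=2,
        )
    return placed


def _truncated_exp_delay(rng: np.random.Generator, cfg: TirfSimConfig, size: int) -> np.ndarray:
    """Dock-to-fusion delays: exponential truncated to [delay_min, delay_max]."""
    lo, hi, mean = cfg.fusion_delay_min, cfg.fusion_delay_max, cfg.fusion_delay_mean
    u = rng.uniform(size=size)
    # inverse CDF of exp(mean) conditioned on [lo, hi]
    f_lo = 1.0 - np.exp(-lo / mean)
    f_hi = 1.0 - np.exp(-hi / mean)
    return -mean * np.log(1.0 - (f_lo + u * (f_hi - f_lo)))


def simulate_tirf_movie(
    config: TirfSimConfig,
) -> tuple[MovieStack, list[SimulatedVesicle]]:
    """Simulate a single-vesicle fusion movie with full ground truth.

    Docking events are Poisson in number (mean docking_rate * n_frames) with
    uniformly distributed docking frames inside the margins; a fraction
    ``fusion_probability`` of them fuse after a sampled delay, producing a
    spike of ``spike_gain`` times the plateau that decays with ``decay_tau``.
    Returns the noisy movie and the list of simulated vesicles.
    """
    rng = np.random.default_rng(config.seed)
    n_t = config.n_frames
    shape = config.image_shape
    dt = config.frame_interval

    n_events = int(rng.poisson(config.docking_rate * n_t))
    frame_lo = min(config.start_margin, max(n_t - 1, 0))
    frame_hi = max(n_t - config.end_margin, frame_lo + 1)
    dock_frames = np.sort(rng.integers(frame_lo, frame_hi, size=n_events))
    positions = _sample_positions(
        rng, n_events, shape, config.min_separation, margin=4
    )
    n_events = len(positions)
    dock_frames = dock_frames[:n_events]

    fused = rng.uniform(size=n_events) < config.fusion_probability
    delays = _truncated_exp_delay(rng, config, n_events)

    # spatial kernel with unit central-pixel amplitude
    half = max(3, int(np.ceil(3 * config.psf_sigma)))
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(rr**2 + cc**2) / (2.0 * config.psf_sigma**2))

    movie = np.zeros((n_t,) + shape, dtype=np.float32)
    truth: list[SimulatedVesicle] = []
    t_idx = np.arange(n_t)
    for i in range(n_events):
        r, c = positions[i]
        dock = int(dock_frames[i])
        amp = np.zeros(n_t, dtype=np.float32)
        a = config.spot_amplitude
        if fused[i]:
            fus = dock + max(2, int(round(delays[i] / dt)))
            fus = min(fus, n_t - 1)
            amp[dock:fus] = a
            tail = t_idx[fus:] - fus
            amp[fus:] = config.spike_gain * a * np.exp(-tail * dt / config.decay_tau)
            fusion_frame: int | None = fus
        else:
            amp[dock:] = a
            fusion_frame = None
        movie[:, r - half : r + half + 1, c - half : c + half + 1] += (
            amp[:, None, None] * kernel[None, :, :]
        )
        truth.append(SimulatedVesicle(i, r, c, dock, fusion_frame, a))

    if config.background_sd > 0:
        movie += rng.standard_normal(movie.shape, dtype=np.float32) * np.float32(
            config.background_sd
        )
    movie += np.float32(config.background_mean)
    return MovieStack(movie, dt), truth


# --------------------------------------------------------------------------
# Binding time courses


@dataclass(frozen=True)
class BindingSimConfig:
    """Conditions of a simulated liposome-binding time course."""

    n_liposomes_saturation: float = 200.0
    rate_constant: float = 0.01  # 1/s
    image_period: float = 30.0  # s
    duration: float = 900.0  # s of post-injection observation
    alpha: float = 0.34  # fusion efficiency
    beta: float = 2.0  # dequenching intensity gain
    i_liposome: float = 1.0
    baseline: float = 50.0
    noise_sd: float = 0.0
    n_baseline_images: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 1.0:
            raise ValueError("beta must be >= 1")
        if self.rate_constant <= 0:
            raise ValueError("rate_constant must be positive")


def binding_expected_intensity(config: BindingSimConfig, t_since_injection) -> np.ndarray:
    """Noiseless expected intensity at time t after injection.

    baseline + N(t) i_lip (1 - alpha + alpha beta), with first-order binding
    N(t) = N_sat (1 - exp(-k t)).
    """
    t = np.asarray(t_since_injection, dtype=float)
    n_t = config.n_liposomes_saturation * (1.0 - np.exp(-config.rate_constant * t))
    per_lip = observed_intensity(1.0, config.alpha, config.beta, config.i_liposome)
    return config.baseline + n_t * per_lip


def simulate_binding_series(config: BindingSimConfig) -> tuple[BindingTimeCourse, dict]:
    """Simulate a binding time course; returns the series and its ground truth.

    The first ``n_baseline_images`` images precede injection (flagged as
    baseline); injection happens at the first post-baseline image time.
    Ground truth holds the noiseless saturation intensity I_obs and rate k.
    """
    rng = np.random.default_rng(config.seed)
    n_post = int(np.floor(config.duration / config.image_period)) + 1
    times = np.arange(config.n_baseline_images + n_post) * config.image_period
    t_inj = times[config.n_baseline_images]
    t_rel = np.clip(times - t_inj, 0.0, None)
    intensity = binding_expected_intensity(config, t_rel)
    intensity = np.where(times < t_inj, config.baseline, intensity)
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=times.size)
    is_baseline = times < t_inj
    i_obs = observed_intensity(
        config.n_liposomes_saturation, config.alpha, config.beta, config.i_liposome
    )
    truth = {
        "saturation_intensity": i_obs,
        "rate_constant": config.rate_constant,
        "baseline": config.baseline,
        "n_liposomes_saturation": config.n_liposomes_saturation,
    }
    return BindingTimeCourse(times, intensity, is_baseline), truth


# --------------------------------------------------------------------------
# FLIC terrace sets


@dataclass(frozen=True)
class FlicSimConfig:
    """Conditions of simulated FLIC terrace-intensity sets."""

    oxide_thicknesses: tuple = tuple(default_oxide_thicknesses())
    true_dye_height: float = 4.5  # nm above the membrane surface
    scale: float = 1000.0
    background: float = 100.0
    noise_fraction: float = 0.05
    n_sets: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "oxide_thicknesses", tuple(self.oxide_thicknesses))
        if len(self.oxide_thicknesses) != 16:
            raise ValueError("exactly 16 oxide thicknesses required")
        if self.true_dye_height < 0:
            raise ValueError("true_dye_height must be >= 0")


def simulate_flic_sets(
    config: FlicSimConfig, optics: FlicOpticsParams | None = None
) -> list[FlicMeasurement]:
    """Simulate n_sets 16-terrace intensity sets at a known dye height.

    Each intensity is (scale * F(d_ox, h) + background) perturbed by
    multiplicative Gaussian noise of relative size ``noise_fraction``.
    """
    optics = optics or FlicOpticsParams()
    rng = np.random.default_rng(config.seed)
    d_ox = np.asarray(config.oxide_thicknesses, dtype=float)
    f = _forward_matrix(optics, d_ox, np.array([config.true_dye_height]))[:, 0]
    clean = config.scale * f + config.background
    sets = []
    for i in range(config.n_sets):
        noisy = clean * (1.0 + config.noise_fraction * rng.standard_normal(16))
        sets.append(FlicMeasurement(d_ox, np.clip(noisy, 0.0, None), set_id=i))
    return sets


# --------------------------------------------------------------------------
# Planar-bilayer current traces


@dataclass(frozen=True)
class BlmSimConfig:
    """Conditions of a simulated voltage-clamp current trace (3.5 min default)."""

    duration: float = 210.0  # s
    sample_rate: float = 1000.0  # Hz
    event_rate: float = 17 / 3.5  # events per minute
    event_amplitude_mean: float = 20.0  # pA
    event_amplitude_sd: float = 3.0
    event_decay_tau: float = 0.3  # s
    baseline_current: float = 5.0  # pA
    noise_sd: float = 2.5  # pA
    event_times: tuple | None = None  # fixed times override the Poisson draw
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")


def simulate_current_trace(config: BlmSimConfig) -> tuple[CurrentTrace, np.ndarray]:
    """Simulate a current trace with transient fusion-conductance spikes.

    Event times are Poisson at ``event_rate`` per minute (or the fixed
    ``event_times`` when given); each event adds an instantaneous positive
    amplitude step that decays exponentially with ``event_decay_tau`` on a
    Gaussian-noise baseline.  Returns the trace and the true event times.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate
    n = int(round(config.duration * config.sample_rate))
    times = np.arange(n) * dt
    if config.event_times is not None:
        ev = np.sort(np.asarray(config.event_times, dtype=float))
    else:
        n_ev = rng.poisson(config.event_rate * config.duration / 60.0)
        ev = np.sort(rng.uniform(0.0, config.duration, size=n_ev))
    current = np.full(n, config.baseline_current, dtype=float)
    for t0 in ev:
        amp = max(rng.normal(config.event_amplitude_mean, config.event_amplitude_sd), 0.0)
        i0 = int(np.ceil(t0 / dt - 1e-12))
        if i0 >= n:
            continue
        tail = times[i0:] - times[i0]
        current[i0:] += amp * np.exp(-tail / config.event_decay_tau)
    if config.noise_sd > 0:
        current = current + rng.normal(0.0, config.noise_sd, size=n)
    return CurrentTrace(times, current), ev
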