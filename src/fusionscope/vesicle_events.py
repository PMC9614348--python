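"""Docking/fusion classification of single-vesicle traces and fusion probability.

A docked vesicle shows a sudden jump in spot fluorescence with no subsequent
decay; a vesicle that fuses shows, after docking, a large spike (the
dequenching burst, about twice the docked plateau) followed by rapid decay as
the labeled lipids diffuse away into the planar membrane.  Vesicles that do
not fuse within 1 s of docking are counted in the non-fused population, and
the per-condition fusion probability is the fraction of docked vesicles that
fused, with a Wilson 95% confidence interval.  Conditions are compared by
one-way ANOVA over per-bilayer replicate probabilities with Dunnett-style
contrasts against the control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .stats import AnovaResult, one_way_anova_vs_control
from .tirf_image import ParticleTrace

__all__ = [
    "ClassifierParams",
    "VesicleEvent",
    "ConditionResult",
    "classify_trace",
    "classify_traces",
    "fusion_probability",
    "compare_conditions",
    "events_to_frame",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the trace classifier; all configurable.

    dock_k : docking step threshold, in units of the trace noise SD.
    dock_persistence : frames the intensity must stay elevated to call docking.
    spike_factor : fusion spike must reach this multiple of the docked
        plateau step above baseline.
    decay_window : seconds after the spike within which the trace must decay.
    decay_return_frac : decayed means the post-spike level falls below
        baseline + this fraction of the plateau step.
    fusion_cutoff : seconds after docking within which fusion must occur,
        implemented as ceil(cutoff / frame_interval) frames (50 at 20 ms).
    baseline_frames : initial frames used for the pre-dock baseline estimate.
    """

    dock_k: float = 5.0
    dock_persistence: int = 5
    spike_factor: float = 1.5
    decay_window: float = 0.5
    decay_return_frac: float = 0.5
    fusion_cutoff: float = 1.0
    baseline_frames: int = 15


@dataclass
class VesicleEvent:
    """Classified outcome for one detected particle."""

    particle_id: int
    dock_frame: int | None
    fusion_frame: int | None
    classification: str  # fused | non_fused | rejected
    dock_to_fusion: float | None = None  # seconds, when fused

    def __post_init__(self) -> None:
        if self.classification not in ("fused", "non_fused", "rejected"):
            raise ValueError(f"bad classification {self.classification!r}")
        if (self.classification == "fused") != (self.fusion_frame is not None):
            raise ValueError("classification 'fused' iff fusion_frame present")
        if self.fusion_frame is not None and self.dock_frame is not None:
            if self.dock_frame > self.fusion_frame:
                raise ValueError("dock_frame must be <= fusion_frame")


@dataclass
class ConditionResult:
    """Fusion probability for one condition (alcohol type + dose)."""

    condition: str
    n_docked: int
    n_fused: int
    fusion_probability: float
    ci95: tuple[float, float]


def _noise_sd(series: np.ndarray) -> float:
    """Robust noise SD from first differences (insensitive to steps/spikes)."""
    d = np.diff(series)
    mad = np.median(np.abs(d - np.median(d)))
    sd = 1.4826 * mad / math.sqrt(2.0)
    return sd if sd > 0 else (series.std() or 1.0)


def classify_trace(
    trace: ParticleTrace,
    frame_interval: float = 0.020,
    params: ClassifierParams | None = None,
) -> VesicleEvent:
    """Classify one particle trace as fused, non-fused, or rejected.

    Docking: first frame where the peak (central-pixel) intensity exceeds the
    pre-dock baseline by ``dock_k`` noise SDs and stays elevated for
    ``dock_persistence`` consecutive frames.  Fusion: the largest post-docking
    excursion within the 1 s cutoff must reach ``spike_factor`` times the
    docked plateau step and the trace must decay back toward baseline within
    ``decay_window``.  A spike later than the cutoff leaves the vesicle in the
    non-fused population; a trace with no docking step is rejected.
    """
    p = params or ClassifierParams()
    y = np.asarray(trace.peak_series, dtype=float)
    pid = trace.particle_id
    n = y.size
    cutoff_frames = math.ceil(p.fusion_cutoff / frame_interval)
    if n < p.baseline_frames + p.dock_persistence:
        return VesicleEvent(pid, None, None, "rejected")

    sigma = _noise_sd(y)
    base = float(np.median(y[: p.baseline_frames]))
    above = y > base + p.dock_k * sigma
    # first run of >= dock_persistence consecutive elevated frames
    dock = None
    run = 0
    for t in range(n):
        run = run + 1 if above[t] else 0
        if run >= p.dock_persistence:
            dock = t - p.dock_persistence + 1
            break
    if dock is None:
        return VesicleEvent(pid, None, None, "rejected")

    # fusion candidate: maximum within the cutoff window after docking
    w_end = min(dock + cutoff_frames + 1, n)
    window = y[dock:w_end]
    fmax = dock + int(np.argmax(window))
    peak = y[fmax]

    # docked plateau: frames between docking and the spike (fall back to the
    # docking frames themselves for near-immediate fusion)
    if fmax - dock >= 3:
        plateau = float(np.median(y[dock:fmax]))
    else:
        plateau = float(np.median(y[dock : dock + p.dock_persistence]))
    step = max(plateau - base, p.dock_k * sigma)

    spike_ok = (peak - base) >= p.spike_factor * step
    decay_frames = max(1, int(round(p.decay_window / frame_interval)))
    tail = y[fmax + 1 : fmax + 1 + decay_frames]
    decay_ok = tail.size > 0 and float(np.min(tail)) <= base + p.decay_return_frac * step

    if spike_ok and decay_ok and (fmax - dock) <= cutoff_frames:
        return VesicleEvent(
            pid, dock, fmax, "fused", dock_to_fusion=(fmax - dock) * frame_interval
        )
    return VesicleEvent(pid, dock, None, "non_fused")


def classify_traces(
    traces: "list[ParticleTrace]",
    frame_interval: float = 0.020,
    params: ClassifierParams | None = None,
) -> list[VesicleEvent]:
    return [classify_trace(t, frame_interval, params) for t in traces]


def fusion_probability(
    events: "list[VesicleEvent]", condition: str = ""
) -> ConditionResult:
    """Fusion probability = fused / (fused + non-fused), Wilson 95% CI.

    Rejected traces are excluded from the denominator; zero docked events is
    an error (no data to estimate from).
    """
    n_fused = sum(1 for e in events if e.classification == "fused")
    n_non = sum(1 for e in events if e.classification == "non_fused")
    n_docked = n_fused + n_non
    if n_docked == 0:
        raise ValueError("no docked events: insufficient data for fusion probability")
    lo, hi = proportion_confint(n_fused, n_docked, alpha=0.05, method="wilson")
    return ConditionResult(condition, n_docked, n_fused, n_fused / n_docked, (lo, hi))


def compare_conditions(
    replicate_probabilities: "dict[str, list[float]]", control: str
) -> AnovaResult:
    """One-way ANOVA across conditions on per-replicate fusion probabilities.

    The replicate unit is one supported bilayer (one experiment); each
    condition needs at least two replicates.
    """
    return one_way_anova_vs_control(replicate_probabilities, control=control)


def events_to_frame(events: "list[VesicleEvent]") -> pd.DataFrame:
    """Events as a CSV-ready table."""
    return pd.DataFrame(
        {
            "particle_id": [e.particle_id for e in events],
            "dock_frame": [e.dock_frame for e in events],
            "fusion_frame": [e.fusion_frame for e in events],
            "classification": [e.classification for e in events],
            "dock_to_fusion_s": [e.dock_to_fusion for e in events],
        }
    )
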