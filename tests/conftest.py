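"""Shared fixtures: synthetic movies and the end-to-end TIRF pipeline run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fusionscope import synthgen as sg
from fusionscope import tirf_image as ti
from fusionscope import vesicle_events as ve

N_PIPELINE_SEEDS = 20


@dataclass
class PipelineRun:
    """Outcome of one movie through detect -> extract -> classify, vs truth."""

    seed: int
    n_true: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    n_classified: int
    n_correct: int
    estimated_p: float
    ci95: tuple[float, float]
    generator_p: float


def run_tirf_pipeline(seed: int, config: sg.TirfSimConfig | None = None) -> PipelineRun:
    """Simulate one fusion movie and push it through the full analysis chain."""
    cfg = config or sg.TirfSimConfig(seed=seed)
    movie, truth = sg.simulate_tirf_movie(cfg)
    filtered = ti.moving_average_filter(movie, window=3)
    proj = ti.max_projection(filtered)
    centers = ti.detect_particles(
        proj, min_separation=max(2, cfg.min_separation - 2), threshold_sd=5.0,
        psf_sigma=cfg.psf_sigma,
    )
    traces = ti.extract_traces(filtered, centers)
    events = ve.classify_traces(traces, cfg.frame_interval)

    true_pos = np.array([(v.row, v.col) for v in truth]).reshape(-1, 2)
    det_pos = np.array([t.center for t in traces]).reshape(-1, 2)
    n_matched = n_correct = 0
    matched_truth: set[int] = set()
    if len(truth) and len(traces):
        tree = cKDTree(true_pos)
        dist, idx = tree.query(det_pos)
        for ev, d, i in zip(events, dist, idx):
            if d > 2.0:
                continue
            n_matched += 1
            matched_truth.add(int(i))
            gt = "fused" if truth[i].fused else "non_fused"
            n_correct += ev.classification == gt
    res = ve.fusion_probability(events) if events else None
    return PipelineRun(
        seed=seed,
        n_true=len(truth),
        n_detected=len(traces),
        n_matched=n_matched,
        precision=n_matched / len(traces) if traces else 1.0,
        recall=len(matched_truth) / len(truth) if truth else 1.0,
        n_classified=n_matched,
        n_correct=n_correct,
        estimated_p=res.fusion_probability if res else float("nan"),
        ci95=res.ci95 if res else (float("nan"), float("nan")),
        generator_p=cfg.fusion_probability,
    )


@pytest.fixture(scope="session")
def tirf_pipeline_runs() -> list[PipelineRun]:
    """Full-pipeline results on 20 seeded movies at the study conditions.

    Study conditions: 3000 frames at 20 ms, ~200 expected docking events per
    movie, generator fusion probability 0.34, spot SNR 10.
    """
    return [run_tirf_pipeline(seed) for seed in range(N_PIPELINE_SEEDS)]


@pytest.fixture(scope="session")
def small_movie():
    """A light movie (600 frames, 64 px) with ground truth, for unit tests."""
    cfg = sg.TirfSimConfig(
        n_frames=600,
        image_shape=(64, 64),
        docking_rate=25 / 600,
        seed=42,
        end_margin=60,
    )
    movie, truth = sg.simulate_tirf_movie(cfg)
    return cfg, movie, truth
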