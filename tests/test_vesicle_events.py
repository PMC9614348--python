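"""Trace classification, fusion probability and condition comparison."""

import numpy as np
import pytest

from fusionscope.stats import one_way_anova_vs_control
from fusionscope.tirf_image import ParticleTrace
from fusionscope.vesicle_events import (
    ClassifierParams,
    VesicleEvent,
    classify_trace,
    classify_traces,
    compare_conditions,
    events_to_frame,
    fusion_probability,
)

DT = 0.020


def _make_trace(n=300, base=100.0, noise=2.0, dock=None, plateau=20.0,
                fusion=None, spike_gain=2.0, decay_tau=0.10, seed=0):
    """Synthesise a peak-intensity series with optional dock step and fusion spike."""
    rng = np.random.default_rng(seed)
    y = np.full(n, base) + rng.normal(0, noise, n)
    if dock is not None:
        end = fusion if fusion is not None else n
        y[dock:end] += plateau
        if fusion is not None:
            t = np.arange(n - fusion)
            y[fusion:] += spike_gain * plateau * np.exp(-t * DT / decay_tau)
    return ParticleTrace(0, (5, 5), y, y)


class TestClassifyTrace:
    def test_docking_only_step_is_non_fused(self):
        ev = classify_trace(_make_trace(dock=60), DT)
        assert ev.classification == "non_fused"
        assert abs(ev.dock_frame - 60) <= 2

    def test_dock_then_spike_decay_is_fused_with_timing(self):
        # spike 150 ms (~8 frames) after docking
        ev = classify_trace(_make_trace(dock=60, fusion=68), DT)
        assert ev.classification == "fused"
        assert ev.dock_to_fusion == pytest.approx(0.15, abs=0.04)

    def test_late_spike_beyond_one_second_is_non_fused(self):
        # spike 1.5 s (75 frames) after docking
        ev = classify_trace(_make_trace(n=400, dock=60, fusion=135), DT)
        assert ev.classification == "non_fused"

    def test_flat_trace_rejected(self):
        ev = classify_trace(_make_trace(), DT)
        assert ev.classification == "rejected"
        assert ev.dock_frame is None

    def test_classification_counts_partition_inputs(self):
        traces = [
            _make_trace(seed=s, dock=d, fusion=f)
            for s, d, f in [(1, 60, 70), (2, 80, None), (3, None, None), (4, 50, 58)]
        ]
        events = classify_traces(traces, DT)
        counts = {k: sum(e.classification == k for e in events)
                  for k in ("fused", "non_fused", "rejected")}
        assert sum(counts.values()) == len(traces)
        assert counts["rejected"] == 1

    def test_raising_cutoff_only_moves_non_fused_to_fused(self):
        traces = [
            _make_trace(seed=s, dock=50, fusion=50 + f, n=400)
            for s, f in [(1, 10), (2, 30), (3, 70), (4, 90), (5, None)]
            if f is not None
        ] + [_make_trace(seed=9, dock=50, n=400)]
        short = classify_traces(traces, DT, ClassifierParams(fusion_cutoff=1.0))
        long = classify_traces(traces, DT, ClassifierParams(fusion_cutoff=2.0))
        for a, b in zip(short, long):
            if a.classification == "fused":
                assert b.classification == "fused"

    def test_event_invariants_enforced(self):
        with pytest.raises(ValueError):
            VesicleEvent(0, 10, 5, "fused")
        with pytest.raises(ValueError):
            VesicleEvent(0, 10, None, "fused")


class TestFusionProbability:
    def test_zero_fused(self):
        events = [VesicleEvent(i, 5, None, "non_fused") for i in range(50)]
        assert fusion_probability(events).fusion_probability == 0.0

    def test_control_level(self):
        events = [VesicleEvent(i, 5, 10, "fused", 0.1) for i in range(34)]
        events += [VesicleEvent(i, 5, None, "non_fused") for i in range(34, 100)]
        res = fusion_probability(events, "control")
        assert res.fusion_probability == pytest.approx(0.34)
        assert res.ci95[0] < 0.34 < res.ci95[1]

    def test_rejected_excluded_from_denominator(self):
        events = [VesicleEvent(0, 5, 8, "fused", 0.06),
                  VesicleEvent(1, 5, None, "non_fused"),
                  VesicleEvent(2, None, None, "rejected")]
        res = fusion_probability(events)
        assert res.n_docked == 2

    def test_large_sample_estimate_concentrates(self):
        rng = np.random.default_rng(0)
        fused = rng.uniform(size=10_000) < 0.5
        events = [
            VesicleEvent(i, 5, 10 if f else None, "fused" if f else "non_fused",
                         0.1 if f else None)
            for i, f in enumerate(fused)
        ]
        assert fusion_probability(events).fusion_probability == pytest.approx(0.5, abs=0.02)

    def test_no_docked_events_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            fusion_probability([VesicleEvent(0, None, None, "rejected")])


class TestCompareConditions:
    def test_identical_groups_give_f_zero(self):
        res = compare_conditions(
            {"control": [0.3, 0.3, 0.3], "etoh": [0.3, 0.3, 0.3]}, "control"
        )
        assert res.f_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(1)
        res = compare_conditions(
            {"control": 0.3 + 1e-3 * rng.normal(size=4),
             "etoh": 0.6 + 1e-3 * rng.normal(size=4)},
            "control",
        )
        assert res.p_value < 1e-6
        assert res.significant_conditions() == ["etoh"]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_conditions({"control": [0.3], "etoh": [0.5, 0.6]}, "control")

    def test_null_type_one_error_rate(self):
        # 3 groups x 4 replicates from one normal distribution
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {f"g{i}": rng.normal(size=4) for i in range(3)}
            res = one_way_anova_vs_control(groups, control="g0")
            rejections += res.p_value <= 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.025)


class TestPipelineRecovery:
    def test_recovery_on_study_condition_movies(self, tirf_pipeline_runs):
        """Detection, classification and probability recovery at SNR 10."""
        runs = tirf_pipeline_runs
        assert all(r.n_true >= 150 for r in runs)
        pooled_acc = sum(r.n_correct for r in runs) / sum(r.n_classified for r in runs)
        assert pooled_acc >= 0.95
        assert np.mean([r.precision for r in runs]) >= 0.95
        assert np.mean([r.recall for r in runs]) >= 0.95
        covered = sum(r.ci95[0] <= r.generator_p <= r.ci95[1] for r in runs)
        assert covered >= 0.9 * len(runs)

    def test_events_table_round_trip(self):
        events = [VesicleEvent(0, 5, 9, "fused", 0.08),
                  VesicleEvent(1, 7, None, "non_fused")]
        df = events_to_frame(events)
        assert list(df["classification"]) == ["fused", "non_fused"]
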