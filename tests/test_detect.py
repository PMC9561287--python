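"""Detection: quantization, grammar parsing, outcome classification."""

import numpy as np
import pytest

import ribotrace as rt
from ribotrace.detect import (
    DISASSEMBLY_50S,
    DISASSEMBLY_70S,
    MOVIE_END,
    ROTATION,
    STALL_CENSORED,
    TC_ARRIVAL,
    DetectionConfig,
    Event,
    EventSequence,
    Segment,
    Segmentation,
    benchmark_detection,
    classify_outcome,
    ideal_segmentation,
    parse_events,
    quantize_levels,
)
from ribotrace.emission import EmissionConfig, Trace, render_trace, trace_rng
from ribotrace.kinetics import default_program, make_preset, sample_trajectory


def _seg(levels, dt=5.0, trace_id="t"):
    """Build a segmentation from (green, red) label pairs, dt seconds each."""
    segs = [
        Segment(i * dt, (i + 1) * dt, g, r) for i, (g, r) in enumerate(levels)
    ]
    return Segmentation(trace_id=trace_id, frame_period=0.1, segments=segs)


CANONICAL = [
    ("HIGH", 0),  # PIC
    ("LOW", 0),  # joined, waiting codon 1
    ("LOW", 1),  # TC arrival codon 1
    ("MED", 1),  # rotation 1
    ("LOW", 1),  # translocation 1; suppressor decoding
    ("MED", 1),  # rotation 2
    ("LOW", 0),  # translocation 2 (labelled tRNA departs)
    ("LOW", 1),  # arrival codon 3
    ("MED", 1),  # rotation 3
    ("LOW", 1),
    ("LOW", 2),  # arrival codon 4 (double occupancy)
    ("MED", 2),  # rotation 4
    ("LOW", 1),  # translocation 4, departure
    ("LOW", 2),  # arrival codon 5
    ("MED", 2),  # rotation 5
    ("LOW", 1),
    ("LOW", 2),  # arrival codon 6
    ("MED", 2),  # rotation 6
    ("LOW", 1),  # translocation 6: complete
]


class TestQuantize:
    def test_noiseless_trace_recovers_ideal_levels(self, noiseless_cohort):
        cfg = rt.EmissionConfig(noise_sd=0.0)
        det = DetectionConfig.from_emission(cfg)
        preset = rt.make_preset("UTu1", 50, 1.0, bleach_rate_green=0.0, bleach_rate_red=0.0)
        for i in range(20):
            rng = trace_rng(7, i)
            traj = sample_trajectory(default_program(), preset, rng, trace_id=f"x{i}")
            tr = render_trace(traj, cfg, rng=rng)
            seg = quantize_levels(tr, det)
            ideal = ideal_segmentation(traj, cfg.frame_period)
            assert [(s.green, s.red) for s in seg.segments] == [
                (s.green, s.red) for s in ideal.segments
            ]
            for a, b in zip(seg.segments, ideal.segments):
                assert abs(a.t_start - b.t_start) <= cfg.frame_period + 1e-9

    def test_constant_zero_trace_is_single_zero_segment(self):
        n = 100
        tr = Trace("z", "p", np.arange(n) * 0.1, np.zeros(n), np.zeros(n))
        seg = quantize_levels(tr)
        assert len(seg.segments) == 1
        assert seg.segments[0].green == "ZERO" and seg.segments[0].red == 0

    def test_too_short_trace_raises(self):
        tr = Trace("s", "p", np.arange(3) * 0.1, np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            quantize_levels(tr)

    def test_min_dwell_merges_noise_blips(self):
        n = 200
        g = np.full(n, 0.15)
        g[100] = 0.45  # single-frame blip cannot be a real segment
        tr = Trace("b", "p", np.arange(n) * 0.1, g, np.zeros(n))
        seg = quantize_levels(tr, DetectionConfig(smooth_window=1))
        assert [s.green for s in seg.segments] == ["LOW"]

    def test_level_reestimation_tolerates_miscalibrated_centers(self):
        rng = np.random.default_rng(0)
        true_levels = np.repeat([1.2, 0.25, 0.6], 400)  # scaled vs defaults
        tr = Trace(
            "m", "p", np.arange(1200) * 0.1, true_levels + rng.normal(0, 0.05, 1200), np.zeros(1200)
        )
        seg = quantize_levels(tr, DetectionConfig(estimate_levels=True))
        assert [s.green for s in seg.segments] == ["HIGH", "LOW", "MED"]


class TestParse:
    def test_canonical_translation_parses_six_rotations(self):
        ev = parse_events(_seg(CANONICAL))
        rotations = ev.of_type(ROTATION)
        assert [e.codon for e in rotations] == [1, 2, 3, 4, 5, 6]
        # labelled-tRNA occupancy alternates double/single over late codons
        arrivals = ev.of_type(TC_ARRIVAL)
        assert [e.codon for e in arrivals] == [1, 3, 4, 5, 6]
        assert ev.events[-1].type == MOVIE_END
        assert ev.anomalous_from is None

    def test_return_to_high_is_50S_disassembly(self):
        seg = _seg(CANONICAL[:6] + [("HIGH", 0)])
        ev = parse_events(seg)
        assert ev.events[-1].type == DISASSEMBLY_50S

    def test_drop_to_zero_is_70S_disassembly(self):
        seg = _seg(CANONICAL[:7] + [("ZERO", 0)])
        ev = parse_events(seg)
        assert ev.events[-1].type == DISASSEMBLY_70S

    def test_zero_with_red_persisting_from_high_is_signal_loss(self):
        seg = _seg([("HIGH", 0), ("ZERO", 0)])
        ev = parse_events(seg)
        assert ev.events[-1].type == "SIGNAL_LOSS"

    def test_grammar_violation_truncates_and_flags(self):
        # medium intensity before any joining event is inconsistent
        seg = _seg([("HIGH", 0), ("MED", 0), ("LOW", 0)])
        ev = parse_events(seg)
        assert ev.anomalous_from == pytest.approx(5.0)
        assert ev.of_type(ROTATION) == []


class TestClassify:
    def test_completed_trace(self):
        out = classify_outcome(parse_events(_seg(CANONICAL)))
        assert out.outcome == "COMPLETED"
        assert out.decoded_codons == 6
        assert out.disassembly_phase == "none"

    def test_pre_translocation_disassembly_phase(self):
        # disassembly fires from the rotated state after the suppression codon
        seg = _seg(CANONICAL[:6] + [("HIGH", 0)])
        out = classify_outcome(parse_events(seg))
        assert out.outcome == DISASSEMBLY_50S
        assert out.decoded_codons == 2
        assert out.disassembly_phase == "pre_translocation"

    def test_post_translocation_disassembly_phase_and_dwell(self):
        seg = _seg(CANONICAL[:7] + [("ZERO", 0)])
        out = classify_outcome(parse_events(seg))
        assert out.outcome == DISASSEMBLY_70S
        assert out.decoded_codons == 2
        assert out.disassembly_phase == "post_translocation"
        # one 5 s segment between the suppressor translocation and the drop
        assert out.disassembly_dwell == pytest.approx(5.0)

    def test_censored_trace_is_stall(self):
        seg = _seg(CANONICAL[:5])
        out = classify_outcome(parse_events(seg))
        assert out.outcome == STALL_CENSORED
        assert out.decoded_codons == 1

    def test_rotation_without_arrival_is_not_scored_at_labelled_codons(self):
        # codon 3 rotation with no red arrival in its window
        levels = CANONICAL[:7] + [("MED", 0), ("LOW", 0)]
        out = classify_outcome(parse_events(_seg(levels)))
        assert out.decoded_codons == 2

    def test_suppression_codon_scored_from_green_alone(self):
        out = classify_outcome(parse_events(_seg(CANONICAL[:7])))
        assert out.decoded_codons == 2
        assert out.decoding_dwells[2] == pytest.approx(5.0)


class TestBenchmark:
    def test_noiseless_detection_is_perfect(self, noiseless_cohort):
        res = noiseless_cohort
        rep = benchmark_detection(res.outcomes, res.truths, res.events)
        assert rep["outcome_accuracy"] == 1.0
        assert all(v == 1.0 for v in rep["event_recall"].values())
        assert all(v == 1.0 for v in rep["event_precision"].values())
        assert abs(rep["dwell_bias"]["decoding"]) <= 0.1

    def test_default_noise_outcome_accuracy(self, ut50_cohort):
        rep = benchmark_detection(ut50_cohort.outcomes, ut50_cohort.truths)
        assert rep["outcome_accuracy"] >= 0.97

    def test_empty_report(self):
        rep = benchmark_detection([], [])
        assert rep["n"] == 0

    def test_id_mismatch_raises(self, noiseless_cohort):
        with pytest.raises(ValueError):
            benchmark_detection(noiseless_cohort.outcomes, noiseless_cohort.truths[:5])

    def test_accuracy_degrades_monotonically_with_noise(self):
        preset = rt.make_preset("UTu1", 50, 1.0)
        accs = []
        for noise in (0.05, 0.12, 0.2):
            cfg = rt.EmissionConfig(noise_sd=noise)
            res = rt.run_condition(preset, 150, seed=31, emission_cfg=cfg)
            rep = benchmark_detection(res.outcomes, res.truths)
            accs.append(rep["outcome_accuracy"])
        assert accs[0] >= accs[1] >= accs[2]
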