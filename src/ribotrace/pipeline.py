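"""End-to-end helpers: simulate -> render -> detect -> classify in memory."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import (
    DetectionConfig,
    EventSequence,
    TraceOutcome,
    classify_outcome,
    parse_events,
    quantize_levels,
)
from .emission import EmissionConfig, render_trace, trace_rng
from .kinetics import CodonProgram, KineticPreset, Trajectory, default_program, sample_trajectory

__all__ = ["CohortResult", "run_condition", "analyze_traces"]


@dataclass
class CohortResult:
    """Everything the statistics layer needs about one simulated cohort."""

    preset: KineticPreset
    outcomes: list[TraceOutcome]
    truths: list[Trajectory]
    events: list[EventSequence] = field(default_factory=list)


def analyze_trace(trace, det_cfg: DetectionConfig, program: CodonProgram):
    seg = quantize_levels(trace, det_cfg)
    ev = parse_events(seg, det_cfg)
    return classify_outcome(ev, program), ev


def analyze_traces(traces, det_cfg: DetectionConfig | None = None, program=None):
    """Detect, parse and classify a collection of traces."""
    det_cfg = det_cfg or DetectionConfig()
    program = program or default_program()
    outcomes, events = [], []
    for tr in traces:
        out, ev = analyze_trace(tr, det_cfg, program)
        outcomes.append(out)
        events.append(ev)
    return outcomes, events


def run_condition(
    preset: KineticPreset,
    n: int,
    seed: int,
    emission_cfg: EmissionConfig | None = None,
    det_cfg: DetectionConfig | None = None,
    program: CodonProgram | None = None,
    keep_events: bool = False,
) -> CohortResult:
    """Simulate a cohort and push every trace through the full pipeline.

    Traces are processed one at a time so memory stays flat in ``n``.
    """
    emission_cfg = emission_cfg or EmissionConfig()
    det_cfg = det_cfg or DetectionConfig.from_emission(emission_cfg)
    program = program or default_program()
    outcomes: list[TraceOutcome] = []
    truths: list[Trajectory] = []
    events: list[EventSequence] = []
    for i in range(n):
        rng = trace_rng(seed, i)
        traj = sample_trajectory(program, preset, rng, trace_id=f"{preset.preset_id}:{i:06d}")
        trace = render_trace(traj, emission_cfg, rng=rng, seed=seed)
        out, ev = analyze_trace(trace, det_cfg, program)
        outcomes.append(out)
        truths.append(traj)
        if keep_events:
            events.append(ev)
    return CohortResult(preset=preset, outcomes=outcomes, truths=truths, events=events)
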