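"""Trace segmentation, event-grammar parsing and per-trace outcome calls.

The detector is deliberately simple and fully deterministic: a running
median tames the frame noise, frames are assigned to the nearest
calibrated level with a hysteresis margin so boundary chatter cannot
toggle levels, and segments shorter than a minimum dwell are merged into
the closer flanking level.  The resulting level sequence is then parsed
against the two-channel signal grammar of the assay: green high-to-low
marks 50S joining, low-to-medium a rotation (one per decoded codon),
medium-to-low a translocation, a return to high a 50S dissociation, a
drop to baseline a 70S dissociation or signal loss, and red unit steps
mark labelled-tRNA arrivals and departures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt

from . import kinetics as km
from .emission import EmissionConfig, Trace

__all__ = [
    "DetectionConfig",
    "Segment",
    "Segmentation",
    "Event",
    "EventSequence",
    "TraceOutcome",
    "quantize_levels",
    "ideal_segmentation",
    "parse_events",
    "classify_outcome",
    "benchmark_detection",
]

GREEN_LABELS = ("ZERO", "LOW", "MED", "HIGH")  # ascending intensity

# event types
DELIVERY = "DELIVERY"
JOIN_50S = "JOIN_50S"
TC_ARRIVAL = "TC_ARRIVAL"
ROTATION = "ROTATION"
TRANSLOCATION = "TRANSLOCATION"
TC_DEPARTURE = "TC_DEPARTURE"
DISASSEMBLY_50S = "DISASSEMBLY_50S"
DISASSEMBLY_70S = "DISASSEMBLY_70S"
SIGNAL_LOSS = "SIGNAL_LOSS"
MOVIE_END = "MOVIE_END"

# outcome labels
COMPLETED = "COMPLETED"
STALL_CENSORED = "STALL_CENSORED"
BLEACH_CENSORED = "BLEACH_CENSORED"


@dataclass(frozen=True)
class DetectionConfig:
    """Settings for level quantization and grammar parsing.

    Level centers default to the emission configuration's known values;
    set ``estimate_levels`` to re-fit them per trace by 1-D k-means for
    robustness against miscalibration.
    """

    smooth_window: int = 5
    min_dwell_frames: int = 3
    hysteresis_frac: float = 0.5
    green_centers: tuple[float, float, float, float] = (0.0, 0.15, 0.45, 1.0)  # ZERO,LOW,MED,HIGH
    red_unit: float = 0.5
    delivery_time: float = km.DELIVERY_TIME
    estimate_levels: bool = False

    @classmethod
    def from_emission(cls, cfg: EmissionConfig, **overrides) -> "DetectionConfig":
        base = dict(
            green_centers=(cfg.green_baseline, cfg.green_low, cfg.green_med, cfg.green_high),
            red_unit=cfg.red_unit,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def red_centers(self) -> tuple[float, float, float]:
        return (0.0, self.red_unit, 2.0 * self.red_unit)


@dataclass
class Segment:
    """Constant-level stretch of a trace in both channels."""

    t_start: float
    t_end: float
    green: str  # HIGH / MED / LOW / ZERO
    red: int  # 0 / 1 / 2


@dataclass
class Segmentation:
    trace_id: str
    frame_period: float
    segments: list[Segment]


def _assign_with_hysteresis(values: np.ndarray, centers: np.ndarray, frac: float) -> np.ndarray:
    """Nearest-level assignment with a hysteresis deadband.

    A frame is assigned outright only when it lies past the midpoint
    toward a level by ``frac/2`` of the inter-level gap; frames inside the
    deadband inherit the previous confident label.
    """
    order = np.argsort(centers)
    c = centers[order]
    bounds = []
    for i in range(len(c) - 1):
        gap = c[i + 1] - c[i]
        margin = 0.5 * (1.0 - frac) * gap
        bounds.append(c[i] + margin)  # end of zone i
        bounds.append(c[i + 1] - margin)  # start of zone i+1
    pos = np.searchsorted(np.asarray(bounds), values)
    zone = np.where(pos % 2 == 0, pos // 2, -1)
    if (zone < 0).any():
        # an uncertain frame inherits the previous confident label, but
        # only if that label bounds its deadband; a stale label from a
        # distant level must not survive a large jump
        idx = np.arange(len(values))
        last_ok = np.maximum.accumulate(np.where(zone >= 0, idx, -1))
        prev = np.where(last_ok >= 0, zone[np.clip(last_ok, 0, None)], -1)
        nearest = np.argmin(np.abs(values[:, None] - c[None, :]), axis=1)
        band = pos // 2  # deadband b sits between levels b and b+1
        keep = (prev == band) | (prev == band + 1)
        zone = np.where(zone >= 0, zone, np.where(keep, prev, nearest))
    return order[zone]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode ``labels`` as (start, stop, label) with stop exclusive."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(labels)]))
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def _merge_short_runs(
    labels: np.ndarray, smoothed: np.ndarray, centers: np.ndarray, min_len: int
) -> np.ndarray:
    """Merge runs shorter than ``min_len`` into the closer flanking level."""
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            return labels
        short = [
            (b - a, i) for i, (a, b, _) in enumerate(runs) if (b - a) < min_len
        ]
        if not short:
            return labels
        _, i = min(short)
        a, b, _ = runs[i]
        seg_mean = float(smoothed[a:b].mean())
        candidates = []
        if i > 0:
            candidates.append(runs[i - 1][2])
        if i + 1 < len(runs):
            candidates.append(runs[i + 1][2])
        new = min(candidates, key=lambda lab: abs(centers[lab] - seg_mean))
        labels[a:b] = new


def _quantize_channel(
    values: np.ndarray, centers: np.ndarray, cfg: DetectionConfig
) -> np.ndarray:
    if len(values) < cfg.smooth_window:
        raise ValueError("trace shorter than the smoothing window")
    win = cfg.smooth_window
    smoothed = medfilt(values, kernel_size=win if win % 2 == 1 else win + 1)
    if cfg.estimate_levels:
        centers = _refit_centers(smoothed, centers)
    labels = _assign_with_hysteresis(smoothed, centers, cfg.hysteresis_frac)
    return _merge_short_runs(labels, smoothed, centers, cfg.min_dwell_frames)


def _refit_centers(values: np.ndarray, init: np.ndarray) -> np.ndarray:
    """Per-trace 1-D k-means refinement of the level centers.

    Plain Lloyd iterations seeded at the calibrated centers; a level with
    no assigned frames keeps its initial center.
    """
    centers = init.astype(float).copy()
    for _ in range(25):
        lab = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(len(centers)):
            sel = values[lab == j]
            if len(sel):
                new[j] = sel.mean()
        if np.allclose(new, centers, atol=1e-6):
            break
        centers = new
    return centers


def quantize_levels(trace: Trace, cfg: DetectionConfig | None = None) -> Segmentation:
    """Segment a noisy two-channel trace into discrete levels.

    Runs per-channel median smoothing, hysteresis level assignment and
    short-segment merging, then combines the two channels on the union of
    their breakpoints.
    """
    cfg = cfg or DetectionConfig()
    fp = float(trace.times[1] - trace.times[0]) if len(trace.times) > 1 else 0.1
    g_lab = _quantize_channel(np.asarray(trace.green, float), np.asarray(cfg.green_centers), cfg)
    r_lab = _quantize_channel(np.asarray(trace.red, float), np.asarray(cfg.red_centers), cfg)
    combined = g_lab * 10 + r_lab
    segs = []
    for a, b, _ in _runs(combined):
        segs.append(
            Segment(
                t_start=a * fp,
                t_end=b * fp,
                green=GREEN_LABELS[g_lab[a]],
                red=int(r_lab[a]),
            )
        )
    return Segmentation(trace_id=trace.trace_id, frame_period=fp, segments=segs)


_STATE_TO_GREEN = {
    km.PIC: "HIGH",
    km.DIS_50S: "HIGH",
    km.NONROT: "LOW",
    km.STALLED: "LOW",
    km.ROT: "MED",
    km.DIS_70S: "ZERO",
    km.BLEACHED: "ZERO",
}


def ideal_segmentation(
    traj: km.Trajectory, frame_period: float | None = 0.1
) -> Segmentation:
    """Ground-truth level sequence implied by a trajectory.

    Applies the same state-to-level mapping as the renderer (including
    the red-bleach cut) and optionally rounds breakpoints to the frame
    grid, so it is directly comparable with a detected segmentation.
    """
    bleach = traj.red_bleach_time

    def snap(t: float) -> float:
        return round(t / frame_period) * frame_period if frame_period else t

    raw: list[Segment] = []
    for iv in traj.intervals:
        pieces = [(iv.t_start, iv.t_end, iv.cy5_count)]
        if bleach is not None and iv.t_start < bleach < iv.t_end:
            pieces = [(iv.t_start, bleach, iv.cy5_count), (bleach, iv.t_end, 0)]
        elif bleach is not None and iv.t_start >= bleach:
            pieces = [(iv.t_start, iv.t_end, 0)]
        for a, b, cy5 in pieces:
            raw.append(Segment(snap(a), snap(b), _STATE_TO_GREEN[iv.state], int(min(cy5, 2))))
    merged: list[Segment] = []
    for seg in raw:
        if seg.t_end <= seg.t_start:
            continue
        if merged and merged[-1].green == seg.green and merged[-1].red == seg.red:
            merged[-1].t_end = seg.t_end
        else:
            if merged:
                seg.t_start = merged[-1].t_end
            merged.append(seg)
    return Segmentation(trace_id=traj.trace_id, frame_period=frame_period or 0.0, segments=merged)


@dataclass(frozen=True)
class Event:
    type: str
    time: float
    codon: int | None = None


@dataclass
class EventSequence:
    trace_id: str
    events: list[Event]
    anomalous_from: float | None = None

    def of_type(self, etype: str) -> list[Event]:
        return [e for e in self.events if e.type == etype]


def _remove_terminal_artifacts(segs: list[Segment]) -> list[Segment]:
    """Enforce absorbing terminal signatures; reject blinks and flickers.

    Disassembly and bleaching are irreversible: a drop to baseline (or a
    dequench to high after joining) followed later by translation-level
    signal is physically inconsistent.  For each such conflicting pair of
    adjacent green runs, the shorter run is the artifact — a sub-second
    dark blink inside an active phase, or a noise flicker inside a long
    dark tail — and is relabelled to the other's level.
    """
    while True:
        runs: list[tuple[int, int]] = []  # (first segment idx, last segment idx)
        for i, s in enumerate(segs):
            if runs and segs[runs[-1][0]].green == s.green:
                runs[-1] = (runs[-1][0], i)
            else:
                runs.append((i, i))
        changed = False
        for r in range(len(runs) - 1):
            a0, a1 = runs[r]
            b0, b1 = runs[r + 1]
            ga, gb = segs[a0].green, segs[b0].green
            conflict = (ga == "ZERO") or (ga == "HIGH" and r > 0 and gb in ("LOW", "MED"))
            if not conflict:
                continue
            dur_a = segs[a1].t_end - segs[a0].t_start
            dur_b = segs[b1].t_end - segs[b0].t_start
            if dur_a < dur_b:
                for i in range(a0, a1 + 1):
                    segs[i].green = gb
            else:
                for i in range(b0, b1 + 1):
                    segs[i].green = ga
            changed = True
            break
        if not changed:
            return segs
        merged: list[Segment] = []
        for s in segs:
            if merged and merged[-1].green == s.green and merged[-1].red == s.red:
                merged[-1].t_end = s.t_end
            else:
                merged.append(s)
        segs = merged


def parse_events(seg: Segmentation, cfg: DetectionConfig | None = None) -> EventSequence:
    """Parse a segmentation against the assay's signal grammar.

    The mapping is deterministic; a level transition that the grammar
    does not allow truncates parsing at the last consistent event, with
    the remainder marked anomalous rather than raising.
    """
    cfg = cfg or DetectionConfig()
    segs = _remove_terminal_artifacts([Segment(s.t_start, s.t_end, s.green, s.red) for s in seg.segments])
    events: list[Event] = [Event(DELIVERY, cfg.delivery_time)]
    joined = False
    in_rot = False
    codon = 0
    terminal = False
    anomalous_from: float | None = None

    for i in range(1, len(segs)):
        prev, cur = segs[i - 1], segs[i]
        t = cur.t_start
        if cur.red != prev.red:
            if cur.red > prev.red:
                events.append(Event(TC_ARRIVAL, t, codon + 1))
            else:
                events.append(Event(TC_DEPARTURE, t))
        g0, g1 = prev.green, cur.green
        if g1 == g0:
            continue
        if g1 == "ZERO":
            red_coterminates = prev.red > 0 and cur.red == 0
            if red_coterminates or g0 in ("LOW", "MED"):
                events.append(Event(DISASSEMBLY_70S, t))
            else:
                events.append(Event(SIGNAL_LOSS, t))
            terminal = True
        elif g0 == "HIGH" and g1 == "LOW" and not joined:
            events.append(Event(JOIN_50S, t))
            joined = True
        elif g0 == "LOW" and g1 == "MED" and joined and not in_rot:
            codon += 1
            events.append(Event(ROTATION, t, codon))
            in_rot = True
        elif g0 == "MED" and g1 == "LOW" and in_rot:
            events.append(Event(TRANSLOCATION, t, codon))
            in_rot = False
        elif g0 in ("LOW", "MED") and g1 == "HIGH" and joined:
            events.append(Event(DISASSEMBLY_50S, t))
            terminal = True
        else:
            anomalous_from = t
            break
        if terminal:
            # any later level change is anomalous (at most one terminal
            # event), except within a short grace window: the red dye of a
            # departing complex may lag the green signature by a frame
            grace = 2 * seg.frame_period
            for j in range(i + 1, len(segs)):
                a, b = segs[j - 1], segs[j]
                if (a.green != b.green or a.red != b.red) and b.t_start - t > grace:
                    anomalous_from = b.t_start
                    break
            break

    if not terminal and anomalous_from is None and segs:
        events.append(Event(MOVIE_END, segs[-1].t_end))
    return EventSequence(trace_id=seg.trace_id, events=events, anomalous_from=anomalous_from)


@dataclass
class TraceOutcome:
    """Per-trace classification and dwell table."""

    trace_id: str
    decoded_codons: int
    outcome: str
    disassembly_phase: str  # none / pre_translocation / post_translocation
    decoding_dwells: dict[int, float]
    rotated_dwells: dict[int, float]
    disassembly_dwell: float | None
    anomalous: bool = False

    def to_record(self) -> dict:
        rec = {
            "trace_id": self.trace_id,
            "decoded_codons": self.decoded_codons,
            "outcome": self.outcome,
            "disassembly_phase": self.disassembly_phase,
            "disassembly_dwell": self.disassembly_dwell,
            "anomalous": self.anomalous,
        }
        for k, v in sorted(self.decoding_dwells.items()):
            rec[f"decoding_dwell_{k}"] = v
        for k, v in sorted(self.rotated_dwells.items()):
            rec[f"rotated_dwell_{k}"] = v
        return rec


def classify_outcome(
    evseq: EventSequence, program: km.CodonProgram | None = None
) -> TraceOutcome:
    """Classify a parsed event sequence into a per-trace outcome.

    A rotation at a dye-labelled codon is accepted only if a labelled-tRNA
    arrival fell inside that codon's non-rotated window (the suppression
    codon is scored from the green channel alone, its tRNA being dark).
    The disassembly phase is read from the state the signature fired
    from: a rotated state means pre-translocation, a non-rotated state
    post-translocation.
    """
    program = program or km.default_program()
    events = evseq.events
    join = next((e for e in events if e.type == JOIN_50S), None)
    rot = {e.codon: e.time for e in events if e.type == ROTATION}
    trans = {e.codon: e.time for e in events if e.type == TRANSLOCATION}
    arrivals = [e.time for e in events if e.type == TC_ARRIVAL]

    decoded = 0
    decoding_dwells: dict[int, float] = {}
    rotated_dwells: dict[int, float] = {}
    if join is not None:
        for k in range(1, len(program) + 1):
            if k not in rot:
                break
            window_start = trans.get(k - 1, join.time) if k > 1 else join.time
            if program[k - 1].dye_labeled and not any(
                window_start < a <= rot[k] for a in arrivals
            ):
                break
            decoded = k
            decoding_dwells[k] = rot[k] - window_start
            if k in trans:
                rotated_dwells[k] = trans[k] - rot[k]

    dis = next(
        (e for e in events if e.type in (DISASSEMBLY_50S, DISASSEMBLY_70S)), None
    )
    phase = "none"
    dis_dwell = None
    if dis is not None:
        last_rot = max((t for t in rot.values() if t < dis.time), default=None)
        last_trans = max((t for t in trans.values() if t < dis.time), default=None)
        if last_rot is not None and (last_trans is None or last_rot > last_trans):
            phase = "pre_translocation"
        else:
            phase = "post_translocation"
            ref = last_trans if last_trans is not None else (join.time if join else None)
            if ref is not None:
                dis_dwell = dis.time - ref

    if decoded == len(program):
        outcome = COMPLETED
        phase = "none"
        dis_dwell = None
    elif dis is not None:
        outcome = dis.type
    elif any(e.type == SIGNAL_LOSS for e in events):
        outcome = BLEACH_CENSORED
    else:
        outcome = STALL_CENSORED

    return TraceOutcome(
        trace_id=evseq.trace_id,
        decoded_codons=decoded,
        outcome=outcome,
        disassembly_phase=phase if outcome in (DISASSEMBLY_50S, DISASSEMBLY_70S) else "none",
        decoding_dwells=decoding_dwells,
        rotated_dwells=rotated_dwells,
        disassembly_dwell=dis_dwell if outcome in (DISASSEMBLY_50S, DISASSEMBLY_70S) else None,
        anomalous=evseq.anomalous_from is not None,
    )


_TRUTH_TO_OUTCOME = {
    "COMPLETED": COMPLETED,
    km.DIS_50S: DISASSEMBLY_50S,
    km.DIS_70S: DISASSEMBLY_70S,
    km.STALLED: STALL_CENSORED,
    "CENSORED_END": STALL_CENSORED,
    km.BLEACHED: BLEACH_CENSORED,
}


def expected_outcome(traj: km.Trajectory) -> str:
    """Detection-vocabulary outcome implied by a ground-truth trajectory."""
    return _TRUTH_TO_OUTCOME[traj.outcome_truth]


def benchmark_detection(
    outcomes: list[TraceOutcome],
    truths: list[km.Trajectory],
    events: list[EventSequence] | None = None,
    frame_period: float = 0.1,
    time_tol: float = 0.3,
) -> dict:
    """Compare detected outcomes with paired ground truth.

    Matches traces by id; events are compared against the event sequence
    implied by each trajectory's ideal level sequence, matched greedily
    by type within ``time_tol`` seconds.  Returns a JSON-serializable
    report with per-type recall/precision, an outcome confusion matrix,
    and dwell biases.
    """
    if not outcomes and not truths:
        return {
            "n": 0,
            "outcome_accuracy": None,
            "confusion": {},
            "event_recall": {},
            "event_precision": {},
            "dwell_bias": {},
        }
    by_id = {t.trace_id: t for t in truths}
    if set(o.trace_id for o in outcomes) - set(by_id):
        raise ValueError("detected outcomes contain trace ids absent from the truth log")
    events_by_id = {e.trace_id: e for e in events} if events else {}

    confusion: dict[str, dict[str, int]] = {}
    n_correct = 0
    tp: dict[str, int] = {}
    fn: dict[str, int] = {}
    fp: dict[str, int] = {}
    decode_errors = []
    dec_bias = []
    dis_bias = []

    for out in outcomes:
        traj = by_id[out.trace_id]
        truth_out = expected_outcome(traj)
        confusion.setdefault(truth_out, {}).setdefault(out.outcome, 0)
        confusion[truth_out][out.outcome] += 1
        if out.outcome == truth_out:
            n_correct += 1
        decode_errors.append(out.decoded_codons - traj.last_codon_truth)

        det_ev = events_by_id.get(out.trace_id)
        if det_ev is not None:
            truth_ev = parse_events(ideal_segmentation(traj, frame_period))
            _match_events(truth_ev.events, det_ev.events, time_tol, tp, fn, fp)

        truth_decoding = _truth_decoding_dwells(traj)
        for k, v in out.decoding_dwells.items():
            if k in truth_decoding:
                dec_bias.append(v - truth_decoding[k])
        truth_dis = _truth_disassembly_dwell(traj)
        if out.disassembly_dwell is not None and truth_dis is not None:
            dis_bias.append(out.disassembly_dwell - truth_dis)

    types = sorted(set(tp) | set(fn) | set(fp))
    recall = {
        t: tp.get(t, 0) / max(tp.get(t, 0) + fn.get(t, 0), 1) for t in types
    }
    precision = {
        t: tp.get(t, 0) / max(tp.get(t, 0) + fp.get(t, 0), 1) for t in types
    }
    return {
        "n": len(outcomes),
        "outcome_accuracy": n_correct / len(outcomes) if outcomes else None,
        "confusion": confusion,
        "event_recall": recall,
        "event_precision": precision,
        "decoded_codon_mean_abs_error": float(np.mean(np.abs(decode_errors))) if decode_errors else None,
        "dwell_bias": {
            "decoding": float(np.mean(dec_bias)) if dec_bias else None,
            "disassembly": float(np.mean(dis_bias)) if dis_bias else None,
        },
    }


def _match_events(truth, detected, tol, tp, fn, fp):
    used = [False] * len(detected)
    for te in truth:
        hit = None
        for j, de in enumerate(detected):
            if not used[j] and de.type == te.type and abs(de.time - te.time) <= tol:
                hit = j
                break
        if hit is None:
            fn[te.type] = fn.get(te.type, 0) + 1
        else:
            used[hit] = True
            tp[te.type] = tp.get(te.type, 0) + 1
    for j, de in enumerate(detected):
        if not used[j]:
            fp[de.type] = fp.get(de.type, 0) + 1


def _truth_decoding_dwells(traj: km.Trajectory) -> dict[int, float]:
    """Per-codon non-rotated residence from the ground-truth intervals."""
    dwells: dict[int, float] = {}
    for iv in traj.intervals:
        if iv.state == km.NONROT and iv.codon is not None:
            dwells[iv.codon] = dwells.get(iv.codon, 0.0) + (iv.t_end - iv.t_start)
    # the trailing idle interval after the last codon is not a decoding dwell
    rotated = {iv.codon for iv in traj.intervals if iv.state == km.ROT}
    return {k: v for k, v in dwells.items() if k in rotated}


def _truth_disassembly_dwell(traj: km.Trajectory) -> float | None:
    ivs = traj.intervals
    for i, iv in enumerate(ivs):
        if iv.state in (km.DIS_50S, km.DIS_70S) and i > 0 and ivs[i - 1].state == km.NONROT:
            return ivs[i - 1].t_end - ivs[i - 1].t_start
    return None
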