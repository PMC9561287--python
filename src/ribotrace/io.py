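"""Dataset layout: per-trace CSV files, a JSON manifest, a JSONL truth log.

A dataset directory contains::

    manifest.json          trace_id -> file, preset, seed; config hashes
    truth.jsonl            one ground-truth record per trace
    traces/<trace_id>.csv  columns time_s, green, red

External traces can be analysed by providing the same layout.  An
optional single-file HDF5 container (one group per trace, same fields)
is supported for compactness.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import TraceOutcome
from .emission import EmissionConfig, Trace
from .kinetics import Interval, Trajectory

__all__ = [
    "write_dataset",
    "read_manifest",
    "read_trace",
    "iter_traces",
    "read_truth_log",
    "write_outcomes",
    "read_outcomes",
]


def _traj_record(traj: Trajectory) -> dict:
    return {
        "trace_id": traj.trace_id,
        "preset_id": traj.preset_id,
        "outcome_truth": traj.outcome_truth,
        "last_codon_truth": traj.last_codon_truth,
        "red_bleach_time": traj.red_bleach_time,
        "green_bleach_time": traj.green_bleach_time,
        "intervals": [iv.to_record() for iv in traj.intervals],
    }


def trajectory_from_record(rec: dict) -> Trajectory:
    return Trajectory(
        trace_id=rec["trace_id"],
        preset_id=rec["preset_id"],
        intervals=[
            Interval(r["state"], r["codon"], r["t_start"], r["t_end"], r["cy5_count"])
            for r in rec["intervals"]
        ],
        outcome_truth=rec["outcome_truth"],
        last_codon_truth=rec["last_codon_truth"],
        red_bleach_time=rec.get("red_bleach_time"),
        green_bleach_time=rec.get("green_bleach_time"),
    )


def write_dataset(
    out_dir: str | Path,
    traces: list[Trace],
    truths: list[Trajectory],
    cfg: EmissionConfig,
    seed: int,
    preset_id: str,
    provenance: dict | None = None,
) -> Path:
    """Write traces, manifest and truth log; returns the dataset directory."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    entries = {}
    for tr in traces:
        fname = f"traces/{tr.trace_id.replace(':', '_').replace('/', '_')}.csv"
        df = pd.DataFrame({"time_s": tr.times, "green": tr.green, "red": tr.red})
        df.to_csv(out / fname, index=False, float_format="%.6g")
        entries[tr.trace_id] = {"file": fname, "preset": tr.preset_id, "seed": tr.seed}
    manifest = {
        "preset_id": preset_id,
        "seed": seed,
        "n_traces": len(traces),
        "emission": dataclasses.asdict(cfg),
        "emission_hash": cfg.config_hash(),
        "traces": entries,
    }
    if provenance:
        manifest["provenance"] = provenance
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "truth.jsonl", "w") as fh:
        for traj in truths:
            fh.write(json.dumps(_traj_record(traj)) + "\n")
    return out


def read_manifest(dataset_dir: str | Path) -> dict:
    path = Path(dataset_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no dataset manifest at {path}")
    with open(path) as fh:
        return json.load(fh)


def read_trace(dataset_dir: str | Path, trace_id: str, manifest: dict | None = None) -> Trace:
    manifest = manifest or read_manifest(dataset_dir)
    entry = manifest["traces"][trace_id]
    df = pd.read_csv(Path(dataset_dir) / entry["file"])
    return Trace(
        trace_id=trace_id,
        preset_id=entry["preset"],
        times=df["time_s"].to_numpy(),
        green=df["green"].to_numpy(),
        red=df["red"].to_numpy(),
        seed=entry.get("seed"),
        emission_hash=manifest.get("emission_hash", ""),
    )


def iter_traces(dataset_dir: str | Path):
    """Yield traces in manifest order; missing files are collected and reported."""
    manifest = read_manifest(dataset_dir)
    missing = [
        tid
        for tid, e in manifest["traces"].items()
        if not (Path(dataset_dir) / e["file"]).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"dataset is missing {len(missing)} trace file(s): {', '.join(sorted(missing)[:10])}"
        )
    for tid in manifest["traces"]:
        yield read_trace(dataset_dir, tid, manifest)


def read_truth_log(dataset_dir: str | Path) -> list[Trajectory]:
    path = Path(dataset_dir) / "truth.jsonl"
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(trajectory_from_record(json.loads(line)))
    return out


def write_outcomes(path: str | Path, outcomes: list[TraceOutcome]) -> None:
    """Outcomes as JSON-lines plus a tidy CSV next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [o.to_record() for o in outcomes]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    pd.DataFrame(records).to_csv(path.with_suffix(".csv"), index=False)


def read_outcomes(path: str | Path) -> list[TraceOutcome]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            decoding = {
                int(k.rsplit("_", 1)[1]): v
                for k, v in rec.items()
                if k.startswith("decoding_dwell_") and v is not None
            }
            rotated = {
                int(k.rsplit("_", 1)[1]): v
                for k, v in rec.items()
                if k.startswith("rotated_dwell_") and v is not None
            }
            out.append(
                TraceOutcome(
                    trace_id=rec["trace_id"],
                    decoded_codons=rec["decoded_codons"],
                    outcome=rec["outcome"],
                    disassembly_phase=rec["disassembly_phase"],
                    decoding_dwells=decoding,
                    rotated_dwells=rotated,
                    disassembly_dwell=rec.get("disassembly_dwell"),
                    anomalous=rec.get("anomalous", False),
                )
            )
    return out
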