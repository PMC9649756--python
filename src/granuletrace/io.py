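"""Reading and writing the pipeline's on-disk formats.

Traces travel as CSV (frame, time_s, spot_intensity, background_intensity
[, s_true]); tracks as CSV (track_id, frame, x, y) with x = column and
y = row, 0-based; events as CSV; schedules, configs and fit/normalization
reports as JSON; image stacks as multi-page TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from granuletrace.bursts import BurstEvent, BurstThresholds
from granuletrace.imaging import SpotTrack
from granuletrace.signals import IntensityTrace
from granuletrace.synthetic import (
    FrameStack,
    GroundTruthSchedule,
    ScheduledEvent,
    TraceRenderConfig,
)

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_events_csv",
    "read_events_csv",
    "write_schedule_json",
    "read_schedule_json",
    "read_render_config_json",
    "write_json",
    "write_stack_tiff",
    "read_stack_tiff",
]


def write_trace_csv(trace: IntensityTrace, path: str | Path) -> None:
    data = {
        "frame": np.arange(len(trace)),
        "time_s": trace.time_s,
        "spot_intensity": trace.y_raw,
        "background_intensity": trace.c_raw,
    }
    if trace.s_true is not None:
        data["s_true"] = trace.s_true
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace_csv(path: str | Path, channel: str = "") -> IntensityTrace:
    df = pd.read_csv(path)
    return IntensityTrace(
        time_s=df["time_s"].to_numpy(),
        y_raw=df["spot_intensity"].to_numpy(),
        c_raw=df["background_intensity"].to_numpy(),
        channel=channel,
        s_true=df["s_true"].to_numpy() if "s_true" in df else None,
    )


def write_tracks_csv(tracks: list[SpotTrack], path: str | Path) -> None:
    rows = [
        {"track_id": tr.track_id, "frame": t, "x": c, "y": r}
        for tr in tracks
        for r, c, t in tr.points
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"]).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[SpotTrack]:
    df = pd.read_csv(path).sort_values(["track_id", "frame"])
    tracks = []
    for tid, grp in df.groupby("track_id"):
        points = [(float(y), float(x), int(f)) for f, x, y in zip(grp["frame"], grp["x"], grp["y"])]
        tracks.append(SpotTrack(track_id=int(tid), points=points))
    return tracks


def write_events_csv(
    events_by_trace: dict[str, list[BurstEvent]], path: str | Path
) -> None:
    rows = [
        {
            "trace_id": tid,
            "direction": e.direction,
            "start_frame": e.start_index,
            "end_frame": e.end_index,
            "amplitude": e.amplitude,
            "duration_s": e.duration_s,
        }
        for tid, events in events_by_trace.items()
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=["trace_id", "direction", "start_frame", "end_frame", "amplitude", "duration_s"],
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> dict[str, list[BurstEvent]]:
    df = pd.read_csv(path)
    out: dict[str, list[BurstEvent]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.trace_id), []).append(
            BurstEvent(
                direction=row.direction,
                start_index=int(row.start_frame),
                end_index=int(row.end_frame),
                amplitude=float(row.amplitude),
                duration_s=float(row.duration_s),
            )
        )
    return out


def write_schedule_json(schedule: GroundTruthSchedule, path: str | Path) -> None:
    payload = {
        "duration_s": schedule.duration_s,
        "seed": schedule.seed,
        "initial_content": schedule.initial_content,
        "events": [
            {"time_s": e.time_s, "direction": e.direction, "amplitude": e.amplitude}
            for e in schedule.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule_json(path: str | Path) -> GroundTruthSchedule:
    payload = json.loads(Path(path).read_text())
    return GroundTruthSchedule(
        events=[ScheduledEvent(**e) for e in payload["events"]],
        duration_s=payload["duration_s"],
        seed=payload["seed"],
        initial_content=payload.get("initial_content", 0.0),
    )


def read_render_config_json(path: str | Path) -> TraceRenderConfig:
    payload = json.loads(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(TraceRenderConfig)}
    return TraceRenderConfig(**{k: v for k, v in payload.items() if k in fields})


def write_json(payload: dict, path: str | Path) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))


def thresholds_to_dict(th: BurstThresholds) -> dict:
    return dataclasses.asdict(th)


def write_stack_tiff(stack: FrameStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32))


def read_stack_tiff(path: str | Path, frame_interval_s: float) -> FrameStack:
    return FrameStack(frames=tifffile.imread(path), frame_interval_s=frame_interval_s)
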