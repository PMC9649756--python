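"""Spot detection, linking and sub-frame trace extraction from image stacks.

For every tracked bright spot, a 14x14 pixel sub-frame centered on the
centroid is classified by two-threshold (three-class) Otsu into spot region,
cell background and dark background; the per-frame means of the spot-region
and cell-background classes form the paired intensity trace the rest of the
pipeline consumes.  A simple greedy nearest-neighbour detector/linker is
provided for stacks without externally computed tracks.

Conventions: coordinates are 0-based (row, col) with pixel centers at
integers; the 14-px sub-frame has its top-left corner at the rounded
centroid minus (7, 7); spots within 7 px of a border are skipped per frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label

from granuletrace.synthetic import FrameStack

__all__ = [
    "SpotTrack",
    "SubframeClassification",
    "detect_spots",
    "link_tracks",
    "classify_subframe",
    "extract_trace",
    "measure_spot_area",
]

DARK_BACKGROUND = 0
CELL_BACKGROUND = 1
SPOT_REGION = 2


@dataclass
class SpotTrack:
    """One spot followed through time: (row, col, frame) points."""

    track_id: int
    points: list[tuple[float, float, int]]

    def __post_init__(self) -> None:
        frames = [t for _, _, t in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing within a track")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SubframeClassification:
    """Three-class Otsu labelling of one sub-frame.

    labels: 0 = dark background, 1 = cell background, 2 = spot region.
    """

    labels: np.ndarray
    thresholds: tuple[float, float]
    degenerate: bool = False


def detect_spots(
    frame: np.ndarray,
    top_fraction: float = 0.10,
    min_separation: float = 5.0,
) -> list[tuple[float, float]]:
    """Find bright-spot centroids in a single frame.

    Local intensity maxima at least ``min_separation`` px apart are
    candidates; of these, only the brightest ``top_fraction`` (by peak
    intensity, default the top 10%) are kept, and each is refined to the
    intensity-weighted centroid of its local neighbourhood.  Candidates not
    exceeding the frame median are treated as background plateaus and
    dropped, so a uniform frame yields no spots.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame must be non-empty")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if np.ptp(frame) == 0:
        return []

    coords = peak_local_max(
        frame, min_distance=max(1, int(np.ceil(min_separation))), exclude_border=False
    )
    if len(coords) == 0:
        return []
    values = frame[coords[:, 0], coords[:, 1]]
    above = values > np.median(frame)
    coords, values = coords[above], values[above]
    if len(coords) == 0:
        return []
    cutoff = np.quantile(values, 1.0 - top_fraction)
    keep = values >= cutoff
    coords = coords[keep]

    radius = 3
    centroids: list[tuple[float, float]] = []
    for r, c in coords:
        r0, r1 = max(0, r - radius), min(frame.shape[0], r + radius + 1)
        c0, c1 = max(0, c - radius), min(frame.shape[1], c + radius + 1)
        window = frame[r0:r1, c0:c1]
        weights = window - window.min()
        total = weights.sum()
        if total == 0:
            centroids.append((float(r), float(c)))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centroids.append(
            (float((weights * rr).sum() / total), float((weights * cc).sum() / total))
        )
    centroids.sort()
    return centroids


def link_tracks(
    frame_centroids: list[list[tuple[float, float]]],
    max_displacement: float,
) -> list[SpotTrack]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Pairs are matched in order of increasing distance (ties broken by lower
    (row, col)); a spot with no match within ``max_displacement`` terminates
    its track, and unmatched detections start new tracks.
    """
    if max_displacement <= 0:
        raise ValueError(f"max_displacement must be > 0, got {max_displacement}")
    tracks: list[SpotTrack] = []
    active: dict[int, tuple[float, float]] = {}  # track index -> last position
    next_id = 0
    for t, centroids in enumerate(frame_centroids):
        pairs = []
        for ti, (pr, pc) in active.items():
            for ci, (r, c) in enumerate(centroids):
                d = float(np.hypot(r - pr, c - pc))
                if d <= max_displacement:
                    pairs.append((d, (r, c), ti, ci))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        new_active: dict[int, tuple[float, float]] = {}
        for d, _, ti, ci in pairs:
            if ti in used_tracks or ci in used_spots:
                continue
            used_tracks.add(ti)
            used_spots.add(ci)
            r, c = centroids[ci]
            tracks[ti].points.append((r, c, t))
            new_active[ti] = (r, c)
        for ci, (r, c) in enumerate(centroids):
            if ci in used_spots:
                continue
            tracks.append(SpotTrack(track_id=next_id, points=[(r, c, t)]))
            new_active[len(tracks) - 1] = (r, c)
            next_id += 1
        active = new_active
    return tracks


def classify_subframe(subframe: np.ndarray) -> SubframeClassification:
    """Three-class Otsu classification of a sub-frame.

    The brightest class is the spot region, the middle class the cell
    background and the dimmest the dark background.  A sub-frame with all
    pixels equal has no defined classes and is flagged degenerate (all
    pixels labelled cell background); one with only two distinct levels
    falls back to a single Otsu threshold (no dark-background class).
    """
    subframe = np.asarray(subframe, dtype=float)
    if np.ptp(subframe) == 0:
        return SubframeClassification(
            labels=np.full(subframe.shape, CELL_BACKGROUND, dtype=int),
            thresholds=(float(subframe.flat[0]), float(subframe.flat[0])),
            degenerate=True,
        )
    try:
        t1, t2 = threshold_multiotsu(subframe, classes=3)
    except ValueError:
        # fewer than three distinct grey levels
        t = float(threshold_otsu(subframe))
        labels = np.where(subframe > t, SPOT_REGION, CELL_BACKGROUND)
        return SubframeClassification(labels=labels, thresholds=(t, t))
    labels = np.digitize(subframe, bins=[t1, t2])
    return SubframeClassification(labels=labels, thresholds=(float(t1), float(t2)))


def extract_trace(
    stack: FrameStack,
    track: SpotTrack,
    subframe_width: int = 14,
):
    """Build the paired spot/background trace of one track from a stack.

    Per frame, the sub-frame around the centroid is Otsu-classified and the
    means of the spot-region and cell-background pixels become the spot and
    background values.  Frames whose sub-frame does not fit inside the image
    are skipped with a warning; degenerate (uniform) sub-frames contribute
    the uniform value to both channels and are flagged.
    """
    half = subframe_width // 2
    frames = stack.frames
    n_t, n_r, n_c = frames.shape
    times, ys, cs, degenerate = [], [], [], []
    skipped = 0
    for row, col, t in track.points:
        r0 = int(round(row)) - half
        c0 = int(round(col)) - half
        if t < 0 or t >= n_t or r0 < 0 or c0 < 0 or r0 + subframe_width > n_r or c0 + subframe_width > n_c:
            skipped += 1
            continue
        sub = frames[t, r0 : r0 + subframe_width, c0 : c0 + subframe_width]
        cls = classify_subframe(sub)
        if cls.degenerate:
            value = float(sub.flat[0])
            degenerate.append(len(times))
            ys.append(value)
            cs.append(value)
        else:
            spot = sub[cls.labels == SPOT_REGION]
            cell = sub[cls.labels == CELL_BACKGROUND]
            ys.append(float(spot.mean()) if spot.size else float(sub.max()))
            cs.append(float(cell.mean()) if cell.size else float(sub.min()))
        times.append(t * stack.frame_interval_s)
    if skipped:
        warnings.warn(
            f"track {track.track_id}: {skipped} frame(s) skipped (sub-frame outside image)",
            stacklevel=2,
        )
    from granuletrace.signals import IntensityTrace

    return IntensityTrace(
        time_s=np.asarray(times),
        y_raw=np.asarray(ys),
        c_raw=np.asarray(cs),
        channel=f"track-{track.track_id}",
        degenerate_frames=degenerate,
    )


def measure_spot_area(classification: SubframeClassification) -> int:
    """Area (pixels) of the largest 8-connected spot-region component."""
    mask = classification.labels == SPOT_REGION
    if not mask.any():
        return 0
    labelled = cc_label(mask, connectivity=2)
    return int(np.bincount(labelled.ravel())[1:].max())
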