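"""Run-length burst detection on normalized granule traces.

A burst is a sustained, statistically significant rise (entry of a
nucleoprotein complex) or fall (shedding) in the extracted signal S(t).
Under a null of symmetric memory-less noise, the chance that an increment is
positive is p_inc (estimated per trace); a run of m consecutive positive
increments then has probability p_inc**m, and requiring this to be at most
2**-10 ("1 in 1000") gives the run-length threshold

    m = -10 / log2(p_inc)

(and analogously for decrements with p_dec).  Because the moving-average
smoothing correlates nearby increments, thresholds below the smoothing
window span are raised to the span.  An isolated reversal — one opposing or
zero increment flanked by same-direction increments — does not break a run,
but at most one such interruption is tolerated per run and it does not
count toward m (m counts same-direction increments only); this keeps the
null probability of a spurious run at or below the 1-in-1000 level, which a
more permissive bridging rule would inflate by an order of magnitude.  Runs
meeting their threshold become positive/negative events; spans between
significant events are recorded as unclassified, and the trace outside the
first/last significant event is discarded as unclassifiable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BurstThresholds",
    "BurstEvent",
    "compute_step_probabilities",
    "compute_thresholds",
    "segment_trace",
    "detect_bursts",
    "inter_event_intervals",
]

POSITIVE = "positive"
NEGATIVE = "negative"
UNCLASSIFIED = "unclassified"

#: run-probability null: one in 2**10 ("1 in 1000")
DEFAULT_ALPHA = 2.0**-10


@dataclass
class BurstThresholds:
    """Per-trace step statistics and enforced run-length thresholds.

    ``m_inc_raw``/``m_dec_raw`` are the unrounded -10/log2(p) values before
    the minimum-threshold rule; ``m_inc``/``m_dec`` are the enforced
    integer thresholds actually used (may be ``inf`` when p = 0).
    """

    p_inc: float
    p_dec: float
    n_tot: int
    m_inc: float
    m_dec: float
    min_span: int
    m_inc_raw: float
    m_dec_raw: float


@dataclass
class BurstEvent:
    """One classified trace segment.

    ``start_index``/``end_index`` are frame indices into S; the amplitude is
    the endpoint difference S[end] - S[start] on the normalized signal.
    """

    direction: str
    start_index: int
    end_index: int
    amplitude: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")


def compute_step_probabilities(s: np.ndarray) -> tuple[float, float, int]:
    """Empirical probabilities of instantaneous increases and decreases.

    Increments are dS(t_i) = S(t_i) - S(t_{i-1}); NaN-adjacent increments
    are excluded.  Zero increments count in the total but in neither
    direction, so p_inc + p_dec <= 1.
    """
    s = np.asarray(s, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 points to form increments")
    ds = np.diff(s)
    ds = ds[np.isfinite(ds)]
    n_tot = len(ds)
    if n_tot == 0:
        return 0.0, 0.0, 0
    p_inc = float(np.sum(ds > 0)) / n_tot
    p_dec = float(np.sum(ds < 0)) / n_tot
    return p_inc, p_dec, n_tot


def compute_thresholds(
    p_inc: float, p_dec: float, min_span: int = 13, alpha: float = DEFAULT_ALPHA
) -> BurstThresholds:
    """Run-length thresholds from per-trace step probabilities.

    ``alpha`` is the run null probability (default 2**-10); the threshold
    solves p**m = alpha, rounded up to whole time points, and is never
    allowed below ``min_span`` (the smoothing window correlates increments
    over that many points).  p = 0 gives an infinite threshold (no bursts
    detectable in that direction); p = 1 is degenerate and pinned at the
    minimum with a warning.
    """
    for name, p in (("p_inc", p_inc), ("p_dec", p_dec)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    # -10/log2(p) generalizes to log(alpha)/log(p)
    scale = math.log2(alpha)

    def one(p: float) -> tuple[float, float]:
        if p == 0:
            return math.inf, math.inf
        if p == 1:
            warnings.warn(
                "degenerate step probability p = 1; threshold set to the minimum span",
                stacklevel=2,
            )
            return float(min_span), float(min_span)
        raw = scale / math.log2(p)
        # ceil with an epsilon so closed-form thresholds (e.g. exactly 20)
        # are not pushed up by floating-point fuzz
        return raw, float(max(min_span, math.ceil(raw - 1e-9)))

    m_inc_raw, m_inc = one(p_inc)
    m_dec_raw, m_dec = one(p_dec)
    return BurstThresholds(
        p_inc=p_inc,
        p_dec=p_dec,
        n_tot=0,
        m_inc=m_inc,
        m_dec=m_dec,
        min_span=min_span,
        m_inc_raw=m_inc_raw,
        m_dec_raw=m_dec_raw,
    )


def _find_runs(
    sign: np.ndarray, direction: int, max_interruptions: int = 1
) -> list[tuple[int, int, int]]:
    """Maximal same-direction runs of increment signs, tolerating up to
    ``max_interruptions`` isolated interruptions (a single opposing/zero
    increment flanked by the run's direction).  Returns inclusive
    (first, last, n_same_direction) increment indices; runs start and end
    on a same-direction increment."""
    runs: list[tuple[int, int, int]] = []
    n = len(sign)
    i = 0
    while i < n:
        if sign[i] != direction:
            i += 1
            continue
        start = i
        last_good = i
        n_same = 1
        used = 0
        j = i + 1
        while j < n:
            if sign[j] == direction:
                last_good = j
                n_same += 1
                j += 1
            elif (
                last_good == j - 1
                and used < max_interruptions
                and j + 1 < n
                and sign[j + 1] == direction
            ):
                used += 1
                j += 1  # isolated interruption, bridged
            else:
                break
        runs.append((start, last_good, n_same))
        i = last_good + 1
    return runs


def segment_trace(
    s: np.ndarray,
    thresholds: BurstThresholds,
    frame_interval_s: float,
    max_interruptions: int = 1,
) -> list[BurstEvent]:
    """Classify a normalized trace into positive/negative/unclassified events.

    Runs containing at least the direction's threshold of same-direction
    increments (a tolerated isolated reversal does not count toward the
    threshold) become events with amplitude S[end]-S[start].  Gaps strictly
    between consecutive significant events are emitted as unclassified
    events; anything before the first or after the last significant event
    is discarded.  A trace with no significant run returns an empty list.
    """
    s = np.asarray(s, dtype=float)
    ds = np.diff(s)
    sign = np.zeros(len(ds), dtype=int)
    finite = np.isfinite(ds)
    sign[finite & (ds > 0)] = 1
    sign[finite & (ds < 0)] = -1

    significant: list[BurstEvent] = []
    for direction, label, m in (
        (1, POSITIVE, thresholds.m_inc),
        (-1, NEGATIVE, thresholds.m_dec),
    ):
        if math.isinf(m):
            continue
        for a, b, n_same in _find_runs(sign, direction, max_interruptions):
            if n_same >= m:
                start, end = a, b + 1  # frame indices
                significant.append(
                    BurstEvent(
                        direction=label,
                        start_index=start,
                        end_index=end,
                        amplitude=float(s[end] - s[start]),
                        duration_s=(end - start) * frame_interval_s,
                    )
                )
    significant.sort(key=lambda e: (e.start_index, e.end_index))
    if not significant:
        return []

    events: list[BurstEvent] = [significant[0]]
    for nxt in significant[1:]:
        prev = events[-1]
        if nxt.start_index > prev.end_index:
            gap_amp = s[nxt.start_index] - s[prev.end_index]
            events.append(
                BurstEvent(
                    direction=UNCLASSIFIED,
                    start_index=prev.end_index,
                    end_index=nxt.start_index,
                    amplitude=float(gap_amp),
                    duration_s=(nxt.start_index - prev.end_index) * frame_interval_s,
                )
            )
        events.append(nxt)
    return events


def detect_bursts(
    s: np.ndarray,
    frame_interval_s: float,
    min_span: int = 13,
    alpha: float = DEFAULT_ALPHA,
    max_interruptions: int = 1,
) -> tuple[list[BurstEvent], BurstThresholds]:
    """Per-trace threshold computation followed by segmentation."""
    p_inc, p_dec, n_tot = compute_step_probabilities(s)
    thresholds = compute_thresholds(p_inc, p_dec, min_span=min_span, alpha=alpha)
    thresholds.n_tot = n_tot
    events = segment_trace(s, thresholds, frame_interval_s, max_interruptions)
    return events, thresholds


def inter_event_intervals(
    events: list[BurstEvent],
    direction: str,
    frame_interval_s: float,
) -> list[float]:
    """Start-to-start intervals (seconds) between consecutive events of one
    direction (entry-to-entry or shedding-to-shedding).  Fewer than two
    matching events yield an empty list."""
    if direction not in (POSITIVE, NEGATIVE):
        raise ValueError(f"direction must be '{POSITIVE}' or '{NEGATIVE}'")
    starts = [e.start_index for e in events if e.direction == direction]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("events must be time-ordered")
    return [float((b - a) * frame_interval_s) for a, b in zip(starts, starts[1:])]
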