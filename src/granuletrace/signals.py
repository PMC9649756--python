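"""Photobleaching-aware normalization of spot/background trace pairs.

The observed spot signal is modelled as y(t) = (S(t) + c0) * f(t) + noise
and the observed background as c(t) = c0 * f(t) + noise, where S(t) is the
granule signal of interest, c0 the (assumed constant) underlying background
and f(t) the photobleaching decay.  Because f(t) multiplies both channels it
cancels in the ratio y/c, so

    S(t) = c0 * (y(t) / c(t) - 1)

recovers S regardless of the bleaching timescale.  In practice y is smoothed
with a centered 13-point moving average (2 min at 6 frames/min) and c is
replaced by a cubic-polynomial trend fit before taking the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTrace",
    "NormalizedTrace",
    "smooth_trace",
    "fit_background",
    "normalize_signal",
    "estimate_c0",
    "normalize_trace",
]


@dataclass
class IntensityTrace:
    """Paired spot/background intensity series — the pipeline's central record.

    ``s_true`` is only populated for synthetic traces and holds the injected
    underlying signal; ``degenerate_frames`` marks frames where sub-frame
    classification was undefined (all pixels equal).
    """

    time_s: np.ndarray
    y_raw: np.ndarray
    c_raw: np.ndarray
    channel: str = ""
    s_true: np.ndarray | None = None
    clipped: bool = False
    degenerate_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.y_raw = np.asarray(self.y_raw, dtype=float)
        self.c_raw = np.asarray(self.c_raw, dtype=float)
        n = len(self.time_s)
        if n < 2:
            raise ValueError("trace must have at least 2 frames")
        if len(self.y_raw) != n or len(self.c_raw) != n:
            raise ValueError("time, spot and background series must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.y_raw)) and np.all(np.isfinite(self.c_raw))):
            raise ValueError("intensities must be finite")
        if self.s_true is not None:
            self.s_true = np.asarray(self.s_true, dtype=float)

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass
class NormalizedTrace:
    """Result of the normalization pipeline for one trace.

    ``S`` satisfies S = c0_hat * (y_smooth / c_fit - 1) elementwise on
    unmasked frames; frames with non-positive fitted background are NaN and
    listed in ``masked_frames``.
    """

    S: np.ndarray
    y_smooth: np.ndarray
    c_fit: np.ndarray
    c0_hat: float
    span: int
    background_coeffs: np.ndarray
    masked_frames: list[int] = field(default_factory=list)
    time_s: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.S)


def smooth_trace(series: np.ndarray, span: int = 13) -> np.ndarray:
    """Centered moving average with edge-truncated windows.

    At the trace ends the window shrinks to the available points (no padding
    or reflection), so no synthetic values are introduced.  ``span`` must be
    odd so the window is symmetric about each point.
    """
    series = np.asarray(series, dtype=float)
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be odd and >= 1, got {span}")
    if span > len(series):
        raise ValueError(f"span {span} exceeds series length {len(series)}")
    return (
        pd.Series(series).rolling(window=span, center=True, min_periods=1).mean().to_numpy()
    )


def fit_background(
    time_s: np.ndarray, c_raw: np.ndarray, degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial trend of the measured background.

    A low-order (default cubic) polynomial captures the slow background
    drift while eliminating frame-to-frame noise.  Returns the fitted series
    and the polynomial coefficients (ascending powers, unscaled domain) for
    audit.
    """
    time_s = np.asarray(time_s, dtype=float)
    c_raw = np.asarray(c_raw, dtype=float)
    if len(c_raw) <= degree:
        raise ValueError(f"need more than degree={degree} points, got {len(c_raw)}")
    if len(np.unique(time_s)) <= degree:
        raise ValueError("repeated timestamps make the polynomial fit rank-deficient")
    # fit in a scaled domain for conditioning, report unscaled coefficients
    poly = np.polynomial.Polynomial.fit(time_s, c_raw, deg=degree)
    return poly(time_s), poly.convert().coef


def normalize_signal(
    y: np.ndarray, c: np.ndarray, c0: float
) -> np.ndarray:
    """Extract the underlying signal S = c0 * (y / c - 1) elementwise.

    Photobleaching cancels in the ratio y/c.  Frames with non-positive
    background are undefined and returned as NaN (a warning reports how
    many); downstream statistics skip them.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    if c0 <= 0:
        raise ValueError(f"c0 must be > 0, got {c0}")
    bad = c <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} frame(s) have non-positive background; masked as NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        s = c0 * (y / c - 1.0)
    s = np.where(bad, np.nan, s)
    return s


def estimate_c0(c_fit: np.ndarray) -> float:
    """Estimate the underlying background constant as the mean fitted background.

    Any positive choice of c0 rescales S globally without changing increment
    signs, so burst classification is invariant to this convention.
    """
    c_fit = np.asarray(c_fit, dtype=float)
    if len(c_fit) == 0:
        raise ValueError("c_fit must be non-empty")
    if np.any(c_fit <= 0):
        raise ValueError("c_fit must be positive")
    return float(np.mean(c_fit))


def normalize_trace(
    trace: IntensityTrace,
    span: int = 13,
    degree: int = 3,
    c0: float | None = None,
) -> NormalizedTrace:
    """Full normalization pipeline: smooth, fit background, extract S(t).

    ``c0`` overrides the background-constant estimate (useful when the true
    constant is known, e.g. for synthetic traces); by default it is the mean
    of the fitted background over the unmasked frames.
    """
    y_smooth = smooth_trace(trace.y_raw, span=span)
    c_fit, coeffs = fit_background(trace.time_s, trace.c_raw, degree=degree)
    positive = c_fit > 0
    if not np.any(positive):
        raise ValueError("fitted background is non-positive everywhere")
    c0_hat = float(c0) if c0 is not None else estimate_c0(c_fit[positive])
    s = normalize_signal(y_smooth, c_fit, c0_hat)
    masked = [int(i) for i in np.flatnonzero(~np.isfinite(s))]
    return NormalizedTrace(
        S=s,
        y_smooth=y_smooth,
        c_fit=c_fit,
        c0_hat=c0_hat,
        span=span,
        background_coeffs=coeffs,
        masked_frames=masked,
        time_s=trace.time_s,
    )
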