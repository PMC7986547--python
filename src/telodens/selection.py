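"""Telomere smear selection and background correction.

The telomere-specific signal occupies a contiguous row range of the lane
profile.  Its borders can be found automatically from intensity thresholds:
with W the width constant (default 0.28),

    OD_lt = OD_lb + W * (OD_lmax - OD_lb)        (left border threshold)
    OD_rt = OD_rb + W * (OD_rmax - OD_rb)        (right border threshold)

where OD_lmax is the profile maximum up to the right edge r of the
user-declared first-peak area, OD_lb the minimum left of that maximum, and
mirrored quantities on the right from the left edge l of the last-peak area
to the end of the scan.  The border rows are the outermost rows at which the
smoothed profile crosses its threshold, scanning inward from the profile
ends — the widest area consistent with the thresholds.  W = 0 therefore
opens the selection to the flanking baselines, W = 1 collapses it onto the
peaks.

Background is removed by subtracting a straight line anchored on the two
flanks of the selected smear: in each flank interval, local minima of the
smoothed profile that lie below the interval median are collected and, when
at least three exist, a line through them supplies the anchor at the middle
of their row range (otherwise the interval minimum is the anchor).  The line
through the two anchors is subtracted from the profile; negative values are
clamped to zero.  Skipping this correction typically *underestimates*
telomere length, because the 1/L weighting of the estimator amplifies any
baseline signal at the short-fragment end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .densitometry import IntensityProfile

__all__ = [
    "PeakAreaSpec",
    "SmearBorders",
    "BackgroundModel",
    "smooth",
    "auto_borders",
    "manual_borders",
    "background_correct",
]

DEFAULT_W = 0.28
DEFAULT_SPAN = 0.05


def _vals(profile) -> np.ndarray:
    if isinstance(profile, IntensityProfile):
        return np.asarray(profile.values, dtype=float)
    return np.asarray(profile, dtype=float)


@dataclass(frozen=True)
class PeakAreaSpec:
    """User-declared row ranges of the first and last smear peak (0-based, inclusive).

    For a unimodal smear the two areas coincide; for band-like multi-modal
    signals the first-peak area covers the longest-fragment band and the
    last-peak area the shortest-fragment band.
    """

    first_peak: tuple[int, int]
    last_peak: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (a, b) in (("first_peak", self.first_peak), ("last_peak", self.last_peak)):
            if b < a:
                raise ValueError(f"{name} range ({a}, {b}) is inverted")

    @classmethod
    def unimodal(cls, left_row: int, right_row: int) -> "PeakAreaSpec":
        return cls((left_row, right_row), (left_row, right_row))


@dataclass(frozen=True)
class SmearBorders:
    """Selected smear row range [left_row, right_row], 0-based inclusive."""

    left_row: int
    right_row: int
    method: str = "auto"
    threshold_left: float = float("nan")
    threshold_right: float = float("nan")

    def __post_init__(self) -> None:
        if self.right_row <= self.left_row:
            raise ValueError(f"borders ({self.left_row}, {self.right_row}) are not increasing")
        if self.method not in ("auto", "manual"):
            raise ValueError(f"unknown border method {self.method!r}")


@dataclass(frozen=True)
class BackgroundModel:
    """Linear baseline through a left and right anchor point (row, OD)."""

    left_anchor: tuple[float, float]
    right_anchor: tuple[float, float]
    minima_used_left: int
    minima_used_right: int

    def __post_init__(self) -> None:
        if self.right_anchor[0] <= self.left_anchor[0]:
            raise ValueError("background anchors must be ordered left < right")

    @property
    def slope(self) -> float:
        (x0, y0), (x1, y1) = self.left_anchor, self.right_anchor
        return (y1 - y0) / (x1 - x0)

    @property
    def intercept(self) -> float:
        return self.left_anchor[1] - self.slope * self.left_anchor[0]

    def baseline(self, rows) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(rows, dtype=float)


def smooth(profile, span: float = DEFAULT_SPAN) -> np.ndarray:
    """Centered moving average with window = max(3, round(span * n)), odd.

    Edges are handled by shrinking the window to the available rows.
    """
    if not 0 < span <= 1:
        raise ValueError("smoothing span must lie in (0, 1]")
    v = _vals(profile)
    n = v.size
    if n < 3:
        return v.copy()
    w = max(3, int(round(span * n)))
    if w % 2 == 0:
        w += 1
    h = w // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def auto_borders(
    profile,
    peaks: PeakAreaSpec,
    W: float = DEFAULT_W,
    span: float = DEFAULT_SPAN,
) -> SmearBorders:
    """Automatic smear border selection from the W-threshold rule.

    The profile is smoothed first; see the module docstring for the
    threshold construction.  Raises when the profile is flat (no
    telomere-specific signal to threshold against).
    """
    if not 0 <= W <= 1:
        raise ValueError("W must lie in [0, 1]")
    od = _vals(profile)
    n = od.size
    s = smooth(od, span)
    r = min(peaks.first_peak[1], n - 1)
    l = min(peaks.last_peak[0], n - 1)

    left_seg = s[: r + 1]
    od_lmax = float(left_seg.max())
    i = int(np.argmax(left_seg))
    od_lb = float(s[: i + 1].min())

    right_seg = s[l:]
    od_rmax = float(right_seg.max())
    j = l + int(np.argmax(right_seg))
    od_rb = float(s[j:].min())

    tol = 1e-12 * max(abs(od_lmax), abs(od_rmax), 1.0)
    if od_lmax - od_lb <= tol and od_rmax - od_rb <= tol:
        raise ValueError("no telomere-specific signal detected: profile is flat")

    od_lt = od_lb + W * (od_lmax - od_lb)
    od_rt = od_rb + W * (od_rmax - od_rb)

    left_hits = np.nonzero(s[: i + 1] >= od_lt)[0]
    left_row = int(left_hits[0]) if left_hits.size else i
    right_hits = j + np.nonzero(s[j:] >= od_rt)[0]
    right_row = int(right_hits[-1]) if right_hits.size else j

    if right_row <= left_row:
        # W close to 1 on a unimodal smear collapses both crossings onto the
        # peak row; keep the minimal valid selection around it
        left_row = max(min(left_row, right_row) - 1, 0)
        right_row = min(max(left_row + 1, right_row + 1), n - 1)
    return SmearBorders(left_row, right_row, "auto", od_lt, od_rt)


def manual_borders(left_row: int, right_row: int) -> SmearBorders:
    """Manually chosen smear borders (0-based inclusive rows).

    Background correction is refused downstream for manual borders; only the
    automatic selection guarantees that the flanking intervals are
    signal-free.
    """
    return SmearBorders(int(left_row), int(right_row), "manual")


def _local_minima(s: np.ndarray) -> list[int]:
    """Strict first-difference sign-change minima; plateaus yield their center row."""
    n = s.size
    minima: list[int] = []
    k = 1
    while k < n - 1:
        if s[k] < s[k - 1]:
            m = k
            while m + 1 < n and s[m + 1] == s[m]:
                m += 1
            if m < n - 1 and s[m + 1] > s[m]:
                minima.append((k + m) // 2)
            k = m + 1
        else:
            k += 1
    return minima


def _flank_anchor(od: np.ndarray, s: np.ndarray, start: int, stop: int) -> tuple[tuple[float, float], int]:
    """Anchor point for one flank interval [start, stop] (inclusive).

    Returns ((row, OD), number of minima used).  Fewer than three qualifying
    minima (or a sub-3-row interval) falls back to the interval minimum.
    """
    idx = np.arange(start, stop + 1)
    if idx.size >= 3:
        seg = s[start : stop + 1]
        med = float(np.median(seg))
        mins = [start + m for m in _local_minima(seg)]
        kept = [m for m in mins if s[m] < med]
        if len(kept) >= 3:
            rows = np.asarray(kept, dtype=float)
            coef = np.polyfit(rows, od[kept], 1)
            mid = (rows.min() + rows.max()) / 2.0
            return (float(mid), float(np.polyval(coef, mid))), len(kept)
    k = start + int(np.argmin(s[start : stop + 1]))
    return (float(k), float(od[k])), 0


def background_correct(
    profile,
    borders: SmearBorders,
    span: float = DEFAULT_SPAN,
) -> tuple[np.ndarray, BackgroundModel]:
    """Subtract a linear baseline anchored on the smear's two flanks.

    Only automatic borders are accepted: with manual borders there is no
    guarantee the flanking intervals hold background alone.  Returns the
    corrected profile (clamped at zero) and the fitted baseline.
    """
    if borders.method != "auto":
        raise ValueError(
            "background correction requires automatically selected borders; "
            "re-run the automatic smear selection instead of manual borders"
        )
    od = _vals(profile)
    n = od.size
    s = smooth(od, span)
    left_anchor, n_left = _flank_anchor(od, s, 0, borders.left_row)
    right_anchor, n_right = _flank_anchor(od, s, borders.right_row, n - 1)
    if right_anchor[0] <= left_anchor[0]:  # pathological overlap; pin to interval ends
        left_anchor = (0.0, od[0])
        right_anchor = (float(n - 1), od[-1])
    model = BackgroundModel(left_anchor, right_anchor, n_left, n_right)
    corrected = np.maximum(od - model.baseline(np.arange(n)), 0.0)
    return corrected, model
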