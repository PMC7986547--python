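"""Weighted-median telomere length statistics.

Signal intensity at a scan row is proportional to the hybridised telomeric
*mass* at that fragment length, so the number of fragments of length L_k
contributing OD_k is proportional to OD_k / L_k.  The estimator therefore
builds the cumulative sum of weighted intensities

    C_k = sum_{m<=k} OD_m / L_m ,

a monotone curve whose inversion at C_n/2 gives the weighted median
fragment length: with C_i <= C_n/2 < C_{i+1}, the median is the linear
interpolation of L between (C_i, L_i) and (C_{i+1}, L_{i+1}).  Quartiles
invert the same curve at C_n/4 and 3 C_n/4.  Intensity profiles are
smoothed (5% span moving average) before evaluation; lengths never are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationModel
from .densitometry import IntensityProfile
from .selection import (
    DEFAULT_SPAN,
    DEFAULT_W,
    PeakAreaSpec,
    SmearBorders,
    auto_borders,
    background_correct,
    smooth,
)

__all__ = [
    "TelomereEstimate",
    "weighted_cumsum",
    "weighted_median",
    "weighted_quartiles",
    "estimate_lane",
    "analyze_profile",
]


@dataclass
class TelomereEstimate:
    """Five-number summary of one lane's telomere smear, in bp."""

    label: str
    weighted_median_bp: float
    q1_bp: float
    q3_bp: float
    min_bp: float
    max_bp: float
    n_pixels: int
    background_corrected: bool = False
    borders: SmearBorders | None = None

    def __post_init__(self) -> None:
        eps = 1e-9 * max(1.0, abs(self.max_bp))
        ordered = (
            self.min_bp
            <= self.q1_bp + eps
            and self.q1_bp <= self.weighted_median_bp + eps
            and self.weighted_median_bp <= self.q3_bp + eps
            and self.q3_bp <= self.max_bp + eps
        )
        if not ordered:
            raise ValueError(
                f"inconsistent five-number summary for lane {self.label!r}: "
                f"{self.min_bp}, {self.q1_bp}, {self.weighted_median_bp}, "
                f"{self.q3_bp}, {self.max_bp}"
            )
        if self.n_pixels < 2:
            raise ValueError("a smear estimate needs at least 2 pixels")


def _validate(od: np.ndarray, lengths: np.ndarray) -> None:
    if od.shape != lengths.shape or od.ndim != 1 or od.size < 2:
        raise ValueError("od and lengths_bp must be equal-length 1-D vectors of size >= 2")
    if np.any(lengths <= 0):
        raise ValueError("fragment lengths must be positive")
    if np.any(od < 0):
        raise ValueError("optical densities must be non-negative")
    if not np.any(od > 0):
        raise ValueError("empty signal: all optical densities are zero")


def weighted_cumsum(od, lengths_bp) -> np.ndarray:
    """Cumulative sum of OD_k / L_k along the scan rows."""
    od = np.asarray(od, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    _validate(od, lengths)
    return np.cumsum(od / lengths)


def _invert_cumulative(C: np.ndarray, L: np.ndarray, target: float) -> float:
    """Predict L at a target value of the cumulative curve C.

    Uses the bracketing pair C_i <= target < C_{i+1}.  When the target falls
    below C_1 the curve is extended continuously to (0, L_0) with L_0 the
    length one row before the first (linear extrapolation in row space).
    """
    idx = int(np.searchsorted(C, target, side="right"))
    if idx >= C.size:  # target == C_n (only reachable at the 3rd-quartile end)
        return float(L[-1])
    if idx == 0:
        L0 = 2.0 * L[0] - L[1]
        return L0 + (L[0] - L0) * target / C[0] if C[0] > 0 else float(L[0])
    c_lo, c_hi = C[idx - 1], C[idx]
    return float(L[idx - 1] + (L[idx] - L[idx - 1]) * (target - c_lo) / (c_hi - c_lo))


def weighted_median(od, lengths_bp, presmooth: bool = True, span: float = DEFAULT_SPAN) -> float:
    """Weighted median telomere length (bp) of a profile segment."""
    od = np.asarray(od, dtype=float)
    if presmooth:
        od = smooth(od, span)
    lengths = np.asarray(lengths_bp, dtype=float)
    _validate(od, lengths)
    C = np.cumsum(od / lengths)
    return _invert_cumulative(C, lengths, C[-1] / 2.0)


def weighted_quartiles(
    od, lengths_bp, presmooth: bool = True, span: float = DEFAULT_SPAN
) -> tuple[float, float]:
    """1st and 3rd weighted quartiles (bp), returned sorted ascending."""
    od = np.asarray(od, dtype=float)
    if presmooth:
        od = smooth(od, span)
    lengths = np.asarray(lengths_bp, dtype=float)
    _validate(od, lengths)
    C = np.cumsum(od / lengths)
    qa = _invert_cumulative(C, lengths, C[-1] / 4.0)
    qb = _invert_cumulative(C, lengths, 3.0 * C[-1] / 4.0)
    return (qa, qb) if qa <= qb else (qb, qa)


def estimate_lane(
    profile: IntensityProfile,
    borders: SmearBorders,
    model: CalibrationModel,
    correct_bg: bool = False,
    span: float = DEFAULT_SPAN,
) -> TelomereEstimate:
    """Full five-number telomere estimate for one lane.

    The (optionally background-corrected) profile is smoothed over its full
    length, restricted to the selected smear rows, converted to fragment
    lengths through the calibration, and summarised by the weighted median
    and quartiles.  Minimum and maximum are the predicted lengths at the two
    border rows; ``n_pixels`` is the selected row count and doubles as the n
    of the downstream group statistics.
    """
    od = np.asarray(profile.values, dtype=float)
    n = od.size
    if not 0 <= borders.left_row < borders.right_row < n:
        raise ValueError(f"borders {borders} outside profile of length {n}")
    if correct_bg:
        od, _ = background_correct(od, borders, span=span)
    od = smooth(od, span)
    rows = np.arange(borders.left_row, borders.right_row + 1)
    raw = np.atleast_1d(model(rows))
    if np.any(raw <= 0):
        raise ValueError(
            "selected rows map to non-positive fragment lengths; the calibration "
            "is being extrapolated beyond its ladder range"
        )
    lengths = raw
    seg = od[rows[0] : rows[-1] + 1]
    med = weighted_median(seg, lengths, presmooth=False)
    q1, q3 = weighted_quartiles(seg, lengths, presmooth=False)
    lo, hi = sorted((float(lengths[0]), float(lengths[-1])))
    # threshold crossings sit on the smear flanks, so the quartiles normally lie
    # strictly inside [lo, hi]; clip guards the degenerate flat-calibration case
    q1, q3 = max(q1, lo), min(q3, hi)
    med = min(max(med, q1), q3)
    return TelomereEstimate(
        label=profile.label,
        weighted_median_bp=med,
        q1_bp=q1,
        q3_bp=q3,
        min_bp=lo,
        max_bp=hi,
        n_pixels=int(rows.size),
        background_corrected=correct_bg,
        borders=borders,
    )


def analyze_profile(
    profile: IntensityProfile,
    peaks: PeakAreaSpec,
    model: CalibrationModel,
    correct_bg: bool = True,
    W: float = DEFAULT_W,
    span: float = DEFAULT_SPAN,
) -> TelomereEstimate:
    """Automatic selection + optional correction + estimate for one lane.

    Runs the automatic border selection, and with ``correct_bg`` subtracts
    the flank baseline and then *re-selects* the borders on the corrected
    profile before estimating: a strong background can push the threshold
    crossings far beyond the smear, and re-selection on the corrected
    profile restores the selection the clean signal would have produced.
    """
    borders = auto_borders(profile, peaks, W=W, span=span)
    if not correct_bg:
        return estimate_lane(profile, borders, model, span=span)
    corrected, _ = background_correct(profile, borders, span=span)
    corrected_profile = IntensityProfile(
        corrected,
        label=profile.label,
        role=profile.role,
        selection=profile.selection,
        lane_center_col=profile.lane_center_col,
    )
    borders = auto_borders(corrected_profile, peaks, W=W, span=span)
    est = estimate_lane(corrected_profile, borders, model, span=span)
    est.background_corrected = True
    return est
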