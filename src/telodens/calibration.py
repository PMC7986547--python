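"""Migration calibration: map pixel row to fragment length (bp).

A DNA size ladder lane provides bands of known fragment length.  Band peaks
are located in the ladder's intensity profile, assigned to ladder fragments,
and the relationship length ~ pixel row is fitted with a polynomial whose
order is chosen by successive nested-model ANOVA F-tests: starting from a
straight line, each order k model is tested against order k+1 (null: the
simpler model suffices) and the ascent stops at the first non-rejection.
The deepest order in the chain of consecutive rejections at p <= alpha is
used.

Uneven migration across a wide gel ("smiling"/tilt) is corrected by loading
a second ladder on the opposite side and interpolating *virtual markers*:
for each fragment length shared by the two ladders, a straight line through
the two (lane column, band row) points predicts that band's row at every
sample lane column, extrapolating for lanes outside the two ladders.  Each
virtual marker is fitted as above and the most frequent selected order is
imposed on all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats

from .densitometry import IntensityProfile

__all__ = [
    "LadderSpec",
    "PeakAssignment",
    "CalibrationModel",
    "NonMonotoneLadderWarning",
    "detect_peaks",
    "assign_ladder",
    "fit_calibration",
    "predict_length",
    "build_virtual_markers",
    "load_ladder_presets",
]


class NonMonotoneLadderWarning(UserWarning):
    """Band rows do not increase as fragment length decreases."""


@dataclass(frozen=True)
class LadderSpec:
    """A DNA size marker: named list of fragment lengths in bp, longest first."""

    name: str
    fragments_bp: tuple[float, ...]

    def __post_init__(self) -> None:
        frags = tuple(float(f) for f in self.fragments_bp)
        object.__setattr__(self, "fragments_bp", frags)
        if len(frags) < 3:
            raise ValueError("a ladder needs at least 3 fragments")
        if any(f <= 0 for f in frags):
            raise ValueError("fragment lengths must be positive")
        if any(b >= a for a, b in zip(frags, frags[1:])):
            raise ValueError("fragment lengths must be strictly decreasing")


@dataclass
class PeakAssignment:
    """Pairs of (fragment length bp, pixel row) for one ladder lane."""

    pairs: list[tuple[float, float]]
    lane_center_col: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValueError(
                "at least 3 fragment/peak pairs are required; "
                "the length/migration relationship cannot be fitted otherwise"
            )
        bp = self.bp
        rows = self.rows
        order = np.argsort(-bp)  # decreasing bp
        if not np.all(np.diff(rows[order]) > 0):
            warnings.warn(
                "ladder assignment is not monotone: pixel rows do not strictly "
                "increase with decreasing fragment length",
                NonMonotoneLadderWarning,
                stacklevel=2,
            )

    @property
    def bp(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=float)

    @property
    def rows(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)


@dataclass
class CalibrationModel:
    """Fitted polynomial mapping pixel row -> fragment length L (bp)."""

    poly: Polynomial
    order: int
    fit_rows: tuple[float, float]
    anova_pvalues: list[float] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        """Raw-power coefficients, ascending order (c0 + c1*row + ...)."""
        return self.poly.convert().coef

    def __call__(self, rows) -> np.ndarray:
        """Raw polynomial evaluation, possibly non-positive on extrapolation."""
        return self.poly(np.asarray(rows, dtype=float))

    def predict_length(self, rows) -> np.ndarray:
        return predict_length(self, rows)


def predict_length(model: CalibrationModel, rows) -> np.ndarray:
    """Evaluate the calibration at pixel rows; lengths below 1 bp are floored.

    Flooring only happens on extrapolation far outside the fitted band range
    and is flagged with a warning.
    """
    pred = np.atleast_1d(model(rows)).astype(float)
    if np.any(pred < 1.0):
        warnings.warn(
            "calibration predicts fragment lengths below 1 bp "
            "(extrapolation outside the fitted ladder range); values floored at 1",
            UserWarning,
            stacklevel=2,
        )
        pred = np.maximum(pred, 1.0)
    return pred if np.ndim(rows) else float(pred[0])


def detect_peaks(profile: IntensityProfile | np.ndarray, sensitivity: float = 0.1,
                 span: float = 0.01) -> list[int]:
    """Locate ladder band peaks in a marker intensity profile.

    The profile is lightly smoothed (moving average, ``span`` of its length;
    narrower than the 5% evaluation span so closely spaced ladder bands stay
    resolved) and local maxima are kept when their prominence is at least
    ``sensitivity * (max - min)`` of the smoothed profile.  ``sensitivity``
    is the user-facing peak-search slider: small values find faint bands,
    1.0 keeps only the global maximum.
    """
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must lie in (0, 1]")
    from .selection import smooth

    values = np.asarray(profile.values if isinstance(profile, IntensityProfile) else profile,
                        dtype=float)
    if np.count_nonzero(values) < 3:
        raise ValueError("marker profile needs at least 3 nonzero rows")
    s = smooth(values, span)
    rng = s.max() - s.min()
    if rng <= 0:
        return []
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(s, prominence=sensitivity * rng)
    return [int(p) for p in peaks]


def assign_ladder(
    peaks: Sequence[int],
    ladder: LadderSpec,
    mapping: Sequence[tuple[int, int]] | None = None,
    lane_center_col: float = float("nan"),
) -> PeakAssignment:
    """Pair ladder fragments with detected peaks.

    ``mapping`` lists (fragment index, peak index) pairs; by default fragment
    i maps to peak i, which is right when every band was detected.  Bands
    missed by the peak search are simply left out of the mapping (at least 3
    pairs must remain).
    """
    if mapping is None:
        k = min(len(ladder.fragments_bp), len(peaks))
        mapping = [(i, i) for i in range(k)]
    peak_idx = [p for _, p in mapping]
    if len(set(peak_idx)) != len(peak_idx):
        raise ValueError("duplicate peak index in ladder mapping")
    pairs = []
    for fi, pi in mapping:
        if not 0 <= fi < len(ladder.fragments_bp):
            raise IndexError(f"fragment index {fi} out of range for ladder {ladder.name!r}")
        if not 0 <= pi < len(peaks):
            raise IndexError(f"peak index {pi} out of range ({len(peaks)} peaks)")
        pairs.append((ladder.fragments_bp[fi], float(peaks[pi])))
    return PeakAssignment(pairs, lane_center_col=lane_center_col)


def _poly_rss(rows: np.ndarray, bp: np.ndarray, order: int) -> tuple[Polynomial, float]:
    poly = Polynomial.fit(rows, bp, order)
    resid = bp - poly(rows)
    return poly, float(resid @ resid)


def _nested_f_pvalue(rss_lo: float, rss_hi: float, n: int, order_hi: int, tss: float) -> float:
    """p-value of the F-test of polynomial order_hi against order_hi - 1."""
    df_resid = n - (order_hi + 1)
    if df_resid <= 0:
        return 1.0
    tiny = max(tss, 1.0) * 1e-24
    if rss_hi <= tiny:
        # higher model interpolates the data exactly
        return 1.0 if rss_lo <= tiny else 0.0
    f = (rss_lo - rss_hi) / (rss_hi / df_resid)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, 1, df_resid))


def fit_calibration(
    assignment: PeakAssignment,
    alpha: float = 0.05,
    max_order: int = 6,
    force_order: int | None = None,
) -> CalibrationModel:
    """Fit L ~ poly(row) with ANOVA-driven polynomial order selection.

    Orders 1, 2, ... are fitted by least squares; each adjacent pair is
    compared by a nested-model F-test (null: the lower order suffices).  The
    selected order is the deepest one in the chain of consecutive rejections
    at p <= alpha.  ``max_order`` is capped at (#pairs - 2) so a residual
    degree of freedom remains for the last test.  ``force_order`` skips the
    selection and fits that order directly (the manual-adjustment path, also
    used when imposing a consensus order on virtual markers).
    """
    rows = assignment.rows
    bp = assignment.bp
    n = rows.size
    # a row assigned two different lengths is unfittable; exact duplicate pairs are fine
    seen: dict[float, float] = {}
    for length, row in assignment.pairs:
        if row in seen and seen[row] != length:
            raise ValueError(
                "degenerate design: repeated pixel rows with conflicting lengths "
                "in the ladder assignment"
            )
        seen[row] = length
    n_unique = len(seen)
    if force_order is not None:
        if not 1 <= force_order <= n_unique - 1:
            raise ValueError(f"forced order {force_order} infeasible for {n_unique} distinct rows")
        poly, _ = _poly_rss(rows, bp, force_order)
        return CalibrationModel(poly, force_order, (float(rows.min()), float(rows.max())))
    if max_order < 1:
        raise ValueError("max_order must be at least 1")
    max_order = min(max_order, n_unique - 2)
    max_order = max(max_order, 1)

    tss = float(np.sum((bp - bp.mean()) ** 2))
    polys: dict[int, Polynomial] = {}
    rss: dict[int, float] = {}
    for k in range(1, max_order + 1):
        polys[k], rss[k] = _poly_rss(rows, bp, k)

    selected = 1
    pvals: list[float] = []
    for k in range(1, max_order):
        p = _nested_f_pvalue(rss[k], rss[k + 1], n, k + 1, tss)
        pvals.append(p)
        if p <= alpha:
            selected = k + 1
        else:
            break

    model = CalibrationModel(
        polys[selected], selected, (float(rows.min()), float(rows.max())), pvals
    )
    grid = np.linspace(model.fit_rows[0], model.fit_rows[1], 101)
    if np.any(model(grid) <= 0):
        warnings.warn(
            "fitted calibration predicts non-positive lengths inside the band range",
            UserWarning,
            stacklevel=2,
        )
    return model


def build_virtual_markers(
    left: PeakAssignment,
    right: PeakAssignment,
    lane_centers: Sequence[float],
    alpha: float = 0.05,
    max_order: int = 6,
) -> list[CalibrationModel]:
    """Correct tilted migration with per-lane virtual markers.

    For each fragment length present in both flanking ladders, the band row
    is interpolated linearly in the column direction between the two ladder
    lanes (and extrapolated beyond them).  Each lane's virtual (bp, row)
    assignment is fitted like a real ladder; the most frequent selected
    polynomial order is then imposed on every virtual marker (ties broken
    toward the smaller order).
    """
    if not np.isfinite(left.lane_center_col) or not np.isfinite(right.lane_center_col):
        raise ValueError("both markers need a lane_center_col to interpolate between")
    if left.lane_center_col == right.lane_center_col:
        raise ValueError("marker lanes share the same column; no tilt line defined")
    left_rows = {bp: row for bp, row in left.pairs}
    right_rows = {bp: row for bp, row in right.pairs}
    shared = sorted(set(left_rows) & set(right_rows), reverse=True)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} fragment lengths shared between the two markers; need >= 3"
        )
    x0, x1 = left.lane_center_col, right.lane_center_col

    assignments = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonMonotoneLadderWarning)
        for col in lane_centers:
            t = (col - x0) / (x1 - x0)
            pairs = [(bp, left_rows[bp] + t * (right_rows[bp] - left_rows[bp])) for bp in shared]
            assignments.append(PeakAssignment(pairs, lane_center_col=float(col)))

    fits = [fit_calibration(a, alpha=alpha, max_order=max_order) for a in assignments]
    orders = [m.order for m in fits]
    counts = {o: orders.count(o) for o in set(orders)}
    best = max(counts.values())
    consensus = min(o for o, c in counts.items() if c == best)
    return [
        m if m.order == consensus else fit_calibration(a, force_order=consensus)
        for m, a in zip(fits, assignments)
    ]


def load_ladder_presets() -> dict[str, LadderSpec]:
    """Ladder presets shipped with the package (name -> LadderSpec)."""
    import json
    from importlib import resources

    text = resources.files("telodens").joinpath("data/ladders.json").read_text()
    raw = json.loads(text)
    return {name: LadderSpec(name, tuple(frags)) for name, frags in raw.items()}
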