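"""Synthetic TRF gel generation with exact ground truth.

Gels are composed from first principles: a monotone migration curve
row = a - b*ln(L) (the classic log-size electrophoresis law) places each
fragment length L at a scan row; ladder lanes render Gaussian bands at the
known fragment rows; sample lanes render smears whose *intensity density
over bp*, f(L), is a lognormal or a mixture of narrow bands.  The pixel
signal at a row is f(L(row)) |dL/drow|, i.e. the bp-space density carried
through the migration Jacobian, so the analytic 1/L-weighted statistics of
f are the exact ground truth for the weighted-median estimator.

Composition order: lane signals + linear background gradient + blotch
artifacts, ground truth captured, then pixel noise, then clipping to
[0, 1].  A gel-wide tilt (linear per-column row offset) emulates uneven
migration ("smiling" in its simplest, straight-lane form) and exercises the
virtual-marker correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import LadderSpec
from .densitometry import GelImage, LaneSelection, Rect

__all__ = [
    "MigrationCurve",
    "LognormalSmear",
    "BandMixture",
    "LadderLane",
    "SampleLane",
    "GelRecipe",
    "GroundTruth",
    "render_gel",
    "render_lane_profile",
    "true_weighted_stats",
    "default_demo_recipe",
    "selections_for",
]


@dataclass(frozen=True)
class MigrationCurve:
    """row = a - b * ln(L): longer fragments migrate less (smaller row)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("migration slope b must be positive")

    def row_of(self, bp) -> np.ndarray:
        return self.a - self.b * np.log(np.asarray(bp, dtype=float))

    def bp_of(self, row) -> np.ndarray:
        return np.exp((self.a - np.asarray(row, dtype=float)) / self.b)


@dataclass(frozen=True)
class LognormalSmear:
    """Unimodal smear: intensity density over bp is lognormal.

    ``median_bp`` is the median of the *intensity* distribution; ``sigma``
    its log-scale spread.
    """

    median_bp: float
    sigma: float

    def pdf(self, L) -> np.ndarray:
        L = np.asarray(L, dtype=float)
        mu = np.log(self.median_bp)
        return np.exp(-((np.log(L) - mu) ** 2) / (2 * self.sigma**2)) / (
            L * self.sigma * np.sqrt(2 * np.pi)
        )

    def support(self) -> tuple[float, float]:
        mu = np.log(self.median_bp)
        return float(np.exp(mu - 5 * self.sigma)), float(np.exp(mu + 5 * self.sigma))


@dataclass(frozen=True)
class BandMixture:
    """Multi-band smear: mixture of narrow Gaussians in bp.

    Emulates the fragmented, band-like telomere patterns seen in telomerase
    mutants and ALT tumour cells.  ``bands`` is a sequence of (bp, weight);
    each band's bp-space sigma is ``rel_width * bp``.
    """

    bands: tuple[tuple[float, float], ...]
    rel_width: float = 0.02

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band mixture needs at least one band")
        object.__setattr__(self, "bands", tuple((float(b), float(w)) for b, w in self.bands))

    def pdf(self, L) -> np.ndarray:
        L = np.asarray(L, dtype=float)
        total = np.zeros_like(L)
        for bp, w in self.bands:
            s = self.rel_width * bp
            total += w * np.exp(-((L - bp) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
        return total

    def support(self) -> tuple[float, float]:
        lo = min(bp * (1 - 6 * self.rel_width) for bp, _ in self.bands)
        hi = max(bp * (1 + 6 * self.rel_width) for bp, _ in self.bands)
        return max(lo, 1.0), hi


@dataclass(frozen=True)
class LadderLane:
    ladder: LadderSpec
    col_start: int
    col_stop: int
    band_sigma_px: float = 2.5
    intensity: float = 0.8
    label: str = "M"


@dataclass(frozen=True)
class SampleLane:
    label: str
    col_start: int
    col_stop: int
    smear: LognormalSmear | BandMixture
    intensity: float = 0.6


@dataclass
class GelRecipe:
    width: int
    height: int
    migration: MigrationCurve
    ladders: list[LadderLane] = field(default_factory=list)
    samples: list[SampleLane] = field(default_factory=list)
    tilt_rows: float = 0.0  # row offset at the rightmost column, linear across width
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)  # b0 + bx*x + by*y, x,y in [0,1]
    blotches: list[tuple[float, float, float, float]] = field(default_factory=list)  # (row, col, sigma, amp)
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact per-lane statistics and artifact surfaces, captured before noise."""

    lane_stats: dict[str, tuple[float, float, float]]  # label -> (median, q1, q3) bp
    ladder_band_rows: dict[str, list[float]]  # label -> band rows at the lane's center column
    background: np.ndarray


def true_weighted_stats(
    smear: LognormalSmear | BandMixture, n_grid: int = 10_000
) -> tuple[float, float, float]:
    """Analytic (median, q1, q3) of the 1/L-weighted intensity distribution.

    Inverts the cumulative of f(L)/L on an ``n_grid``-point grid over the
    smear's bp support — the quantity the pipeline's weighted median
    estimates from the rendered gel.
    """
    lo, hi = smear.support()
    L = np.linspace(lo, hi, n_grid)
    g = smear.pdf(L) / L
    C = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(L))])
    C /= C[-1]
    q1, med, q3 = np.interp([0.25, 0.5, 0.75], C, L)
    return float(med), float(q1), float(q3)


def render_lane_profile(
    smear: LognormalSmear | BandMixture,
    migration: MigrationCurve,
    n_rows: int,
    intensity: float = 1.0,
    tilt_offset: float = 0.0,
) -> np.ndarray:
    """Clean (noise- and background-free) lane OD profile over scan rows.

    The bp-space density is carried through the migration Jacobian
    |dL/drow| = L/b and peak-normalized to ``intensity``.
    """
    rows = np.arange(n_rows, dtype=float) - tilt_offset
    L = migration.bp_of(rows)
    u = smear.pdf(L) * L / migration.b
    peak = u.max()
    if peak <= 0:
        return np.zeros(n_rows)
    return intensity * u / peak


def _column_offsets(recipe: GelRecipe) -> np.ndarray:
    if recipe.width == 1:
        return np.zeros(1)
    return recipe.tilt_rows * np.arange(recipe.width) / (recipe.width - 1)


def render_gel(recipe: GelRecipe) -> tuple[GelImage, GroundTruth]:
    """Render a synthetic TRF scan and its exact ground truth."""
    H, W = recipe.height, recipe.width
    img = np.zeros((H, W))
    offsets = _column_offsets(recipe)
    rows = np.arange(H, dtype=float)

    for lane in recipe.samples:
        for col in range(lane.col_start, lane.col_stop):
            img[:, col] += render_lane_profile(
                lane.smear, recipe.migration, H, lane.intensity, offsets[col]
            )
    for lad in recipe.ladders:
        base_rows = recipe.migration.row_of(np.asarray(lad.ladder.fragments_bp))
        for col in range(lad.col_start, lad.col_stop):
            centers = base_rows + offsets[col]
            for c in centers:
                img[:, col] += lad.intensity * np.exp(
                    -((rows - c) ** 2) / (2 * lad.band_sigma_px**2)
                )

    b0, bx, by = recipe.background
    x = np.arange(W) / max(W - 1, 1)
    y = np.arange(H) / max(H - 1, 1)
    background = b0 + bx * x[None, :] + by * y[:, None]
    img = img + background
    for brow, bcol, sigma, amp in recipe.blotches:
        d2 = (rows[:, None] - brow) ** 2 + (np.arange(W)[None, :] - bcol) ** 2
        img += amp * np.exp(-d2 / (2 * sigma**2))

    truth = GroundTruth(
        lane_stats={lane.label: true_weighted_stats(lane.smear) for lane in recipe.samples},
        ladder_band_rows={
            lad.label: list(
                recipe.migration.row_of(np.asarray(lad.ladder.fragments_bp))
                + offsets[(lad.col_start + lad.col_stop - 1) // 2]
            )
            for lad in recipe.ladders
        },
        background=background,
    )

    if recipe.noise_sigma > 0:
        rng = np.random.default_rng(recipe.seed)
        img = img + rng.normal(0.0, recipe.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    for lane in list(recipe.samples) + list(recipe.ladders):
        block = img[:, lane.col_start : lane.col_stop]
        sat = np.mean(block >= 1.0)
        if sat > 0.20:
            warnings.warn(
                f"lane {lane.label!r}: {sat:.0%} of pixels saturated at OD 1.0; "
                "densitometry requires loading within the dynamic range",
                UserWarning,
                stacklevel=2,
            )
    return GelImage(img, source="<synthetic>", format="synthetic"), truth


def selections_for(recipe: GelRecipe) -> list[LaneSelection]:
    """Lane selections matching the recipe's rendered columns (full height)."""
    out = []
    for lad in recipe.ladders:
        out.append(
            LaneSelection(
                lad.label, "marker", [Rect(lad.col_start, lad.col_stop, 0, recipe.height)]
            )
        )
    for lane in recipe.samples:
        out.append(
            LaneSelection(
                lane.label, "sample", [Rect(lane.col_start, lane.col_stop, 0, recipe.height)]
            )
        )
    return out


def default_demo_recipe(seed: int = 0) -> GelRecipe:
    """A small Arabidopsis-like demo gel: two ladders flanking four smears.

    Smears sit in the 2-4 kb range typical of wild-type *Arabidopsis
    thaliana* telomeres; one lane carries a band-like pattern as seen in
    telomerase mutants.
    """
    migration = MigrationCurve(a=820.0, b=85.0)
    ladder = LadderSpec(
        "demo-1kb", (10000, 8000, 6000, 5000, 4000, 3000, 2500, 2000, 1500, 1000, 750, 500)
    )
    samples = [
        SampleLane("S1", 60, 90, LognormalSmear(3000, 0.15)),
        SampleLane("S2", 100, 130, LognormalSmear(3300, 0.15)),
        SampleLane("S3", 140, 170, LognormalSmear(2400, 0.18)),
        SampleLane(
            "S4", 180, 210, BandMixture(((3800, 0.5), (2600, 0.3), (1800, 0.2)), rel_width=0.03)
        ),
    ]
    return GelRecipe(
        width=260,
        height=420,
        migration=migration,
        ladders=[
            LadderLane(ladder, 10, 40, label="M_left"),
            LadderLane(ladder, 220, 250, label="M_right"),
        ],
        samples=samples,
        tilt_rows=6.0,
        background=(0.02, 0.01, 0.03),
        blotches=[(60.0, 155.0, 6.0, 0.25)],
        noise_sigma=0.01,
        seed=seed,
    )
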