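"""Boxplot / violin presentation of per-lane telomere estimates.

The box drawn for each lane is exactly its five-number summary: central
line = weighted median, box = 1st/3rd weighted quartiles, whiskers =
min/max of the selected smear.  The violin outline is not a kernel density
of resampled points but the lane's own smoothed (background-corrected) OD
as a function of bp between min and max, area-normalized per lane, so
band-like multimodal smears keep their modes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calibration import CalibrationModel
from .densitometry import IntensityProfile
from .metrics import TelomereEstimate
from .selection import DEFAULT_SPAN, smooth

__all__ = ["violin_density", "render_plots"]


def violin_density(
    profile_values: np.ndarray,
    estimate: TelomereEstimate,
    model: CalibrationModel,
    span: float = DEFAULT_SPAN,
) -> tuple[np.ndarray, np.ndarray]:
    """(bp, density) pairs for one lane's violin, unit area, min..max range."""
    od = smooth(profile_values, span)
    b = estimate.borders
    rows = np.arange(b.left_row, b.right_row + 1)
    bp = np.atleast_1d(model(rows))
    order = np.argsort(bp)
    bp, dens = bp[order], od[rows][order]
    area = np.trapezoid(dens, bp)
    if area > 0:
        dens = dens / area
    return bp, dens


def render_plots(
    estimates: Sequence[TelomereEstimate],
    out: str | Path,
    style: str = "box",
    profiles: Sequence[IntensityProfile] | None = None,
    models: Sequence[CalibrationModel] | None = None,
    span: float = DEFAULT_SPAN,
) -> Path:
    """Write a box or violin panel of all lane estimates to ``out``."""
    if not estimates:
        raise ValueError("need at least one estimate to plot")
    if style not in ("box", "violin"):
        raise ValueError(f"unknown plot style {style!r}")
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(estimates), 4.5))
    positions = np.arange(1, len(estimates) + 1)

    if style == "box":
        stats_list = [
            {
                "label": e.label,
                "med": e.weighted_median_bp,
                "q1": e.q1_bp,
                "q3": e.q3_bp,
                "whislo": e.min_bp,
                "whishi": e.max_bp,
                "fliers": [],
            }
            for e in estimates
        ]
        ax.bxp(stats_list, positions=positions, showfliers=False)
    else:
        if profiles is None or models is None:
            raise ValueError("violin plots need the lane profiles and calibration models")
        for pos, (est, prof, model) in enumerate(zip(estimates, profiles, models), start=1):
            bp, dens = violin_density(np.asarray(prof.values, float), est, model, span)
            half = 0.4 * dens / dens.max() if dens.max() > 0 else dens
            ax.fill_betweenx(bp, pos - half, pos + half, alpha=0.6)
            ax.plot([pos], [est.weighted_median_bp], marker="s", color="black")
            ax.plot([pos, pos], [est.q1_bp, est.q3_bp], linestyle="none")
            ax.plot([pos], [est.q1_bp], marker="^", color="black", markersize=5)
            ax.plot([pos], [est.q3_bp], marker="v", color="black", markersize=5)
        ax.set_xticks(positions)
        ax.set_xticklabels([e.label for e in estimates])
    ax.set_ylabel("telomere length (bp)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
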