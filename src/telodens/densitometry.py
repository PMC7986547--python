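"""Gel scan loading and lane densitometry.

A terminal restriction fragment (TRF) scan is read as a grayscale optical
density (OD) matrix with values in [0, 1].  The convention throughout the
package is *signal is bright*: dark bands on a light background must be
loaded with ``invert=True`` so that high OD means more hybridisation signal.
Row index increases downward, i.e. with increasing migration distance and
decreasing fragment size.

Rectangular lane selections are reduced to one-dimensional intensity
profiles by summing pixel OD across the selected columns at each scan row.
Profiles are exchanged with other densitometry software through ``.xlsx``
workbooks (one column per lane, plus a metadata sheet with the pixel
coordinates of every selection).

Coordinates are 0-based and half-open internally; workbook metadata and
config files use 1-based inclusive coordinates, which is how users read
pixel positions off a gel image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "Rect",
    "GelImage",
    "LaneSelection",
    "IntensityProfile",
    "load_scan",
    "resize_scan",
    "extract_profile",
    "export_workbook",
    "import_workbook",
]

# ITU-R BT.709 luminance weights for RGB -> grayscale reduction
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class Rect:
    """Rectangular pixel selection, 0-based half-open ranges."""

    col_start: int
    col_stop: int
    row_start: int
    row_stop: int

    def __post_init__(self) -> None:
        if self.col_stop <= self.col_start or self.row_stop <= self.row_start:
            raise ValueError(f"empty rectangle {self}")

    @property
    def n_cols(self) -> int:
        return self.col_stop - self.col_start

    @property
    def n_rows(self) -> int:
        return self.row_stop - self.row_start

    @property
    def center_col(self) -> float:
        return (self.col_start + self.col_stop - 1) / 2.0

    def to_inclusive_1based(self) -> tuple[int, int, int, int]:
        return (self.col_start + 1, self.col_stop, self.row_start + 1, self.row_stop)

    @classmethod
    def from_inclusive_1based(cls, col_start: int, col_end: int, row_start: int, row_end: int) -> "Rect":
        return cls(col_start - 1, col_end, row_start - 1, row_end)


@dataclass
class GelImage:
    """Normalized grayscale scan: OD matrix in [0, 1], shape (height, width)."""

    pixels: np.ndarray
    source: str = "<memory>"
    format: str = "array"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixel matrix must be 2-D and non-empty")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LaneSelection:
    """User-drawn lane area: one rectangle for a sample, one or more for a marker."""

    label: str
    role: str
    rects: list[Rect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("marker", "sample"):
            raise ValueError(f"role must be 'marker' or 'sample', got {self.role!r}")
        if not self.rects:
            raise ValueError(f"selection {self.label!r} has no rectangles")
        if self.role == "sample" and len(self.rects) != 1:
            raise ValueError(f"sample {self.label!r} must have exactly one rectangle")

    @property
    def center_col(self) -> float:
        return float(np.mean([r.center_col for r in self.rects]))


@dataclass
class IntensityProfile:
    """Per-row summed OD of one lane, aligned to the scan rows.

    ``values[k]`` is the optical density of scan row ``k`` (the OD_k of the
    smear statistics); rows outside the selected area are zero.
    """

    values: np.ndarray
    label: str = ""
    role: str = "sample"
    selection: LaneSelection | None = None
    lane_center_col: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if self.values.size and self.values.min() < -1e-9:
            raise ValueError("profile values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


def _to_unit_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a decoded raster array to a luminance matrix in [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:
        a = a[..., :3].astype(float) @ _LUMA if a.shape[2] >= 3 else a[..., 0].astype(float)
    else:
        a = a.astype(float)
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(arr).dtype).max)
        a = a / scale
    return np.clip(a, 0.0, 1.0)


def load_scan(path: str | Path, invert: bool = False) -> GelImage:
    """Load a TRF scan (JPEG, BMP, PNG, TIFF ...) as a grayscale OD matrix.

    Color images are reduced by standard luminance weighting and integer
    pixel values rescaled so every OD lies in [0, 1].  With ``invert`` each
    value v becomes 1 - v; use it for dark-band-on-light-background scans so
    that hybridisation signal is bright.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            fmt = im.format or "unknown"
            arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    gray = _to_unit_gray(arr)
    if invert:
        gray = 1.0 - gray
    return GelImage(gray, source=str(path), format=fmt)


def resize_scan(img: GelImage, factor: float) -> GelImage:
    """Rescale a scan by ``factor`` using bilinear resampling.

    Dimensions are rounded to the nearest integer; the result must be at
    least 8 px on each side.
    """
    if factor <= 0:
        raise ValueError("resize factor must be positive")
    if factor == 1.0:
        return replace(img, pixels=img.pixels.copy())
    from skimage.transform import resize as _sk_resize

    new_shape = (int(round(img.height_px * factor)), int(round(img.width_px * factor)))
    if min(new_shape) < 8:
        raise ValueError(f"resized scan {new_shape} would be degenerate (< 8 px)")
    out = _sk_resize(img.pixels, new_shape, order=1, anti_aliasing=factor < 1, preserve_range=True)
    return replace(img, pixels=np.clip(out, 0.0, 1.0))


def _check_rect_bounds(rect: Rect, img: GelImage, label: str) -> None:
    if (
        rect.col_start < 0
        or rect.row_start < 0
        or rect.col_stop > img.width_px
        or rect.row_stop > img.height_px
    ):
        raise ValueError(
            f"selection {label!r}: rectangle {rect} outside image "
            f"{img.height_px}x{img.width_px}"
        )


def extract_profile(img: GelImage, sel: LaneSelection) -> IntensityProfile:
    """Sum pixel OD across a selection's columns at each scan row.

    A marker drawn from several rectangles (adjacent ladder lanes) is merged
    into a single profile by averaging the per-rectangle row sums, so that a
    ladder built from two or three rectangles has comparable magnitude.
    """
    per_rect = []
    for rect in sel.rects:
        _check_rect_bounds(rect, img, sel.label)
        v = np.zeros(img.height_px)
        v[rect.row_start : rect.row_stop] = img.pixels[
            rect.row_start : rect.row_stop, rect.col_start : rect.col_stop
        ].sum(axis=1)
        per_rect.append(v)
    values = per_rect[0] if len(per_rect) == 1 else np.mean(per_rect, axis=0)
    return IntensityProfile(
        values, label=sel.label, role=sel.role, selection=sel, lane_center_col=sel.center_col
    )


def export_workbook(profiles: Sequence[IntensityProfile], path: str | Path) -> None:
    """Write profiles to an .xlsx workbook.

    Sheet ``profiles`` holds one column per lane (header = label); sheet
    ``selections`` records each rectangle's pixel coordinates (1-based
    inclusive) and the lane role.
    """
    if not profiles:
        raise ValueError("need at least one profile to export")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("all profiles must share the scan height")
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "profiles"
    ws.append([p.label for p in profiles])
    for k in range(n):
        ws.append([float(p.values[k]) for p in profiles])
    meta = wb.create_sheet("selections")
    meta.append(["label", "role", "rect_index", "col_start", "col_end", "row_start", "row_end"])
    for p in profiles:
        if p.selection is None:
            continue
        for idx, rect in enumerate(p.selection.rects):
            c0, c1, r0, r1 = rect.to_inclusive_1based()
            meta.append([p.label, p.role, idx, c0, c1, r0, r1])
    try:
        wb.save(Path(path))
    except OSError as exc:
        raise OSError(f"cannot write workbook {path}: {exc}") from exc


def import_workbook(path: str | Path) -> list[IntensityProfile]:
    """Read lane profiles from an .xlsx/.xls workbook.

    Accepts this package's own exports as well as plain spreadsheets from
    third-party densitometry programs (one numeric column per lane, header
    row with lane labels).  When a ``selections`` metadata sheet is present
    the selections and roles are reattached; otherwise every profile gets
    role ``sample`` and an unknown selection.
    """
    from openpyxl import load_workbook

    wb = load_workbook(Path(path), read_only=False, data_only=True)
    sheet = wb["profiles"] if "profiles" in wb.sheetnames else wb[wb.sheetnames[0]]
    rows = list(sheet.iter_rows(values_only=True))
    if not rows or all(c is None for c in rows[0]):
        raise ValueError(f"workbook {path}: empty profile sheet")
    headers = [str(c) if c is not None else f"lane{i+1}" for i, c in enumerate(rows[0])]
    body = rows[1:]
    cols: dict[str, list[float]] = {h: [] for h in headers}
    for r in body:
        for h, c in zip(headers, r):
            if c is None:
                continue
            if not isinstance(c, (int, float)):
                raise ValueError(f"workbook {path}: non-numeric cell {c!r} in column {h!r}")
            cols[h].append(float(c))
    lengths = {len(v) for v in cols.values()}
    if lengths == {0}:
        raise ValueError(f"workbook {path}: no numeric data below the header row")
    if len(lengths) != 1:
        raise ValueError(f"workbook {path}: ragged column lengths {sorted(lengths)}")

    selections: dict[str, LaneSelection] = {}
    if "selections" in wb.sheetnames:
        meta_rows = list(wb["selections"].iter_rows(values_only=True))[1:]
        by_label: dict[str, tuple[str, list[Rect]]] = {}
        for row in meta_rows:
            if row is None or row[0] is None:
                continue
            label, role, _idx, c0, c1, r0, r1 = row[:7]
            rect = Rect.from_inclusive_1based(int(c0), int(c1), int(r0), int(r1))
            by_label.setdefault(str(label), (str(role), []))[1].append(rect)
        for label, (role, rects) in by_label.items():
            selections[label] = LaneSelection(label, role, rects)

    profiles = []
    for h in headers:
        sel = selections.get(h)
        profiles.append(
            IntensityProfile(
                np.asarray(cols[h]),
                label=h,
                role=sel.role if sel else "sample",
                selection=sel,
                lane_center_col=sel.center_col if sel else float("nan"),
            )
        )
    return profiles
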