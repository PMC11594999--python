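"""Reading and writing lifetime matrices, ROIs and cohort manifests.

A *lifetime matrix* is a 2-D ``float64`` numpy array of per-pixel mean
fluorescence lifetimes in picoseconds.  Pixels without a lifetime estimate
(e.g. masked extracellular plasma) are encoded as NaN; NaN is legal in a
stored matrix but rejected inside a declared region of interest, because
every downstream statistic is defined on a fully observed rectangle.

Coordinate convention: 0-based, half-open rectangles, ``x`` = column,
``y`` = row, origin at the top-left — i.e. ``values[y0:y1, x0:x1]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ROIRect",
    "CellRecord",
    "MANIFEST_COLUMNS",
    "as_lifetime_matrix",
    "read_lifetime_matrix",
    "write_lifetime_matrix",
    "extract_roi",
    "read_manifest",
    "write_manifest",
    "manifest_frame",
]

#: Mandatory manifest columns, in canonical order.
MANIFEST_COLUMNS = (
    "cell_id",
    "patient_id",
    "group",
    "subtype",
    "shape_class",
    "roi_x0",
    "roi_y0",
    "roi_x1",
    "roi_y1",
    "path",
)


@dataclass(frozen=True)
class ROIRect:
    """Axis-aligned rectangle, 0-based half-open: ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"ROI coordinate {name}={v!r} is not an integer")
            object.__setattr__(self, name, int(v))
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate ROI rectangle {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def within(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= w and self.y1 <= h


@dataclass
class CellRecord:
    """Identity and provenance of one imaged cell."""

    cell_id: str
    patient_id: str
    group: str  # "control" | "scd"
    subtype: str  # e.g. "control", "nonsickled", "sickled"
    shape_class: str  # "round" | "sickled"
    roi: ROIRect
    path: str = ""
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "cell_id": self.cell_id,
            "patient_id": self.patient_id,
            "group": self.group,
            "subtype": self.subtype,
            "shape_class": self.shape_class,
            "roi_x0": self.roi.x0,
            "roi_y0": self.roi.y0,
            "roi_x1": self.roi.x1,
            "roi_y1": self.roi.y1,
            "path": self.path,
        }
        row.update(self.extra)
        return row


def as_lifetime_matrix(values) -> np.ndarray:
    """Validate and coerce *values* into a lifetime matrix.

    Raises ``ValueError`` for non-2-D input, zero-sized axes, or finite
    negative lifetimes.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"lifetime matrix must be 2-D, got shape {m.shape}")
    if m.shape[0] < 1 or m.shape[1] < 1:
        raise ValueError(f"lifetime matrix must be at least 1x1, got {m.shape}")
    finite = m[np.isfinite(m)]
    if finite.size and finite.min() < 0:
        raise ValueError("lifetime matrix contains negative lifetimes")
    return m


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    if suffix in {".tif", ".tiff"}:
        return "tiff"
    raise ValueError(f"cannot infer matrix format from suffix {suffix!r}")


def read_lifetime_matrix(path, format: str | None = None) -> np.ndarray:
    """Read a lifetime matrix from tab-separated text or single-channel TIFF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        rows: list[list[float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    rows.append([float(tok) for tok in line.split("\t")])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
        if not rows:
            raise ValueError(f"{path}: empty matrix file")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
        return as_lifetime_matrix(np.array(rows, dtype=float))
    if fmt == "tiff":
        m = tifffile.imread(path)
        return as_lifetime_matrix(np.asarray(m, dtype=float))
    raise ValueError(f"unsupported matrix format {fmt!r}")


def write_lifetime_matrix(m, path, format: str | None = None) -> Path:
    """Write a matrix as .tsv (bit-exact round trip) or 32-bit float TIFF."""
    m = as_lifetime_matrix(m)
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        with open(path, "w") as fh:
            for row in m:
                fh.write("\t".join(repr(float(v)) for v in row))
                fh.write("\n")
    elif fmt == "tiff":
        tifffile.imwrite(path, m.astype(np.float32), photometric="minisblack")
    else:
        raise ValueError(f"unsupported matrix format {fmt!r}")
    return path


def extract_roi(m, roi: ROIRect, *, allow_nan: bool = False) -> np.ndarray:
    """Return a copy of the ROI interior of *m*.

    NaN inside a declared ROI is rejected unless ``allow_nan`` — statistics
    are only defined on fully observed rectangles strictly inside the cell.
    """
    m = as_lifetime_matrix(m)
    if not roi.within(m.shape):
        raise ValueError(f"ROI {roi} exceeds matrix bounds {m.shape}")
    out = m[roi.y0 : roi.y1, roi.x0 : roi.x1].copy()
    if not allow_nan and np.isnan(out).any():
        raise ValueError(f"ROI {roi} contains NaN pixels")
    return out


def manifest_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Tabulate records; mandatory columns first, extras preserved after."""
    rows = [r.to_row() for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    extras = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    return df[list(MANIFEST_COLUMNS) + extras]


def write_manifest(records: Iterable[CellRecord] | pd.DataFrame, path) -> Path:
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else manifest_frame(records)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing mandatory columns: {missing}")
    df.to_csv(path, sep="\t", index=False)
    return path


def _record_from_row(row: Mapping) -> CellRecord:
    roi = ROIRect(int(row["roi_x0"]), int(row["roi_y0"]), int(row["roi_x1"]), int(row["roi_y1"]))
    extra = {k: v for k, v in row.items() if k not in MANIFEST_COLUMNS}
    return CellRecord(
        cell_id=str(row["cell_id"]),
        patient_id=str(row["patient_id"]),
        group=str(row["group"]),
        subtype=str(row["subtype"]),
        shape_class=str(row["shape_class"]),
        roi=roi,
        path=str(row["path"]) if not pd.isna(row["path"]) else "",
        extra=extra,
    )


def read_manifest(path) -> list[CellRecord]:
    """Read a tab-separated manifest into cell records; extras preserved."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing mandatory columns: {missing}")
    return [_record_from_row(row) for _, row in df.iterrows()]
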