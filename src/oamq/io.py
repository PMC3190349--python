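"""File readers and writers: NIfTI/TIFF mask stacks, CSV tables, YAML.

Conventions: mask stacks are held as ``(slices, rows, cols)`` boolean
arrays with in-plane pixel spacing and slice spacing in mm (slice
spacing = slice thickness plus inter-slice gap); any nonzero voxel is
foreground. CSV files are UTF-8 with a header row and '.' decimal;
numeric output keeps full double precision — rounding happens only in
human-readable summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .bml import BmlMeasurement, Region, Timepoint

logger = logging.getLogger(__name__)

__all__ = [
    "MaskStack",
    "read_mask_stack",
    "write_mask_stack",
    "read_lesion_table",
    "read_annotations",
    "LESION_TABLE_COLUMNS",
]

LESION_TABLE_COLUMNS = [
    "lesion_id",
    "knee_id",
    "region",
    "timepoint",
    "ap_cm",
    "ml_cm",
    "si_cm",
    "peak_signal",
    "reference_signal",
    "n_sagittal_slices",
    "n_coronal_slices",
]


class SchemaError(ValueError):
    """A table is missing required columns or contains invalid rows."""


class GeometryError(ValueError):
    """Mask geometry metadata is missing or inconsistent."""


@dataclass(frozen=True)
class MaskStack:
    """A binary mask stack with physical geometry."""

    data: np.ndarray  # (slices, rows, cols) bool
    pixel_spacing_mm: tuple[float, float]
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=bool)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 3:
            raise GeometryError("mask stack must be 3-dimensional")
        if not all(s > 0 for s in self.pixel_spacing_mm) or not self.slice_spacing_mm > 0:
            raise GeometryError("all spacings must be > 0")

    @property
    def n_slices(self) -> int:
        return int(self.data.shape[0])


def write_mask_stack(stack: MaskStack, path: str | Path) -> Path:
    """Write a mask stack as NIfTI-1 with spacings in the header.

    The on-disk axis order is (col, row, slice) per NIfTI convention;
    :func:`read_mask_stack` restores the in-memory (slice, row, col)
    order.
    """
    path = Path(path)
    sr, sc = stack.pixel_spacing_mm
    # in-memory (slice, row, col) -> on-disk (col, row, slice)
    vol = np.transpose(stack.data.astype(np.uint8), (2, 1, 0))
    affine = np.diag([sc, sr, stack.slice_spacing_mm, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((sc, sr, stack.slice_spacing_mm))
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> MaskStack:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not z > 0 for z in zooms):
        raise GeometryError(
            f"{path}: NIfTI header has non-positive zooms {zooms}; "
            "pixel_spacing_mm/slice_spacing_mm unavailable"
        )
    vol = np.asanyarray(img.dataobj) != 0
    if vol.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got {vol.ndim}D")
    data = np.transpose(vol, (2, 1, 0))  # (col,row,slice) -> (slice,row,col)
    sc, sr, sz = (float(z) for z in zooms)
    return MaskStack(data=data, pixel_spacing_mm=(sr, sc), slice_spacing_mm=sz)


def _read_tiff(path: Path) -> MaskStack:
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise GeometryError(
            f"{path}: TIFF masks need a YAML sidecar with pixel_spacing_mm "
            "and slice_spacing_mm; none found"
        )
    meta = yaml.safe_load(sidecar.read_text(encoding="utf-8")) or {}
    for key in ("pixel_spacing_mm", "slice_spacing_mm"):
        if key not in meta:
            raise GeometryError(f"{sidecar}: missing required field {key!r}")
    ps = meta["pixel_spacing_mm"]
    if np.isscalar(ps):
        ps = (float(ps), float(ps))
    else:
        ps = (float(ps[0]), float(ps[1]))
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return MaskStack(
        data=arr != 0,
        pixel_spacing_mm=ps,
        slice_spacing_mm=float(meta["slice_spacing_mm"]),
    )


def read_mask_stack(path: str | Path) -> MaskStack:
    """Read a binary mask stack from NIfTI-1 or multi-page TIFF + sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith((".tif", ".tiff")):
        return _read_tiff(path)
    raise ValueError(f"{path}: unsupported mask format (need .nii[.gz] or .tif[f])")


def read_lesion_table(path: str | Path) -> list[BmlMeasurement]:
    """Read and validate a lesion-measurement CSV.

    One row per lesion per timepoint. Rows violating the measurement
    invariants raise with their (1-based, header-exclusive) row number;
    rows failing the slice-visibility rule (fewer than 2 sagittal and 2
    coronal slices) are rejected the same way, since such findings do
    not qualify as lesions.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in LESION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out: list[BmlMeasurement] = []
    for i, row in df.iterrows():
        rownum = int(i) + 1
        try:
            m = BmlMeasurement(
                lesion_id=str(row["lesion_id"]),
                knee_id=str(row["knee_id"]),
                region=Region(str(row["region"])),
                timepoint=Timepoint(str(row["timepoint"])),
                ap_cm=float(row["ap_cm"]),
                ml_cm=float(row["ml_cm"]),
                si_cm=float(row["si_cm"]),
                peak_signal=float(row["peak_signal"]),
                reference_signal=float(row["reference_signal"]),
                n_sagittal_slices=int(row["n_sagittal_slices"]),
                n_coronal_slices=int(row["n_coronal_slices"]),
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}: row {rownum}: {exc}") from exc
        if not m.is_valid_lesion:
            raise SchemaError(
                f"{path}: row {rownum}: lesion {m.lesion_id} visible on "
                "fewer than 2 sagittal and 2 coronal slices — not a valid BML"
            )
        out.append(m)
    return out


def read_annotations(path: str | Path) -> dict[int, list[tuple[int, int]]]:
    """Read lesion-gap annotations: CSV of slice_index, label_a, label_b."""
    df = pd.read_csv(path, comment="#")
    for col in ("slice_index", "label_a", "label_b"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out: dict[int, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["slice_index"]), []).append(
            (int(row["label_a"]), int(row["label_b"]))
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> Path:
    """Write a DataFrame as CSV, optionally preceded by a '#' comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
    return path
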