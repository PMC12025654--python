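"""Image, ROI, and cohort-table I/O with explicit coordinate conventions.

All rasters are 0-based, row-major, and pixel-centered.  The physical
pixel scale is never inferred from file metadata: it is a required
argument, defaulting to 6 mm / 500 px = 0.012 mm/px only where a whole
pipeline is configured at once.  Integer images round-trip losslessly.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, FormatError, SchemaError
from .synthetic import COHORT_COLUMNS, DEFAULT_PIXEL_SCALE_MM


@dataclasses.dataclass
class EnFaceAngiogram:
    """A 2-D en-face OCTA intensity grid with isotropic physical scale."""

    data: np.ndarray
    pixel_scale_mm: float
    quality: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or 0 in self.data.shape:
            raise FormatError(f"angiogram must be a non-empty 2-D grid, got shape {self.data.shape}")
        if self.pixel_scale_mm <= 0:
            raise FormatError("pixel_scale_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def field_size_mm(self) -> float:
        return self.data.shape[1] * self.pixel_scale_mm


@dataclasses.dataclass
class MnvRoi:
    """Binary inclusion mask delineating the MNV region on its angiogram."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("ROI mask must be 2-D")

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def read_angiogram(path, pixel_scale_mm: float) -> EnFaceAngiogram:
    """Read a grayscale TIFF/PNG angiogram and attach its pixel scale.

    Integer intensities are preserved exactly.  Multi-channel (RGB)
    input is rejected: en-face decorrelation images are single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            data = tifffile.imread(path)
        else:
            from PIL import Image

            data = np.asarray(Image.open(path))
    except (IOError, OSError):
        raise
    except Exception as exc:  # corrupt container formats raise various errors
        raise IOError(f"unreadable image {path}: {exc}") from exc
    if np.asarray(data).ndim != 2:
        raise FormatError(
            f"{path} is not a single-channel 2-D image (shape {np.asarray(data).shape}); "
            "RGB/stacked input is not supported"
        )
    return EnFaceAngiogram(data=data, pixel_scale_mm=pixel_scale_mm)


def write_angiogram(img: EnFaceAngiogram, path) -> None:
    """Write as 16-bit grayscale TIFF (floats in [0, 1] are scaled)."""
    import tifffile

    path = Path(path)
    data = img.data
    if np.issubdtype(data.dtype, np.floating):
        data = np.round(np.clip(data, 0.0, 1.0) * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, data)


def _rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd polygon fill sampled at pixel centers.

    ``vertices`` are float (row, col) pairs; a pixel is inside when its
    center (integer row, col) lies inside the polygon.
    """
    from matplotlib.path import Path as MplPath

    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise FormatError("polygon ROI needs >= 3 [row, col] vertices")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([cc.ravel(), rr.ravel()])  # (x, y) order
    poly = MplPath(vertices[:, ::-1])  # (col, row) -> (x, y)
    inside = poly.contains_points(pts).reshape(shape)
    return inside


def read_roi(path, shape: tuple[int, int]) -> MnvRoi:
    """Read an ROI (PNG mask or polygon JSON) congruent with ``shape``.

    Mask PNGs are thresholded at zero ({0, 255} convention); polygon
    JSON files hold ``{"vertices": [[row, col], ...]}`` in pixel
    coordinates and are rasterized with pixel-center containment.  An
    empty ROI is flagged with a warning, not an error, so batch runs can
    record the failure per eye.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such ROI: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        vertices = payload["vertices"] if isinstance(payload, dict) else payload
        mask = _rasterize_polygon(np.asarray(vertices, dtype=float), shape)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
        if arr.ndim != 2:
            raise FormatError(f"ROI mask {path} must be single-channel")
        if arr.shape != tuple(shape):
            raise FormatError(
                f"ROI shape {arr.shape} does not match image shape {tuple(shape)}"
            )
        mask = arr > 0
    roi = MnvRoi(mask=mask)
    if roi.empty:
        warnings.warn(f"ROI {path} is empty", stacklevel=2)
    return roi


def write_roi(roi: MnvRoi, path) -> None:
    from PIL import Image

    Image.fromarray((roi.mask.astype(np.uint8)) * 255).save(Path(path))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and value constraints of a cohort table.

    Returns a typed copy.  Violations raise :class:`SchemaError` (missing
    columns) or :class:`CohortValidationError` listing offending rows.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    out = df.copy()
    bad_rows: list[int] = []
    messages: list[str] = []

    type_bad = ~out["mnv_type"].isin([1, 2, 3])
    if type_bad.any():
        rows = list(np.flatnonzero(type_bad.to_numpy()))
        bad_rows += rows
        messages.append(f"mnv_type outside {{1,2,3}} at rows {rows}")

    for col in ("bcva_baseline_logmar", "bcva_3y_logmar"):
        nonfinite = ~np.isfinite(out[col].to_numpy(dtype=float))
        if nonfinite.any():
            rows = list(np.flatnonzero(nonfinite))
            bad_rows += rows
            messages.append(f"{col} non-finite at rows {rows}")

    ivi = out["ivi_count_3y"].to_numpy()
    ivi_bad = (~np.isfinite(ivi.astype(float))) | (ivi.astype(float) < 0) | (
        ivi.astype(float) != np.round(ivi.astype(float))
    )
    if ivi_bad.any():
        rows = list(np.flatnonzero(ivi_bad))
        bad_rows += rows
        messages.append(f"ivi_count_3y not a non-negative integer at rows {rows}")

    for col in ("area_mm2", "suml_mm", "fd", "flow_density_pct"):
        vals = out[col].to_numpy(dtype=float)
        neg = (~np.isfinite(vals)) | (vals < 0)
        if neg.any():
            rows = list(np.flatnonzero(neg))
            bad_rows += rows
            messages.append(f"{col} negative or non-finite at rows {rows}")

    if messages:
        raise CohortValidationError("; ".join(messages), rows=sorted(set(bad_rows)))

    out["mnv_type"] = out["mnv_type"].astype(int)
    out["ivi_count_3y"] = out["ivi_count_3y"].astype(int)
    for col in ("area_mm2", "suml_mm", "fd", "flow_density_pct",
                "bcva_baseline_logmar", "bcva_3y_logmar"):
        out[col] = out[col].astype(float)
    return out


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such cohort file: {path}")
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)


def write_results(report: dict, path) -> None:
    """Serialize an analysis/metrics report as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, default=float))
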