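"""Readers and writers for the tabular and volumetric formats of the pipeline.

Tables are UTF-8 CSV with dot decimals; volumes are multi-page TIFF stacks or
NIfTI files. Voxel size comes from NIfTI headers or a YAML sidecar
(``<volume>.meta.yaml`` with keys dz/dy/dx in mm) and falls back to the
scanner defaults 0.9 x 0.6 x 0.6 mm with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .ct import DEFAULT_VOXEL_SIZE_MM, CoreVolume

__all__ = [
    "ColumnSpec",
    "TableSchema",
    "SchemaError",
    "FORAM_SCHEMA",
    "USERIES_SCHEMA",
    "CORAL_DATE_SCHEMA",
    "HYDRO_SCHEMA",
    "SLICE_CONTENT_SCHEMA",
    "read_table",
    "read_volume",
    "write_volume",
    "load_slice_content",
    "summarize_slice_content",
]

log = logging.getLogger("coralmound")


class SchemaError(ValueError):
    """A mandatory column is missing or the header cannot be interpreted."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    aliases: Tuple[str, ...] = ()
    required: bool = True
    default: Optional[float] = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: Tuple[ColumnSpec, ...]


def _normalize(header: str) -> str:
    # case-insensitive, tolerate unit suffixes like "mgca (mmol/mol)"
    h = header.strip().lower()
    for sep in ("(", "["):
        if sep in h:
            h = h.split(sep)[0]
    return h.strip().replace(" ", "_").replace("-", "_")


FORAM_SCHEMA = TableSchema("foram", (
    ColumnSpec("depth_cm", ("depth",)),
    ColumnSpec("mgca", ("mg_ca",)),
    ColumnSpec("d18o_c", ("d18o", "d18oc")),
    ColumnSpec("alca", ("al_ca",), required=False),
    ColumnSpec("feca", ("fe_ca",), required=False),
    ColumnSpec("sd2_mgca", (), required=False, default=0.1),
    ColumnSpec("sd2_d18o", (), required=False, default=0.06),
))

USERIES_SCHEMA = TableSchema("useries", (
    ColumnSpec("sample_id", ("id", "sample")),
    ColumnSpec("depth_cm", ("depth",)),
    ColumnSpec("ar230_238", ("230th_238u", "ar230")),
    ColumnSpec("sd2_ar230", ("sd2_230",)),
    ColumnSpec("d234U", ("d234u", "d234u_measured"), required=False),
    ColumnSpec("ar234_238", (), required=False),
    ColumnSpec("sd2_d234U", ("sd2_d234u", "sd2_234")),
    ColumnSpec("th232_ppb", ("232th_ppb", "th232")),
))

CORAL_DATE_SCHEMA = TableSchema("coral_dates", (
    ColumnSpec("depth_cm", ("depth",)),
    ColumnSpec("age_ka", ("age",)),
    ColumnSpec("sd2_age_ka", ("sd2", "sd2_age"), required=False, default=0.0),
    ColumnSpec("reliable", (), required=False, default=1.0),
))

HYDRO_SCHEMA = TableSchema("hydrography", (
    ColumnSpec("depth_m", ("depth",)),
    ColumnSpec("temperature", ("t", "temp")),
    ColumnSpec("salinity", ("s", "sal")),
    ColumnSpec("pressure_dbar", ("pressure", "p"), required=False),
    ColumnSpec("d18o_sw", ("d18osw",), required=False),
    ColumnSpec("sigma_theta", ("sigma",), required=False),
))

SLICE_CONTENT_SCHEMA = TableSchema("slice_content", (
    ColumnSpec("slice_index", ("slice", "index"), required=False),
    ColumnSpec("depth_mm", ("depth",), required=False),
    ColumnSpec("coral_percent", ("coral", "percent", "coral_vol_percent")),
))


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV against a schema: alias-tolerant headers, typed columns.

    Rows with non-numeric cells in required numeric columns are dropped with
    a logged warning carrying their line numbers; a missing required column
    raises :class:`SchemaError` naming the expectation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    lookup: Dict[str, str] = {}
    for col in raw.columns:
        lookup[_normalize(col)] = col

    out = pd.DataFrame(index=raw.index)
    for spec in schema.columns:
        src = None
        for cand in (spec.name.lower(), *[a.lower() for a in spec.aliases]):
            if cand in lookup:
                src = lookup[cand]
                break
        if src is None:
            if spec.required:
                raise SchemaError(
                    f"table '{schema.name}' at {path} is missing mandatory "
                    f"column '{spec.name}' (accepted aliases: {list(spec.aliases)}; "
                    f"found: {list(raw.columns)})"
                )
            if spec.default is not None:
                out[spec.name] = spec.default
            continue
        out[spec.name] = raw[src]

    numeric_cols = [c for c in out.columns if c != "sample_id"]
    bad = pd.Series(False, index=out.index)
    for c in numeric_cols:
        coerced = pd.to_numeric(out[c], errors="coerce")
        newly_bad = coerced.isna() & out[c].notna()
        bad |= newly_bad
        out[c] = coerced
    required_numeric = [
        s.name for s in schema.columns if s.required and s.name != "sample_id"
        and s.name in out.columns
    ]
    if required_numeric:
        bad |= out[required_numeric].isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in out.index[bad]]  # +2: header + 1-based
        log.warning("%s: dropped %d invalid row(s) at line(s) %s",
                    path, int(bad.sum()), lines)
        out = out[~bad].reset_index(drop=True)
    return out


def _read_sidecar_voxel_size(path: Path) -> Optional[Tuple[float, float, float]]:
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if not sidecar.exists():
        return None
    meta = yaml.safe_load(sidecar.read_text())
    try:
        return (float(meta["dz"]), float(meta["dy"]), float(meta["dx"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"sidecar {sidecar} must define dz, dy, dx in mm") from exc


def read_volume(path, voi_mask_path=None) -> CoreVolume:
    """Read a TIFF stack or NIfTI volume into a :class:`CoreVolume`.

    The slice axis is array axis 0. An optional VOI mask volume (same format,
    nonzero = inside) can accompany the data. When no voxel-size metadata is
    available, the defaults 0.9 x 0.6 x 0.6 mm are applied with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = "".join(path.suffixes).lower()
    voxel_size = _read_sidecar_voxel_size(path)
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: a 3-D volume is required, got {data.ndim}-D")
        # NIfTI is (x, y, z); move the slice axis first.
        data = np.transpose(data, (2, 1, 0))
        if voxel_size is None:
            zooms = img.header.get_zooms()[:3]
            if all(z > 0 for z in zooms):
                voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    else:
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValueError(f"{path}: a 3-D volume is required, got {data.ndim}-D")
    if voxel_size is None:
        warnings.warn(
            f"{path}: no voxel-size metadata; assuming "
            f"{DEFAULT_VOXEL_SIZE_MM} mm (dz, dy, dx)", stacklevel=2,
        )
        voxel_size = DEFAULT_VOXEL_SIZE_MM
    voi = None
    if voi_mask_path is not None:
        voi = read_volume(voi_mask_path).voxels > 0
    return CoreVolume(data, voxel_size, voi)


def write_volume(path, volume: CoreVolume) -> None:
    """Write a volume as multi-page TIFF plus a voxel-size sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(volume.voxels, dtype=np.float32),
                     photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    dz, dy, dx = volume.voxel_size
    sidecar.write_text(yaml.safe_dump({"dz": float(dz), "dy": float(dy),
                                       "dx": float(dx)}))


def load_slice_content(path) -> pd.DataFrame:
    """Load a per-slice coral-content table (e.g. a published supplement)."""
    return read_table(path, SLICE_CONTENT_SCHEMA)


def summarize_slice_content(df: pd.DataFrame) -> Dict[str, float]:
    """Mean/max/min coral percent of an ingested per-slice table."""
    vals = df["coral_percent"].astype(float)
    vals = vals[np.isfinite(vals)]
    if vals.empty:
        raise ValueError("no finite coral_percent values")
    return {
        "mean_percent": float(vals.mean()),
        "max_percent": float(vals.max()),
        "min_percent": float(vals.min()),
        "n_slices": int(vals.size),
    }
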