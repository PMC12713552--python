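"""Readers/writers for the pipeline's CSV, image, and mask formats.

Fiber tables follow the per-fiber CSV dialect of commercial morphometry
exports: one row per measured object with ``area_um2`` and ``minferet_um``
columns (extra columns pass through untouched). Output files carry a
provenance comment header (package version, seed, config hash) so a run
can be traced; readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .samples import BiopsySample, normalize_sex
from .segmentation import LabelMask

REQUIRED_FIBER_COLUMNS = ("area_um2", "minferet_um")

_YEARS = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:y|yr|yrs|year|years)\s*$", re.I)
_MONTHS = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:m|mo|mos|month|months)\s*$", re.I)
_NUMERIC = re.compile(r"^\s*\d+(?:\.\d+)?\s*$")


def parse_age_months(value) -> float:
    """Parse an age to real-valued completed months.

    Accepts plain numbers (months), ``"7 years"``/``"7y"``, and
    ``"6 months"``/``"6m"``. Range expressions like ``"0-3 months"`` are
    rejected: an exact age is required for cohort assignment.
    """
    s = str(value)
    if _NUMERIC.match(s):
        return float(s)
    m = _YEARS.match(s)
    if m:
        return float(m.group(1)) * 12.0
    m = _MONTHS.match(s)
    if m:
        return float(m.group(1))
    raise ValueError(
        f"cannot parse age {value!r}: give months (numeric, 'Nm') or years ('Ny'); "
        "age ranges are not accepted"
    )


def provenance_header(seed=None, config: dict | None = None) -> str:
    from . import __version__

    h = hashlib.sha1(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# myosize v{__version__} | seed={seed} | config_sha1={h}"


def write_fiber_csv(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write a per-fiber table with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        df.to_csv(fh, index=False)


def read_fiber_csv(path) -> pd.DataFrame:
    """Read a per-fiber measurement CSV (μm / μm² units).

    Requires ``area_um2`` and ``minferet_um`` columns; any extra columns
    are preserved. Comment lines starting with ``#`` are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty: no fiber measurements") from None
    if df.empty and df.columns.empty:
        raise ValueError(f"{path} is empty: no fiber measurements")
    for col in REQUIRED_FIBER_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path} is missing required column {col!r}")
    return df


def read_metadata_csv(path) -> list[BiopsySample]:
    """Read biopsy metadata into :class:`BiopsySample` stubs.

    Columns: ``sample_id``, ``age`` (or ``age_months``), ``sex``, and
    optionally ``muscle_site`` and ``fibers_csv_path`` (loaded when
    present). Sex is normalized to male/female, ages to months; errors
    carry the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "age" not in df.columns and "age_months" not in df.columns:
        raise ValueError(f"{path} needs an 'age' or 'age_months' column")
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise ValueError(f"{path} needs 'sample_id' and 'sex' columns")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id(s) in {path}: {sorted(set(dup))}")
    age_col = "age_months" if "age_months" in df.columns else "age"
    out = []
    for i, row in df.iterrows():
        try:
            age = parse_age_months(row[age_col])
        except ValueError as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from None
        fibers = pd.DataFrame(columns=["label_id", "area_um2", "minferet_um"])
        fpath = row.get("fibers_csv_path")
        if isinstance(fpath, str) and fpath:
            fpath = Path(fpath)
            if not fpath.is_absolute():
                fpath = path.parent / fpath
            fibers = read_fiber_csv(fpath)
        out.append(
            BiopsySample(
                sample_id=str(row["sample_id"]),
                age_months=age,
                sex=normalize_sex(row["sex"]),
                fibers=fibers,
                muscle_site=str(row.get("muscle_site", "unknown")),
            )
        )
    return out


def write_label_mask(mask: LabelMask, path) -> None:
    """Write a label mask as 16-bit TIFF (pixel size in the description)."""
    if mask.data.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(
        path, mask.data.astype(np.uint16),
        description=json.dumps({"pixel_size_um": mask.pixel_size}),
    )


def read_label_mask(path, pixel_size: float | None = None) -> LabelMask:
    """Read a 16-bit TIFF label mask; pixel size from tags unless given."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if pixel_size is None:
            desc = tf.pages[0].tags.get("ImageDescription")
            try:
                pixel_size = float(json.loads(desc.value)["pixel_size_um"])
            except Exception:
                raise ValueError(
                    f"{path} carries no pixel size; pass pixel_size explicitly"
                ) from None
    return LabelMask(np.asarray(data).astype(np.int32), pixel_size)


def write_image(image: np.ndarray, path) -> None:
    """Write an RGB section image as TIFF or PNG depending on suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def write_json(obj, path, seed=None, config: dict | None = None) -> None:
    payload = {"_provenance": provenance_header(seed, config).lstrip("# "), **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
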