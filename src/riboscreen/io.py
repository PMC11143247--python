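"""File input/output: plate images, plate maps, measurement tables, curves."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_image(path, image: np.ndarray) -> Path:
    """Write a grayscale plate image (16-bit TIFF by default, PNG supported).

    TIFFs are written without a datetime tag so reruns are byte-identical.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image, photometric="minisblack", software=None)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, image)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return path


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG plate image as a 2D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse any accidental channel axis
        img = img.mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"{path} is not a 2D grayscale image")
    return img


def write_plate_map(path, plate_map: pd.DataFrame) -> Path:
    path = Path(path)
    plate_map.to_csv(path, index=False)
    return path


def read_plate_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"row", "col", "strain_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map {path} missing columns: {sorted(missing)}")
    if "plate_id" not in df.columns:
        df.insert(0, "plate_id", "plate1")
    return df


def read_curves(path) -> pd.DataFrame:
    """Read long-format plate-reader data (well, condition, time, OD, F)."""
    df = pd.read_csv(path)
    required = {"well", "time_h", "od600", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curves file {path} missing columns: {sorted(missing)}")
    if "is_blank" not in df.columns:
        df["is_blank"] = False
    if "condition_molar" not in df.columns:
        df["condition_molar"] = 0.0
    return df


def read_per_strain_table(path, strain_col: str | None = None,
                          value_col: str | None = None) -> pd.DataFrame:
    """Read an external per-strain screen table (CSV or Excel).

    Accepts a deposited screen datafile with one row per strain and a value
    column of replicate-mean corrected ratios; returns the ``strain_id, mean,
    sd, n`` schema used by the index/hit-calling stage. Column names are
    matched case-insensitively when not given explicitly.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if strain_col is None:
        for cand in ("strain_id", "strain", "gene", "mutant"):
            if cand in cols:
                strain_col = cols[cand]
                break
    if value_col is None:
        for cand in ("mean", "ratio", "value", "expression", "index"):
            if cand in cols:
                value_col = cols[cand]
                break
    if strain_col is None or value_col is None:
        raise ValueError(
            f"could not identify strain/value columns in {path.name}; "
            f"available: {list(df.columns)}"
        )
    out = pd.DataFrame(
        {"strain_id": df[strain_col].astype(str), "mean": df[value_col]}
    )
    out["sd"] = df[cols["sd"]] if "sd" in cols else np.nan
    out["n"] = df[cols["n"]] if "n" in cols else 1
    return out


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, params: dict, files) -> Path:
    """Machine-readable run manifest: parameters plus a hash per output file."""
    outdir = Path(outdir)
    manifest = {
        "parameters": params,
        "outputs": {
            str(Path(f).relative_to(outdir)): sha256_file(f)
            for f in sorted(map(str, files))
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
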