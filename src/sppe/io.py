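"""Reading and writing of images, manifests, feature tables and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from sppe.ensemble import PROVENANCE_COLS
from sppe.features import FEATURE_NAMES
from sppe.preprocess import RGBImage, ROI

MANIFEST_COLUMNS = ["sample_id", "cultivar_id", "label", "path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def load_image(path: str | Path, sample_id: str = "", cultivar_id: str = "",
               label: str = "unknown") -> RGBImage:
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return RGBImage(
        pixels=pixels, sample_id=sample_id, cultivar_id=cultivar_id, label=label
    )


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def load_manifest_images(manifest: pd.DataFrame, root: str | Path = ".") -> list[RGBImage]:
    root = Path(root)
    out = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = root / p
        out.append(
            load_image(
                p,
                sample_id=row["sample_id"],
                cultivar_id=row.get("cultivar_id", ""),
                label=row.get("label", "unknown"),
            )
        )
    return out


def save_roi(roi: ROI, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a ROI crop as PNG plus a JSON sidecar with its provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png = out_dir / f"{roi.sample_id}_roi.png"
    sidecar = out_dir / f"{roi.sample_id}_roi.json"
    save_image(roi.pixels, png)
    sidecar.write_text(
        json.dumps(
            {"sample_id": roi.sample_id, "origin": list(roi.origin), "side": roi.side}
        )
    )
    return png, sidecar


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path, mode: str = "sppe") -> pd.DataFrame:
    """Read a feature CSV, validating the expected header for the mode."""
    df = pd.read_csv(path)
    if mode in ("sppe", "traditional"):
        expected = FEATURE_NAMES
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"feature table {path} missing columns {missing[:5]}...")
        meta = [c for c in PROVENANCE_COLS if c in df.columns]
        if "sample_id" not in meta or "label" not in meta:
            raise ValueError(f"feature table {path} lacks provenance columns")
    else:  # spp: 1155 wide columns
        wide = [c for c in df.columns if "_L" in c and "T" in c.rsplit("_L", 1)[-1]]
        if len(wide) != 1155:
            raise ValueError(
                f"spp feature table {path} has {len(wide)} wide columns, expected 1155"
            )
    return df


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
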