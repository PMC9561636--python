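"""File formats: TIFF field images, plate maps and feature-table CSVs."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .catalogue import PANEL_CHANNELS, FeatureCatalogue

META_COLUMNS = ["plate_id", "well", "row", "col", "condition", "compound", "spiked"]

_TIFF_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})_F(?P<field>\d+)_C(?P<channel>\w+)\.tiff?$")


def field_image_path(root, plate_id: str, well: str, field: int, channel: str) -> Path:
    return Path(root) / f"{plate_id}_{well}_F{field}_C{channel}.tiff"


def write_field_images(root, plate_id: str, well: str, field: int, images: dict[str, np.ndarray]) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for channel, img in images.items():
        tifffile.imwrite(field_image_path(root, plate_id, well, field, channel), img.astype(np.uint16))


def scan_plate_dir(root, panel: str) -> dict[str, dict[int, dict[str, Path]]]:
    """Index a plate directory: well -> field -> channel -> path."""
    channels = set(PANEL_CHANNELS[panel])
    index: dict[str, dict[int, dict[str, Path]]] = {}
    for p in sorted(Path(root).iterdir()):
        m = _TIFF_RE.match(p.name)
        if not m or m["channel"] not in channels:
            continue
        index.setdefault(m["well"], {}).setdefault(int(m["field"]), {})[m["channel"]] = p
    return index


def load_field(paths: dict[str, Path]) -> dict[str, np.ndarray]:
    return {ch: tifffile.imread(p) for ch, p in paths.items()}


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path, catalogue: FeatureCatalogue | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=["", "nan", "NaN"])
    if "compound" in df.columns:
        df["compound"] = df["compound"].astype(str).replace("nan", "")
    if catalogue is not None:
        missing = [n for n in catalogue.names if n not in df.columns]
        if missing:
            raise ValueError(f"table lacks catalogue features: {missing[:5]} ...")
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata (numeric feature) columns, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]
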