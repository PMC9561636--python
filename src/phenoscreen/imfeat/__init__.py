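"""Image segmentation and well-level feature extraction."""

from __future__ import annotations

import pandas as pd

from ..catalogue import FeatureCatalogue, get_catalogue
from ..io import META_COLUMNS, load_field, scan_plate_dir
from .features import (
    CatalogueError,
    SegmentationResult,
    SegmentParams,
    compute_field_features,
    compute_well_features,
    segment_field,
)
from .segment import (
    ParameterError,
    auto_threshold,
    build_somata,
    classify_cells,
    correct_illumination,
    morphometry,
    segment_channel,
    segment_mitochondria,
    skeletonize_neurites,
)


def extract_plate(
    plate_dir,
    catalogue: FeatureCatalogue,
    plate_map: pd.DataFrame | None = None,
    params: SegmentParams | None = None,
) -> pd.DataFrame:
    """Extract the per-well feature table from a directory of field TIFFs."""
    index = scan_plate_dir(plate_dir, catalogue.panel)
    rows = []
    for well in sorted(index):
        fields = [load_field(index[well][f]) for f in sorted(index[well])]
        feats = compute_well_features(fields, catalogue, params=params)
        rows.append({"well": well, **feats.to_dict()})
    table = pd.DataFrame(rows)
    if plate_map is not None:
        meta = plate_map[[c for c in META_COLUMNS if c in plate_map.columns]]
        table = meta.merge(table, on="well", how="right")
    table.attrs["provenance"] = "raw"
    table.attrs["panel"] = catalogue.panel
    return table


__all__ = [
    "CatalogueError",
    "ParameterError",
    "SegmentParams",
    "SegmentationResult",
    "auto_threshold",
    "build_somata",
    "classify_cells",
    "compute_field_features",
    "compute_well_features",
    "correct_illumination",
    "extract_plate",
    "get_catalogue",
    "morphometry",
    "segment_channel",
    "segment_field",
    "segment_mitochondria",
    "skeletonize_neurites",
]
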