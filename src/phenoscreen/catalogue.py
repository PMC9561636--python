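"""Feature catalogues for the staining panels.

Each panel (a fixed combination of fluorescent stains imaged together) has a
declared catalogue of well-level features.  The catalogue is the contract
between image feature extraction, the synthetic generator and the downstream
analysis: feature tables always carry exactly the catalogue's columns, in
catalogue order.

Panels
------
``panelA``
    Hoechst / aSyn / TH / MAP2 — 126 features, 54 of which are computed on
    the TH-positive cell subpopulation.
``panelMito``
    Hoechst / calcein / TMRM — 96 features, including mitochondrial puncta
    morphology (compactness, form factor) and TMRM intensity.
``panelLAMP1``
    Hoechst / aSyn / LAMP1 / MAP2 — lysosomal variant of panel A, including
    LAMP1 surface-area features.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

PANELS = ("panelA", "panelMito", "panelLAMP1")

#: channels per panel, in acquisition order
PANEL_CHANNELS: dict[str, tuple[str, ...]] = {
    "panelA": ("hoechst", "asyn", "th", "map2"),
    "panelMito": ("hoechst", "calcein", "tmrm"),
    "panelLAMP1": ("hoechst", "asyn", "lamp1", "map2"),
}

POPULATIONS = (
    "field",
    "nuclei",
    "all_cells",
    "TH_pos",
    "MAP2_pos",
    "mitochondria",
    "lysosomes",
    "neurites",
)

FAMILIES = ("count", "ratio", "intensity", "morphology", "texture")

#: per-object intensity summary statistics used throughout the catalogues
INTENSITY_STATS = ("mean", "median", "sd", "q10", "q90", "total")

#: per-population morphology summaries (means over objects)
MORPH_STATS = ("area", "perimeter", "form_factor", "compactness", "eccentricity")


@dataclass(frozen=True)
class FeatureDescriptor:
    """A single named well-level feature."""

    name: str
    panel: str
    channel: str  # "na" for purely geometric features
    population: str
    family: str

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


class FeatureCatalogue:
    """Ordered, duplicate-free collection of :class:`FeatureDescriptor`."""

    def __init__(self, panel: str, descriptors: Iterable[FeatureDescriptor]):
        self.panel = panel
        self.descriptors: tuple[FeatureDescriptor, ...] = tuple(descriptors)
        names = [d.name for d in self.descriptors]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in {panel}: {dupes}")
        for d in self.descriptors:
            if d.panel != panel:
                raise ValueError(f"descriptor {d.name} belongs to {d.panel}, not {panel}")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self) -> Iterator[FeatureDescriptor]:
        return iter(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def subset(self, population: str) -> list[FeatureDescriptor]:
        return [d for d in self.descriptors if d.population == population]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.name, d.panel, d.channel, d.population, d.family) for d in self.descriptors],
            columns=["name", "panel", "channel", "population", "family"],
        )

    def write_manifest(self, path) -> None:
        """Write the catalogue as a CSV manifest (name, panel, channel, population, family)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_manifest(cls, path_or_buf) -> "FeatureCatalogue":
        df = pd.read_csv(path_or_buf)
        descs = [
            FeatureDescriptor(r.name, r.panel, r.channel, r.population, r.family)
            for r in df.itertuples(index=False)
        ]
        if not descs:
            raise ValueError("empty manifest")
        return cls(descs[0].panel, descs)


def _intensity_block(panel, population, channels, stats=INTENSITY_STATS):
    for ch in channels:
        for stat in stats:
            yield FeatureDescriptor(
                f"{population.lower()}_{ch}_intensity_{stat}", panel, ch, population, "intensity"
            )


def _morphology_block(panel, population, stats=MORPH_STATS, suffix="mean"):
    for stat in stats:
        yield FeatureDescriptor(
            f"{population.lower()}_{stat}_{suffix}", panel, "na", population, "morphology"
        )


def _texture_block(panel, population, channels):
    for ch in channels:
        for grain in ("fine", "coarse"):
            yield FeatureDescriptor(
                f"{population.lower()}_{ch}_granularity_{grain}", panel, ch, population, "texture"
            )


def _neurite_block(panel, population, prefix):
    # skeleton topology summaries; counts are per field, *_per_cell are ratios
    items = [
        (f"{prefix}_branch_point_count", "count"),
        (f"{prefix}_end_point_count", "count"),
        (f"{prefix}_total_length", "morphology"),
        (f"{prefix}_branch_points_per_cell", "ratio"),
        (f"{prefix}_length_per_cell", "ratio"),
        (f"{prefix}_mean_branch_length", "morphology"),
    ]
    for name, family in items:
        yield FeatureDescriptor(name, panel, "na", population, family)


def _build_panel_a() -> FeatureCatalogue:
    p = "panelA"
    d: list[FeatureDescriptor] = []
    # whole-field intensities and simple cross-channel ratios          (24 + 2)
    d += _intensity_block(p, "field", PANEL_CHANNELS[p])
    d.append(FeatureDescriptor("field_asyn_to_map2_total_ratio", p, "asyn", "field", "ratio"))
    d.append(FeatureDescriptor("field_th_to_map2_total_ratio", p, "th", "field", "ratio"))
    # nuclei                                                           (13)
    d.append(FeatureDescriptor("nuclei_count", p, "hoechst", "nuclei", "count"))
    d.append(FeatureDescriptor("nuclei_density", p, "hoechst", "nuclei", "count"))
    d += _morphology_block(p, "nuclei")
    d += _intensity_block(p, "nuclei", ("hoechst",))
    # all segmented cells                                              (24)
    d.append(FeatureDescriptor("all_cells_count", p, "na", "all_cells", "count"))
    d += _morphology_block(p, "all_cells")
    d += _intensity_block(p, "all_cells", ("asyn", "th", "map2"))
    # MAP2-positive subpopulation                                      (3)
    d.append(FeatureDescriptor("map2_pos_count", p, "map2", "MAP2_pos", "count"))
    d.append(FeatureDescriptor("map2_pos_fraction", p, "map2", "MAP2_pos", "ratio"))
    d.append(FeatureDescriptor("map2_pos_map2_intensity_mean", p, "map2", "MAP2_pos", "intensity"))
    # MAP2 neurite skeleton                                            (6)
    d += _neurite_block(p, "neurites", "neurites")
    # TH-positive subpopulation: the mDAN-specific feature subset      (54)
    d.append(FeatureDescriptor("th_pos_count", p, "th", "TH_pos", "count"))
    d.append(FeatureDescriptor("th_pos_fraction", p, "th", "TH_pos", "ratio"))
    d += _morphology_block(p, "TH_pos")
    d += _intensity_block(p, "TH_pos", PANEL_CHANNELS[p])
    for ch in PANEL_CHANNELS[p]:
        d.append(FeatureDescriptor(f"th_pos_{ch}_intensity_cv", p, ch, "TH_pos", "intensity"))
    d += _texture_block(p, "TH_pos", PANEL_CHANNELS[p])
    d += _neurite_block(p, "TH_pos", "th_pos_neurite")
    d.append(FeatureDescriptor("th_pos_asyn_high_area_total", p, "asyn", "TH_pos", "morphology"))
    d.append(FeatureDescriptor("th_pos_asyn_high_area_fraction", p, "asyn", "TH_pos", "ratio"))
    d.append(FeatureDescriptor("th_pos_asyn_high_intensity_mean", p, "asyn", "TH_pos", "intensity"))
    d.append(FeatureDescriptor("th_pos_nucleus_area_mean", p, "hoechst", "TH_pos", "morphology"))
    d.append(
        FeatureDescriptor("th_pos_nucleus_hoechst_intensity_mean", p, "hoechst", "TH_pos", "intensity")
    )
    return FeatureCatalogue(p, d)


def _build_panel_mito() -> FeatureCatalogue:
    p = "panelMito"
    d: list[FeatureDescriptor] = []
    # whole field                                                      (18 + 6 + 2)
    d += _intensity_block(p, "field", PANEL_CHANNELS[p])
    d += _texture_block(p, "field", PANEL_CHANNELS[p])
    d.append(FeatureDescriptor("field_tmrm_to_calcein_total_ratio", p, "tmrm", "field", "ratio"))
    d.append(FeatureDescriptor("field_tmrm_to_calcein_mean_ratio", p, "tmrm", "field", "ratio"))
    # nuclei                                                           (16)
    d.append(FeatureDescriptor("nuclei_count", p, "hoechst", "nuclei", "count"))
    d.append(FeatureDescriptor("nuclei_density", p, "hoechst", "nuclei", "count"))
    d += _morphology_block(p, "nuclei")
    d += _intensity_block(p, "nuclei", ("hoechst",))
    d.append(FeatureDescriptor("nuclei_hoechst_intensity_cv", p, "hoechst", "nuclei", "intensity"))
    d += _texture_block(p, "nuclei", ("hoechst",))
    # calcein-masked cells                                             (24)
    d.append(FeatureDescriptor("all_cells_count", p, "calcein", "all_cells", "count"))
    d += _morphology_block(p, "all_cells")
    d += _intensity_block(p, "all_cells", ("calcein", "tmrm"))
    d.append(FeatureDescriptor("all_cells_calcein_intensity_cv", p, "calcein", "all_cells", "intensity"))
    d.append(FeatureDescriptor("all_cells_tmrm_intensity_cv", p, "tmrm", "all_cells", "intensity"))
    d += _texture_block(p, "all_cells", ("calcein", "tmrm"))
    # mitochondrial puncta                                             (30)
    for name, family in [
        ("mito_count", "count"),
        ("mito_count_per_cell", "ratio"),
        ("mito_count_per_cell_sd", "ratio"),
        ("mito_total_area", "morphology"),
        ("mito_area_fraction", "ratio"),
        ("mito_fragmentation_index", "ratio"),
    ]:
        d.append(FeatureDescriptor(name, p, "tmrm", "mitochondria", family))
    d += _morphology_block(p, "mitochondria")
    d += _morphology_block(p, "mitochondria", suffix="sd")
    d.append(FeatureDescriptor("mitochondria_area_q90", p, "na", "mitochondria", "morphology"))
    d.append(FeatureDescriptor("mitochondria_perimeter_q90", p, "na", "mitochondria", "morphology"))
    d += _intensity_block(p, "mitochondria", ("tmrm",))
    d.append(FeatureDescriptor("mitochondria_tmrm_intensity_cv", p, "tmrm", "mitochondria", "intensity"))
    d.append(
        FeatureDescriptor("mitochondria_tmrm_total_per_cell", p, "tmrm", "mitochondria", "ratio")
    )
    d += _texture_block(p, "mitochondria", ("tmrm",))
    d.append(
        FeatureDescriptor("mito_nearest_neighbor_dist_mean", p, "na", "mitochondria", "morphology")
    )
    d.append(FeatureDescriptor("mito_dist_to_nucleus_mean", p, "na", "mitochondria", "morphology"))
    return FeatureCatalogue(p, d)


def _build_panel_lamp1() -> FeatureCatalogue:
    p = "panelLAMP1"
    d: list[FeatureDescriptor] = []
    d += _intensity_block(p, "field", PANEL_CHANNELS[p])
    d.append(FeatureDescriptor("nuclei_count", p, "hoechst", "nuclei", "count"))
    d.append(FeatureDescriptor("nuclei_density", p, "hoechst", "nuclei", "count"))
    d += _morphology_block(p, "nuclei")
    d += _intensity_block(p, "nuclei", ("hoechst",))
    d.append(FeatureDescriptor("all_cells_count", p, "na", "all_cells", "count"))
    d += _morphology_block(p, "all_cells")
    d += _intensity_block(p, "all_cells", ("asyn", "lamp1", "map2"))
    d.append(FeatureDescriptor("map2_pos_count", p, "map2", "MAP2_pos", "count"))
    d.append(FeatureDescriptor("map2_pos_fraction", p, "map2", "MAP2_pos", "ratio"))
    d.append(FeatureDescriptor("map2_pos_map2_intensity_mean", p, "map2", "MAP2_pos", "intensity"))
    d += _neurite_block(p, "neurites", "neurites")
    # lysosomal compartment (LAMP1 surface area is the headline feature)
    for name, family in [
        ("lysosomes_count", "count"),
        ("lysosomes_count_per_cell", "ratio"),
        ("lysosomes_lamp1_surface_area_total", "morphology"),
        ("lysosomes_area_fraction", "ratio"),
    ]:
        d.append(FeatureDescriptor(name, p, "lamp1", "lysosomes", family))
    d += _morphology_block(p, "lysosomes")
    d += _intensity_block(p, "lysosomes", ("lamp1",))
    d.append(FeatureDescriptor("field_asyn_to_map2_total_ratio", p, "asyn", "field", "ratio"))
    d.append(FeatureDescriptor("field_lamp1_to_map2_total_ratio", p, "lamp1", "field", "ratio"))
    return FeatureCatalogue(p, d)


_BUILDERS = {
    "panelA": _build_panel_a,
    "panelMito": _build_panel_mito,
    "panelLAMP1": _build_panel_lamp1,
}

_CACHE: dict[str, FeatureCatalogue] = {}

#: declared catalogue sizes; enforced at load time
EXPECTED_COUNTS = {"panelA": 126, "panelMito": 96}
EXPECTED_TH_POS_COUNT = 54


def get_catalogue(panel: str) -> FeatureCatalogue:
    """Return the packaged catalogue for *panel* (cached, validated)."""
    if panel not in _BUILDERS:
        raise KeyError(f"unknown panel {panel!r}; choose from {sorted(_BUILDERS)}")
    if panel not in _CACHE:
        cat = _BUILDERS[panel]()
        if panel in EXPECTED_COUNTS and len(cat) != EXPECTED_COUNTS[panel]:
            raise AssertionError(
                f"{panel} catalogue has {len(cat)} features, expected {EXPECTED_COUNTS[panel]}"
            )
        if panel == "panelA" and len(cat.subset("TH_pos")) != EXPECTED_TH_POS_COUNT:
            raise AssertionError("panelA TH_pos subset size mismatch")
        _CACHE[panel] = cat
    return _CACHE[panel]


def baseline_value(desc: FeatureDescriptor) -> float:
    """Baseline (untreated control, noise-free) value for a feature.

    The source study reports only relative effects, never absolute scales, so
    baselines are synthetic plumbing: positive, family-appropriate magnitudes.
    """
    n = desc.name
    if "form_factor" in n:
        return 0.75
    if "compactness" in n:
        return 0.65
    if "eccentricity" in n:
        return 0.55
    if n.endswith("_sd") and desc.family == "morphology":
        return 12.0
    if "fraction" in n or "_cv" in n:
        return 0.35
    if "ratio" in n:
        return 0.8
    if "per_cell" in n:
        return 4.0
    if "length" in n:
        return 600.0
    if "granularity" in n:
        return 20.0
    if "dist" in n:
        return 25.0
    if "area" in n:
        return 180.0
    if "perimeter" in n:
        return 55.0
    if "density" in n:
        return 2.5
    if desc.family == "count":
        return 120.0
    if desc.family == "intensity":
        return 900.0
    return 50.0


def baseline_manifest(panel: str) -> pd.Series:
    """Baseline values for every catalogue feature, in catalogue order."""
    cat = get_catalogue(panel)
    return pd.Series({d.name: baseline_value(d) for d in cat}, name="baseline")
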