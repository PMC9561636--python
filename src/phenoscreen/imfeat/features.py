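"""Per-field segmentation orchestration and well-level feature computation.

``segment_field`` turns a dict of channel images into a
:class:`SegmentationResult`; ``compute_field_features`` evaluates every
catalogue feature on one field; ``compute_well_features`` averages fields
into the single row per well that downstream analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from ..catalogue import PANEL_CHANNELS, FeatureCatalogue
from .segment import (
    auto_threshold,
    build_somata,
    classify_cells,
    correct_illumination,
    morphometry,
    segment_channel,
    segment_mitochondria,
    skeletonize_neurites,
)


class CatalogueError(ValueError):
    pass


@dataclass
class SegmentParams:
    soma_radius: float = 10.0
    nucleus_min_size: int = 20
    mito_ball_radius: int = 15
    mito_tophat_radius: int = 5
    mito_min_area: int = 4
    illumination_sigma: float = 50.0
    #: fixed per-channel thresholds; channels absent here use the automatic policy
    thresholds: dict = field(default_factory=dict)


@dataclass
class SegmentationResult:
    panel: str
    images: dict  # illumination-corrected float images per channel
    nuclei: np.ndarray
    somata: np.ndarray
    cell_ids: np.ndarray
    soma_means: dict  # channel -> per-cell mean intensity (aligned to cell_ids)
    th_pos: np.ndarray
    map2_pos: np.ndarray
    channel_thresholds: dict
    mito: np.ndarray | None = None
    lysosomes: np.ndarray | None = None


_SOMA_MARKERS = {
    "panelA": ("map2", "th", "asyn"),
    "panelMito": ("calcein",),
    "panelLAMP1": ("map2", "lamp1", "asyn"),
}


def segment_field(
    images: dict[str, np.ndarray],
    panel: str,
    params: SegmentParams | None = None,
) -> SegmentationResult:
    """Segment one multi-channel field."""
    params = params or SegmentParams()
    channels = PANEL_CHANNELS[panel]
    missing = [ch for ch in channels if ch not in images]
    if missing:
        raise CatalogueError(f"panel {panel} expects channels {channels}; missing {missing}")

    corr = {
        ch: correct_illumination(np.asarray(images[ch], float), params.illumination_sigma)
        for ch in channels
    }
    thr = {
        ch: params.thresholds.get(ch, auto_threshold(corr[ch]))
        for ch in channels
    }
    nuclei = segment_channel(corr["hoechst"], threshold=thr["hoechst"], min_size=params.nucleus_min_size)

    marker_mask = np.zeros(nuclei.shape, dtype=bool)
    for ch in _SOMA_MARKERS[panel]:
        marker_mask |= corr[ch] > thr[ch]
    somata = build_somata(nuclei, marker_mask, radius=params.soma_radius)

    cell_ids = np.array(sorted(set(np.unique(nuclei)) - {0}), dtype=int)
    soma_means = {}
    for ch in channels:
        if len(cell_ids):
            soma_means[ch] = np.asarray(ndimage.mean(corr[ch], labels=somata, index=cell_ids))
        else:
            soma_means[ch] = np.zeros(0)

    th_pos = (
        classify_cells(soma_means["th"]) if "th" in soma_means else np.zeros(len(cell_ids), bool)
    )
    map2_pos = (
        classify_cells(soma_means["map2"]) if "map2" in soma_means else np.zeros(len(cell_ids), bool)
    )

    mito = None
    if panel == "panelMito":
        # mitochondria detection deliberately runs on the raw channel
        mito = segment_mitochondria(
            np.asarray(images["tmrm"], float),
            ball_radius=params.mito_ball_radius,
            tophat_radius=params.mito_tophat_radius,
            min_area=params.mito_min_area,
        )
    lysosomes = None
    if panel == "panelLAMP1":
        lysosomes = segment_channel(corr["lamp1"], threshold=thr["lamp1"], min_size=4)

    return SegmentationResult(
        panel=panel,
        images=corr,
        nuclei=nuclei,
        somata=somata,
        cell_ids=cell_ids,
        soma_means=soma_means,
        th_pos=th_pos,
        map2_pos=map2_pos,
        channel_thresholds=thr,
        mito=mito,
        lysosomes=lysosomes,
    )


# ---------------------------------------------------------------------------
# feature computation helpers


def _dist_stats(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {s: np.nan for s in ("mean", "median", "sd", "q10", "q90")}
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "q10": float(np.quantile(v, 0.10)),
        "q90": float(np.quantile(v, 0.90)),
    }


def _intensity_feats(out, prefix, ch, img, labels, ids) -> None:
    """Object-level intensity statistics + integrated total for one channel."""
    if len(ids):
        means = np.asarray(ndimage.mean(img, labels=labels, index=ids))
        total = float(ndimage.sum(img, labels=labels, index=ids).sum())
    else:
        means, total = np.zeros(0), np.nan
    stats = _dist_stats(means)
    for s, val in stats.items():
        out[f"{prefix}_{ch}_intensity_{s}"] = val
    out[f"{prefix}_{ch}_intensity_total"] = total


def _intensity_cv(out, prefix, ch, img, labels, ids) -> None:
    if len(ids):
        means = np.asarray(ndimage.mean(img, labels=labels, index=ids))
        m = means.mean()
        out[f"{prefix}_{ch}_intensity_cv"] = float(means.std(ddof=1) / m) if m and len(ids) > 1 else np.nan
    else:
        out[f"{prefix}_{ch}_intensity_cv"] = np.nan


def _morph_feats(out, prefix, label_img, suffix="mean") -> "np.ndarray":
    m = morphometry(label_img)
    agg = (lambda a: float(np.mean(a))) if suffix == "mean" else (
        lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    )
    for stat, arr in (
        ("area", m.area),
        ("perimeter", m.perimeter),
        ("form_factor", m.form_factor),
        ("compactness", m.compactness),
        ("eccentricity", m.eccentricity),
    ):
        out[f"{prefix}_{stat}_{suffix}"] = agg(arr) if len(arr) else np.nan
    return m


def _granularity(img: np.ndarray, mask: np.ndarray, radius: int) -> float:
    """Mean residual after a grayscale opening — a simple granularity score."""
    if not mask.any():
        return np.nan
    opened = morphology.opening(img, morphology.disk(radius))
    return float(np.mean((img - opened)[mask]))


def _granularity_feats(out, prefix, ch, img, mask) -> None:
    out[f"{prefix}_{ch}_granularity_fine"] = _granularity(img, mask, 1)
    out[f"{prefix}_{ch}_granularity_coarse"] = _granularity(img, mask, 3)


def _field_feats(out, img, ch) -> None:
    stats = _dist_stats(img.ravel())
    for s, val in stats.items():
        out[f"field_{ch}_intensity_{s}"] = val
    out[f"field_{ch}_intensity_total"] = float(img.sum())


def _neurite_feats(out, prefix, mask, n_cells) -> None:
    _, branch, ends, length = skeletonize_neurites(mask)
    nb, ne = len(branch), len(ends)
    out[f"{prefix}_branch_point_count"] = float(nb)
    out[f"{prefix}_end_point_count"] = float(ne)
    out[f"{prefix}_total_length"] = float(length)
    denom = max(n_cells, 1)
    out[f"{prefix}_branch_points_per_cell"] = nb / denom
    out[f"{prefix}_length_per_cell"] = length / denom
    out[f"{prefix}_mean_branch_length"] = length / max(nb + 1, 1)


def _subset_labels(label_img: np.ndarray, keep_ids: np.ndarray) -> np.ndarray:
    keep = np.zeros(label_img.max() + 1, dtype=bool)
    keep[keep_ids] = True
    return np.where(keep[label_img], label_img, 0)


def compute_field_features(
    images: dict[str, np.ndarray],
    catalogue: FeatureCatalogue,
    seg: SegmentationResult | None = None,
    params: SegmentParams | None = None,
) -> dict[str, float]:
    """Every catalogue feature for one field (NaN where a population is absent)."""
    panel = catalogue.panel
    if seg is None:
        seg = segment_field(images, panel, params)
    if seg.panel != panel:
        raise CatalogueError(f"segmentation is {seg.panel}, catalogue is {panel}")
    corr = seg.images
    area_px = float(next(iter(corr.values())).size)
    out: dict[str, float] = {}

    for ch in PANEL_CHANNELS[panel]:
        _field_feats(out, corr[ch], ch)

    n_nuc = len(seg.cell_ids)
    out["nuclei_count"] = float(n_nuc)
    out["nuclei_density"] = 1e4 * n_nuc / area_px
    nuc_morph = _morph_feats(out, "nuclei", seg.nuclei)
    _intensity_feats(out, "nuclei", "hoechst", corr["hoechst"], seg.nuclei, seg.cell_ids)

    n_cells = len(seg.cell_ids)
    out["all_cells_count"] = float(n_cells)
    _morph_feats(out, "all_cells", seg.somata)
    soma_channels = {
        "panelA": ("asyn", "th", "map2"),
        "panelMito": ("calcein", "tmrm"),
        "panelLAMP1": ("asyn", "lamp1", "map2"),
    }[panel]
    for ch in soma_channels:
        _intensity_feats(out, "all_cells", ch, corr[ch], seg.somata, seg.cell_ids)

    if panel in ("panelA", "panelLAMP1"):
        n_map2 = int(seg.map2_pos.sum())
        out["map2_pos_count"] = float(n_map2)
        out["map2_pos_fraction"] = n_map2 / n_cells if n_cells else np.nan
        map2_ids = seg.cell_ids[seg.map2_pos]
        out["map2_pos_map2_intensity_mean"] = (
            float(seg.soma_means["map2"][seg.map2_pos].mean()) if n_map2 else np.nan
        )
        map2_mask = (corr["map2"] > seg.channel_thresholds["map2"]) & (seg.somata == 0)
        _neurite_feats(out, "neurites", map2_mask, n_cells)
        out["field_asyn_to_map2_total_ratio"] = float(corr["asyn"].sum() / corr["map2"].sum())

    if panel == "panelA":
        out["field_th_to_map2_total_ratio"] = float(corr["th"].sum() / corr["map2"].sum())
        th_ids = seg.cell_ids[seg.th_pos]
        n_th = len(th_ids)
        out["th_pos_count"] = float(n_th)
        out["th_pos_fraction"] = n_th / n_cells if n_cells else np.nan
        th_somata = _subset_labels(seg.somata, th_ids)
        th_nuclei = _subset_labels(seg.nuclei, th_ids)
        _morph_feats(out, "th_pos", th_somata)
        th_mask = th_somata > 0
        for ch in PANEL_CHANNELS[panel]:
            _intensity_feats(out, "th_pos", ch, corr[ch], th_somata, th_ids)
            _intensity_cv(out, "th_pos", ch, corr[ch], th_somata, th_ids)
            _granularity_feats(out, "th_pos", ch, corr[ch], th_mask)
        th_neurite_mask = (corr["th"] > seg.channel_thresholds["th"]) & (seg.somata == 0)
        _neurite_feats(out, "th_pos_neurite", th_neurite_mask, n_th)
        high_thr = 1.5 * seg.channel_thresholds["asyn"]
        high = (corr["asyn"] > high_thr) & th_mask
        out["th_pos_asyn_high_area_total"] = float(high.sum()) if n_th else np.nan
        out["th_pos_asyn_high_area_fraction"] = (
            float(high.sum() / th_mask.sum()) if th_mask.any() else np.nan
        )
        out["th_pos_asyn_high_intensity_mean"] = (
            float(corr["asyn"][high].mean()) if high.any() else np.nan
        )
        if n_th:
            nm = morphometry(th_nuclei)
            out["th_pos_nucleus_area_mean"] = float(nm.area.mean()) if len(nm.area) else np.nan
            out["th_pos_nucleus_hoechst_intensity_mean"] = float(
                np.asarray(ndimage.mean(corr["hoechst"], labels=th_nuclei, index=th_ids)).mean()
            )
        else:
            out["th_pos_nucleus_area_mean"] = np.nan
            out["th_pos_nucleus_hoechst_intensity_mean"] = np.nan

    if panel == "panelMito":
        out["field_tmrm_to_calcein_total_ratio"] = float(corr["tmrm"].sum() / corr["calcein"].sum())
        out["field_tmrm_to_calcein_mean_ratio"] = float(corr["tmrm"].mean() / corr["calcein"].mean())
        for ch in PANEL_CHANNELS[panel]:
            _granularity_feats(out, "field", ch, corr[ch], np.ones(corr[ch].shape, bool))
        _intensity_cv(out, "nuclei", "hoechst", corr["hoechst"], seg.nuclei, seg.cell_ids)
        _granularity_feats(out, "nuclei", "hoechst", corr["hoechst"], seg.nuclei > 0)
        for ch in ("calcein", "tmrm"):
            _intensity_cv(out, "all_cells", ch, corr[ch], seg.somata, seg.cell_ids)
            _granularity_feats(out, "all_cells", ch, corr[ch], seg.somata > 0)

        mito = seg.mito
        ids = np.array(sorted(set(np.unique(mito)) - {0}), dtype=int)
        n_mito = len(ids)
        out["mito_count"] = float(n_mito)
        out["mito_count_per_cell"] = n_mito / n_cells if n_cells else np.nan
        total_area = float((mito > 0).sum())
        out["mito_total_area"] = total_area
        out["mito_area_fraction"] = total_area / area_px
        out["mito_fragmentation_index"] = n_mito / total_area if total_area else np.nan
        mm = _morph_feats(out, "mitochondria", mito)
        _morph_feats(out, "mitochondria", mito, suffix="sd")
        out["mitochondria_area_q90"] = float(np.quantile(mm.area, 0.9)) if n_mito else np.nan
        out["mitochondria_perimeter_q90"] = float(np.quantile(mm.perimeter, 0.9)) if n_mito else np.nan
        tmrm_raw = np.asarray(images["tmrm"], float)
        _intensity_feats(out, "mitochondria", "tmrm", tmrm_raw, mito, ids)
        _intensity_cv(out, "mitochondria", "tmrm", tmrm_raw, mito, ids)
        out["mitochondria_tmrm_total_per_cell"] = (
            out["mitochondria_tmrm_intensity_total"] / n_cells if n_cells else np.nan
        )
        _granularity_feats(out, "mitochondria", "tmrm", tmrm_raw, mito > 0)
        if n_mito >= 2:
            cent = mm.centroids
            d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
            np.fill_diagonal(d, np.inf)
            out["mito_nearest_neighbor_dist_mean"] = float(d.min(axis=1).mean())
        else:
            out["mito_nearest_neighbor_dist_mean"] = np.nan
        if n_mito and n_nuc:
            nd = np.linalg.norm(
                mm.centroids[:, None, :] - nuc_morph.centroids[None, :, :], axis=2
            )
            out["mito_dist_to_nucleus_mean"] = float(nd.min(axis=1).mean())
        else:
            out["mito_dist_to_nucleus_mean"] = np.nan
        if n_mito and n_cells:
            # per-cell punctum counts via nearest nucleus assignment
            owner = np.argmin(
                np.linalg.norm(mm.centroids[:, None, :] - nuc_morph.centroids[None, :, :], axis=2),
                axis=1,
            )
            counts = np.bincount(owner, minlength=n_cells)
            out["mito_count_per_cell_sd"] = float(counts.std(ddof=1)) if n_cells > 1 else 0.0
        else:
            out["mito_count_per_cell_sd"] = np.nan

    if panel == "panelLAMP1":
        out["field_lamp1_to_map2_total_ratio"] = float(corr["lamp1"].sum() / corr["map2"].sum())
        lys = seg.lysosomes
        ids = np.array(sorted(set(np.unique(lys)) - {0}), dtype=int)
        n_lys = len(ids)
        out["lysosomes_count"] = float(n_lys)
        out["lysosomes_count_per_cell"] = n_lys / n_cells if n_cells else np.nan
        total_area = float((lys > 0).sum())
        out["lysosomes_lamp1_surface_area_total"] = total_area
        out["lysosomes_area_fraction"] = total_area / area_px
        _morph_feats(out, "lysosomes", lys)
        _intensity_feats(out, "lysosomes", "lamp1", corr["lamp1"], lys, ids)

    missing = [n for n in catalogue.names if n not in out]
    if missing:
        raise CatalogueError(f"feature computation incomplete: {missing[:5]} ...")
    return {n: out[n] for n in catalogue.names}


def compute_well_features(
    fields: list[dict[str, np.ndarray]],
    catalogue: FeatureCatalogue,
    params: SegmentParams | None = None,
) -> pd.Series:
    """Mean over fields of the per-field feature vectors (NaNs skipped)."""
    if not fields:
        raise ValueError("need at least one field")
    rows = [compute_field_features(imgs, catalogue, params=params) for imgs in fields]
    df = pd.DataFrame(rows, columns=catalogue.names)
    with np.errstate(invalid="ignore"):
        return df.mean(axis=0, skipna=True)
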