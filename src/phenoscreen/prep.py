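"""Preprocessing of well-level feature tables.

Order of operations is fixed: per-plate median normalization to a reference
condition, robust outlier-well removal, then correlated-feature pruning.
Every step is recorded in a :class:`PrepReport` that can replay the whole
preprocessing deterministically on the raw table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io import META_COLUMNS, feature_columns


@dataclass
class PrepReport:
    """Replayable record of all preprocessing decisions."""

    reference_condition: str | None = None
    reference_medians: dict = dc_field(default_factory=dict)  # plate -> {feature: median}
    dropped_degenerate: list = dc_field(default_factory=list)  # features with bad reference median
    removed_wells: list = dc_field(default_factory=list)  # {"plate_id", "well", "reason", ...}
    dropped_correlated: list = dc_field(default_factory=list)  # {"feature", "partner", "r"}
    r_threshold: float | None = None
    z_cut: float | None = None
    frac_cut: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "PrepReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def normalize_to_reference(
    table: pd.DataFrame,
    reference_condition: str,
    report: PrepReport | None = None,
    min_reference_wells: int = 3,
) -> tuple[pd.DataFrame, PrepReport]:
    """Divide each feature by its per-plate median over reference wells.

    After normalization the per-plate reference-condition median of every
    kept feature is exactly 1.  Features whose reference median is not a
    positive finite number (anywhere) are dropped and logged.
    """
    report = report or PrepReport()
    report.reference_condition = reference_condition
    feats = feature_columns(table)
    out = table.copy()
    bad: set[str] = set()
    for plate, grp in table.groupby("plate_id"):
        ref = grp[grp["condition"] == reference_condition]
        if len(ref) < min_reference_wells:
            raise ValueError(
                f"plate {plate}: {len(ref)} reference wells "
                f"('{reference_condition}'), need >= {min_reference_wells}"
            )
        med = ref[feats].median()
        report.reference_medians[str(plate)] = {f: float(med[f]) for f in feats}
        degenerate = med.index[(~np.isfinite(med)) | (med <= 1e-12)]
        bad.update(degenerate)
        ok = [f for f in feats if f not in degenerate]
        out.loc[grp.index, ok] = grp[ok] / med[ok]
    for f in sorted(bad):
        report.dropped_degenerate.append(f)
    out = out.drop(columns=sorted(bad))
    out.attrs = dict(table.attrs)
    out.attrs["provenance"] = "normalized"
    return out, report


def remove_outlier_wells(
    table: pd.DataFrame,
    z_cut: float = 3.5,
    frac_cut: float = 0.2,
    report: PrepReport | None = None,
    min_group: int = 8,
) -> tuple[pd.DataFrame, PrepReport]:
    """Drop wells that are gross outliers across many features.

    Within each plate x condition group the robust z-score
    (x - median) / (1.4826 * MAD) is computed per feature; a well is removed
    when more than ``frac_cut`` of its (MAD > 0) features exceed ``z_cut``
    in absolute value.  Wells with any non-finite feature are removed too.
    """
    report = report or PrepReport()
    report.z_cut, report.frac_cut = z_cut, frac_cut
    feats = feature_columns(table)
    drop_idx: list[int] = []
    for (plate, cond), grp in table.groupby(["plate_id", "condition"]):
        if len(grp) < min_group:
            raise ValueError(
                f"plate {plate} condition {cond}: {len(grp)} wells, need >= {min_group}"
            )
        x = grp[feats].to_numpy(float)
        finite = np.isfinite(x).all(axis=1)
        med = np.nanmedian(x, axis=0)
        mad = np.nanmedian(np.abs(x - med), axis=0)
        votable = mad > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(x - med) / (1.4826 * mad)
        frac = (
            (np.abs(z[:, votable]) > z_cut).mean(axis=1)
            if votable.any()
            else np.zeros(len(grp))
        )
        for i, (idx, well) in enumerate(zip(grp.index, grp["well"])):
            if not finite[i]:
                drop_idx.append(idx)
                report.removed_wells.append(
                    {"plate_id": str(plate), "well": well, "reason": "non-finite"}
                )
            elif frac[i] > frac_cut:
                drop_idx.append(idx)
                report.removed_wells.append(
                    {
                        "plate_id": str(plate),
                        "well": well,
                        "reason": "robust-z vote",
                        "outlier_feature_fraction": float(frac[i]),
                    }
                )
    out = table.drop(index=drop_idx).reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out, report


def drop_correlated_features(
    table: pd.DataFrame,
    r_threshold: float = 0.9,
    report: PrepReport | None = None,
    min_wells: int = 10,
) -> tuple[pd.DataFrame, PrepReport]:
    """Greedy decorrelation in catalogue (column) order.

    The first feature is always kept; each subsequent feature is dropped iff
    its absolute Pearson correlation with any previously *kept* feature
    reaches ``r_threshold``.  Zero-variance features are dropped first.
    """
    report = report or PrepReport()
    report.r_threshold = r_threshold
    feats = feature_columns(table)
    if len(table) < min_wells:
        raise ValueError(f"{len(table)} wells, need >= {min_wells} for correlation pruning")
    x = table[feats].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    kept: list[int] = []
    for j, f in enumerate(feats):
        if sd[j] == 0 or not np.isfinite(sd[j]):
            report.dropped_correlated.append({"feature": f, "partner": None, "r": None,
                                              "reason": "zero variance"})
            continue
        partner = None
        for k in kept:
            r = float(np.corrcoef(x[:, j], x[:, k])[0, 1])
            if abs(r) >= r_threshold:
                partner = (feats[k], r)
                break
        if partner is None:
            kept.append(j)
        else:
            report.dropped_correlated.append(
                {"feature": f, "partner": partner[0], "r": partner[1], "reason": "correlated"}
            )
    keep_names = [feats[j] for j in kept]
    out = table[[c for c in table.columns if c in META_COLUMNS or c in keep_names]].copy()
    out.attrs = dict(table.attrs)
    out.attrs["provenance"] = "pruned"
    return out, report


def preprocess(
    table: pd.DataFrame,
    reference_condition: str,
    z_cut: float = 3.5,
    frac_cut: float = 0.2,
    r_threshold: float = 0.9,
) -> tuple[pd.DataFrame, PrepReport]:
    """normalize -> remove outlier wells -> drop correlated features."""
    report = PrepReport()
    out, report = normalize_to_reference(table, reference_condition, report)
    out, report = remove_outlier_wells(out, z_cut, frac_cut, report)
    out, report = drop_correlated_features(out, r_threshold, report)
    return out, report


def replay(table: pd.DataFrame, report: PrepReport) -> pd.DataFrame:
    """Re-apply a recorded preprocessing to the raw table, bit-exactly."""
    feats = feature_columns(table)
    out = table.copy()
    for plate, grp in out.groupby("plate_id"):
        med = report.reference_medians[str(plate)]
        ok = [f for f in feats if f not in report.dropped_degenerate]
        out.loc[grp.index, ok] = grp[ok] / pd.Series(med)[ok]
    out = out.drop(columns=[f for f in report.dropped_degenerate if f in out.columns])
    removed = {(r["plate_id"], r["well"]) for r in report.removed_wells}
    mask = [
        (str(p), w) in removed for p, w in zip(out["plate_id"], out["well"])
    ]
    out = out[~np.asarray(mask)].reset_index(drop=True)
    dropped = {d["feature"] for d in report.dropped_correlated}
    out = out.drop(columns=[c for c in out.columns if c in dropped])
    out.attrs = dict(table.attrs)
    out.attrs["provenance"] = "pruned"
    return out
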