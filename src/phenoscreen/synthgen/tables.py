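"""Sample well-level feature tables with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..catalogue import FeatureCatalogue, baseline_manifest
from .effects import EffectProfile, NoiseModel
from .plate import PlateLayout

META_COLUMNS = ["plate_id", "well", "row", "col", "condition", "compound", "spiked"]


@dataclass
class GroundTruth:
    """Everything the feature table deliberately does not reveal.

    ``wells``         per-well truth: condition, compound, spiked flag, outlier flag
    ``effect_factors``per-condition resolved factor vectors (conditions x features)
    ``plate_factors`` per-plate multiplicative batch factors (plates x features)
    """

    wells: pd.DataFrame
    effect_factors: pd.DataFrame
    plate_factors: pd.DataFrame


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def sample_feature_table(
    layout: PlateLayout,
    catalogue: FeatureCatalogue,
    effects: dict[str, EffectProfile],
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one feature table for *layout* from the generative model.

    Each well's value for feature *f* is::

        baseline_f * effect_f(condition) * plate_f * mean_over_fields(noise)

    where the field noise is unit-mean log-normal with CV ``field_cv``, the
    well noise log-normal with CV ``well_cv`` and the plate batch factor
    log-normal with log-scale SD ``plate_batch_sd``.  A random subset of
    wells (rate ``outlier_rate``) has every feature multiplied by
    ``outlier_scale``, emulating gross technical failures.

    Spiked wells use the profile registered under their compound name.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    wells = layout.wells
    n_wells = len(wells)
    names = catalogue.names
    n_feat = len(names)

    missing = set()
    for _, r in wells.iterrows():
        key = r["compound"] if r["spiked"] else r["condition"]
        if key not in effects:
            missing.add(key)
    if missing:
        raise KeyError(f"no EffectProfile registered for condition(s): {sorted(missing)}")

    baseline = baseline_manifest(catalogue.panel).to_numpy()
    resolved = {k: p.resolve(catalogue).to_numpy() for k, p in effects.items()}
    factor_rows = np.vstack(
        [
            resolved[r["compound"] if r["spiked"] else r["condition"]]
            for _, r in wells.iterrows()
        ]
    )

    plate_factor = np.exp(rng.normal(0.0, noise.plate_batch_sd, size=n_feat))
    well_noise = _lognormal_factor(rng, noise.well_cv, (n_wells, n_feat))
    n_fields = layout.spec.fields_per_well
    field_noise = _lognormal_factor(rng, noise.field_cv, (n_wells, n_feat, n_fields)).mean(axis=2)

    values = baseline[None, :] * factor_rows * plate_factor[None, :] * well_noise * field_noise

    outlier = rng.random(n_wells) < noise.outlier_rate
    values[outlier] *= noise.outlier_scale

    table = wells[META_COLUMNS].copy()
    table = pd.concat([table, pd.DataFrame(values, columns=names, index=table.index)], axis=1)
    table.attrs["provenance"] = "raw"
    table.attrs["panel"] = catalogue.panel

    truth_wells = wells[META_COLUMNS].copy()
    truth_wells["outlier"] = outlier
    truth = GroundTruth(
        wells=truth_wells,
        effect_factors=pd.DataFrame(resolved, index=names).T,
        plate_factors=pd.DataFrame(
            [plate_factor], columns=names, index=[layout.plate_id]
        ),
    )
    return table, truth


def sample_plates(
    layouts: list[PlateLayout],
    catalogue: FeatureCatalogue,
    effects: dict[str, EffectProfile],
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Sample several plates (independent batch factors) into one table."""
    ss = np.random.SeedSequence(seed)
    tables, truths = [], []
    for layout, child in zip(layouts, ss.spawn(len(layouts))):
        t, g = sample_feature_table(
            layout, catalogue, effects, noise, seed=child.generate_state(1)[0]
        )
        tables.append(t)
        truths.append(g)
    table = pd.concat(tables, ignore_index=True)
    table.attrs["provenance"] = "raw"
    table.attrs["panel"] = catalogue.panel
    return table, truths
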