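"""Condition effect profiles and the noise model for synthetic plates.

Effects are multiplicative per-feature factors relative to the untreated
control baseline.  The default mutant profile encodes the study system's
headline phenotypes: elevated aSyn staining (+15%), reduced TMRM intensity
(-33%), fewer neurite branches, more compact mitochondria and an enlarged
high-intensity aSyn area.  Compound profiles are expressed as a rescue
fraction ``shift`` toward control (geometric interpolation of the factors)
plus optional compound-specific factors such as direct aSyn lowering.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import pandas as pd

from ..catalogue import FeatureCatalogue


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal variability of synthetic feature values."""

    well_cv: float = 0.10
    plate_batch_sd: float = 0.05  # log-scale SD of the per-plate factor
    field_cv: float = 0.15
    outlier_rate: float = 0.01
    outlier_scale: float = 5.0

    def __post_init__(self) -> None:
        for name in ("well_cv", "plate_batch_sd", "field_cv", "outlier_rate", "outlier_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.outlier_rate >= 0.1:
            raise ValueError("outlier_rate must be < 0.1")


@dataclass(frozen=True)
class EffectProfile:
    """Per-feature multiplicative effects for one condition.

    ``factors`` maps feature names *or glob patterns* to factors; the first
    matching pattern (insertion order) wins.  ``shift`` in [0, 1] pulls the
    resolved factors toward 1 (the control profile) on a log scale: 0 keeps
    the base profile, 1 is indistinguishable from control.
    """

    factors: dict[str, float] = field(default_factory=dict)
    shift: float = 0.0
    base: "EffectProfile | None" = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift <= 1.0:
            raise ValueError("shift must lie in [0, 1]")
        for pat, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {pat!r} must be > 0")

    def _base_factor(self, feature_name: str) -> float:
        if self.base is not None:
            return self.base.factor_for(feature_name)
        return 1.0

    def factor_for(self, feature_name: str) -> float:
        base = self._base_factor(feature_name)
        if self.shift:
            base = base ** (1.0 - self.shift)
        for pattern, f in self.factors.items():
            if feature_name == pattern or fnmatch.fnmatchcase(feature_name, pattern):
                return base * f
        return base

    def resolve(self, catalogue: FeatureCatalogue) -> pd.Series:
        """Factor for every catalogue feature, in catalogue order."""
        return pd.Series(
            {name: self.factor_for(name) for name in catalogue.names}, name="factor"
        )


CONTROL = EffectProfile()

#: default mutant phenotype, shared across panels (patterns only match
#: features that exist in the respective catalogue)
MUTANT_FACTORS = {
    "th_pos_asyn_high_area*": 1.5,
    "th_pos_asyn_high_intensity*": 1.5,
    "*asyn_intensity_mean": 1.15,
    "*asyn_intensity_median": 1.15,
    "*asyn_intensity_q90": 1.15,
    "*asyn_intensity_total": 1.15,
    "*tmrm_intensity_mean": 0.67,
    "*tmrm_intensity_median": 0.67,
    "*tmrm_intensity_q90": 0.67,
    "*tmrm_intensity_total": 0.67,
    "*branch_point_count": 0.7,
    "*branch_points_per_cell": 0.7,
    "mitochondria_compactness_mean": 1.2,
    "mitochondria_form_factor_mean": 1.1,
}

MUTANT = EffectProfile(factors=dict(MUTANT_FACTORS))


def mutant_profile() -> EffectProfile:
    return MUTANT


def compound_profile(shift: float, extra: dict[str, float] | None = None) -> EffectProfile:
    """Mutant cells rescued a fraction *shift* of the way toward control."""
    return EffectProfile(factors=dict(extra or {}), shift=shift, base=MUTANT)


#: compound-specific aSyn lowering on top of a partial phenotype rescue
PEP005 = compound_profile(0.5, {"*asyn_intensity_mean": 0.85, "*asyn_intensity_median": 0.85,
                                "*asyn_intensity_q90": 0.85, "*asyn_intensity_total": 0.85})
PROSTRATIN = compound_profile(0.7, {"*asyn_intensity_mean": 0.75, "*asyn_intensity_median": 0.75,
                                    "*asyn_intensity_q90": 0.75, "*asyn_intensity_total": 0.75})

DEFAULT_PROFILES: dict[str, EffectProfile] = {
    "control": CONTROL,
    "mutant": MUTANT,
    "PEP005": PEP005,
    "prostratin": PROSTRATIN,
}
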