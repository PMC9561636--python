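"""Screening statistics on classification scores.

Z-factor assay quality, leave-one-feature-out attribution, 3-SD hit calling,
replicate-power estimation, two-group tests and bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .profclass import CVSpec, score_wells, train_reference


@dataclass(frozen=True)
class ZFactorResult:
    mu_pos: float
    mu_neg: float
    sd_pos: float
    sd_neg: float
    z: float
    defined: bool

    def __float__(self) -> float:
        return self.z


def z_factor(scores_pos, scores_neg) -> ZFactorResult:
    """Z' = 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg| with sample SDs."""
    p = np.asarray(scores_pos, float)
    n = np.asarray(scores_neg, float)
    if p.size < 2 or n.size < 2:
        raise ValueError("need >= 2 scores per class")
    mu_p, mu_n = p.mean(), n.mean()
    sd_p, sd_n = p.std(ddof=1), n.std(ddof=1)
    if mu_p == mu_n:
        return ZFactorResult(mu_p, mu_n, sd_p, sd_n, -np.inf, defined=False)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return ZFactorResult(float(mu_p), float(mu_n), float(sd_p), float(sd_n), float(z), True)


@dataclass
class AttributionResult:
    """Leave-one-feature-out Z-factor attribution."""

    z_full: float
    table: pd.DataFrame  # feature, z_without, delta_z; sorted by delta_z desc

    def ranked_features(self) -> list[str]:
        return self.table["feature"].tolist()


def _model_class_z(model, table) -> float:
    scored = score_wells(model, table)
    pos = scored.loc[scored["condition"] == model.class_pos, "score"]
    neg = scored.loc[scored["condition"] == model.class_neg, "score"]
    return z_factor(pos, neg).z


def loocv_attribution(
    table: pd.DataFrame,
    class_neg: str,
    class_pos: str,
    algorithm: str = "SVM",
    cv: CVSpec | None = None,
    grid: dict | None = None,
    features: list[str] | None = None,
) -> AttributionResult:
    """Retrain with each feature left out once; attribute Z-factor drops.

    The same CV seed is reused for every retrain so that delta_z reflects the
    removed feature, not resampling noise.
    """
    from .io import feature_columns

    cv = cv or CVSpec()
    feats = features if features is not None else feature_columns(table)
    if len(feats) < 2:
        raise ValueError("need >= 2 features to leave one out")
    meta_cols = [c for c in table.columns if c not in feats]

    full = train_reference(table[meta_cols + feats], class_neg, class_pos, algorithm, cv, grid)
    z_full = _model_class_z(full, table)

    rows = []
    for f in feats:
        rest = [g for g in feats if g != f]
        m = train_reference(table[meta_cols + rest], class_neg, class_pos, algorithm, cv, grid)
        z_wo = _model_class_z(m, table)
        rows.append({"feature": f, "z_without": z_wo, "delta_z": z_full - z_wo})
    out = pd.DataFrame(rows).sort_values("delta_z", ascending=False, ignore_index=True)
    return AttributionResult(z_full=z_full, table=out)


@dataclass
class HitCall:
    reference_median: float
    reference_sd: float
    k: float
    wells: pd.DataFrame  # score, distance (in ref SDs), hit, direction
    hit_fraction_by_condition: pd.Series
    degenerate: bool = False


def call_hits(
    scores,
    reference_scores,
    k: float = 3.0,
    conditions=None,
    min_reference: int = 8,
) -> HitCall:
    """Flag wells whose score is > k reference-SDs from the reference median."""
    s = np.asarray(scores, float)
    ref = np.asarray(reference_scores, float)
    if ref.size < min_reference:
        raise ValueError(f"need >= {min_reference} reference wells, got {ref.size}")
    if k <= 0:
        raise ValueError("k must be > 0")
    m = float(np.median(ref))
    sd = float(ref.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate reference (SD = 0): no hits called")
        wells = pd.DataFrame(
            {"score": s, "distance": np.zeros_like(s), "hit": False, "direction": 0}
        )
        return HitCall(m, sd, k, wells, pd.Series(dtype=float), degenerate=True)
    dist = (s - m) / sd
    hit = np.abs(dist) > k
    wells = pd.DataFrame(
        {"score": s, "distance": dist, "hit": hit, "direction": np.sign(dist).astype(int)}
    )
    if conditions is not None:
        wells["condition"] = np.asarray(conditions)
        frac = wells.groupby("condition")["hit"].mean()
    else:
        frac = pd.Series({"all": float(hit.mean())})
    return HitCall(m, sd, k, wells, frac)


@dataclass
class PowerResult:
    effect_size: float
    k: float
    power_target: float
    directional: bool
    n_sim: int
    power_by_n: pd.Series  # index n, non-decreasing by construction
    minimal_n: int | None  # None when target not reached at n_max
    analytic_p: float | None = None


def _analytic_p(d: float, k: float, directional: bool) -> float:
    """Per-well probability of landing beyond the k-SD threshold, normal null."""
    if directional:
        return float(stats.norm.cdf(d - k))
    return float(stats.norm.cdf(d - k) + stats.norm.cdf(-d - k))


def replicate_power(
    null_model: str | np.ndarray = "normal",
    d: float = 2.0,
    k: float = 3.0,
    power_target: float = 0.85,
    n_max: int = 1000,
    n_sim: int = 2000,
    directional: bool = True,
    method: str = "mc",
    seed: int = 0,
) -> PowerResult:
    """How many replicate wells are needed to see at least one k-SD hit?

    Wells are drawn from the null shifted by ``d`` null-SDs; a replicate set
    succeeds when at least one well lies beyond ``k`` SDs from the null
    median (in the shift direction when ``directional``, either way
    otherwise).  ``method="analytic"`` (normal null only) uses the closed
    form 1 - (1 - p)^n instead of simulation.
    """
    if d < 0:
        raise ValueError("effect size d must be >= 0")
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must lie in (0, 1)")

    is_normal = isinstance(null_model, str) and null_model == "normal"
    if method == "analytic":
        if not is_normal:
            raise ValueError("analytic method requires the normal null")
        p = _analytic_p(d, k, directional)
        n = np.arange(1, n_max + 1)
        power = 1.0 - (1.0 - p) ** n
        series = pd.Series(power, index=n)
    elif method == "mc":
        rng = np.random.default_rng(seed)
        if is_normal:
            med, sd = 0.0, 1.0
            draws = rng.standard_normal((n_sim, n_max)) + d * sd
        else:
            ref = np.asarray(null_model, float)
            if ref.size < 8:
                raise ValueError("empirical null needs >= 8 scores")
            med, sd = float(np.median(ref)), float(ref.std(ddof=1))
            draws = rng.choice(ref, size=(n_sim, n_max), replace=True) + d * sd
        if directional:
            beyond = draws > med + k * sd
        else:
            beyond = np.abs(draws - med) > k * sd
        # shared draws across n make the power curve monotone by construction
        any_hit = np.cumsum(beyond, axis=1) > 0
        series = pd.Series(any_hit.mean(axis=0), index=np.arange(1, n_max + 1))
        p = _analytic_p(d, k, directional) if is_normal else None
    else:
        raise ValueError("method must be 'mc' or 'analytic'")

    reached = series.index[series >= power_target]
    minimal_n = int(reached[0]) if len(reached) else None
    return PowerResult(
        effect_size=d,
        k=k,
        power_target=power_target,
        directional=directional,
        n_sim=n_sim if method == "mc" else 0,
        power_by_n=series,
        minimal_n=minimal_n,
        analytic_p=p,
    )


def compare_groups(x, y, test: str = "auto"):
    """Two-sided two-group comparison; returns (statistic, p_value, test_used)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 values per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups")
        return 0.0, 1.0, "degenerate"
    if test == "auto":
        normal = all(
            np.ptp(g) > 0 and stats.shapiro(g).pvalue > 0.05 for g in (x, y)
        )
        test = "welch" if normal else "mannwhitney"
    if test == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue), "mannwhitney"
    if test == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue), "welch"
    raise ValueError("test must be 'mannwhitney', 'welch' or 'auto'")


def bootstrap_median_ci(
    x, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    x = np.asarray(x, float)
    if x.size < 5:
        raise ValueError("need >= 5 values")
    rng = np.random.default_rng(seed)
    medians = np.median(
        rng.choice(x, size=(n_boot, x.size), replace=True), axis=1
    )
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(medians, alpha)), float(np.quantile(medians, 1.0 - alpha))
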