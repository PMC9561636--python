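"""Two-class reference profiling models and decision-space mapping.

A reference model is an ensemble of ``n_repeats`` fits, each trained on a
stratified shuffled 80% slice with grid-searched hyperparameters and tested
on the held-out 20%.  The per-well score is the ensemble-mean decision value,
affinely normalized so that the training-set class medians sit at exactly
0 (negative class) and 1 (positive class); other conditions mapped through
the model land on this axis, where proximity means phenotypic similarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import GridSearchCV, ShuffleSplit, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import feature_columns

ALGORITHMS = ("LDA", "SVM", "GBM")

DEFAULT_GRIDS = {
    "SVM": {"clf__C": [0.01, 0.1, 1, 10]},
    "LDA": {},
    "GBM": {
        "clf__max_iter": [100, 300],
        "clf__max_depth": [3, 5],
        "clf__learning_rate": [0.05, 0.1],
    },
}


class ClassError(ValueError):
    pass


class MappingError(KeyError):
    pass


@dataclass(frozen=True)
class CVSpec:
    """Repeated stratified shuffle-split evaluation protocol."""

    train_fraction: float = 0.8
    n_repeats: int = 25
    stratified: bool = True
    seed: int = 0
    inner_folds: int = 3  # grid-search folds inside each training slice

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")


def _make_estimator(algorithm: str) -> Pipeline:
    if algorithm == "SVM":
        clf = SVC(kernel="linear", C=1.0)
    elif algorithm == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif algorithm == "GBM":
        clf = HistGradientBoostingClassifier(random_state=0)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class ProfileModel:
    """Trained two-class reference model (ensemble over CV repeats)."""

    algorithm: str
    class_neg: str
    class_pos: str
    feature_names: list[str]
    fits: list = dc_field(default_factory=list)
    chosen_params: list = dc_field(default_factory=list)
    test_accuracies: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    anchor_neg: float = 0.0
    anchor_pos: float = 1.0
    cv: CVSpec = dc_field(default_factory=CVSpec)

    @property
    def accuracy_mean(self) -> float:
        return float(self.test_accuracies.mean())

    @property
    def accuracy_sem(self) -> float:
        a = self.test_accuracies
        return float(a.std(ddof=1) / np.sqrt(len(a)))

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-mean signed decision value (log-odds for GBM)."""
        return np.mean([f.decision_function(X) for f in self.fits], axis=0)

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        span = self.anchor_pos - self.anchor_neg
        if span == 0:
            raise ClassError("degenerate anchors: classes are not separated")
        return (raw - self.anchor_neg) / span

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "algorithm": self.algorithm,
            "class_neg": self.class_neg,
            "class_pos": self.class_pos,
            "feature_names": self.feature_names,
            "chosen_params": self.chosen_params,
            "test_accuracies": self.test_accuracies.tolist(),
            "anchor_neg": self.anchor_neg,
            "anchor_pos": self.anchor_pos,
            "cv": self.cv.__dict__,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.fits, d / "fits.joblib")

    @classmethod
    def load(cls, directory) -> "ProfileModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        cv = CVSpec(**meta.pop("cv"))
        fits = joblib.load(d / "fits.joblib")
        return cls(
            fits=fits,
            cv=cv,
            test_accuracies=np.asarray(meta.pop("test_accuracies")),
            **meta,
        )


def _class_matrix(table: pd.DataFrame, class_neg: str, class_pos: str, features=None):
    feats = features if features is not None else feature_columns(table)
    sub = table[table["condition"].isin([class_neg, class_pos])]
    for cls in (class_neg, class_pos):
        if not (sub["condition"] == cls).any():
            raise ClassError(f"condition {cls!r} absent from table")
    X = sub[feats].to_numpy(float)
    if not np.isfinite(X).all():
        raise ClassError("non-finite feature values; preprocess the table first")
    y = (sub["condition"] == class_pos).to_numpy(int)
    return sub, X, y, feats


def train_reference(
    table: pd.DataFrame,
    class_neg: str,
    class_pos: str,
    algorithm: str = "SVM",
    cv: CVSpec | None = None,
    grid: dict | None = None,
    min_wells: int = 10,
) -> ProfileModel:
    """Train the ensemble reference model separating two conditions."""
    cv = cv or CVSpec()
    grid = DEFAULT_GRIDS[algorithm] if grid is None else grid
    sub, X, y, feats = _class_matrix(table, class_neg, class_pos)
    for cls, n in zip((class_neg, class_pos), np.bincount(y, minlength=2)):
        if n < min_wells:
            raise ClassError(f"class {cls!r} has {n} wells, need >= {min_wells}")

    splitter_cls = StratifiedShuffleSplit if cv.stratified else ShuffleSplit
    splitter = splitter_cls(
        n_splits=cv.n_repeats, train_size=cv.train_fraction, random_state=cv.seed
    )
    fits, params, accs = [], [], []
    for train_idx, test_idx in splitter.split(X, y):
        est = _make_estimator(algorithm)
        if grid:
            search = GridSearchCV(est, grid, cv=cv.inner_folds, scoring="accuracy", n_jobs=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(X[train_idx], y[train_idx])
            best = search.best_estimator_
            params.append(search.best_params_)
        else:
            best = est.fit(X[train_idx], y[train_idx])
            params.append({})
        fits.append(best)
        accs.append(float(best.score(X[test_idx], y[test_idx])))

    model = ProfileModel(
        algorithm=algorithm,
        class_neg=class_neg,
        class_pos=class_pos,
        feature_names=list(feats),
        fits=fits,
        chosen_params=params,
        test_accuracies=np.asarray(accs),
        cv=cv,
    )
    raw = model.raw_scores(X)
    model.anchor_neg = float(np.median(raw[y == 0]))
    model.anchor_pos = float(np.median(raw[y == 1]))
    return model


def score_wells(model: ProfileModel, table: pd.DataFrame) -> pd.DataFrame:
    """Map wells (seen or unseen) onto the normalized reference axis."""
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise MappingError(f"table lacks model feature(s): {missing}")
    X = table[model.feature_names].to_numpy(float)
    raw = model.raw_scores(X)
    out = table[[c for c in ("plate_id", "well", "condition", "compound", "spiked") if c in table.columns]].copy()
    out["raw_score"] = raw
    out["score"] = model.normalize(raw)
    return out


def cross_plate_validate(
    table: pd.DataFrame,
    class_neg: str,
    class_pos: str,
    algorithm: str = "SVM",
    grid: dict | None = None,
    train_plate: str | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Fit on one plate, report accuracy on every other plate."""
    plates = list(dict.fromkeys(table["plate_id"]))
    if len(plates) < 2:
        raise ValueError("cross-plate validation needs >= 2 plates")
    train_plate = plates[0] if train_plate is None else train_plate
    grid = DEFAULT_GRIDS[algorithm] if grid is None else grid

    _, Xtr, ytr, feats = _class_matrix(
        table[table["plate_id"] == train_plate], class_neg, class_pos
    )
    est = _make_estimator(algorithm)
    if grid:
        est = GridSearchCV(est, grid, cv=3, scoring="accuracy", n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Xtr, ytr)

    result: dict[str, float] = {}
    for plate in plates:
        if plate == train_plate:
            continue
        sub = table[table["plate_id"] == plate]
        try:
            _, X, y, _ = _class_matrix(sub, class_neg, class_pos, features=feats)
        except ClassError as exc:
            warnings.warn(f"plate {plate} skipped: {exc}")
            continue
        result[str(plate)] = float(est.score(X, y))
    return result


def pca_embed(table: pd.DataFrame, n_components: int = 2):
    """Standardize features, project onto principal components.

    Returns ``(coordinates, explained_variance_fractions)``; components
    beyond the data rank are truncated with a warning.
    """
    feats = feature_columns(table)
    X = table[feats].to_numpy(float)
    max_rank = min(X.shape[0], X.shape[1])
    if n_components > max_rank:
        warnings.warn(f"n_components {n_components} exceeds rank bound {max_rank}; truncating")
        n_components = max_rank
    Xs = StandardScaler().fit_transform(X)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Xs)
    return coords, pca.explained_variance_ratio_
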