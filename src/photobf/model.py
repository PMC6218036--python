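"""nu-SVR body-fat prediction with the study's training protocol.

Three feature sets are compared against the DXA criterion:

* ``nophoto`` — age, sex, race, BMI (the baseline a clinic already has);
* ``volume`` — the above plus photographic body volume BV_PHOTO;
* ``volume_shape`` — the above plus the one-hot shape encoding BS_PHOTO.

Each model is a nu-SVR with an RBF kernel. Hyperparameters (gamma, cost,
nu) are chosen by exhaustive grid search — gamma and cost over powers of
two 2^-10..2^10, nu over 0.1..1.0 in steps of 0.1 — scored by internal
3-fold cross-validated MSE on the training set (a resubstitution scorer
is available behind a flag). Evaluation uses one round of 3-fold
cross-validation in which *everything* fit from data — shape-cluster
centroids, feature standardization statistics, hyperparameters — is
derived from the training folds only; each subject is predicted exactly
once. Children and adults are modelled as separate cohorts.

Continuous features are standardized with training-fold statistics; RBF
kernels on raw mixed-unit features (years, kg/m^2, liters) are
scale-pathological otherwise.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import NuSVR

from . import shape as shape_mod
from .errors import InsufficientSampleError, ValidationError
from .shape import BSEncoding, ShapeClusterModel, ShapeCurves

logger = logging.getLogger(__name__)

FEATURE_SETS = ("nophoto", "volume", "volume_shape")
PREDICTION_COLUMNS = {"nophoto": "bf_nophoto", "volume": "bf_volume", "volume_shape": "bf_photo"}


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates, photographic features and criterion %BF for one subject."""

    subject_id: str
    age: float
    sex: int
    race: int
    height_cm: float
    weight_kg: float
    bmi: float
    bf_dxa_pct: float
    bv_photo_L: float
    curves: ShapeCurves | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.bf_dxa_pct < 70.0):
            raise ValidationError(f"bf_dxa_pct={self.bf_dxa_pct} outside (0, 70)")
        if self.bv_photo_L <= 0:
            raise ValidationError("bv_photo_L must be positive")
        implied = self.weight_kg / (self.height_cm / 100.0) ** 2
        if abs(implied - self.bmi) > 0.1:
            raise ValidationError(
                f"bmi={self.bmi:.2f} inconsistent with height/weight (implies {implied:.2f})"
            )


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameter grids for the nu-SVR search."""

    gamma_exponents: tuple[int, ...] = tuple(range(-10, 11))
    cost_exponents: tuple[int, ...] = tuple(range(-10, 11))
    nu_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    seed: int = 0
    internal_folds: int = 3
    #: "cv" scores each grid point by internal K-fold MSE; "resubstitution"
    #: scores on the training points themselves.
    selection: str = "cv"

    def __post_init__(self) -> None:
        if any(not (0.0 < nu <= 1.0) for nu in self.nu_grid):
            raise ValidationError("nu values must lie in (0, 1]")
        if self.selection not in ("cv", "resubstitution"):
            raise ValidationError("selection must be 'cv' or 'resubstitution'")

    @classmethod
    def coarse(cls, seed: int = 0) -> "SVRConfig":
        """Documented coarse grid for end-to-end runs: exponents
        {-10,-6,-2,2,6,10} for gamma and cost, nu {0.2,...,1.0 step 0.2}."""
        return cls(
            gamma_exponents=(-10, -6, -2, 2, 6, 10),
            cost_exponents=(-10, -6, -2, 2, 6, 10),
            nu_grid=(0.2, 0.4, 0.6, 0.8, 1.0),
            seed=seed,
        )


_CONTINUOUS = {"age", "bmi", "bv"}


def _feature_columns(feature_set: str, encoding: BSEncoding | None) -> list[str]:
    cols = ["age", "sex", "race", "bmi"]
    if feature_set in ("volume", "volume_shape"):
        cols.append("bv")
    if feature_set == "volume_shape":
        if encoding is None:
            raise ValidationError("volume_shape features require a shape encoding")
        cols += [f"fc_k{i}" for i in range(len(encoding.fc_onehot))]
        cols += [f"sc_k{i}" for i in range(len(encoding.sc_onehot))]
    return cols


def build_features(
    record: SubjectRecord, feature_set: str, encoding: BSEncoding | None = None
) -> np.ndarray:
    """Raw (unstandardized) feature vector for one subject."""
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature set {feature_set!r}")
    for name in ("age", "sex", "race", "bmi"):
        if getattr(record, name) is None:
            raise ValidationError(f"missing required field '{name}'")
    vec = [record.age, record.sex, record.race, record.bmi]
    if feature_set in ("volume", "volume_shape"):
        vec.append(record.bv_photo_L)
    if feature_set == "volume_shape":
        if encoding is None:
            raise ValidationError("volume_shape features require a shape encoding")
        vec = np.concatenate([vec, encoding.concat()])
    return np.asarray(vec, dtype=float)


@dataclass
class FeatureScaler:
    """Standardizes continuous columns using training-set moments only."""

    continuous_idx: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, columns: list[str]) -> "FeatureScaler":
        idx = np.array([i for i, c in enumerate(columns) if c in _CONTINUOUS], dtype=int)
        mean = X[:, idx].mean(axis=0)
        sd = X[:, idx].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return cls(continuous_idx=idx, mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = X.astype(float).copy()
        out[:, self.continuous_idx] = (out[:, self.continuous_idx] - self.mean) / self.sd
        return out


@dataclass
class TrainedModel:
    feature_set: str
    svr: NuSVR
    scaler: FeatureScaler
    columns: list[str]
    gamma: float
    cost: float
    nu: float
    cv_mse: float
    cluster_model: ShapeClusterModel | None = None

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return self.svr.predict(self.scaler.transform(X_raw))


def _design_matrix(
    records: list[SubjectRecord],
    feature_set: str,
    encodings: list[BSEncoding] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if feature_set == "volume_shape":
        X = np.vstack(
            [build_features(r, feature_set, e) for r, e in zip(records, encodings)]
        )
        columns = _feature_columns(feature_set, encodings[0])
    else:
        X = np.vstack([build_features(r, feature_set) for r in records])
        columns = _feature_columns(feature_set, None)
    y = np.array([r.bf_dxa_pct for r in records])
    return X, y, columns


def _make_svr(gamma: float, cost: float, nu: float) -> NuSVR:
    return NuSVR(kernel="rbf", gamma=gamma, C=cost, nu=nu)


def grid_search_train(
    train: list[SubjectRecord],
    cfg: SVRConfig,
    feature_set: str,
    encodings: list[BSEncoding] | None = None,
    min_train: int = 20,
) -> TrainedModel:
    """Exhaustive (gamma, cost, nu) search, then refit on the full training set.

    Every grid point is scored by internal ``cfg.internal_folds``-fold CV
    mean squared error on the training data (or resubstitution MSE when
    ``cfg.selection == "resubstitution"``); the lowest-MSE combination
    wins, ties broken toward smaller exponents / smaller nu. Deterministic
    given ``cfg.seed``.
    """
    if len(train) < min_train:
        raise InsufficientSampleError(f"grid search requires >= {min_train} training subjects")
    X_raw, y, columns = _design_matrix(train, feature_set, encodings)
    if np.var(y) == 0:
        raise ValidationError("training target has zero variance")
    scaler = FeatureScaler.fit(X_raw, columns)
    X = scaler.transform(X_raw)

    if cfg.selection == "cv":
        kf = KFold(n_splits=cfg.internal_folds, shuffle=True, random_state=cfg.seed)
        splits = list(kf.split(X))
    best = None
    for ge in cfg.gamma_exponents:
        for ce in cfg.cost_exponents:
            for nu in cfg.nu_grid:
                gamma, cost = 2.0**ge, 2.0**ce
                if cfg.selection == "cv":
                    sse, cnt = 0.0, 0
                    for tr, te in splits:
                        m = _make_svr(gamma, cost, nu).fit(X[tr], y[tr])
                        resid = m.predict(X[te]) - y[te]
                        sse += float(resid @ resid)
                        cnt += len(te)
                    mse = sse / cnt
                else:
                    m = _make_svr(gamma, cost, nu).fit(X, y)
                    resid = m.predict(X) - y
                    mse = float(resid @ resid) / len(y)
                if best is None or mse < best[0]:
                    best = (mse, gamma, cost, nu)
    mse, gamma, cost, nu = best
    svr = _make_svr(gamma, cost, nu).fit(X, y)
    return TrainedModel(
        feature_set=feature_set, svr=svr, scaler=scaler, columns=columns,
        gamma=gamma, cost=cost, nu=nu, cv_mse=mse,
    )


@dataclass(frozen=True)
class FoldProvenance:
    """What was fit on which subjects — the leak-audit trail for one fold."""

    fold: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    k_fc: int
    k_sc: int
    centroid_hash: str
    scaler_means: dict[str, np.ndarray]
    hyperparameters: dict[str, tuple[float, float, float]]


@dataclass
class CVResult:
    """Pooled out-of-fold predictions for every model and subject."""

    predictions: pd.DataFrame  # subject_id, fold, bf_dxa, bf_nophoto, bf_volume, bf_photo
    pearson_r: dict[str, float]
    provenance: list[FoldProvenance]
    seed: int


def _hash_centroids(model: ShapeClusterModel) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.fc.centroids).tobytes())
    h.update(np.ascontiguousarray(model.sc.centroids).tobytes())
    return h.hexdigest()[:16]


def cross_validate(
    cohort: list[SubjectRecord],
    cfg: SVRConfig,
    seed: int,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    n_folds: int = 3,
    rounds: int = 1,
) -> CVResult:
    """One round of 3-fold CV with per-fold cluster fitting and grid search.

    Subjects are shuffled with ``seed`` and split into ``n_folds``
    near-equal folds. Within each fold: shape clusters are fit on the
    training folds only, the test fold is encoded by nearest centroid,
    each feature-set model is grid-search-trained, and the held-out fold
    predicted. After one round every subject carries exactly one
    prediction per model. ``rounds > 1`` repeats the protocol with fresh
    shuffles and pools all predictions.
    """
    if len(cohort) < 30:
        raise InsufficientSampleError("cross-validation requires at least 30 subjects")
    if any(r.curves is None for r in cohort) and "volume_shape" in feature_sets:
        raise ValidationError("volume_shape models require shape curves on every record")

    rows = []
    provenance: list[FoldProvenance] = []
    for rnd in range(rounds):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rnd)
        idx = np.arange(len(cohort))
        for fold, (tr, te) in enumerate(kf.split(idx)):
            if len(tr) <= 10:
                raise InsufficientSampleError("training folds need > 10 subjects for clustering")
            train = [cohort[i] for i in tr]
            test = [cohort[i] for i in te]

            cluster_model = None
            train_enc = test_enc = None
            if "volume_shape" in feature_sets:
                cluster_model = shape_mod.fit_shape_clusters(
                    [r.curves for r in train], seed=cfg.seed
                )
                train_enc = [shape_mod.encode_shape(r.curves, cluster_model) for r in train]
                test_enc = [shape_mod.encode_shape(r.curves, cluster_model) for r in test]

            fold_preds = {}
            scaler_means = {}
            hypers = {}
            for fs in feature_sets:
                enc = train_enc if fs == "volume_shape" else None
                model = grid_search_train(train, cfg, fs, encodings=enc)
                X_test, _, _ = _design_matrix(
                    test, fs, test_enc if fs == "volume_shape" else None
                )
                pred = model.predict(X_test)
                out_of_range = (pred <= 0) | (pred >= 70)
                if out_of_range.any():
                    warnings.warn(
                        f"{out_of_range.sum()} predicted %BF values outside (0, 70) "
                        f"in fold {fold} ({fs}); reported unclipped",
                        stacklevel=2,
                    )
                fold_preds[fs] = pred
                scaler_means[fs] = model.scaler.mean.copy()
                hypers[fs] = (model.gamma, model.cost, model.nu)

            for j, rec in enumerate(test):
                row = {
                    "subject_id": rec.subject_id,
                    "round": rnd,
                    "fold": fold,
                    "bf_dxa": rec.bf_dxa_pct,
                }
                for fs in feature_sets:
                    row[PREDICTION_COLUMNS[fs]] = float(fold_preds[fs][j])
                rows.append(row)
            provenance.append(
                FoldProvenance(
                    fold=fold + rnd * n_folds,
                    train_ids=tuple(r.subject_id for r in train),
                    test_ids=tuple(r.subject_id for r in test),
                    k_fc=cluster_model.k_fc if cluster_model else 0,
                    k_sc=cluster_model.k_sc if cluster_model else 0,
                    centroid_hash=_hash_centroids(cluster_model) if cluster_model else "",
                    scaler_means=scaler_means,
                    hyperparameters=hypers,
                )
            )

    preds = pd.DataFrame(rows)
    pearson = {
        fs: float(np.corrcoef(preds["bf_dxa"], preds[PREDICTION_COLUMNS[fs]])[0, 1])
        for fs in feature_sets
    }
    return CVResult(predictions=preds, pearson_r=pearson, provenance=provenance, seed=seed)


def split_strata(records: list[SubjectRecord]) -> dict[str, list[SubjectRecord]]:
    """Children (6-18 y) and adults (>= 19 y) as separate cohorts."""
    return {
        "children": [r for r in records if r.age < 19],
        "adults": [r for r in records if r.age >= 19],
    }
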