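"""The two-layer SVM architecture.

Positive training windows are split into two K-means clusters; each cluster,
together with randomly drawn negatives at a 1:3 positive:negative ratio,
trains an RBF-kernel SVM with probability outputs ("clustered model 1" and
"clustered model 2").  These first-layer models act purely as variable
generators: every sample is pushed through both, and the concatenated
(positive, negative) probability pairs — a 4-vector — train a second-layer
RBF SVM that makes the final call.  The first-layer models are frozen once
fitted; second-layer training never touches them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import sklearn
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import EncodingScheme, SampleSet

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def _fit(clf: SVC, X: np.ndarray, y: np.ndarray) -> SVC:
    # libsvm's built-in Platt calibration is the probability mechanism this
    # architecture stacks on; silence scikit-learn's migration warning.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
        clf.fit(X, y)
    return clf

#: Fixed order of the second-layer input vector.
META_FEATURE_ORDER = ("p1_pos", "p1_neg", "p2_pos", "p2_neg")


@dataclass
class TrainingConfig:
    """Hyperparameters of the two-layer model.

    The default (C, gamma) pairs — (0.5, 2^-7) for both clustered models and
    (32, 8) for the second layer — are the grid-search optima of the original
    study conditions and are used verbatim when ``grid_search`` is off.
    """

    k_clusters: int = 2
    neg_ratio: float = 3.0
    first_layer_C: float = 0.5
    first_layer_gamma: float = 0.0078125
    second_layer_C: float = 32.0
    second_layer_gamma: float = 8.0
    kernel: str = "rbf"
    seed: int = 0
    grid_search: bool = False

    def __post_init__(self) -> None:
        for name in ("first_layer_C", "first_layer_gamma", "second_layer_C", "second_layer_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        if self.kernel != "rbf":
            raise ValueError("only the rbf kernel is supported")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)


@dataclass
class ClusteredModel:
    """A first-layer probability generator trained on one positive cluster.

    ``cluster_index`` is 1 or 2 (cluster 1 is the larger positive subset).
    The classifier outputs calibrated (p_pos, p_neg) with p_pos + p_neg = 1.
    """

    cluster_index: int
    classifier: SVC
    training_ids: list[int]

    def predict_proba_pairs(self, X: np.ndarray) -> np.ndarray:
        """Return an n x 2 array of (p_pos, p_neg) rows."""
        proba = self.classifier.predict_proba(np.asarray(X, dtype=float))
        classes = list(self.classifier.classes_)
        p_pos = proba[:, classes.index(1)]
        return np.column_stack([p_pos, 1.0 - p_pos])


@dataclass
class TwoLayerModel:
    """The assembled stacked predictor: two frozen generators + second-layer SVM."""

    scheme: EncodingScheme | None
    cluster_models: tuple[ClusteredModel, ClusteredModel]
    second_layer: SVC
    config: TrainingConfig


def cluster_positives(
    positive_features: np.ndarray, k: int = 2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-means over raw positive feature vectors.

    Clusters are renumbered so cluster 0 is the larger one (ties broken by
    lower centroid norm).  Returns (assignments, centers) with assignments
    in 0..k-1 following the renumbering.
    """
    X = np.asarray(positive_features, dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least {k} positive samples to form {k} clusters, got {len(X)}")
    km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], norms[c]))
    relabel = {old: new for new, old in enumerate(order)}
    assignments = np.array([relabel[c] for c in raw])
    centers = km.cluster_centers_[order]
    return assignments, centers


def sample_negatives(
    negative_pool: np.ndarray, n_positive: int, ratio: float = 3.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement draw of round(ratio * n_positive) negatives.

    When the pool is smaller than requested, the whole pool is returned with
    a warning.  Returns (subset, indices into the pool).
    """
    pool = np.asarray(negative_pool, dtype=float)
    if len(pool) == 0:
        raise ValueError("negative pool is empty")
    n_want = int(round(ratio * n_positive))
    rng = np.random.default_rng(seed)
    if n_want >= len(pool):
        if n_want > len(pool):
            warnings.warn(
                f"negative pool ({len(pool)}) smaller than requested ({n_want}); using whole pool"
            )
        idx = np.arange(len(pool))
    else:
        idx = np.sort(rng.choice(len(pool), size=n_want, replace=False))
    return pool[idx], idx


def train_clustered_model(
    positives: np.ndarray,
    negatives: np.ndarray,
    C: float,
    gamma: float,
    seed: int = 0,
    cluster_index: int = 1,
    training_ids: Sequence[int] | None = None,
) -> ClusteredModel:
    """Fit one first-layer RBF SVM with Platt-style probability calibration."""
    positives = np.asarray(positives, dtype=float)
    negatives = np.asarray(negatives, dtype=float)
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([positives, negatives])
    y = np.concatenate([np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)])
    clf = SVC(C=C, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
    _fit(clf, X, y)
    return ClusteredModel(
        cluster_index=cluster_index,
        classifier=clf,
        training_ids=list(training_ids) if training_ids is not None else [],
    )


def meta_features(
    X: np.ndarray, model1: ClusteredModel, model2: ClusteredModel
) -> np.ndarray:
    """Second-layer inputs: (p1_pos, p1_neg, p2_pos, p2_neg) per sample."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    expect = model1.classifier.n_features_in_
    if X.shape[1] != expect:
        raise ValueError(f"feature width {X.shape[1]} does not match first-layer input ({expect})")
    return np.hstack([model1.predict_proba_pairs(X), model2.predict_proba_pairs(X)])


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def fit_first_layer(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig, max_retries: int = 5
) -> tuple[ClusteredModel, ClusteredModel]:
    """Cluster the positives and fit both clustered models.

    Degenerate clusterings (an empty cluster) trigger a bounded number of
    reseeded retries before erroring out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("training data must contain both classes")
    fl_C, fl_gamma = config.first_layer_C, config.first_layer_gamma
    for attempt in range(max_retries):
        seed = _derive_seed(config.seed, attempt)
        assignments, _ = cluster_positives(X[pos_idx], k=config.k_clusters, seed=seed)
        sizes = np.bincount(assignments, minlength=config.k_clusters)
        if (sizes > 0).all():
            break
        logger.warning("empty positive cluster on attempt %d; retrying with new seed", attempt + 1)
    else:
        raise RuntimeError(f"K-means produced an empty cluster in {max_retries} attempts")
    models: list[ClusteredModel] = []
    for c in range(config.k_clusters):
        cluster_pos_idx = pos_idx[assignments == c]
        neg_seed = _derive_seed(config.seed, 100 + c)
        sampled_neg, sub = sample_negatives(
            X[neg_idx], len(cluster_pos_idx), ratio=config.neg_ratio, seed=neg_seed
        )
        if config.grid_search:
            Xc = np.vstack([X[cluster_pos_idx], sampled_neg])
            yc = np.concatenate([np.ones(len(cluster_pos_idx), int), np.zeros(len(sampled_neg), int)])
            fl_C, fl_gamma = grid_search(
                Xc, yc, DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, seed=_derive_seed(config.seed, 200 + c)
            )
        models.append(
            train_clustered_model(
                X[cluster_pos_idx],
                sampled_neg,
                C=fl_C,
                gamma=fl_gamma,
                seed=_derive_seed(config.seed, 300 + c),
                cluster_index=c + 1,
                training_ids=list(cluster_pos_idx) + list(neg_idx[sub]),
            )
        )
    if config.k_clusters == 1:
        # single-generator degenerate mode: duplicate the generator
        models.append(models[0])
    return models[0], models[1]


def fit_second_layer(meta: np.ndarray, y: np.ndarray, config: TrainingConfig) -> SVC:
    """Fit the second-layer RBF SVM on the 4-dimensional probability vectors."""
    y_int = np.asarray(y, dtype=bool).astype(int)
    C, gamma = config.second_layer_C, config.second_layer_gamma
    if config.grid_search:
        C, gamma = grid_search(
            meta, y_int, DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, seed=_derive_seed(config.seed, 400)
        )
    clf = SVC(C=C, gamma=gamma, kernel="rbf", probability=True,
              random_state=_derive_seed(config.seed, 500))
    _fit(clf, meta, y_int)
    return clf


def train_two_layer(samples: SampleSet, config: TrainingConfig) -> TwoLayerModel:
    """Full training pipeline: cluster, fit generators, stack, fit second layer.

    All training samples pass through both frozen generators; the second
    layer is trained on their 4-vector meta-features with the original
    labels.
    """
    m1, m2 = fit_first_layer(samples.X, samples.y, config)
    meta = meta_features(samples.X, m1, m2)
    second = fit_second_layer(meta, samples.y, config)
    return TwoLayerModel(
        scheme=samples.scheme, cluster_models=(m1, m2), second_layer=second, config=config
    )


def predict(
    model: TwoLayerModel, samples: SampleSet, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Score samples with the stacked model.

    Returns (labels, scores); the score is the second-layer positive-class
    probability and the label is score >= threshold.
    """
    if (model.scheme is None) != (samples.scheme is None) or (
        model.scheme is not None and model.scheme != samples.scheme
    ):
        raise ValueError(
            f"encoding scheme mismatch: model has {model.scheme}, samples have {samples.scheme}"
        )
    meta = meta_features(samples.X, *model.cluster_models)
    proba = model.second_layer.predict_proba(meta)
    classes = list(model.second_layer.classes_)
    scores = proba[:, classes.index(1)]
    return scores >= threshold, scores


def train_single_svm(samples: SampleSet, config: TrainingConfig) -> SVC:
    """Baseline: one RBF SVM on the raw features (no clustering, no stacking)."""
    clf = SVC(
        C=config.first_layer_C,
        gamma=config.first_layer_gamma,
        kernel="rbf",
        probability=True,
        random_state=_derive_seed(config.seed, 600),
    )
    _fit(clf, samples.X, samples.y.astype(int))
    return clf


def predict_single_svm(
    clf: SVC, samples: SampleSet, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    proba = clf.predict_proba(samples.X)
    classes = list(clf.classes_)
    scores = proba[:, classes.index(1)]
    return scores >= threshold, scores


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

#: Default grids of common SVM tooling: C = 2^-5..2^15, gamma = 2^-15..2^3, step x4.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search maximizing inner-CV accuracy.

    Ties go to the smallest C, then the smallest gamma.  Inner folds whose
    training part is single-class are skipped with a warning.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_splits = min(inner_folds, int(np.bincount(y).min()))
    splits = None
    if n_splits >= 2 and len(X) > n_splits:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            accs: list[float] = []
            if splits is None:
                clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(X, y)
                accs.append(float(clf.score(X, y)))
            else:
                for train, test in splits:
                    if len(np.unique(y[train])) < 2:
                        warnings.warn("inner fold with a single class skipped")
                        continue
                    clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(X[train], y[train])
                    accs.append(float(clf.score(X[test], y[test])))
            score = float(np.mean(accs)) if accs else -np.inf
            if best is None or score > best[0] + 1e-12:
                best = (score, C, gamma)
    assert best is not None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: TwoLayerModel, path: str | Path) -> None:
    """Persist the model as a single versioned archive (joblib)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "sklearn_version": sklearn.__version__,
        "scheme": model.scheme.to_dict() if model.scheme else None,
        "config": model.config.to_dict(),
        "meta_feature_order": list(META_FEATURE_ORDER),
        "calibration": "platt sigmoid (libsvm pairwise coupling)",
        "cluster_models": [
            {"cluster_index": m.cluster_index, "classifier": m.classifier, "training_ids": m.training_ids}
            for m in model.cluster_models
        ],
        "second_layer": model.second_layer,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TwoLayerModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    cms = tuple(
        ClusteredModel(
            cluster_index=d["cluster_index"],
            classifier=d["classifier"],
            training_ids=d["training_ids"],
        )
        for d in payload["cluster_models"]
    )
    return TwoLayerModel(
        scheme=EncodingScheme.from_dict(payload["scheme"]) if payload["scheme"] else None,
        cluster_models=cms,  # type: ignore[arg-type]
        second_layer=payload["second_layer"],
        config=TrainingConfig.from_dict(payload["config"]),
    )
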