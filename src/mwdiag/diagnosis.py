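"""Random-forest diagnosis with EA/MA/EAC channel-angle architectures.

Every (scan, channel) signature or feature vector is one observation row
labelled with its scan's class; scans are only fused at prediction time.
Three model families differ in which channel angles feed a forest:

* **EA(Z)** — one forest per single channel angle Z (7 models on a 12-ring);
* **MA(0..U)** — one forest pooling every channel with angle <= U (6 models);
* **EAC(0..U)** — one EA member per distinct angle <= U, members fused by
  majority vote (6 models).

Per-channel predictions become one diagnosis per scan through *antenna
grouping*: a majority vote over the W channels closest to the tumour
(ranked by two-leg path length).  Hyperparameters (number of trees, features
per split, minimum leaf size) are tuned by sequential model-based (Bayesian)
search minimising the forest's out-of-bag misclassification error, and
generalisation is estimated with k-fold nested cross-validation stratified
by class at the scan level, keeping all 78 signals of a scan together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DataError
from .geometry import ChannelRanking, RingArray, distinct_angles

__all__ = [
    "LABELS",
    "ForestConfig",
    "TrainedForest",
    "ClassificationModel",
    "ScanDiagnosis",
    "FoldPlan",
    "CVResult",
    "train_forest",
    "optimise_hyperparameters",
    "build_model",
    "predict_channels",
    "antenna_grouping",
    "fuse_channel_predictions",
    "diagnose_scans",
    "make_fold_plan",
    "nested_cv",
    "model_family",
    "observation_columns",
]

LABELS = ("benign", "malignant")

#: default hyperparameter search space (inclusive integer bounds)
DEFAULT_SEARCH_SPACE = {
    "n_trees": (50, 500),
    "n_features_per_split": (1, 30),
    "min_leaf_size": (1, 20),
}

META_COLUMNS = ("scan_id", "tx", "rx", "angle", "label")


def observation_columns(table: pd.DataFrame) -> list[str]:
    """Feature/data columns of an observation table (everything non-meta)."""
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters under optimisation."""

    n_trees: int = 200
    n_features_per_split: int = 5
    min_leaf_size: int = 1

    def __post_init__(self) -> None:
        if min(self.n_trees, self.n_features_per_split, self.min_leaf_size) < 1:
            raise ConfigError(f"all forest hyperparameters must be >= 1: {self}")


@dataclass
class TrainedForest:
    """A fitted ensemble plus its OOB error and impurity importances."""

    estimator: RandomForestClassifier
    oob_error: float
    importances: np.ndarray
    classes: tuple[str, ...]
    config: ForestConfig
    X_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)

    def malignant_proba(self, X: np.ndarray) -> np.ndarray:
        j = list(self.estimator.classes_).index("malignant")
        return self.estimator.predict_proba(X)[:, j]


def train_forest(
    features: np.ndarray, labels, config: ForestConfig, seed: int = 0
) -> TrainedForest:
    """Fit a bagged forest of ``config.n_trees`` trees and score it out-of-bag.

    Each tree trains on a bootstrap resample (about one third of the
    observations are left out of each tree and score it as its OOB set) with
    ``n_features_per_split`` candidate features per split.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("training data must contain both classes")
    if counts.min() < 2:
        raise DataError("need at least 2 observations per class")
    if config.n_features_per_split > X.shape[1]:
        raise ConfigError(
            f"n_features_per_split={config.n_features_per_split} exceeds dimension {X.shape[1]}"
        )
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.n_features_per_split,
        min_samples_leaf=config.min_leaf_size,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # few trees on small data can leave rows without OOB votes; the OOB
        # estimate over covered rows is still the selection criterion
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        rf.fit(X, y)
    return TrainedForest(
        estimator=rf,
        oob_error=1.0 - float(rf.oob_score_),
        importances=rf.feature_importances_.copy(),
        classes=tuple(str(c) for c in rf.classes_),
        config=config,
        X_train=X,
        y_train=y,
    )


def _expected_improvement(mu, sigma, best):
    z = np.where(sigma > 0, (best - mu) / np.maximum(sigma, 1e-12), 0.0)
    return np.where(sigma > 0, (best - mu) * norm.cdf(z) + sigma * norm.pdf(z), 0.0)


def optimise_hyperparameters(
    features: np.ndarray,
    labels,
    search_space: dict | None = None,
    budget: int = 30,
    seed: int = 0,
    return_history: bool = False,
):
    """Sequential model-based (Bayesian) search minimising OOB error.

    Starts from a seeded random design, then fits a Gaussian-process
    surrogate (Matern 5/2) over the unit-scaled integer space and evaluates
    the candidate with maximum expected improvement.  Returns the
    best-evaluated config; ties break towards the smaller ``n_trees``.
    """
    if budget < 5:
        raise ConfigError(f"search budget must be at least 5 evaluations, got {budget}")
    space = dict(DEFAULT_SEARCH_SPACE) if search_space is None else dict(search_space)
    if not space:
        raise ConfigError("empty hyperparameter search space")
    X = np.asarray(features, dtype=float)
    keys = ("n_trees", "n_features_per_split", "min_leaf_size")
    bounds = []
    for k in keys:
        lo, hi = space.get(k, DEFAULT_SEARCH_SPACE[k])
        if k == "n_features_per_split":
            hi = min(hi, X.shape[1])
            lo = min(lo, hi)
        bounds.append((int(lo), int(hi)))

    rng = np.random.default_rng(seed)

    def draw() -> tuple[int, int, int]:
        return tuple(int(rng.integers(lo, hi + 1)) for lo, hi in bounds)

    def scale(p) -> np.ndarray:
        return np.array([
            (v - lo) / (hi - lo) if hi > lo else 0.0 for v, (lo, hi) in zip(p, bounds)
        ])

    evaluated: dict[tuple[int, int, int], float] = {}

    def evaluate(p: tuple[int, int, int]) -> float:
        if p not in evaluated:
            cfg = ForestConfig(*p)
            evaluated[p] = train_forest(X, labels, cfg, seed=seed).oob_error
        return evaluated[p]

    n_init = min(5, budget)
    while len(evaluated) < n_init:
        evaluate(draw())

    while len(evaluated) < budget:
        pts = np.array([scale(p) for p in evaluated])
        errs = np.array(list(evaluated.values()))
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=0.3),
            alpha=1e-4, normalize_y=True, random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(pts, errs)
        cand = [draw() for _ in range(128)]
        cand = [p for p in cand if p not in evaluated] or [draw()]
        mu, sigma = gp.predict(np.array([scale(p) for p in cand]), return_std=True)
        ei = _expected_improvement(mu, sigma, errs.min())
        evaluate(cand[int(np.argmax(ei))])

    best = min(evaluated.items(), key=lambda kv: (kv[1], kv[0]))
    config = ForestConfig(*best[0])
    if return_history:
        history = [(ForestConfig(*p), e) for p, e in evaluated.items()]
        return config, history
    return config


@dataclass
class ClassificationModel:
    """EA/MA/EAC model: member forests keyed by channel angle (MA by its upper bound)."""

    kind: str
    angle_spec: float
    forests: dict[float, TrainedForest]

    @property
    def member_angles(self) -> list[float]:
        return sorted(self.forests)


@dataclass
class ScanDiagnosis:
    """Fused benign/malignant call for one scan."""

    scan_id: str
    channel_votes: dict
    w_used: int
    fused_label: str
    fused_score: float


@dataclass
class FoldPlan:
    """Scan-level fold assignment for stratified k-fold cross-validation."""

    k: int
    assignment: dict[str, int]
    stratified: bool = True


def _rows_for(kind: str, angle: float, table: pd.DataFrame) -> pd.DataFrame:
    if kind == "EA":
        sub = table[table["angle"] == angle]
    elif kind in ("MA", "EAC"):
        sub = table[table["angle"] <= angle]
    else:
        raise ConfigError(f"unknown model kind {kind!r}")
    if sub.empty:
        raise DataError(f"no channels available for {kind} model at angle {angle}")
    return sub


def build_model(
    kind: str,
    angle: float,
    table: pd.DataFrame,
    config: ForestConfig | dict[float, ForestConfig],
    seed: int = 0,
) -> ClassificationModel:
    """Train an EA/MA/EAC model from an observation table.

    ``table`` holds one row per (scan, channel) with meta columns
    scan_id/tx/rx/angle/label plus the data columns.  ``config`` is a single
    ForestConfig (shared by all members) or a per-angle mapping for EAC.
    """
    cols = observation_columns(table)
    sub = _rows_for(kind, angle, table)
    forests: dict[float, TrainedForest] = {}
    if kind in ("EA", "MA"):
        cfg = config if isinstance(config, ForestConfig) else config[angle]
        forests[angle] = train_forest(sub[cols].to_numpy(), sub["label"].to_numpy(), cfg, seed)
    else:  # EAC: one EA member per distinct angle in range
        for z in sorted(sub["angle"].unique()):
            member = sub[sub["angle"] == z]
            cfg = config if isinstance(config, ForestConfig) else config[z]
            forests[float(z)] = train_forest(
                member[cols].to_numpy(), member["label"].to_numpy(), cfg, seed
            )
    return ClassificationModel(kind=kind, angle_spec=float(angle), forests=forests)


def predict_channels(model: ClassificationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-channel predicted labels and malignancy scores for every member forest."""
    cols = observation_columns(table)
    parts = []
    for z, forest in model.forests.items():
        if model.kind == "EA" or model.kind == "EAC":
            sub = table[table["angle"] == z]
        else:  # MA member covers the pooled range
            sub = table[table["angle"] <= z]
        if sub.empty:
            continue
        X = sub[cols].to_numpy()
        proba = forest.malignant_proba(X)
        part = sub[list(META_COLUMNS)].copy()
        part["member_angle"] = z
        part["malignant_score"] = proba
        part["predicted"] = np.where(proba >= 0.5, "malignant", "benign")
        parts.append(part)
    if not parts:
        raise DataError("no rows matched the model's channel angles")
    return pd.concat(parts, ignore_index=True)


def antenna_grouping(
    channel_votes: dict,
    ranking: ChannelRanking,
    w: int,
    threshold: float = 0.5,
    scan_id: str = "",
) -> ScanDiagnosis:
    """Majority vote over the W channels closest to the tumour.

    ``channel_votes`` maps (tx, rx) to a predicted label.  The fused score is
    the malignant fraction among the W closest voting channels; ties at the
    threshold go to malignant (favouring sensitivity in a screening context).
    """
    ordered = [ch for ch in ranking.channels if (ch.tx, ch.rx) in channel_votes]
    if not 1 <= w <= len(ordered):
        raise DataError(f"W={w} out of range [1,{len(ordered)}]")
    votes = [channel_votes[(ch.tx, ch.rx)] for ch in ordered[:w]]
    score = sum(v == "malignant" for v in votes) / w
    label = "malignant" if score >= threshold else "benign"
    return ScanDiagnosis(
        scan_id=scan_id, channel_votes=dict(channel_votes), w_used=w,
        fused_label=label, fused_score=score,
    )


def fuse_channel_predictions(
    kind: str,
    channel_preds: pd.DataFrame,
    rankings: dict[str, ChannelRanking],
    w: int | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Fuse per-channel predictions into one diagnosis per scan.

    EA/MA: antenna grouping over the model's channels.  EAC: each EA member
    groups over its own channels first, then member decisions are fused by
    unweighted majority (ties to malignant); the fused score is the mean of
    the member scores so it stays usable for ROC sweeps.
    """
    records = []
    for scan_id, scan_rows in channel_preds.groupby("scan_id", sort=True):
        ranking = rankings[scan_id]
        member_diags = []
        for _, member_rows in scan_rows.groupby("member_angle"):
            votes = {
                (int(r.tx), int(r.rx)): r.predicted for r in member_rows.itertuples()
            }
            w_eff = len(votes) if w is None else min(w, len(votes))
            member_diags.append(
                antenna_grouping(votes, ranking, w_eff, threshold, scan_id=scan_id)
            )
        if kind == "EAC" and len(member_diags) > 1:
            n_mal = sum(d.fused_label == "malignant" for d in member_diags)
            label = "malignant" if n_mal >= len(member_diags) / 2 else "benign"
            score = float(np.mean([d.fused_score for d in member_diags]))
            w_used = max(d.w_used for d in member_diags)
        else:
            d = member_diags[0]
            label, score, w_used = d.fused_label, d.fused_score, d.w_used
        true_label = scan_rows["label"].iloc[0]
        records.append({
            "scan_id": scan_id, "true_label": true_label,
            "fused_score": score, "fused_label": label, "w_used": w_used,
        })
    return pd.DataFrame.from_records(records)


def diagnose_scans(
    model: ClassificationModel,
    table: pd.DataFrame,
    rankings: dict[str, ChannelRanking],
    w: int | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Predict every channel row, then fuse to one diagnosis per scan."""
    return fuse_channel_predictions(
        model.kind, predict_channels(model, table), rankings, w=w, threshold=threshold
    )


def make_fold_plan(scan_ids, labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified scan-level fold assignment; per-fold class counts within 1 of parity."""
    scan_ids = list(scan_ids)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise DataError(f"every class needs at least k={k} scans")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(scan_ids)), labels)):
        for i in test_idx:
            assignment[scan_ids[i]] = fold
    return FoldPlan(k=k, assignment=assignment, stratified=True)


@dataclass
class CVResult:
    """Nested-CV outcome: per-scan test predictions, per-fold AUCs, chosen configs."""

    predictions: pd.DataFrame
    fold_aucs: list[float]
    mean_auc: float
    fold_configs: list[ForestConfig]
    fold_plan: FoldPlan
    channel_predictions: pd.DataFrame | None = None


def nested_cv(
    table: pd.DataFrame,
    rankings: dict[str, ChannelRanking],
    kind: str,
    angle: float,
    k: int = 5,
    seed: int = 0,
    search_space: dict | None = None,
    budget: int = 10,
    w: int | None = None,
    threshold: float = 0.5,
    config: ForestConfig | None = None,
) -> CVResult:
    """Scan-level stratified nested cross-validation.

    Outer folds partition *scans*; inside each training fold the forest
    hyperparameters are tuned on OOB error only (the forest's built-in inner
    criterion), the model is retrained and evaluated on the held-out scans.
    Passing an explicit ``config`` skips the inner search.  The leakage ban —
    no scan contributes rows to both sides of a fold — is asserted on every
    run.
    """
    from .evaluate import roc_curve  # local import to avoid a cycle

    scans = table[["scan_id", "label"]].drop_duplicates().reset_index(drop=True)
    plan = make_fold_plan(scans["scan_id"], scans["label"], k=k, seed=seed)
    fold_of = table["scan_id"].map(plan.assignment)

    parts, chan_parts, aucs, configs = [], [], [], []
    for fold in range(k):
        train_tab = table[fold_of != fold]
        test_tab = table[fold_of == fold]
        overlap = set(train_tab["scan_id"]) & set(test_tab["scan_id"])
        if overlap:  # leakage ban, asserted programmatically on every run
            raise DataError(f"scan(s) {sorted(overlap)[:3]} appear in both train and test")
        model_rows = _rows_for(kind, angle, train_tab)
        cols = observation_columns(table)
        if config is None:
            cfg = optimise_hyperparameters(
                model_rows[cols].to_numpy(), model_rows["label"].to_numpy(),
                search_space=search_space, budget=budget, seed=seed + fold,
            )
        else:
            cfg = config
        model = build_model(kind, angle, train_tab, cfg, seed=seed + fold)
        chan_preds = predict_channels(model, test_tab)
        preds = fuse_channel_predictions(kind, chan_preds, rankings, w=w, threshold=threshold)
        preds.insert(1, "fold", fold)
        chan_preds.insert(0, "fold", fold)
        parts.append(preds)
        chan_parts.append(chan_preds)
        aucs.append(roc_curve(preds["fused_score"], preds["true_label"]).auc)
        configs.append(cfg)
    predictions = pd.concat(parts, ignore_index=True)
    return CVResult(
        predictions=predictions, fold_aucs=aucs, mean_auc=float(np.mean(aucs)),
        fold_configs=configs, fold_plan=plan,
        channel_predictions=pd.concat(chan_parts, ignore_index=True),
    )


def model_family(kind: str, array: RingArray) -> list[float]:
    """Angle specs of a model family: 7 EA angles, or 6 MA/EAC upper bounds."""
    angles = distinct_angles(array)
    if kind == "EA":
        return angles
    if kind in ("MA", "EAC"):
        return angles[1:]  # [0, i*Z] for i = 1..n/2
    raise ConfigError(f"unknown model kind {kind!r}")
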