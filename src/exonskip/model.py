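"""Model building for exon-skipping efficacy: sequence-disjoint data splits,
exhaustive feature-subset search with grid-searched support-vector
regression, model selection by mean validation R-squared, permutation feature
importance, and persistence.

The protocol, per chemistry:

1. Split the filtered records 90/10 into training and test sets, by ASO
   sequence group (no sequence on both sides) and stratified so the two sides
   have similar efficacy distributions.
2. For every feature subset of at most ``max_features`` features that
   contains the experimental ASO concentration, repeat a sequence-disjoint
   80/20 build/validation split ``n_repeats`` times (default 100); on each
   repeat grid-search the SVR hyperparameters C, gamma and epsilon on the
   build portion and score on the validation portion.
3. Select the subset with the highest mean validation R-squared, refit it on
   the full training set, and evaluate on the held-out test set.
4. Estimate feature importance as the mean decrease in test R-squared when
   one feature column is randomly permuted (100 fresh shuffles).

R-squared throughout is the coefficient of determination of the
least-squares linear regression of predicted on experimental efficacy, i.e.
the squared Pearson correlation. Features are standardized (z-scored) using
constants fitted on the build/training portion of each split only.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .features import CONCENTRATION_FEATURE, Standardizer

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TrainingData:
    """Feature matrix, efficacy target and sequence-group labels, row-aligned."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "TrainingData":
        return TrainingData(
            self.X.iloc[idx].reset_index(drop=True), self.y[idx], self.groups[idx]
        )

    @property
    def unique_groups(self) -> np.ndarray:
        return pd.unique(self.groups)


@dataclass(frozen=True)
class ModelSpec:
    """Selected feature subset and RBF-SVR hyperparameters."""

    feature_names: tuple[str, ...]
    C: float
    gamma: float
    epsilon: float
    chemistry: str | None = None
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if CONCENTRATION_FEATURE not in self.feature_names:
            raise ValueError(f"{CONCENTRATION_FEATURE!r} must be part of every model")
        if not (self.C > 0 and self.gamma > 0 and self.epsilon > 0):
            raise ValueError("C, gamma and epsilon must be positive")


@dataclass
class TrainedEfficacyModel:
    """A fitted efficacy regressor plus everything needed to reproduce it."""

    spec: ModelSpec
    scaler: Standardizer
    regressor: SVR
    metadata: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.spec.feature_names if n not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        Xs = self.scaler.transform(X[list(self.spec.feature_names)])
        return self.regressor.predict(Xs.to_numpy(dtype=float))


@dataclass
class SubsetSearchResult:
    """Per-subset validation performance of the exhaustive search."""

    table: pd.DataFrame  # columns: subset, n_features, mean_r2, sd_r2, n_valid
    best_subset: tuple[str, ...]
    n_repeats: int

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["subset"] = out["subset"].map(lambda s: "|".join(s))
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# R-squared
# ---------------------------------------------------------------------------

def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and measurements
    (the R-squared of regressing one on the other). NaN when either side is
    constant."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 2 or np.ptp(y_true) == 0.0 or np.ptp(y_pred) == 0.0:
        return float("nan")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Splits (always at the sequence-group level)
# ---------------------------------------------------------------------------

def _allocate_by_bin(bin_sizes: Sequence[int], total: int) -> list[int]:
    """Largest-remainder allocation of ``total`` picks across bins."""
    sizes = np.asarray(bin_sizes, dtype=float)
    quota = sizes / sizes.sum() * total
    take = np.floor(quota).astype(int)
    remainder = quota - take
    for i in np.argsort(-remainder)[: total - take.sum()]:
        take[i] += 1
    return [int(min(t, s)) for t, s in zip(take, bin_sizes)]


def split_train_test(
    data: TrainingData,
    test_frac: float = 0.10,
    seed: int | None = None,
    n_bins: int = 5,
) -> tuple[TrainingData, TrainingData]:
    """Group-level train/test split, stratified on efficacy.

    Groups (normalised ASO sequences) are binned by their mean efficacy into
    ``n_bins`` quantile bins and the test fraction is drawn from every bin,
    so training and test sets reproduce a similar efficacy distribution while
    sharing no sequence. The bin count is reduced (with a warning) when there
    are too few groups to populate the requested bins.
    """
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({"group": data.groups, "y": data.y})
    group_means = frame.groupby("group", sort=True)["y"].mean()
    n_groups = len(group_means)
    if n_groups < 10:
        raise ValueError(f"need at least 10 sequence groups to split, got {n_groups}")
    n_bins_eff = max(1, min(n_bins, n_groups // 2))
    if n_bins_eff < n_bins:
        logger.warning("too few groups for %d strata; using %d", n_bins, n_bins_eff)
    bins = pd.qcut(group_means.rank(method="first"), q=n_bins_eff, labels=False)
    total_test = max(1, round(test_frac * n_groups))
    test_groups: list[str] = []
    bin_ids = sorted(bins.unique())
    sizes = [int((bins == b).sum()) for b in bin_ids]
    for b, n_take in zip(bin_ids, _allocate_by_bin(sizes, total_test)):
        members = group_means.index[bins == b].to_numpy()
        if n_take > 0:
            test_groups.extend(rng.choice(members, size=n_take, replace=False))
    test_set = set(test_groups)
    is_test = np.array([g in test_set for g in data.groups])
    return data.take(np.flatnonzero(~is_test)), data.take(np.flatnonzero(is_test))


def validation_splits(
    data: TrainingData,
    n_repeats: int = 100,
    build_frac: float = 0.80,
    seed: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated sequence-disjoint build/validation splits of the training set.

    Each repeat independently shuffles the sequence groups and assigns
    ``1 - build_frac`` of them to validation; row indices for both sides are
    returned for every repeat.
    """
    groups = np.sort(data.unique_groups.astype(str))
    if len(groups) < 5:
        raise ValueError(f"need at least 5 sequence groups, got {len(groups)}")
    rng = np.random.default_rng(seed)
    n_val = max(1, round((1.0 - build_frac) * len(groups)))
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(groups)
        val_set = set(perm[:n_val])
        is_val = np.array([g in val_set for g in data.groups])
        splits.append((np.flatnonzero(~is_val), np.flatnonzero(is_val)))
    return splits


def assert_sequence_disjoint(groups_a: Iterable[str], groups_b: Iterable[str]) -> None:
    overlap = set(groups_a) & set(groups_b)
    if overlap:
        raise AssertionError(f"sequence leakage across split: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# Grid search and subset search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperGrid:
    """Log-spaced search grid for the RBF-SVR hyperparameters."""

    C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    epsilon: tuple[float, ...] = (0.01, 0.1, 1.0)

    def points(self) -> list[tuple[float, float, float]]:
        """Grid points in ascending (C, gamma, epsilon) order, which is also
        the tie-breaking order."""
        return list(itertools.product(sorted(self.C), sorted(self.gamma), sorted(self.epsilon)))


DEFAULT_GRID = HyperGrid()

#: Reduced grid used by the scaled-down protocol experiments; spans the same
#: decades as the default with a coarser step so repeated searches stay cheap.
SMALL_GRID = HyperGrid(C=(1.0, 10.0, 100.0), gamma=(0.01, 0.1, 1.0), epsilon=(0.1, 1.0))


def grid_search_fit(
    X_build: pd.DataFrame,
    y_build: np.ndarray,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    grid: HyperGrid = DEFAULT_GRID,
) -> tuple[tuple[float, float, float] | None, float]:
    """Fit an RBF SVR for every grid point and return the point with the
    highest validation R-squared (ties broken by smallest C, then gamma,
    then epsilon). Standardization constants come from the build portion.

    Returns ``(None, nan)`` when the validation target is degenerate
    (constant) or no grid point yields a defined score.
    """
    y_val = np.asarray(y_val, dtype=float)
    if len(y_val) < 2 or np.ptp(y_val) == 0.0:
        logger.warning("degenerate validation set (constant target); repeat skipped")
        return None, float("nan")
    scaler = Standardizer.fit(X_build)
    Xb = scaler.transform(X_build).to_numpy(dtype=float)
    Xv = scaler.transform(X_val).to_numpy(dtype=float)
    yb = np.asarray(y_build, dtype=float)
    best_point, best_r2 = None, -np.inf
    for point in grid.points():
        C, gamma, epsilon = point
        svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
        svr.fit(Xb, yb)
        r2 = r_squared(y_val, svr.predict(Xv))
        if np.isfinite(r2) and r2 > best_r2:
            best_point, best_r2 = point, r2
    if best_point is None:
        return None, float("nan")
    return best_point, float(best_r2)


def enumerate_feature_subsets(
    feature_names: Iterable[str],
    max_features: int = 6,
    forced: tuple[str, ...] = (CONCENTRATION_FEATURE,),
) -> list[tuple[str, ...]]:
    """All feature subsets containing ``forced`` with at most ``max_features``
    features in total, in deterministic order (by size, then lexicographic)."""
    names = list(dict.fromkeys(feature_names))
    forced = tuple(dict.fromkeys(forced))
    missing = [f for f in forced if f not in names]
    if missing:
        raise ValueError(f"forced feature(s) not in registry: {missing}")
    optional = sorted(n for n in names if n not in forced)
    if max_features < len(forced):
        raise ValueError("max_features smaller than the forced set")
    subsets: list[tuple[str, ...]] = []
    for k in range(0, max_features - len(forced) + 1):
        for combo in itertools.combinations(optional, k):
            subsets.append(forced + combo)
    return subsets


@dataclass(frozen=True)
class SearchConfig:
    """Bounds and seeds for the subset-search protocol."""

    max_features: int = 6
    n_repeats: int = 100
    build_frac: float = 0.80
    grid: HyperGrid = DEFAULT_GRID
    forced: tuple[str, ...] = (CONCENTRATION_FEATURE,)
    seed: int | None = None


def _data_hash(data: TrainingData) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(data.X, index=False).to_numpy().tobytes())
    h.update(np.asarray(data.y, dtype=float).tobytes())
    h.update("\x00".join(map(str, data.groups)).encode())
    return h.hexdigest()[:16]


def select_model(
    train: TrainingData,
    config: SearchConfig = SearchConfig(),
    chemistry: str | None = None,
) -> tuple[SubsetSearchResult, TrainedEfficacyModel]:
    """Exhaustive feature-subset search with repeated validation.

    Every subset is scored with the same set of sequence-disjoint
    build/validation splits (shared splits reduce between-subset noise); the
    subset with the highest mean validation R-squared wins, with ties broken
    by smaller subset size then lexicographic feature names. The winner is
    refitted on the full training set using the hyperparameter point most
    often selected across its validation repeats.
    """
    feature_names = list(train.X.columns)
    subsets = enumerate_feature_subsets(feature_names, config.max_features, config.forced)
    splits = validation_splits(train, config.n_repeats, config.build_frac, config.seed)
    for bidx, vidx in splits:
        assert_sequence_disjoint(train.groups[bidx], train.groups[vidx])

    rows = []
    per_subset_params: dict[tuple[str, ...], list[tuple[float, float, float]]] = {}
    for subset in subsets:
        cols = list(subset)
        r2s: list[float] = []
        params: list[tuple[float, float, float]] = []
        for bidx, vidx in splits:
            point, r2 = grid_search_fit(
                train.X.iloc[bidx][cols], train.y[bidx],
                train.X.iloc[vidx][cols], train.y[vidx],
                config.grid,
            )
            if point is not None and np.isfinite(r2):
                r2s.append(r2)
                params.append(point)
        per_subset_params[subset] = params
        rows.append(
            {
                "subset": subset,
                "n_features": len(subset),
                "mean_r2": float(np.mean(r2s)) if r2s else float("nan"),
                "sd_r2": float(np.std(r2s, ddof=1)) if len(r2s) > 1 else float("nan"),
                "n_valid": len(r2s),
            }
        )
    table = pd.DataFrame(rows)
    if not np.isfinite(table["mean_r2"]).any():
        raise RuntimeError("every candidate subset was degenerate; cannot select a model")
    best_idx = min(
        (i for i in range(len(table)) if np.isfinite(table.at[i, "mean_r2"])),
        key=lambda i: (-table.at[i, "mean_r2"], table.at[i, "n_features"], table.at[i, "subset"]),
    )
    best_subset: tuple[str, ...] = table.at[best_idx, "subset"]
    logger.info(
        "selected subset %s (mean validation R^2 %.3f over %d repeats)",
        best_subset, table.at[best_idx, "mean_r2"], table.at[best_idx, "n_valid"],
    )

    counts = Counter(per_subset_params[best_subset])
    best_point = min(counts, key=lambda p: (-counts[p], p))
    C, gamma, epsilon = best_point
    spec = ModelSpec(feature_names=best_subset, C=C, gamma=gamma, epsilon=epsilon,
                     chemistry=chemistry)
    model = fit_model(train, spec, seed=config.seed)
    return SubsetSearchResult(table=table, best_subset=best_subset,
                              n_repeats=config.n_repeats), model


def fit_model(
    train: TrainingData, spec: ModelSpec, seed: int | None = None
) -> TrainedEfficacyModel:
    """Fit the final regressor for a fully specified model on all training
    rows (standardization constants refitted on the same rows)."""
    cols = list(spec.feature_names)
    scaler = Standardizer.fit(train.X[cols])
    Xs = scaler.transform(train.X[cols]).to_numpy(dtype=float)
    svr = SVR(kernel=spec.kernel, C=spec.C, gamma=spec.gamma, epsilon=spec.epsilon)
    svr.fit(Xs, train.y)
    metadata = {
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "seed": seed,
        "n_training_rows": len(train),
        "n_training_groups": len(train.unique_groups),
        "data_hash": _data_hash(train),
        "chemistry": spec.chemistry,
    }
    return TrainedEfficacyModel(spec=spec, scaler=scaler, regressor=svr, metadata=metadata)


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """Mean and sd decrease in R-squared per permuted feature."""

    table: pd.DataFrame  # columns: feature, mean_importance, sd_importance
    baseline_r2: float
    n_repeats: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def permutation_importance(
    model: TrainedEfficacyModel,
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 100,
    seed: int | None = None,
) -> ImportanceReport:
    """Permutation feature importance on held-out data.

    For each feature, the importance is the baseline R-squared minus the
    R-squared obtained after randomly shuffling that feature's column (a
    fresh shuffle per repeat), averaged over ``n_repeats`` repeats. Features
    present in ``X`` but not used by the model have importance exactly 0.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    baseline = r_squared(y, model.predict(X))
    rows = []
    for feature in X.columns:
        if feature not in model.spec.feature_names:
            rows.append({"feature": feature, "mean_importance": 0.0, "sd_importance": 0.0})
            continue
        drops = np.empty(n_repeats)
        Xp = X.copy()
        col = X[feature].to_numpy()
        for rep in range(n_repeats):
            Xp[feature] = rng.permutation(col)
            drops[rep] = baseline - r_squared(y, model.predict(Xp))
        rows.append(
            {
                "feature": feature,
                "mean_importance": float(drops.mean()),
                "sd_importance": float(drops.std(ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    return ImportanceReport(table=pd.DataFrame(rows), baseline_r2=baseline,
                            n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

class ModelPersistenceError(RuntimeError):
    pass


def save_model(model: TrainedEfficacyModel, path: str | Path) -> None:
    """Serialise a trained model (format-versioned archive)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": {
            "feature_names": list(model.spec.feature_names),
            "C": model.spec.C,
            "gamma": model.spec.gamma,
            "epsilon": model.spec.epsilon,
            "chemistry": model.spec.chemistry,
            "kernel": model.spec.kernel,
        },
        "scaler": {
            "feature_names": model.scaler.feature_names,
            "mean": model.scaler.mean_,
            "scale": model.scaler.scale_,
        },
        "regressor": model.regressor,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, expected_data_hash: str | None = None) -> TrainedEfficacyModel:
    """Load a model saved by :func:`save_model`.

    Refuses archives with an unknown format version; a supplied
    ``expected_data_hash`` that disagrees with the stored training-data hash
    triggers a warning (the model may have been trained on different data).
    """
    try:
        payload = joblib.load(path)
        version = payload["format_version"]
    except Exception as exc:
        raise ModelPersistenceError(f"cannot read model archive {path}: {exc}") from exc
    if version != MODEL_FORMAT_VERSION:
        raise ModelPersistenceError(
            f"model format version {version} not supported (expected {MODEL_FORMAT_VERSION})"
        )
    spec = ModelSpec(
        feature_names=tuple(payload["spec"]["feature_names"]),
        C=payload["spec"]["C"],
        gamma=payload["spec"]["gamma"],
        epsilon=payload["spec"]["epsilon"],
        chemistry=payload["spec"]["chemistry"],
        kernel=payload["spec"]["kernel"],
    )
    scaler = Standardizer(
        feature_names=list(payload["scaler"]["feature_names"]),
        mean_=np.asarray(payload["scaler"]["mean"], dtype=float),
        scale_=np.asarray(payload["scaler"]["scale"], dtype=float),
    )
    metadata = payload["metadata"]
    if expected_data_hash is not None and metadata.get("data_hash") != expected_data_hash:
        warnings.warn(
            "training-data hash in model archive does not match the supplied data",
            stacklevel=2,
        )
    return TrainedEfficacyModel(spec=spec, scaler=scaler,
                                regressor=payload["regressor"], metadata=metadata)


# ---------------------------------------------------------------------------
# Assembling training data from records
# ---------------------------------------------------------------------------

def build_training_data(records, context_for, registry, resources=None) -> TrainingData:
    """Compute the feature matrix for a set of records.

    ``context_for`` maps a record to its :class:`~exonskip.features.TargetContext`.
    Records whose feature vector is incomplete (a feature failed or returned
    a non-finite value) are excluded with a log line.
    """
    from .features import compute_features  # local import to keep module load light

    rows, ys, groups = [], [], []
    n_dropped = 0
    for rec in records:
        ctx = context_for(rec)
        if rec.target_start is None or rec.target_end is None:
            logger.warning("record without target coordinates skipped: %s...", rec.aso_sequence[:12])
            n_dropped += 1
            continue
        vec = compute_features(ctx, rec.target_start, rec.target_end, rec.aso_sequence,
                               rec.concentration_uM, registry, resources)
        if not vec.complete:
            logger.warning("incomplete feature vector excluded (%s)", "; ".join(vec.errors))
            n_dropped += 1
            continue
        rows.append(vec.values)
        ys.append(rec.efficacy_pct)
        groups.append(rec.normalized_sequence)
    if n_dropped:
        logger.info("excluded %d of %d records from training", n_dropped, n_dropped + len(rows))
    return TrainingData(pd.DataFrame(rows), np.asarray(ys), np.asarray(groups, dtype=object))
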