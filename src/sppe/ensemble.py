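"""Training and weighted sub-region voting.

One base classifier is trained on every level-1/2 sub-region descriptor;
a sample is classified by the weighted majority vote of its 20 sub-region
predictions (level-1 members weigh 1/3 each, level-2 members 1/12 each, so
each level carries equal total influence of 4/3).  The whole-region
("traditional") descriptor and the 1155-long concatenated pyramid vector
("spp") are provided as baseline modes.

Evaluation is always group-bound: all rows of a sample travel together
between train and test (leave-one-sample-out or grouped k-fold).
"""

from __future__ import annotations

import io
import json
import pickle
import zipfile
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from sppe.features import FEATURE_NAMES, extract_all
from sppe.pyramid import PyramidSet, spp_concat

MODES = ("traditional", "spp", "sppe")
PROVENANCE_COLS = ["sample_id", "cultivar_id", "level", "tile_index", "label"]

#: Default per-member voting weights; 4 * w1 == 16 * w2 (equal level mass).
DEFAULT_W1 = 1.0 / 3.0
DEFAULT_W2 = 1.0 / 12.0

_TIE_EPS = 1e-9


class GroupLeakageError(AssertionError):
    """A sample's rows appeared in both the training and the test side."""


@dataclass
class VoteWeights:
    """Per-member vote weights for level-1 and level-2 sub-regions."""

    w1: float = DEFAULT_W1
    w2: float = DEFAULT_W2

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("vote weights must be positive")

    def member_weight(self, level: int) -> float:
        if level == 1:
            return self.w1
        if level == 2:
            return self.w2
        raise ValueError(f"level {level} regions do not vote")

    @property
    def total(self) -> float:
        """Total score mass distributed over classes: 4*w1 + 16*w2."""
        return 4 * self.w1 + 16 * self.w2


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the four stock base learners.

    knn: Euclidean, k=5.  tree: pruned decision tree (min leaf 2).
    rf: 100 trees, 7 candidate features per split.  svm: polynomial
    kernel, gamma=0.02, degree 3, on standardized features.
    """
    name = name.lower()
    if name in ("knn", "k-nn"):
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name in ("tree", "j48", "dt"):
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    if name in ("rf", "forest"):
        return RandomForestClassifier(
            n_estimators=100, max_features=7, random_state=seed
        )
    if name == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="poly", gamma=0.02, degree=3, random_state=seed)),
            ]
        )
    raise ValueError(f"unknown classifier {name!r}; choose knn/tree/rf/svm")


CLASSIFIER_NAMES = ("rf", "knn", "tree", "svm")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def extract_features(
    pyramids: Iterable[PyramidSet],
    labels: dict[str, str] | None = None,
    cultivars: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Extract the 55-feature descriptor of every region of every pyramid.

    Returns one row per region (21 per sample) with provenance columns.
    """
    labels = labels or {}
    cultivars = cultivars or {}
    rows = []
    for pyr in pyramids:
        lbl = labels.get(pyr.sample_id, "unknown")
        cid = cultivars.get(pyr.sample_id, "")
        for region in pyr.regions:
            fv = extract_all(region, label=lbl)
            rec = fv.as_dict()
            rec.update(
                sample_id=pyr.sample_id,
                cultivar_id=cid,
                level=region.level,
                tile_index=region.tile_index,
                label=lbl,
            )
            rows.append(rec)
    return pd.DataFrame(rows, columns=FEATURE_NAMES + PROVENANCE_COLS)


def _is_region_table(obj) -> bool:
    return isinstance(obj, pd.DataFrame)


def build_dataset(
    source,
    mode: str = "sppe",
    labels: dict[str, str] | None = None,
    cultivars: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-mode learning dataset.

    Parameters
    ----------
    source : list of PyramidSet or a region table DataFrame
        When pyramids are given, features are extracted first.
    mode : {"sppe", "spp", "traditional"}
        sppe: one row per level-1/2 sub-region (20 per sample).
        spp: one 1155-wide row per sample (all 21 regions concatenated).
        traditional: one 55-wide row per sample (level 0 only).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    table = source if _is_region_table(source) else extract_features(
        source, labels=labels, cultivars=cultivars
    )
    missing = table.groupby("sample_id").size()
    bad = missing[missing != 21]
    if len(bad):
        raise ValueError(f"samples with missing regions: {list(bad.index)}")

    if mode == "sppe":
        return table[table["level"] >= 1].reset_index(drop=True)
    if mode == "traditional":
        return table[table["level"] == 0].reset_index(drop=True)

    # spp: concatenate the 21 region vectors per sample in canonical order
    records = []
    wide_names: list[str] | None = None
    for sid, grp in table.groupby("sample_id", sort=False):
        grp = grp.sort_values(["level", "tile_index"])
        vectors = [row for row in grp[FEATURE_NAMES].to_numpy()]
        values, wide_names = spp_concat(vectors)
        rec = dict(zip(wide_names, values.tolist()))
        rec["sample_id"] = sid
        rec["label"] = grp["label"].iloc[0]
        records.append(rec)
    return pd.DataFrame(records, columns=(wide_names or []) + ["sample_id", "label"])


def feature_columns(dataset: pd.DataFrame) -> list[str]:
    """The numeric descriptor columns of a dataset (non-provenance)."""
    meta = set(PROVENANCE_COLS)
    return [c for c in dataset.columns if c not in meta]


# ---------------------------------------------------------------------------
# Kennard-Stone split
# ---------------------------------------------------------------------------

def kennard_stone_split(
    vectors: np.ndarray, n_train: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic max-min representative subset selection.

    Features are z-scored, the two mutually most distant points seed the
    training set, then points maximizing the minimum Euclidean distance to
    the chosen set are added until ``n_train`` are selected.  Ties are
    broken by the smallest index.

    Returns
    -------
    (train_indices, test_indices) as sorted integer arrays.
    """
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("vectors must be a 2-D array (one row per sample)")
    n = x.shape[0]
    if not 2 <= n_train < n:
        raise ValueError(f"need 2 <= n_train < {n}, got {n_train}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    # seed pair: maximum distance, smallest (i, j) on ties
    flat = np.round(d2, 12)
    best = flat.max()
    ii, jj = np.where(flat == best)
    pairs = sorted((a, b) for a, b in zip(ii, jj) if a < b)
    i0, j0 = pairs[0]
    chosen = [int(i0), int(j0)]
    remaining = [k for k in range(n) if k not in chosen]
    mind = np.minimum(d2[:, i0], d2[:, j0])
    while len(chosen) < n_train:
        cand = np.round([mind[k] for k in remaining], 12)
        k = remaining[int(np.argmax(cand))]  # argmax picks smallest index on tie
        chosen.append(k)
        remaining.remove(k)
        mind = np.minimum(mind, d2[:, k])
    train = np.sort(np.asarray(chosen))
    test = np.asarray([k for k in range(n) if k not in set(chosen)])
    return train, test


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class SPPeModel:
    """A base learner + voting weights + label codebook."""

    base: object
    weights: VoteWeights = field(default_factory=VoteWeights)
    mode: str = "sppe"
    classes_: list[str] | None = None
    majority_class_: str | None = None
    feature_names_: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def is_fitted(self) -> bool:
        return self.classes_ is not None


def train(model: SPPeModel, dataset: pd.DataFrame) -> SPPeModel:
    """Fit the base learner on every row of the mode's dataset."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    y = dataset["label"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training set has a single class {classes[0]!r}")
    fcols = feature_columns(dataset)
    x = dataset[fcols].to_numpy(dtype=np.float64)
    model.base.fit(x, y)
    model.classes_ = classes.tolist()
    model.majority_class_ = str(classes[np.argmax(counts)])
    model.feature_names_ = fcols
    return model


def _require_fitted(model: SPPeModel) -> None:
    if not model.is_fitted:
        raise ValueError("model is not trained; call train() first")


def vote(
    member_predictions: Sequence[str],
    member_levels: Sequence[int],
    weights: VoteWeights,
    classes: Sequence[str],
    level0_prediction: str | Callable[[], str] | None = None,
    fallback: str | None = None,
) -> tuple[str, dict[str, float]]:
    """Aggregate member predictions into a weighted majority decision.

    Score(class) = sum of member weights over members voting for it.  On a
    tie among top-scoring classes the level-0 prediction decides; failing
    that, ``fallback`` (the training majority class).
    """
    scores = {str(c): 0.0 for c in classes}
    for pred, level in zip(member_predictions, member_levels):
        scores[str(pred)] += weights.member_weight(int(level))
    top = max(scores.values())
    tied = [c for c, s in scores.items() if s >= top - _TIE_EPS]
    if len(tied) == 1:
        return tied[0], scores
    p0 = level0_prediction() if callable(level0_prediction) else level0_prediction
    if p0 is not None:
        return str(p0), scores
    if fallback is not None:
        return str(fallback), scores
    return sorted(tied)[0], scores


def _predict_rows(
    model: SPPeModel, rows: pd.DataFrame
) -> tuple[str, dict[str, float]]:
    """Classify one sample from its region rows (levels 0-2 or 1-2)."""
    voters = rows[rows["level"] >= 1]
    if len(voters) != 20:
        raise ValueError(f"expected 20 voting sub-regions, got {len(voters)}")
    x = voters[model.feature_names_].to_numpy(dtype=np.float64)
    preds = model.base.predict(x)
    level0 = rows[rows["level"] == 0]
    p0 = None
    if len(level0):
        # lazy: the whole-ROI prediction is consulted only on a vote tie
        def p0():
            return str(
                model.base.predict(
                    level0[model.feature_names_].to_numpy(dtype=np.float64)
                )[0]
            )
    return vote(
        preds,
        voters["level"].to_numpy(),
        model.weights,
        model.classes_,
        level0_prediction=p0,
        fallback=model.majority_class_,
    )


def predict_sample(
    model: SPPeModel, pyramid: PyramidSet
) -> tuple[str, dict[str, float]]:
    """Classify a sample by the weighted vote of its 20 sub-regions."""
    _require_fitted(model)
    if model.mode != "sppe":
        raise ValueError("predict_sample requires an sppe-mode model")
    table = extract_features([pyramid])
    return _predict_rows(model, table)


def predict_dataset(model: SPPeModel, dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-sample predictions for any mode's dataset.

    For sppe the dataset must be a region table (level column present); for
    the baselines each row is one sample.
    """
    _require_fitted(model)
    out = []
    if model.mode == "sppe":
        for sid, grp in dataset.groupby("sample_id", sort=False):
            pred, scores = _predict_rows(model, grp)
            rec = {
                "sample_id": sid,
                "truth": grp["label"].iloc[0],
                "prediction": pred,
            }
            rec.update({f"score_{c}": s for c, s in scores.items()})
            out.append(rec)
    else:
        x = dataset[model.feature_names_].to_numpy(dtype=np.float64)
        preds = model.base.predict(x)
        for sid, truth, pred in zip(
            dataset["sample_id"], dataset["label"], preds
        ):
            out.append(
                {"sample_id": sid, "truth": truth, "prediction": str(pred)}
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# grouped evaluation
# ---------------------------------------------------------------------------

def _check_disjoint(train_ids: set, test_ids: set) -> None:
    overlap = train_ids & test_ids
    if overlap:
        raise GroupLeakageError(
            f"samples present in both train and test: {sorted(overlap)}"
        )


def _fold_datasets(table: pd.DataFrame, mode: str, sample_ids: set):
    sub = table[table["sample_id"].isin(sample_ids)]
    if mode == "sppe":
        return build_dataset(sub, mode="sppe"), sub
    ds = build_dataset(sub, mode=mode)
    return ds, ds


def evaluate_folds(
    table: pd.DataFrame,
    folds: list[tuple[set, set]],
    mode: str = "sppe",
    classifier: str | Callable[[], object] = "tree",
    weights: VoteWeights | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/predict over explicit (train_ids, test_ids) sample folds.

    Every fold asserts train/test sample disjointness; sub-regions never
    cross the boundary because selection is by sample_id.
    """
    weights = weights or VoteWeights()
    rows = []
    for train_ids, test_ids in folds:
        _check_disjoint(set(train_ids), set(test_ids))
        # a fresh learner per fold: the factory/name constructs a new instance
        base = (
            classifier() if callable(classifier) else make_classifier(classifier, seed)
        )
        model = SPPeModel(base=base, weights=weights, mode=mode, seed=seed)
        train_ds, _ = _fold_datasets(table, mode, set(train_ids))
        _check_disjoint(set(train_ds["sample_id"]), set(test_ids))
        train(model, train_ds)
        _, test_view = _fold_datasets(table, mode, set(test_ids))
        rows.append(predict_dataset(model, test_view))
    return pd.concat(rows, ignore_index=True)


def loso_evaluate(
    table: pd.DataFrame,
    mode: str = "sppe",
    classifier: str | Callable[[], object] = "tree",
    weights: VoteWeights | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-sample-out evaluation (all regions of a sample held out together)."""
    sample_ids = list(dict.fromkeys(table["sample_id"]))
    if len(sample_ids) < 3:
        raise ValueError("LOSO needs at least 3 samples")
    folds = [
        (set(sample_ids) - {sid}, {sid})
        for sid in sample_ids
    ]
    return evaluate_folds(table, folds, mode, classifier, weights, seed)


def grouped_kfold_evaluate(
    table: pd.DataFrame,
    n_splits: int = 10,
    mode: str = "sppe",
    classifier: str | Callable[[], object] = "tree",
    weights: VoteWeights | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold CV whose folds partition samples, never sub-regions."""
    sample_ids = list(dict.fromkeys(table["sample_id"]))
    if n_splits > len(sample_ids):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    folds = []
    for chunk in np.array_split(order, n_splits):
        test_ids = {sample_ids[i] for i in chunk}
        folds.append((set(sample_ids) - test_ids, test_ids))
    return evaluate_folds(table, folds, mode, classifier, weights, seed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: SPPeModel, path: str) -> None:
    """Write a model archive: pickled learner + JSON metadata."""
    _require_fitted(model)
    meta = {
        "mode": model.mode,
        "w1": model.weights.w1,
        "w2": model.weights.w2,
        "classes": model.classes_,
        "majority_class": model.majority_class_,
        "feature_names": model.feature_names_,
        "seed": model.seed,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        buf = io.BytesIO()
        pickle.dump(model.base, buf)
        zf.writestr("base.pkl", buf.getvalue())


def load_model(path: str) -> SPPeModel:
    """Read a model archive written by :func:`save_model`."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        base = pickle.loads(zf.read("base.pkl"))
    model = SPPeModel(
        base=base,
        weights=VoteWeights(meta["w1"], meta["w2"]),
        mode=meta["mode"],
        seed=meta["seed"],
    )
    model.classes_ = meta["classes"]
    model.majority_class_ = meta["majority_class"]
    model.feature_names_ = meta["feature_names"]
    return model
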