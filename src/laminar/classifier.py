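"""Multi-rater gradient-boosted cortical layer classification.

Manual laminar annotation has no single ground truth: expert raters
disagree systematically at layer boundaries.  The approach here embraces
that: one gradient-boosted tree model (multiclass softmax objective, 100
boosting iterations, learning rate 0.1, other parameters default) is
trained per rater, and the ensemble prediction sums the per-class
probabilities of the member models and takes the argmax.  Evaluation is
always reported in the context of inter-rater variability — model-vs-rater
accuracies side by side with rater-vs-rater agreement — never as a single
"accuracy".

Feature attribution uses the tree models' native TreeSHAP path-dependent
contributions: per instance and per class, the per-feature attributions
plus the base value reconstruct the model's raw (margin) output exactly,
and global feature importance is the mean absolute attribution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

log = logging.getLogger(__name__)

#: fixed class order: six cortical layers, then white matter
LAYER_ORDER = ("I", "II", "III", "IV", "V", "VI", "WM")

#: columns never fed to the classifier (identifiers, coordinates, truth,
#: intensity-derived statistics)
NON_FEATURE_COLUMNS = ("id", "x_um", "y_um", "true_layer", "orientation_rad")
GRAY_PREFIX = "gray_"


def select_feature_columns(table: pd.DataFrame, include_gray: bool = False) -> list[str]:
    """Feature columns eligible for training (drops ids, coordinates, truth
    and — by default — grayscale statistics)."""
    cols = []
    for c in table.columns:
        if c in NON_FEATURE_COLUMNS:
            continue
        if not include_gray and c.startswith(GRAY_PREFIX):
            continue
        cols.append(c)
    return cols


def split_labeled(
    X: pd.DataFrame,
    labels: pd.Series,
    fraction: float = 0.75,
    seed: int = 17,
) -> tuple[pd.Index, pd.Index]:
    """Stratified-by-layer train/test split of the labelled neurons.

    Returns (train index, test index) over the rows of ``X`` whose label is
    present.  Falls back to an unstratified split (with a warning) when any
    class has fewer than 4 labelled neurons.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labeled = labels.reindex(X.index).dropna()
    if len(labeled) < 2:
        raise ValueError("need at least 2 labelled neurons to split")
    stratify = labeled
    counts = labeled.value_counts()
    if counts.min() < 4:
        warnings.warn(
            f"class {counts.idxmin()!r} has only {counts.min()} labelled neurons; "
            "falling back to unstratified split"
        )
        stratify = None
    n_test = len(labeled) - int(round(fraction * len(labeled)))
    if n_test < 1:
        warnings.warn("split fraction leaves no test neurons; forcing one")
    train_idx, test_idx = train_test_split(
        labeled.index,
        train_size=fraction,
        random_state=seed,
        stratify=stratify,
    )
    return pd.Index(train_idx), pd.Index(test_idx)


def _check_finite(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    bad = ~np.isfinite(arr)
    if bad.any():
        cols = [X.columns[j] for j in np.unique(np.nonzero(bad)[1])]
        raise ValueError(f"non-finite values in feature columns: {cols}")


def _ordered_classes(classes) -> list[str]:
    known = [c for c in LAYER_ORDER if c in classes]
    extra = sorted(set(classes) - set(LAYER_ORDER))
    return known + list(extra)


def train_rater_model(
    X: pd.DataFrame,
    labels: pd.Series,
    n_iterations: int = 100,
    learning_rate: float = 0.1,
    seed: int = 17,
    n_jobs: int = 1,
) -> lgb.LGBMClassifier:
    """Train one boosted-tree multiclass model on one rater's labels."""
    labeled = labels.reindex(X.index).dropna()
    if labeled.nunique() < 2:
        raise ValueError("need at least 2 classes to train a layer model")
    Xl = X.loc[labeled.index]
    _check_finite(Xl)
    model = lgb.LGBMClassifier(
        n_estimators=n_iterations,
        learning_rate=learning_rate,
        objective="multiclass",
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=n_jobs,
        verbose=-1,
    )
    model.fit(Xl, labeled.astype(str))
    return model


def _aligned_proba(model, X: pd.DataFrame, classes: Sequence[str]) -> np.ndarray:
    """Probability matrix of ``model`` aligned onto the ensemble class list."""
    proba = model.predict_proba(X)
    out = np.zeros((len(X), len(classes)))
    pos = {c: j for j, c in enumerate(classes)}
    for j, c in enumerate(model.classes_):
        out[:, pos[str(c)]] = proba[:, j]
    return out


class LayerEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Per-rater boosted-tree models combined by summing class probabilities.

    ``fit`` takes the feature table ``X`` and per-rater labels ``y`` (a
    DataFrame with one column per rater, NaN marking neurons that rater did
    not label, or a Series for a single rater).  ``predict`` sums the
    member models' softmax probabilities and takes the argmax, ties broken
    by fixed class order (I < II < ... < WM).

    Parameters mirror the published training recipe: 100 boosting
    iterations, learning rate 0.1, everything else default.
    """

    def __init__(
        self,
        n_iterations: int = 100,
        learning_rate: float = 0.1,
        random_state: int = 17,
        n_jobs: int = 1,
    ):
        self.n_iterations = n_iterations
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.n_jobs = n_jobs

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        if isinstance(y, pd.Series):
            y = y.to_frame(name=y.name or "rater_1")
        if not isinstance(X, pd.DataFrame) or not isinstance(y, pd.DataFrame):
            raise ValueError("X must be a feature DataFrame and y a per-rater label frame")
        _check_finite(X)
        self.raters_ = list(y.columns)
        self.models_ = {}
        all_classes: set[str] = set()
        for j, rater in enumerate(self.raters_):
            model = train_rater_model(
                X,
                y[rater],
                n_iterations=self.n_iterations,
                learning_rate=self.learning_rate,
                seed=self.random_state + j,
                n_jobs=self.n_jobs,
            )
            self.models_[rater] = model
            all_classes |= {str(c) for c in model.classes_}
        self.classes_ = np.array(_ordered_classes(all_classes))
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.schema_hash_ = hashlib.sha1(
            json.dumps(list(map(str, X.columns))).encode()
        ).hexdigest()
        return self

    # -- prediction --------------------------------------------------------
    def _validate_schema(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "models_"):
            raise ValueError("classifier is not fitted")
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        extra = [c for c in X.columns if c not in set(self.feature_names_in_)]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing columns {missing}, extra columns {extra}"
            )
        return X[list(self.feature_names_in_)]

    def ensemble_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Summed per-class probabilities over the member models.

        Each member's probability rows sum to 1, so each row of the summed
        score matrix sums to the number of raters.
        """
        X = self._validate_schema(X)
        return sum(_aligned_proba(m, X, self.classes_) for m in self.models_.values())

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.ensemble_scores(X) / len(self.models_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.ensemble_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]

    # -- attribution -------------------------------------------------------
    def _member_contributions(self, model, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """TreeSHAP contributions of one member, aligned on ensemble classes.

        Returns (contrib, base) with shapes (n, n_classes, n_features) and
        (n, n_classes); contrib.sum(-1) + base equals the member's raw
        margin output for its own classes and 0 for classes it never saw.
        """
        raw = model.booster_.predict(X.to_numpy(float), pred_contrib=True)
        n = len(X)
        m = len(model.classes_)
        nf = X.shape[1]
        raw = raw.reshape(n, m, nf + 1)
        contrib = np.zeros((n, len(self.classes_), nf))
        base = np.zeros((n, len(self.classes_)))
        pos = {c: j for j, c in enumerate(self.classes_)}
        for j, c in enumerate(model.classes_):
            contrib[:, pos[str(c)], :] = raw[:, j, :-1]
            base[:, pos[str(c)]] = raw[:, j, -1]
        return contrib, base


def ensemble_predict(
    ensemble: LayerEnsembleClassifier, X: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Ensemble prediction plus the summed per-class score matrix."""
    scores = ensemble.ensemble_scores(X)
    pred = pd.Series(
        ensemble.classes_[np.argmax(scores, axis=1)], index=X.index, name="predicted_layer"
    )
    return pred, pd.DataFrame(scores, index=X.index, columns=ensemble.classes_)


@dataclass
class Attribution:
    """Additive feature attributions for a set of explained neurons.

    ``contributions`` has shape (n_instances, n_classes, n_features) in
    margin (log-odds) space; ``base`` is (n_instances, n_classes); their
    sum over features plus base reconstructs the model margin.  For an
    ensemble the arrays are averaged over member models (additivity then
    holds against the mean member margin).
    """

    contributions: np.ndarray
    base: np.ndarray
    features: list[str]
    classes: list[str]
    index: pd.Index

    @property
    def global_ranking(self) -> pd.Series:
        """Features ranked by mean |attribution| over instances and classes."""
        imp = np.abs(self.contributions).mean(axis=(0, 1))
        return pd.Series(imp, index=self.features, name="mean_abs_attribution").sort_values(
            ascending=False
        )

    def top_features(self, n: int = 15) -> pd.Series:
        return self.global_ranking.head(n)

    def instance_table(self, i: int) -> pd.DataFrame:
        """Per-class attribution breakdown for one explained neuron."""
        return pd.DataFrame(
            self.contributions[i].T, index=self.features, columns=self.classes
        )


def attribute(
    model: Union[LayerEnsembleClassifier, lgb.LGBMClassifier],
    X: pd.DataFrame,
    scope: Union[str, Sequence] = "global",
) -> Attribution:
    """TreeSHAP attributions for an ensemble or a single member model.

    ``scope`` is either ``"global"`` (explain every row of ``X``) or a
    sequence of neuron ids (rows of ``X``) to explain.
    """
    if isinstance(scope, str):
        if scope != "global":
            raise ValueError(f"scope must be 'global' or an id sequence, got {scope!r}")
        Xs = X
    else:
        scope = list(scope)
        unknown = [i for i in scope if i not in X.index]
        if unknown:
            raise ValueError(f"scope references unknown neuron ids: {unknown}")
        Xs = X.loc[scope]
    if isinstance(model, LayerEnsembleClassifier):
        Xs_v = model._validate_schema(Xs)
        parts = [model._member_contributions(m, Xs_v) for m in model.models_.values()]
        contrib = np.mean([p[0] for p in parts], axis=0)
        base = np.mean([p[1] for p in parts], axis=0)
        classes = list(model.classes_)
        features = list(model.feature_names_in_)
    else:
        classes = [str(c) for c in model.classes_]
        raw = model.booster_.predict(Xs.to_numpy(float), pred_contrib=True)
        raw = raw.reshape(len(Xs), len(classes), Xs.shape[1] + 1)
        contrib, base = raw[:, :, :-1], raw[:, :, -1]
        features = list(Xs.columns)
    return Attribution(
        contributions=contrib, base=base, features=features, classes=classes, index=Xs.index
    )


def plot_global_importance(ranking: pd.Series, path, top_n: int = 15) -> None:
    """Horizontal bar chart of the top-n features by mean |attribution|."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = ranking.head(top_n)[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(top) + 1.2))
    ax.barh(np.arange(len(top)), top.to_numpy(), color="#4878a8")
    ax.set_yticks(np.arange(len(top)), top.index)
    ax.set_xlabel("mean |attribution| (margin space)")
    ax.set_title(f"Top {len(top)} features by global attribution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# agreement evaluation


def agreement_matrix(labels: Union[pd.DataFrame, dict]) -> dict:
    """Pairwise agreement between label sets sharing a neuron index.

    For each pair of raters, the fraction of co-labelled neurons given the
    identical layer.  Returns the pairwise matrix plus the mean and sample
    standard deviation over distinct pairs.
    """
    if isinstance(labels, dict):
        labels = pd.DataFrame(labels)
    names = list(labels.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 label sets")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pair_accs = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            la, lb = labels[names[a]], labels[names[b]]
            shared = la.notna() & lb.notna()
            if shared.sum() == 0:
                raise ValueError(f"label sets {names[a]!r} and {names[b]!r} share no neurons")
            acc = float((la[shared] == lb[shared]).mean())
            mat.iloc[a, b] = mat.iloc[b, a] = acc
            pair_accs.append(acc)
    pair_accs = np.array(pair_accs)
    return {
        "matrix": mat,
        "pairs": pair_accs,
        "mean": float(pair_accs.mean()),
        "sd": float(pair_accs.std(ddof=1)) if len(pair_accs) > 1 else 0.0,
    }


def model_vs_raters(predictions: pd.Series, labels: pd.DataFrame) -> dict:
    """Accuracy of model predictions against each rater's labels."""
    accs = {}
    for rater in labels.columns:
        l = labels[rater]
        shared = l.notna() & predictions.reindex(l.index).notna()
        if shared.sum() == 0:
            raise ValueError(f"no shared neurons with rater {rater!r}")
        accs[rater] = float((predictions[shared] == l[shared]).mean())
    vals = np.array(list(accs.values()))
    return {
        "per_rater": accs,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }


def extreme_size_report(
    areas: pd.Series,
    layers: pd.Series,
    top_n: int = 50,
    smallest: bool = False,
) -> pd.DataFrame:
    """Layer composition of the ``top_n`` largest (or smallest) neurons.

    Selection is by descending (ascending for ``smallest``) area with ties
    at the cutoff resolved by ascending neuron id.  Returns per-layer
    counts and proportions for layers present in the selection.
    """
    if top_n > len(areas):
        warnings.warn(f"top_n={top_n} > {len(areas)} neurons; truncating")
        top_n = len(areas)
    df = pd.DataFrame({"area": areas, "layer": layers.reindex(areas.index)})
    df["_id"] = df.index
    df = df.sort_values(["area", "_id"], ascending=[smallest, True])
    sel = df.head(top_n)
    counts = sel["layer"].value_counts()
    order = [l for l in LAYER_ORDER if l in counts.index] + [
        l for l in counts.index if l not in LAYER_ORDER
    ]
    counts = counts.reindex(order)
    return pd.DataFrame(
        {"count": counts.astype(int), "proportion": counts / top_n}
    ).rename_axis("layer")


# ---------------------------------------------------------------------------
# model persistence (text-based: boosters as strings + JSON metadata)


def save_ensemble(ensemble: LayerEnsembleClassifier, out_dir) -> None:
    """Serialise a fitted ensemble: one booster text file per rater plus a
    metadata JSON carrying the class list, schema hash and training params."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "raters": ensemble.raters_,
        "classes": list(ensemble.classes_),
        "feature_names": list(map(str, ensemble.feature_names_in_)),
        "schema_hash": ensemble.schema_hash_,
        "params": ensemble.get_params(),
        "member_classes": {
            r: [str(c) for c in m.classes_] for r, m in ensemble.models_.items()
        },
    }
    (out_dir / "ensemble.json").write_text(json.dumps(meta, indent=1))
    for rater, model in ensemble.models_.items():
        model.booster_.save_model(str(out_dir / f"model_{rater}.txt"))


class _LoadedMember:
    """Prediction-only stand-in for a fitted member model built from a saved
    booster (keeps `classes_`, `predict_proba` and `booster_`)."""

    def __init__(self, booster: lgb.Booster, classes: list[str]):
        self.booster_ = booster
        self.classes_ = np.array(classes)

    def predict_proba(self, X) -> np.ndarray:
        arr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.booster_.predict(arr)


def load_ensemble(out_dir) -> LayerEnsembleClassifier:
    """Reload a saved ensemble for prediction and attribution."""
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "ensemble.json").read_text())
    ens = LayerEnsembleClassifier(**meta["params"])
    ens.raters_ = meta["raters"]
    ens.classes_ = np.array(meta["classes"])
    ens.feature_names_in_ = np.asarray(meta["feature_names"], dtype=object)
    ens.n_features_in_ = len(meta["feature_names"])
    ens.schema_hash_ = meta["schema_hash"]
    ens.models_ = {
        r: _LoadedMember(
            lgb.Booster(model_file=str(out_dir / f"model_{r}.txt")),
            meta["member_classes"][r],
        )
        for r in ens.raters_
    }
    return ens
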