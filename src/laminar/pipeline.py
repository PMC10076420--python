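"""End-to-end orchestration: phenotype -> regions -> ensemble -> evaluation.

Convenience layer gluing the feature, region and classifier stages into the
standard experiment: characterise every neuron, partition the section into
laminar regions, train one boosted-tree model per rater on a stratified
75/25 split, and report ensemble performance in the context of inter-rater
variability.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    LayerEnsembleClassifier,
    agreement_matrix,
    model_vs_raters,
    select_feature_columns,
    split_labeled,
)
from .neighborhood import DEFAULT_K, DEFAULT_R, build_feature_table
from .regions import DEFAULT_DENSITY_K, partition_regions, partition_to_features
from .synthetic import RaterNoiseConfig, SceneConfig, generate_scene, simulate_raters

log = logging.getLogger(__name__)


def build_phenotype(
    records: pd.DataFrame,
    K: Sequence[int] = DEFAULT_K,
    R: int = DEFAULT_R,
    k_density: int = DEFAULT_DENSITY_K,
    include_gray: bool = False,
):
    """Neighbourhood features plus region-derived features for a neuron table.

    Returns ``(X, partition)``: the classifier-ready feature table (indexed
    by neuron id) and the raw region partition.  ``k_density`` must be a
    member of ``K``.
    """
    if k_density not in set(K):
        raise ValueError(f"k_density={k_density} must be one of K={list(K)}")
    features = build_feature_table(records, K=K, R=R, include_gray=include_gray)
    partition = partition_regions(records, features, k_density=k_density)
    X = pd.concat([features, partition_to_features(partition)], axis=1)
    return X, partition


def run_synthetic_study(
    seed: int = 17,
    scene: Optional[SceneConfig] = None,
    noise: Optional[RaterNoiseConfig] = None,
    K: Sequence[int] = (50, 100, 250),
    R: int = DEFAULT_R,
    k_density: int = DEFAULT_DENSITY_K,
    fraction: float = 0.75,
    n_iterations: int = 100,
    learning_rate: float = 0.1,
    n_raters: int = 3,
) -> dict:
    """One full simulate/train/evaluate experiment at the given seed.

    The scene is generated with the study seed, three raters annotate it
    through jittered boundaries, per-rater models are trained on the 75%
    stratified training split, and all metrics are measured on the held-out
    25%.  Returns a dict with the data, the fitted ensemble, and the
    evaluation: ensemble and per-model accuracy versus generative truth,
    model-vs-rater accuracies and rater-vs-rater agreement.
    """
    scene = scene or SceneConfig()
    noise = noise or RaterNoiseConfig()
    records, geometry = generate_scene(scene, seed=seed)
    labels = simulate_raters(records, geometry, noise=noise, n_raters=n_raters, seed=seed + 1)
    truth = pd.Series(
        records["true_layer"].to_numpy(), index=labels.index, name="true_layer"
    )
    X, partition = build_phenotype(records, K=K, R=R, k_density=k_density)
    feat_cols = select_feature_columns(X)
    Xf = X[feat_cols].fillna(X[feat_cols].median(numeric_only=True))
    train_idx, test_idx = split_labeled(Xf, truth, fraction=fraction, seed=seed + 2)
    ensemble = LayerEnsembleClassifier(
        n_iterations=n_iterations, learning_rate=learning_rate, random_state=seed + 3
    )
    ensemble.fit(Xf.loc[train_idx], labels.loc[train_idx])
    pred = pd.Series(ensemble.predict(Xf.loc[test_idx]), index=test_idx, name="predicted_layer")
    single_accs = {}
    for rater, model in ensemble.models_.items():
        p = model.predict(Xf.loc[test_idx])
        single_accs[rater] = float((np.asarray(p, dtype=object) == truth.loc[test_idx].to_numpy()).mean())
    ensemble_acc = float((pred == truth.loc[test_idx]).mean())
    agreement = agreement_matrix(labels)
    vs_raters = model_vs_raters(pred, labels.loc[test_idx])
    return {
        "records": records,
        "geometry": geometry,
        "labels": labels,
        "truth": truth,
        "X": Xf,
        "partition": partition,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "ensemble": ensemble,
        "pred": pred,
        "ensemble_accuracy": ensemble_acc,
        "single_model_accuracies": single_accs,
        "mean_single_accuracy": float(np.mean(list(single_accs.values()))),
        "rater_agreement": agreement,
        "model_vs_raters": vs_raters,
    }
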