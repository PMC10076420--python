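# laminar

Neuron-centric analysis of human cortical cytoarchitecture: per-neuron
phenotyping, laminar region features, and supervised cortical-layer
classification with a multi-rater boosted-tree ensemble.

## The problem

The isocortex is organised into six layers plus white matter, distinguished
by the density, size and shape of their neurons.  Classical quantitative
histology samples pixel profiles drawn perpendicular to the cortical
surface; `laminar` instead treats each segmented neuron as the unit of
analysis.  Given an instance segmentation of a NeuN-stained section (or an
ImageJ-style particle table), it builds an interpretable feature vector per
neuron and learns to map that phenotype to a layer — so a whole-section
laminar parcellation is just the set of per-neuron predictions, and every
prediction can be explained feature by feature.

The package is for quantitative neuroanatomists and image-analysis people
who have neuron segmentations and (possibly disagreeing) manual layer
annotations, and want reproducible, explainable laminar maps.

## What is computed

**Morphometry** (per neuron, µm units): area, perimeter, circularity
4πA/P², roundness 4A/(π·major²), Feret diameter, optional gray-value
statistics (excluded from classification).

**k-neighbourhood features** for k ∈ {50, 100, 250, 500, 1000}: distance
statistics; neighbour-aggregated morphometry; convex-hull area/perimeter
and within-neighbourhood nearest-neighbour statistics; the nearest-neighbour
index

$$\mathrm{NNI}_i \;=\; \frac{\tfrac1n\sum_j d^{\mathrm{nn}}_j}{0.5\sqrt{\mathrm{HullArea}(i)/n}},$$

≈ 1 for complete spatial randomness, > 1 dispersed, < 1 clustered; and
angular-slice diversity over R = 8 sectors,

$$\mathrm{Shannon} = -\sum_{r=1}^{R} p_r \ln p_r \in [0, \ln R], \qquad
\mathrm{Simpson} = \sum_{r=1}^{R} p_r^2 \in [1/R,\, 1].$$

**Region features**: sparse/average/dense density classes by multi-level
intraclass-variance (Otsu) thresholding of a local-density proxy; the
sparse class split into layer I vs white matter by neighbourhood hull area;
per-neuron distances to the recovered regions; cortical depth, thickness
and relative depth — all without drawing a single cortical profile.

**Classification**: one gradient-boosted tree model per annotator
(multiclass softmax, 100 iterations, learning rate 0.1), combined by
summing class probabilities.  Evaluation reports rater-vs-rater agreement
next to model-vs-rater accuracy; attribution uses exact TreeSHAP
contributions (additive per instance and class).

**Synthetic cortex**: a laminar scene generator (Poisson bands with
layer-specific densities and soma-size distributions, rendered masks, and
simulated raters that jitter band boundaries with smooth correlated noise)
makes the entire pipeline testable end to end with no data downloads.

## Worked example

```python
from laminar import SceneConfig, run_synthetic_study, attribute

study = run_synthetic_study(seed=101, scene=SceneConfig(section_width_um=700),
                            K=(50, 100, 250))

agree = study["rater_agreement"]
print(f"rater agreement:        {agree['mean']:.3f} +/- {agree['sd']:.3f}")
vs = study["model_vs_raters"]
print(f"model vs raters:        {vs['mean']:.3f} +/- {vs['sd']:.3f}")
print(f"ensemble vs truth:      {study['ensemble_accuracy']:.3f}")
print(f"mean single model:      {study['mean_single_accuracy']:.3f}")

ranking = attribute(study["ensemble"],
                    study["X"].loc[study["test_idx"]].iloc[:500]).global_ranking
print("top 5 features:")
for name, value in ranking.head(5).items():
    print(f"  {name:24s} {value:.3f}")
```

prints

```
rater agreement:        0.756 +/- 0.044
model vs raters:        0.873 +/- 0.040
ensemble vs truth:      0.884
mean single model:      0.820
top 5 features:
  dist_to_wm               1.402
  relative_depth           0.586
  dist_to_dense            0.477
  cortical_depth           0.319
  250_hull_area            0.173
```

Read this as: the three simulated annotators agree with each other on 75.6 %
of neurons (their boundary placements differ), while the trained ensemble
agrees with each annotator on 87.3 % — the model sits *inside* the
disagreement envelope rather than copying any one rater — and matches the
generative ground-truth layer for 88.4 % of held-out neurons, better than
the average of its three member models.  The attribution ranking shows the
ensemble leans on depth-family features (distance to white matter, relative
cortical depth), with neighbourhood geometry next; single-neuron body
measurements contribute little on their own.

There is also a CLI over the same library for shell pipelines:

```bash
laminar simulate --out-dir run/            # scene + simulated raters
laminar features --neurons run/neurons.csv --out run/features.csv
laminar regions  --neurons run/neurons.csv --features run/features.csv --out run/regions.csv
laminar train    --neurons run/neurons.csv --labels run/raters.csv --out-dir run/model
laminar predict  --model run/model --features run/model/features.csv --out run/pred.csv
laminar explain  --model run/model --features run/model/features.csv --out run/shap.csv
laminar report   --predictions run/pred.csv --labels run/raters.csv \
                 --neurons run/neurons.csv --out run/report.json
laminar measure  --labels section_labels.tif --out neurons.csv   # real masks
```

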