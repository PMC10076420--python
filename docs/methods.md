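# Methods

`laminar` analyses the cytoarchitecture of NeuN-stained cortical sections at
the level of individual neurons rather than pixels.  Every segmented neuron
is described by an engineered phenotype — body morphometry, statistics of
its k nearest neighbours, and features derived from laminar regions — and a
supervised model maps that phenotype to one of the six isocortical layers or
white matter.  Because expert annotations of layer boundaries disagree
systematically, one model is trained per annotator and the models are
combined into an ensemble; evaluation is always reported against the
backdrop of inter-rater variability.

## Morphometry

Input is an instance-segmentation label raster (0 = background, k = neuron
k) with a spatial calibration in µm/pixel (default 0.226, a 40x slide-scan
resolution).  Measurements reproduce the classical particle-analysis
quantities:

* **area** — pixel count × resolution²;
* **perimeter** — weighted boundary-step estimator on the 8-connected outer
  boundary chain (straight step 1, diagonal √2).  Holes are ignored.
* **circularity** — 4πA/P², clipped to ≤ 1 (the chain estimator slightly
  overestimates smooth perimeters, ~2–3 % for a disc of radius 20 px);
* **roundness** — 4A/(π·major²) with the moment-derived best-fit-ellipse
  major axis (the 4σ convention of `skimage.regionprops`).  For a 10×40 px
  rectangle this gives ≈ 0.24 (the fitted-ellipse axis of a rectangle is
  longer than its side, 4·40/√12 ≈ 46.2);
* **Feret diameter** — maximum pairwise distance over the convex hull of
  boundary pixel centres; for thin rectangles this sits ~3 % under the
  corner-to-corner diagonal, within the 5 % rasterisation tolerance used
  throughout;
* optional grayscale statistics (mean, median, Fisher–Pearson skewness,
  excess kurtosis) over the component's intensity pixels.  Intensity-derived
  values depend on staining and are **excluded from classification**.

Components under 4 px are flagged degenerate and excluded (shape statistics
are undefined at that scale).  Coordinates use the image convention (origin
top-left, x rightward, y downward); everything downstream is in µm.

## Neighbourhood features

Neighbourhoods are defined by neighbour count k ∈ {50, 100, 250, 500, 1000}
— not by a fixed radius — so features adapt to local density and are
invariant to image resolution.  This range corresponds roughly to the
biological scale of interlayer distances.  Per neuron and per k:

* distance statistics of the k neighbour distances (k-th, mean, max, min,
  skewness, kurtosis, and the entropy of a 10-bin equal-width histogram,
  natural log);
* neighbour aggregates: mean/median/sd of area, circularity, roundness and
  Feret diameter over the k neighbours;
* convex-hull descriptors of the neighbourhood (hull area and perimeter;
  mean and sd of each member's nearest-neighbour distance within the
  membership set).  The hull membership is the k neighbours plus the
  central neuron: for interior neurons the centre never changes the hull,
  for boundary neurons it stabilises it;
* the **nearest-neighbour index**

      NNI = mean within-set nearest-neighbour distance / (0.5 √(hull_area / k)),

  a Clark–Evans-style dispersion measure: ≈ 1 under complete spatial
  randomness, > 1 for regular dispersion, < 1 for clustering.  The
  numerator uses each member's nearest neighbour (this is what gives the
  CSR expectation of 1); the variant that averages centre-to-neighbour
  distances instead is kept as an optional `*_nni_raw` column.  Without
  edge correction the estimate is biased slightly high (the point-set hull
  under-covers the territory and boundary members lack outward
  neighbours); measured mean on 2000-point Poisson patterns is ≈ 1.10–1.14,
  inside the ±0.15 calibration band;
* **angular-slice diversity**: the neighbourhood is divided into R equal
  sectors (default R = 8, i.e. 45°; the angle origin is the image x-axis,
  counter-clockwise, ties to the lower sector) and the occupancy
  proportions p are summarised by Shannon (−Σ p ln p ∈ [0, ln R]) and
  Simpson (Σ p² ∈ [1/R, 1]) indices.  Neurons in layer interiors see
  uniform sectors (high Shannon); neurons at layer borders or in thin
  layers see uneven sectors.

k-nearest-neighbour queries are exact (kd-tree with a probe past the cutoff;
ties broken by ascending neuron index, verified against brute force).  The
batch path resolves within-set nearest neighbours from a 16-entry prefix of
each point's global neighbour list with an exact fallback, and is tested
identical to the per-neuron API.

## Region features

Laminar regions are recovered from 1-D multimodal feature distributions by
minimisation of within-class variance (multi-level Otsu).  The search is an
exhaustive scan over a 256-bin quantisation of the value range, which makes
it deterministic and directly checkable against brute force; when empty
valley bins create runs of exact co-optima the middle of the tied set is
returned.  A guard flags splits whose between-class variance fraction is
below 0.5 (the input is then not convincingly multimodal).

* **Density classes.**  The local-density proxy is 1/(mean distance to the
  100 nearest neighbours).  A 3-class split on the **log** of the proxy
  assigns sparse / average / dense.  Log-spaced binning matters: density
  spreads multiplicatively, and on a linear scale the sparse mode (a few
  percent of neurons) is absorbed while the broad dense mode gets split.
  Layers II and IV emerge dense; III, V, VI average; layer I and white
  matter sparse.
* **Sparse split.**  Sparse neurons separate into layer I versus white
  matter by a 2-class split of log hull area, by default at k = 500: a
  layer-I hull stays pinned between the tissue border and the dense layer
  II however many neighbours are taken, while a white-matter hull keeps
  growing, so the separation is strongest at large k.
* **Coherence filter.**  Before distances are measured, layer-I and WM
  region members are filtered to their largest spatially connected
  component (members linked when closer than 3× the median within-region
  nearest-neighbour distance).  A handful of density-misclassified deep
  neurons would otherwise act as false anchors and corrupt every
  distance-to-region feature.
* **Depth and thickness.**  Cortical depth = distance to the nearest
  layer-I member; thickness = depth + distance to the nearest WM member;
  relative depth = depth/thickness ∈ [0, 1].  This is a profile-free,
  per-neuron approximation of pial-to-WM position: no transverse profiles
  are drawn anywhere in the pipeline.  Both raw distances are kept so other
  conventions can be reconstructed.

## Layer classification

One gradient-boosted tree model per rater (LightGBM, multiclass softmax
objective, 100 boosting iterations, learning rate 0.1, all other parameters
default, deterministic given the seed).  Grayscale columns are excluded;
non-finite features are rejected naming the offending columns.  The
ensemble sums the member models' class-probability vectors and predicts the
argmax, ties broken by fixed class order I < II < … < WM.  Labelled data is
split 75 % / 25 % stratified by layer before training; all metrics are
measured on the held-out quarter.

Because no single ground truth exists for real annotations, evaluation
reports the pairwise rater-vs-rater agreement matrix (mean ± sd over pairs,
sample sd) side by side with model-vs-each-rater accuracies — never a
single "accuracy".  On synthetic data the generative layer is additionally
available as truth.

**Attribution** uses the tree models' native path-dependent TreeSHAP
contributions: per instance, class and member model, per-feature
attributions plus a base value reconstruct the member's raw margin output
exactly (checked to 1e-6).  Ensemble attributions are averaged over
members.  Global importance is the mean absolute attribution over
instances, classes and members.

## Synthetic laminar cortex

The generator emulates the statistical structure the pipeline assumes — it
is the test bed for every stage, not a histology simulator.

* Seven parallel horizontal bands (I–VI + WM, layer I at the top), each a
  homogeneous Poisson process.  Defaults (widths µm @ intensities
  neurons/µm²): I 250 @ 0.0004, II 250 @ 0.010, III 700 @ 0.0025,
  IV 200 @ 0.010, V 500 @ 0.0025, VI 450 @ 0.0025, WM 700 @ 0.0008.  At
  the default 1400 µm section width this yields ≈ 13 000 neurons — the
  scale of a manually labelled histology dataset.  The composition encodes
  the laminar qualitative structure: II/IV densest, I/WM sparsest, III
  holding the largest somata (log-normal areas, median 140 µm², then V at
  110 and VI at 90); layer VI gets the lowest circularity (multipolar
  somata).  An optional shared sinusoidal curvature bends all bands to
  stress depth features on non-flat geometry.
* Soma phenotypes: log-normal areas (log-sd 0.35), Beta-distributed
  circularity, aspect ratio (= roundness) Beta-rescaled to [0.35, 1];
  perimeter and Feret diameter derived consistently from area, circularity
  and aspect.  `render_mask` rasterises records as rotated ellipses with a
  per-neuron gray level plus pixel noise, so the morphometry stage can be
  tested round-trip against generative parameters.
* **Simulated raters** displace every internal band boundary by a smooth
  Gaussian random field along x (white noise on a grid, Gaussian-smoothed,
  normalised by the kernel's l2 norm so the field variance is exact rather
  than per-realisation).  Disagreement is therefore spatially coherent and
  confined to boundary strips — the empirical signature of expert
  disagreement — not i.i.d. label flips.  The layer I/II boundary receives
  0.3× the amplitude (experts find that boundary unmistakable).
  Displacements are clipped at 0.49× the adjacent band width and band
  order is enforced, so labels always respect the laminar order.
* Default noise (amplitude 85 µm sd, correlation length 150 µm) was
  calibrated once so that simulated pairwise rater agreement reproduces the
  range reported for human experts (≈ 0.75–0.81); at the default scene it
  measures 0.787 ± 0.011 over ten seeds.

### What the generator does and does not emulate

It reproduces laminar density/size contrasts, boundary-coherent annotation
noise, and Poisson spatial statistics within bands.  It does **not**
reproduce columnar microstructure, within-band density gradients,
sub-layering, staining artefacts, anisotropic soma orientation fields, or
curved pial surfaces beyond the optional sinusoid.  Passing tests therefore
demonstrate that the pipeline recovers laminar structure *of this
statistical kind*; transfer to real histology rests on the paper-trail of
the individual feature definitions, not on these simulations.

## Problem sizes and numerical choices

* The multi-seed end-to-end test trains on a 700 µm-wide section (~6 500
  neurons, k ∈ {50, 100, 250}) for ten seeds; the default-scene tests and
  the acceptance script use the full 1400 µm scene with the complete k set.
  These sizes were chosen so the whole suite stays desk-scale while keeping
  every population (including the ~950-neuron sparse class) large enough to
  measure.
* Ensemble held-out accuracy against generative truth at the reduced scale
  is ≈ 0.87–0.90 (median over ten seeds ≥ 0.85); ensembles beat the mean of
  their member models in ≥ 8/10 seeds, and the model agrees with each rater
  more than raters agree among themselves — the qualitative signature
  reported for the real annotation study.
* Degenerate geometry (collinear neighbourhoods, coincident points) is
  flagged rather than fatal: hull features become NaN for the affected
  neuron, a feature table is rejected only above 5 % NaN overall.
* All randomness flows from explicit seeds (scene, raters, splits, model
  training); reruns are bit-identical.  kd-tree tie-breaks, sector
  boundaries and argmax ties are all resolved deterministically.

## Known limitations

* Depth/thickness are Euclidean distances to recovered point sets, not
  geodesics to reconstructed surfaces; on strongly folded cortex they
  underestimate true laminar depth.
* The NNI carries the documented positive edge bias (~+0.1 at k = 100);
  comparisons should be made between neurons measured with the same k.
* The density proxy dilutes near band borders (a neuron at the edge of a
  dense band looks about half as dense), so density classes are least
  reliable within ~one neighbourhood radius of a boundary; the classifier
  compensates by combining many k-scales.
* Rater simulation preserves band topology; it cannot express an annotator
  who merges or omits a layer outright.
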