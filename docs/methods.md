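# Methods

## The problem

During laser ablation (LA) of liver tissue, the clinically relevant quantity
is the extent of irreversible thermal damage, but no intraoperative
gold-standard damage readout exists. Surface temperature can be imaged with
an IR camera, and the *peak* temperature a pixel has experienced is a good
proxy for the damage it sustained: coagulative necrosis sets in around
50 °C. This package implements a per-pixel prediction pipeline that learns
to read thermal damage directly from hyperspectral (HS) reflectance:

* **TDSM** (tissue damage segmentation model): classifies each ROI pixel
  into *no damage*, *ring* (the homogeneous coagulated zone), or *thermo*
  (the carbonized/heat-fixed core), supervised by manual annotations.
* **PTPM** (peak temperature prediction model): regresses the peak
  temperature (°C) each pixel has reached, supervised by IR-derived peak
  maps. Thresholding the predicted map at T\* = 50.6 °C yields the ablation
  margin without any human annotation.

## Supervision: peak-temperature maps

Each acquisition step contributes a short burst of IR frames. The last
k = 5 frames before the acquisition event are averaged into a
characteristic map IRᵢ ("~5 frames" in the acquisition protocol; k is
configurable, and the window is anchored at the event timestamp). Because
the HS and IR cameras view the scene through different geometries, each IRᵢ
is warped into the step-1 HS reference frame using an affine transform
fitted by least squares to 5–6 fiducial marker correspondences (markers are
matched by stored ID order; a blob-centroid detector is provided for
synthetic scenes only). The peak map at step i is the element-wise running
maximum

    Pᵢ = max(IR₁,aligned, …, IRᵢ,aligned)

computed after alignment. A pixel lacking aligned coverage at *any* prefix
step is marked invalid rather than zero-filled: a maximum over partial data
would silently under-estimate the supervision. Monotonicity of Pᵢ in i is
asserted on every pipeline run.

Interpolation is bilinear for reflectance and temperature images and
nearest-neighbour for label masks (preserving label discreteness).
Coordinates are 0-based (x = column, y = row), pixel-center.

## The networks

Both models share one small 3-D spectral CNN over an l × w × w reflectance
sub-volume centred on the pixel (l = 100 bands, w = 5 px). The small
spatial window keeps the models spectrally driven and the parameter count
low enough to train from scratch on a single procedure set:

| layer | kernel (z,x,y) | stride | out ch | params |
|-------|---------------|--------|--------|--------|
| Conv1 | (3,3,3) | (1,1,1) | 20 | 560 |
| Pool1 | (3,1,1) | (2,1,1) | 20 | 1,220 |
| Conv2 | (3,3,3) | (1,1,1) | 35 | 18,935 |
| Pool2 | (3,1,1) | (2,1,1) | 35 | 3,710 |
| Conv3 | (3,1,1) | (1,1,1) | 35 | 3,710 |
| Pool3 | (2,1,1) | (2,1,1) | 35 | 2,485 |
| FC    | 455 → 3 or 1 | | | 1,368 / 456 |

"Pooling" layers are trainable 1-D spectral convolutions with stride 2 in
z, not max pooling. Spectral padding is 1 on all six feature layers and
spatial padding is zero — the unique configuration that reproduces both the
455-long flattened feature vector (spectral trace
100→100→50→50→25→25→13, spatial 5→3→1, 35·13 = 455) and the per-layer
parameter counts above. Totals: 31,988 (TDSM) and 31,076 (PTPM), differing
by exactly the 912 parameters of the wider FC head. ReLU precedes every
pooling layer.

The engine is implemented directly in numpy (im2col gather + matmul
forward, exact bincount-fold backward); gradients are verified against
finite differences in the test suite. At these sizes a forward+backward
pass is ~1 ms on one CPU core.

### Training recipe

Plain SGD (no momentum, no weight decay — both configurable), learning rate
0.001, strict batch size 1, exactly 5 epochs over the training pixels with a
seeded per-epoch shuffle, no early stopping and no inner validation split.
Weights are He fan-in initialised from the seed; biases start at zero except
the PTPM's FC bias, which starts at the mean training target so the
relative-error loss begins in a well-scaled regime (with a zero-initialised
head the first SGD epochs are spent climbing from 0 °C to the ~70 °C target
range).

Losses:

* TDSM — softmax cross-entropy with inverse-frequency class weights
  w_c ∝ 1/freq_c normalised so Σw_c = 3 (uniform frequencies recover plain
  cross-entropy). Healthy tissue dominates the ROI, so unweighted training
  would under-serve the ring/thermo classes.
* PTPM — mean relative error |pred − actual| / actual. Targets below 1 °C
  are rejected; tissue baseline is 36 °C, so the bound never binds on real
  data and only guards against degenerate inputs.

### Validation

Strict leave-one-ablation-out cross-validation: with six procedures, six
folds, each holding out one entire procedure. Any other fold count is an
error — per-pixel splits would leak heavily correlated neighbouring pixels
between train and test.

## Specularity exclusion

Specular reflections on the wet liver surface carry no usable spectral
information. The default rule flags a pixel when its calibrated reflectance
is ≥ τ = 0.95 in at least m = 50 of the 100 bands (broadband
near-saturation). The rule is pluggable and externally supplied masks are
accepted. For this rule to work, calibrated reflectance is deliberately
*not* clipped to [0, 1].

## Evaluation conventions

* DICE 2|A∩B|/(|A|+|B|); two empty masks score 1.0 (agreement on absence),
  a non-empty reference against an empty prediction scores 0.
* Per-class accuracy is one-vs-rest binary accuracy over evaluated pixels
  (ROI minus exclusions).
* The relative-error map (pred − actual)/actual·100 is kept signed for
  diagnostics; the aggregated MRE averages its absolute value.
* Aggregation is metric-per-procedure first, then mean ± sd across
  procedures, with the sd reported only when n ≥ 3.
* Margins: ring ∪ thermo from a label map, or P ≥ T\* from a peak map.
  T\* = 50.6 °C is a configuration parameter of this package, not a derived
  quantity.
* Pearson r (with r² and a two-tailed p from the t distribution, n−2 df)
  links class-wise peak temperatures to histology severity scores; p-values
  are reported but never used for gating.

## The synthetic scene generator

Real study data is not distributable, so the generator produces complete
procedures with the statistical structure the method assumes. It is
first-class, tested code, and its defaults are the study conditions used
throughout the tests.

* **Temperature**: a radial Gaussian field (spread σ = 6 px) whose on-grid
  maximum is driven through the acquisition schedule — baseline 36 °C, then
  laser-off thresholds 60, 70, 80, 90, 100, 110 °C, then three
  post-treatment steps at 1/3/5 min decaying exponentially toward baseline
  (time constant 120 s; the acquisition protocol only fixes the time
  points, and any monotone decay serves). Each step yields 5 IR frames with
  0.2 °C frame noise to exercise frame averaging.
* **Spectra**: each pixel's reflectance is a deterministic function of the
  peak temperature reached there, plus i.i.d. band noise (σ = 0.01
  reflectance units). Healthy liver (dark visible, rising past ~590 nm)
  mixes linearly toward a brighter, flatter coagulated spectrum as the peak
  rises 36→100 °C, then darkens broadband with carbonization above 100 °C.
  The two regimes alter the spectral *shape* differently, so the noiseless
  map is injective over [36, 120] °C (verified by grid inversion to
  < 0.1 °C) and regression is well-posed. The shape of this forward model is
  an artifact choice — only smoothness and injectivity matter.
* **Scene furniture**: 5–6 bright broadband marker disks on a ring outside
  the ROI; near-saturating specular clusters inside it; a small per-step
  HS→IR affine misalignment (≤ ~2 px translation, ≤ 2° rotation, ≤ 2%
  scale) that the marker registration must undo.
* **Ground truth** stored per step: peak map, damage labels (no damage
  P < T\*; ring T\* ≤ P < T_char; thermo P ≥ T_char, with T_char = 100 °C
  configurable — the histology gives no sharp carbonization rule), the true
  affine, and the specular mask. Labels are by construction the threshold
  function of the peak map, so with zero noise and zero misalignment the
  full pipeline's dataset must reproduce ground truth pixel-for-pixel — an
  end-to-end identity the tests assert.
* **Histology scores**: per-class severity grades for the parenchymal and
  Glisson assessments drawn around fixed class means (0.13/1.05/1.98 for
  Glisson), reproducing the monotone damage–score relationship that drives
  the correlation analysis.

What the generator does **not** emulate: bioheat physics (no Pennes
equation), optical transport (no Monte Carlo), breathing deformation beyond
the rigid jitter, annotator disagreement structure, or the real spectral
complexity of liver (blood, bile, water absorption features). Passing tests
therefore demonstrate that the pipeline machinery is correct and that the
models can recover an injective spectrum→temperature relationship under
realistic noise and misalignment — not that the specific accuracy figures
would transfer to in vivo data.

## Problem sizes in the test suite

The cross-validated experiment in the acceptance tests runs six 64 × 64
procedures with a 30 px ROI. Training subsamples each (ablation, step) ROI
to 100 pixels/step for the PTPM and 200 pixels/step for the TDSM (seeded),
which the loss curves show is well past convergence at these scene sizes;
held-out evaluation always uses every usable ROI pixel. Late steps (the
110 °C step and the three post-treatment steps) are the basis for the
segmentation and margin-agreement metrics, matching when damage is fully
developed.

## Known limitations

* The spectral forward model is one smooth injective curve; real coagulation
  spectra vary between livers and with surface moisture.
* Margin metrics inherit the generator's circular-symmetry bias; real
  ablation margins are irregular.
* The NN engine is CPU-only and single-threaded by design; it is sized for
  these ~32k-parameter models, not for larger architectures.
* Peak-map supervision assumes the IR emissivity setting is correct and
  applies no radiometric correction (an acquisition-time camera setting).
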