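# Methods

This note records the models, parameter choices and limitations behind
`hfus_iqa`, in the spirit of a package methods appendix. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Label fusion and agreement

Three binary annotations per frame (Expert 1 and Expert 2 are the same
person annotating twice; Expert 3 is a second person) are fused by counting
'no ok' votes into the group label (3→1, 1→2, 2→3, 0→4) and reduced to a
binary label by majority ({2,4} → ok, {1,3} → no ok). Both fusions are
total on the 2³ vote combinations, and the binary reduction of the group
label coincides with the direct majority vote — the test suite checks this
by brute force.

Agreement is unweighted Cohen's kappa computed from a count matrix,
κ = (p_o − p_e)/(1 − p_e). Verbal bands are right-closed Landis–Koch
intervals; the top band (0.8, 1] is named "Perfect", the convention used in
the ultrasound IQA literature this package targets. Degenerate tables: a
table whose whole mass sits on one diagonal cell returns κ = 1 (complete,
if trivial, agreement); a table where each rater uses a single but
*different* category has p_e = 0 and correctly yields κ = 0; an all-zero
table is an error.

## Mamdani fuzzy voting

The FIS input is the triple of per-expert model scores (probability of
'ok'). Operators are fixed to the Mamdani convention: AND = min,
implication = min, aggregation = max, defuzzification = centroid on a
uniform grid of 1001 points (configurable upward; a 10⁵-point integration
oracle in the tests bounds the grid error below 10⁻³). If no rule fires,
the output is the neutral 0.5.

Default sets and rules (all configurable from YAML; the shipped
`data/fis_binary.yaml` / `data/fis_four_class.yaml` are editable copies):

* **Input sets.** `low` = trapezoid (0, 0, 0.2, 0.55), `high` = trapezoid
  (0.45, 0.8, 1, 1). The two sets overlap symmetrically around 0.5. An
  earlier variant meeting exactly at 0.5 (low ending and high starting at
  0.5) leaves the point 0.5 with zero membership in *both* sets, so any
  score of exactly 0.5 silences every rule and the output jumps to the
  neutral fallback — breaking monotonicity of the output in each input.
  The overlap removes the dead zone; monotonicity on a 21³ score grid is
  enforced by test.
* **Output sets.** Four triangles centred at 0.125, 0.375, 0.625, 0.875
  (width 0.25), aligned with the uniform threshold bins.
* **Rule base.** Symmetric in the three inputs and keyed on the count of
  `high` memberships: 0 → lowest output set, 1, 2, 3 → successively higher
  sets. Consequently, for crisp 0/1 scores the thresholded FIS decision
  reproduces majority voting exactly, and the 4-bin output reproduces the
  group fusion — checked over all 8 crisp triples. The binary and
  four-class systems share this structure by default but are independent
  objects, since real tuned systems differ in their rule sets.

Thresholding: the binary decision is ok iff y ≥ 0.5 (boundary assigned
upward). The four bins are y < 0.25 → group 1, [0.25, 0.5) → 3,
[0.5, 0.75] → 2, > 0.75 → 4; the half-open split at 0.5 puts the boundary
on the 'ok'-side group, consistent with the binary rule. Confidence is
2·|y − 0.5|.

## Classifier

The package ships its own NumPy layer engine (`_net.py`: im2col
convolutions, batch normalization, max/average pooling, dense layers, SGD
with momentum, softmax cross-entropy), and expresses three backbones on it:

* `vgg16` — 13 convolutions; transfer-learning default freezes the first
  10. The original fully-connected head is replaced by global average
  pooling + dense, which also makes the network input-size agnostic.
* `densenet201` — growth 32, bottleneck 4, blocks (6, 12, 48, 32) with
  1×1/3×3 convolution pairs and halving transitions: 200 convolutions in
  definition order; default freezes the first 140.
* `tiny_test` — a 16×16 block-mean reduction of the 224×224 input followed
  by two small convolution blocks and two dense layers. The reduction
  keeps the discriminative structure of the synthetic classes (entry-echo
  band presence and tilt, shadow wedges, contrast statistics) while making
  CPU training take seconds.

"Frozen convolution layer" means the convolution's weights and bias are
excluded from the optimizer; batch-norm affine parameters and running
statistics still update, as is usual in fine-tuning. Conv layers are
counted in definition order so freeze counts are reproducible.

Pretrained ImageNet weights are not bundled; the large backbones start from
He-initialised weights unless a checkpoint (`.npz`, the engine's native
format) is loaded. Their role here is to express the transfer-learning
configurations faithfully and verifiably (layer counts, freeze masks,
training loop); training them to clinical-scale accuracy is out of scope at
desk scale.

Training defaults follow the shared regime: SGD momentum 0.9, categorical
cross-entropy, batch size 64, initial learning rate 10⁻⁴, 50 epochs. The
configured rate is *initial*: a step decay (×0.3 at 1/3 and 2/3 of the
epochs) is applied, which stabilises the from-scratch `tiny_test` runs
against occasional momentum-driven oscillation late in training.
`desk_scale_config()` is the documented CPU-scale setting: `tiny_test`,
initial rate 0.05, 15 epochs — a from-scratch network needs a larger step
than a fine-tuned pretrained one. Inputs are scaled to [0,1]; the
transfer-learning backbones additionally standardise with ImageNet channel
statistics. Class order is fixed as (no_ok, ok) and (1, 2, 3, 4). All
randomness flows from the config seed; per-expert models get
`seed + expert_index`.

## Processing paths

Paths 1–4 are binary, 5–8 four-group. Path-specific choices:

* Path 1/6 train only on *reliable* frames (groups 1 and 4, unanimous
  labels) and classify everything; an empty reliable set is an error.
* Path 6's "uniformly thresholded" score-to-group rule reuses the FIS
  output bins (identical thresholds) — an assumption, documented here.
* Multi-model paths (3/4/7/8) train their three models on the same
  train/validation split so the vote compares like with like; whether the
  original experiments shared splits is not stated, shared is assumed.
* Path 5 warns (not errors) when a group is missing from a training fold
  and proceeds on the remaining classes.

## Evaluation

External k-fold (default 5) cross-validation: shuffled test folds differing
in size by at most one; the non-test remainder splits 4:1 into
train/validation (rounded). Splitting is at frame level by default — the
unit used in the original experiments. An examination series contains
near-duplicate frames, so frame-level splitting can leak appearance
information across folds; users wanting stricter generalisation claims
should group frames by patient before splitting.

Metrics: accuracy from the confusion-matrix trace; precision, recall, f1
for the positive class 'ok' in binary problems and macro-averaged in
4-group problems (the averaging convention is not stated upstream; macro is
the standard choice under class imbalance). Algorithm-vs-expert agreement
uses the same kappa as the annotator analysis. The named evaluations pair
paths with reference rules: #1 = unanimous-frames subset with their shared
label; #2/#3/#5/#6 = paths 1–4 against majority-vote labels; #7–#10 =
paths 5–8 against fused group labels. (#4, the per-expert backbone
comparison, is a model-selection table, not an aggregate evaluation, and is
exposed through per-expert reference labels instead.)

## Synthetic data

The generator emulates *statistical* structure, not acoustics: a correct
frame is a bright entry-echo band (Gaussian row profile at row ≈ 34,
σ = 8) over a depth-decaying dermis profile, multiplied by gamma speckle
(shape 5); the failure classes are probe-not-adhered (faint noise, no
band), low contrast (dynamic range compressed ≥ 4× at class-typical
severity), disturbed geometry (band tilted > 20° or broken), and acoustic
shadow (dark vertical wedge). Severity scales with 1 − quality so
mid-quality, expert-discordant frames are milder versions of the same
distortions. There is no wave simulation, no probe/gain variation, no
patient anatomy: passing tests show the *pipeline* behaves correctly on
separably constructed classes, not that any backbone reaches clinical
accuracy on real HFUS data.

Annotators follow a boundary-weighted flip model: nominal label ok iff
quality ≥ 0.5; annotator i flips it with probability rᵢ·b(q),
b(q) = (1 − |2q − 1|)⁴. The quartic makes flips effectively vanish for
clearly good/bad frames while remaining high near the boundary, and gives
the closed form κᵢⱼ = (1 − 2rᵢb)(1 − 2rⱼb) for balanced boundary-quality
frames, which the parameter-recovery test verifies by simulation.
Experts 1 and 2 share a flip rate (same person) but use independent
randomness; the default rates (0.35, 0.35, 0.35) put the simulated
pairwise agreement in the Substantial band, matching the published
inter-observer analysis qualitatively.

Dataset generation draws each frame from four latent types (extreme-bad,
ambiguous-bad, ambiguous-ok, extreme-ok, with quality ranges
0.02–0.30 / 0.40–0.49 / 0.51–0.60 / 0.72–0.95). The type mix is solved by
non-negative least squares over the exact 8-pattern flip enumeration,
integrated over each type's quality distribution, so that the *expected*
fused-group proportions equal the configured targets — by default the
published 8398/1261/1324/6442 split with groups 2+3 rescaled to the 15 %
discordant share. Realized proportions then match within multinomial
sampling error (tested at 3 standard errors), and zero flip rates give
exactly zero discordance. Incorrect-class mixture is uniform (no per-class
breakdown is published). Frames are distributed over 4 sessions, 8
patients and 3 facial locations by default, and written in the session
folder / `*_DataDesc.csv` layout that `load_dataset` reads back
deterministically.

## Problem sizes and numerical choices

The end-to-end study in the tests and the acceptance script uses 600
frames, the default proportions and flip rates, `tiny_test`, 5-fold CV, 15
epochs — chosen as the smallest configuration at which the 5-fold harness,
the three-model voting paths and the group-level kappa are all exercised
meaningfully. Annotation tables accept XLSX and CSV ('ok', 'no ok',
'no_ok', '1' → ok / '0' → no_ok, case- and whitespace-insensitive); legacy
binary .xls requires conversion first. Image resizing is bilinear (the
interpolation is not specified upstream). Float32 throughout the network;
engine determinism holds for a fixed BLAS. Centroid integration uses the
trapezoid rule.

## Known limitations

* No pretrained weights: headline clinical-scale accuracies of the large
  backbones are not reproducible here and are not claimed.
* The default FIS is a declared, symmetric stand-in — the original tuned
  membership breakpoints and rule lists are not published in text form —
  and MATLAB `.fis` files are not parsed.
* Frame-level CV can be optimistic on series data (see above).
* The synthetic generator's classes are deliberately separable; it is a
  harness for the pipeline, not a benchmark of image difficulty.
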