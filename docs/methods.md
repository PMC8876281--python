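# Methods

## The scoring problem

A visit is described by a labeled noncontrast-CT volume (voxel labels 1–9 for
the nine posterior-circulation structures, 0 elsewhere) and an aligned binary
ischemic-lesion mask. Two predictors of poor outcome (modified Rankin Scale
3–6 at discharge) are computed from the same masks:

- **pc-ASPECTS** (semiquantitative): 10 − Σ weights of involved territories,
  with weights 1 for each thalamus, cerebellar hemisphere and PCA territory
  (per side) and 2 for midbrain and pons. The PCA territory is operationalized
  as the occipital-lobe labels. The medulla oblongata is annotated but carries
  weight 0, so eight of the nine structures are scored; the weights sum to 10
  by construction and the class validates this. "Involved" defaults to any
  lesion overlap (> 0 mL); a minimum-volume threshold is configurable to
  suppress single-voxel noise.
- **Quantitative integrated score**: s(x) = b + w·x on the 10-parameter
  lesion-burden vector x (below).

## The 10-parameter feature vector

For structures i = 1..9, x_i = vol(lesion ∩ structure_i) / vol(structure_i).
The tenth parameter covers lesion burden outside the structures; its
denominator is a genuine design choice and two conventions are offered:

- `region` (default): vol(lesion outside structures) / vol(brain −
  structures), so all ten features share "fraction of region lesioned"
  semantics and units;
- `lesion`: the fraction of the total lesion volume that falls outside the
  structures.

The brain region comes from the volume's brain mask when present (the phantom
provides one); otherwise the whole grid is used. A structure with zero volume
contributes a 0 feature with a warning rather than NaN, keeping downstream
fitting total. Features are ratios of voxel counts and therefore independent
of voxel spacing; volumes are count × voxel volume and are reported in mL.

## The integrated-score model

`LesionBurdenLogit` fits Pr(poor | x) = σ(b + w·x) by penalized maximum
likelihood with an L2 (ridge) penalty (λ/2)‖w‖² on the weights only, using
scikit-learn's lbfgs solver underneath. λ defaults to 10⁻⁴·n, i.e. a constant
per-observation penalty: the fit is then invariant to duplicating the dataset,
and the small ridge keeps the weights finite in the separable small-n regimes
this scale targets (cohorts of a few dozen visits). The weighted-sum family
was chosen as the simplest model consistent with evaluating the score by ROC
analysis; the reported score is the linear predictor itself (monotone in the
fitted risk, so AUC is unaffected by whether the intercept is included — it is,
for interpretability of `predict_proba`).

Out-of-fold evaluation (`cross_validated_scores`): visits are partitioned into
k subsets (default 5) whose sizes differ by at most one; each subset is scored
by the model fitted on the other k−1, so no visit's score ever used its own
outcome. Partitioning is by visit, mirroring registry practice of randomizing
over visits; note this is not patient-level separation when patients revisit —
callers holding patient identifiers can pass their own subset ids to get the
leakage-safe variant. A fold whose training part is single-class raises an
error advising a re-partition rather than silently skipping.

Score orientation: higher integrated score = higher risk; pc-ASPECTS is
negated wherever the two are compared on ROC axes.

## Evaluation statistics

- **AUC** is the Mann–Whitney statistic (probability a random poor-prognosis
  case outscores a random good one, ties counted ½), computed from midranks.
  It equals the trapezoidal area under the full ROC point list; the suite
  verifies both identities and brute-force pair counting. Tie handling matters
  here because pc-ASPECTS takes only 11 integer values.
- **Operating point**: Youden's J = sensitivity + specificity − 1 maximized
  over thresholds; ties break toward higher sensitivity, then the lower
  threshold. The rule is configurable in principle but Youden is the only
  built-in, as the standard default for ROC-derived cutoffs.
- **DeLong test**: placement values V10 (per positive) and V01 (per negative)
  are computed by the midrank identity; Var(AUC_A − AUC_B) = (S10_aa −
  2·S10_ab + S10_bb)/m + (S01_aa − 2·S01_ab + S01_bb)/n with empirical
  covariances S; z = ΔAUC/√var against a two-sided normal reference. Identical
  or rank-equivalent score vectors give ΔAUC = 0 with p = 1; zero variance
  with unequal AUCs is rejected as degenerate. Tests cross-check the p-value
  against a 10,000-replicate paired bootstrap and against R's pROC
  implementation.
- **IoU** |A∩B|/|A∪B|; defined as 1 (with a warning) when both masks are
  empty, so per-structure averages over cases remain total.
- **Group comparisons**: 2×2 Pearson χ² without continuity correction (df = 1)
  and Welch's unequal-variance t with mean ± SD reporting. The uncorrected χ²
  on the published gender-by-prognosis margin (13/5 vs 7/11) reproduces
  p ≈ 0.044, which fixes the convention.

## The synthetic phantom and cohort generator

**What it emulates.** Stacks of 512×512-class axial slices (default grid
40×256×256 at 0.5×0.5×5.0 mm — routine head-CT in-plane resolution and slice
thickness) containing nine disjoint structures with exact left/right mirror
symmetry about the midsagittal plane: a midline brainstem column (medulla →
pons → midbrain with increasing z), cerebellar hemispheres posteriorly below
the occipital lobes, and paired thalami. Geometry is specified in fractions of
the grid's physical extent, so any sufficiently large grid hosts the same
stylized anatomy; a grid too small to give every structure at least one voxel
raises a configuration error naming the structure. Voxelization uses voxel
centers at (i + 0.5)·spacing, which makes mirror pairs bit-exact reflections
(equal voxel counts on any grid).

**Lesions** are grown by seeded region growing: a random interior voxel of the
target region, then 6-connected expansion in randomized (heap-priority) order
until round(fraction × region size) voxels are reached — connected, irregular,
and matching the requested volume fraction to within one voxel. Growth is
confined to the target region, so structure labels are never modified and the
achieved fraction is monotone in the request at fixed seed. Unreachable
requests (disconnected region) raise an error reporting the achievable
maximum.

**CT rendering** assigns tissue-class mean attenuation (background −1000 HU,
parenchyma 35 HU, structures 31–38 HU in a plausible gray/white range), sets
lesion voxels hypodense at parenchyma − 20 HU, and adds Gaussian noise
(default SD 2 HU). All randomness is a `numpy` Generator seeded from the
config, so volumes are bit-reproducible.

**Cohorts.** Each visit's true burden vector is drawn from a zero-inflated
Beta model: each of the ten regions is involved with probability 0.35, and an
involved region's fraction is Beta(1.2, 3.0). Outcome is Bernoulli with
Pr(poor) = σ(β₀ + β·x), β = (1.0, 1.0, 0.8, 0.8, 1.2, 1.2, 2.0, 5.0, 3.0,
1.0) and β₀ = −1.6 — brainstem burden weighted heaviest, prevalence ≈ 0.5,
generative AUC ≈ 0.75, in the range reported for CT-based prognostication of
posterior-circulation stroke. The mRS is then drawn uniformly within the
matching range (0–2 or 3–6), so the prognosis dichotomy is consistent by
construction. With `include_masks` the lesion is actually grown on a phantom
grid and the features recomputed from voxel overlap (used at small n and in
the pipeline when mask output is wanted); the default featural route makes
n = 2000 recovery experiments instantaneous. Subset ids come from a seeded
permutation, sizes differing by at most one.

**What passing tests do and do not show.** The generator's features are
independent across regions, lesions are single connected blobs per region,
intensities are piecewise constant plus white noise, and the outcome link is
exactly the model family being fitted. Recovery and AUC-agreement results
therefore validate the *estimation machinery* (no leakage, correct likelihood,
correct CV bookkeeping), not clinical performance; real cohorts have
correlated territory involvement, model misspecification, and far smaller n.

## Desk-scale segmentation

The trainer reproduces the standard SegNet-family protocol end to end at
sizes a single CPU handles:

- **Input featurization**: the brain-windowed intensity (window 35 ± 40 HU,
  mapped to [0,1]) plus coordinate channels — normalized slice position z,
  row, col, and their sin/cos Fourier encodings at frequencies 1, 2, 4, 8 (28
  channels total). Coordinates are supplied deliberately: on a piecewise
  constant phantom, slices at different z place different structures at the
  same in-plane position with near-identical attenuation, so the per-pixel
  task is ill-posed for a purely translation-equivariant network; real CT
  supplies the disambiguating texture and context that the phantom lacks. The
  Fourier encoding lets a shallow network carve position-dependent decision
  boundaries cheaply.
- **Architecture**: a symmetric encoder–decoder (~69k parameters): two
  conv(3×3)+ReLU+maxpool(2×2) stages (widths 32 and 48), a bottleneck conv,
  and a decoder that upsamples with the stored pooling indices (SegNet-style
  unpooling) through mirrored convs to a 10-way per-pixel classifier.
  Convolutions are computed as nine shifted matrix products, which is faster
  on CPU than materializing patch matrices. Spatial sizes must be divisible
  by 4. The size sits below a ResNet-backbone system on purpose: the phantom
  task needs boundary carving, not texture abstraction, and one CPU trains it
  in minutes.
- **Optimization**: per-pixel cross-entropy (the loss family standard for this
  architecture); Adam with initial learning rate 0.001, L2 weight decay 10⁻⁴
  folded into the gradient, minibatch 4. For the first 60% of epochs the loss
  is class-weighted by median-frequency balancing (background dominates the
  pixel count ~5:1 and small structures are ~10³ pixels); the remaining epochs
  train unweighted, which sharpens boundaries that the balanced phase tends to
  overgrow.
- **Schedule and early stopping**: after every epoch the tuning loss is
  evaluated; parameters are checkpointed whenever it improves by more than
  10⁻⁴, and the learning rate is divided by 10 when it fails to do so for 8
  consecutive epochs ("plateau"). The monitor always tracks the objective
  currently optimized and resets at the weighted→unweighted switch; the
  returned model is the checkpoint with the lowest tuning loss of the final
  phase. Training stops early if the learning rate decays below 10⁻⁷.
- **Augmentation**: per sample, either a random crop to the target size, or
  random ±10% scaling (bilinear for the image, nearest-neighbor for labels,
  padded with background if scaled below the crop) followed by a random crop
  — one online draw per epoch per slice, identity when the amplitude is 0 and
  the crop equals the input.
- **Cross-validated evaluation**: cases (slice stacks) are partitioned into k
  seeded folds; each fold is predicted by a model trained on the other folds'
  slices with one held-out training case as the tuning set. IoU is computed
  per structure on the voxel union of each case's slices and averaged over the
  fold's cases (per-case pooling rather than per-slice, matching a volumetric
  reading of segmentation quality); the report is 9 structures × (k folds +
  mean). An injectable predictor bypasses training so the fold bookkeeping can
  be audited with an oracle.

## Numerical conventions and degenerate inputs

- Axis order (slice, row, col), 0-based voxel-center coordinates; NIfTI
  spacing carried in a diagonal affine.
- Empty lesion ⇒ all-zero features and pc-ASPECTS 10; lesion covering all
  scored territories ⇒ 0.
- `iou(∅, ∅) = 1` with a warning; `auc` and `delong_test` refuse single-class
  labels; `chi2_2x2` refuses zero margins; `two_sample_summary` needs n ≥ 2
  per group.
- All stochastic components consume explicit seeds (`numpy` Generators);
  the pipeline derives per-stage seeds from one root seed via `SeedSequence`
  and writes a manifest with artifact SHA-256 checksums, so a bundle is
  reproducible bit-for-bit.
- Problem sizes used by the shipped experiments: cohort studies run at
  n = 2000 (recovery) and n = 200 (demo); phantom property checks use a
  16×64×64 grid at 5×2×2 mm; the segmenter overfit check uses ten 96×96
  slices for up to 200 epochs. These sizes were chosen so every experiment has
  comfortable statistical margin while remaining quick on a laptop core.

## Known limitations

- The phantom's geometry is topological, not anatomical; no partial-volume
  effects, no CT physics (beam hardening, posterior-fossa streak artifacts),
  no DICOM.
- The segmenter's coordinate input means its phantom IoU says nothing about
  segmenting real CT; it validates the training/evaluation *protocol*
  (schedules, checkpointing, fold hygiene), which is the part the rest of the
  package consumes.
- Visit-level cross-validation treats repeat visits as exchangeable; use
  caller-supplied subsets for strict patient-level separation.
- The DeLong test relies on its asymptotic normal reference; at very small n
  (a dozen cases) the bootstrap cross-check in the test suite is the better
  guide to its behavior.
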