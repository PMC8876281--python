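# pcscale

Quantitative prognostic scoring for **posterior circulation ischemic stroke**
from noncontrast-CT structure and lesion masks.

Posterior circulation (vertebrobasilar) stroke carries high mortality and
disability, and prognosis must often be judged from noncontrast CT because MRI
is impractical in the acute setting. The established bedside tool is the
semiquantitative **pc-ASPECTS**: 10 points for the posterior circulation, minus
1 point for ischemic involvement of each thalamus, cerebellar hemisphere, and
PCA territory (left and right), and minus 2 points each for any involvement of
the midbrain or pons. It counts involved territories but ignores *how much* of
each structure is infarcted.

`pcscale` implements the quantitative alternative: given a labeled volume of
nine posterior-circulation structures (left/right cerebellum, left/right
occipital lobe, left/right thalamus, medulla oblongata, midbrain, pons) and a
binary ischemic-lesion mask, it computes

- per-structure volumes (mL) and the **10-parameter lesion-burden feature
  vector** x, where x_i = vol(lesion ∩ structure_i) / vol(structure_i) for the
  nine structures, plus the lesion proportion of brain tissue outside them;
- the automated **pc-ASPECTS** from the same masks;
- the **quantitative integrated score** s(x) = b + w·x, with weights from a
  ridge-penalized logistic regression of the dichotomized outcome (modified
  Rankin Scale at discharge: 0–2 good, 3–6 poor) on x, evaluated strictly
  out-of-fold under k-fold cross-validation over visits;
- the comparison machinery: ROC curves, Mann–Whitney AUC (ties ½), Youden
  operating points, the **DeLong test** for paired AUCs, IoU for segmentation
  quality, and simple group comparisons (Pearson χ², Welch t).

Because no clinical images ship with the package, a **synthetic phantom
module** generates stylized head volumes (nine disjoint ellipsoidal structures,
mirror-symmetric left/right, inside an ellipsoidal brain), grows connected
ischemic lesions by seeded region growing to requested volume fractions,
renders CT-like intensities, and simulates whole cohorts whose outcomes follow
a stated logistic link Pr(poor) = σ(β₀ + β·x) — so every downstream stage has
a known ground truth. A desk-scale **segmentation trainer** (a small numpy
encoder–decoder with SegNet-style pooling indices, Adam, plateau learning-rate
decay and early stopping) exercises the full train/evaluate protocol on those
phantoms.

## Worked example

The end-to-end demo simulates a 200-visit cohort, computes features and
pc-ASPECTS, fits the score out-of-fold, and compares both predictors:

```python
from pcscale import RunConfig, run_pipeline

report = run_pipeline(RunConfig(n=200, k=5, seed=1), out_dir="demo")
```

prints (via the `report` dict / `demo/report.json`):

```
AUC integrated = 0.750  (sens 0.68, spec 0.72)
AUC pc-ASPECTS = 0.681  (sens 0.65, spec 0.66)
dAUC = +0.069,  DeLong z = 2.07,  p = 0.0386
```

The integrated score separates good from poor prognoses better than the
territory-counting scale (AUC 0.750 vs 0.681), and the DeLong paired test puts
that difference at p ≈ 0.04 on this cohort. pc-ASPECTS is negated for the
comparison so both predictors are risk-oriented. The fitted weights are
interpretable as per-unit-burden log-odds:

```python
import pandas as pd
from pcscale import fit_score_model

print(fit_score_model(pd.read_csv("demo/cohort.csv")).summary())
```

```
Integrated prognostic score: ridge logistic regression
  n obs: 200    poor: 100
  penalty lam: 0.02    converged: True (21 iter)
  ------------------------------------
  feature                       weight
  f1 left_cerebellum            2.3831
  f2 right_cerebellum           2.8526
  f3 left_occipital             0.1001
  f4 right_occipital            0.7405
  f5 left_thalamus              2.4559
  f6 right_thalamus             2.2402
  f7 medulla                    3.3572
  f8 midbrain                   4.3705
  f9 pons                       2.1905
  f10 other_regions             0.0397
  intercept                    -2.0621
```

Brainstem burden (f7–f9, especially midbrain) carries the largest weights —
matching the generative model this cohort was drawn from, which the fit is
recovering.

The same stages are available from the shell:

```bash
pcscale pipeline --n 200 --seed 1 --out demo/
pcscale pcaspects --labels labels.nii.gz --lesion lesion.nii.gz
pcscale score --features cohort.csv --folds 5 --seed 1 --out scores.csv
pcscale evaluate --scores scores.csv --pcaspects pca.csv --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `pcscale.phantom` | stylized atlas, lesion growth, CT rendering, cohort simulation |
| `pcscale.volumetry` | `LabelVolume`/`LesionMask`, structure volumes, feature vector, slice stacking |
| `pcscale.scale` | `ScaleDefinition`, pc-ASPECTS, `LesionBurdenLogit` model + results, k-fold CV scores |
| `pcscale.evalstats` | IoU, AUC/ROC, operating points, DeLong test, χ², Welch t |
| `pcscale.segtrain` | numpy encoder–decoder, augmentation, training protocol, fold evaluation |
| `pcscale.pipeline` / `pcscale.cli` | end-to-end bundle with manifest; `pcscale` command |

See `docs/methods.md` for the model details, generator assumptions, and design
decisions.
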