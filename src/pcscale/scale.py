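"""Prognostic scores: automated pc-ASPECTS and the quantitative integrated score.

pc-ASPECTS (posterior circulation Acute Stroke Prognosis Early CT Score) allots
the posterior circulation 10 points and subtracts one point for ischemic
involvement of the left or right thalamus, cerebellum, or PCA territory
(operationalized as the occipital-lobe labels), and two points each for any
involvement of the midbrain or pons.  The medulla oblongata is annotated but
carries no points, so eight of the nine structures are scored.  10 means no
visible posterior-circulation ischemia; 0 means every scored territory is
involved.

The quantitative integrated score replaces territory counting with a weighted
sum of the ten lesion-proportion features.  The weights come from a
ridge-penalized logistic regression of the dichotomized outcome (modified
Rankin Scale at discharge: 0-2 good, 3-6 poor) on the features; the reported
score is the linear predictor, evaluated out-of-fold under a k-fold
cross-validation over visits.  Higher score = higher predicted risk of a poor
prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumetry import (
    FEATURE_NAMES,
    STRUCTURES,
    FeatureVector,
    LabelVolume,
    LesionMask,
)

#: default pc-ASPECTS point weights per structure (medulla scored 0)
DEFAULT_WEIGHTS: dict[str, int] = {
    "left_thalamus": 1,
    "right_thalamus": 1,
    "left_cerebellum": 1,
    "right_cerebellum": 1,
    "left_occipital": 1,   # PCA territory, left
    "right_occipital": 1,  # PCA territory, right
    "midbrain": 2,
    "pons": 2,
    "medulla": 0,
}


@dataclass(frozen=True)
class ScaleDefinition:
    """Territory point weights and the involvement threshold.

    ``threshold_ml`` is the minimum lesion volume (mL) inside a territory for
    it to count as involved; the default 0.0 means any overlap counts.
    """

    weights: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    threshold_ml: float = 0.0
    total_points: int = 10

    def __post_init__(self):
        unknown = set(self.weights) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown territories in scale definition: {sorted(unknown)}")
        if any(w < 0 or int(w) != w for w in self.weights.values()):
            raise ValueError("territory weights must be nonnegative integers")
        if sum(self.weights.values()) != self.total_points:
            raise ValueError(
                f"territory weights sum to {sum(self.weights.values())}, "
                f"expected {self.total_points}"
            )

    def scored_territories(self) -> list[str]:
        return [s for s in STRUCTURES if self.weights.get(s, 0) > 0]


def prognosis_from_mrs(mrs: int) -> str:
    """Dichotomize the modified Rankin Scale: 0-2 -> "good", 3-6 -> "poor"."""
    if int(mrs) != mrs or not 0 <= mrs <= 6:
        raise ValueError(f"mRS must be an integer in 0..6, got {mrs!r}")
    return "good" if mrs <= 2 else "poor"


def pc_aspects(
    labels: LabelVolume,
    lesion: LesionMask,
    scale: ScaleDefinition | None = None,
) -> int:
    """Automated pc-ASPECTS from a label volume and lesion mask.

    A territory is involved when the lesion volume inside it exceeds
    ``scale.threshold_ml``; the score is ``10 - sum(weights of involved
    territories)``.
    """
    scale = scale or ScaleDefinition()
    if lesion.data.shape != labels.data.shape:
        raise ValueError(
            f"lesion shape {lesion.data.shape} != label volume shape {labels.data.shape}"
        )
    vox_ml = labels.voxel_volume_mm3 / 1000.0
    overlap = np.bincount(labels.data[lesion.data].ravel(), minlength=10)
    score = scale.total_points
    for name, w in scale.weights.items():
        vol_ml = overlap[STRUCTURES.index(name) + 1] * vox_ml
        if vol_ml > scale.threshold_ml:
            score -= w
    return int(score)


def pc_aspects_from_features(
    features,
    scale: ScaleDefinition | None = None,
    structure_volumes_ml=None,
) -> int:
    """pc-ASPECTS from a lesion-fraction feature vector.

    With the default any-overlap threshold a territory is involved iff its
    lesion fraction is positive.  A nonzero ``threshold_ml`` additionally needs
    per-structure volumes (mL, in canonical order) to convert fractions to mL.
    """
    scale = scale or ScaleDefinition()
    fv = features.values if isinstance(features, FeatureVector) else np.asarray(features, float)
    if scale.threshold_ml > 0 and structure_volumes_ml is None:
        raise ValueError("threshold_ml > 0 requires per-structure volumes in mL")
    score = scale.total_points
    for name, w in scale.weights.items():
        i = STRUCTURES.index(name)
        vol = fv[i] * (structure_volumes_ml[i] if structure_volumes_ml is not None else 1.0)
        thr = scale.threshold_ml if scale.threshold_ml > 0 else 0.0
        if vol > thr:
            score -= w
    return int(score)


@dataclass
class PatientRecord:
    """One visit: features, outcome, fold assignment and derived scores."""

    visit_id: int
    features: FeatureVector
    mrs: int
    subset: int
    pc_aspects: int | None = None
    integrated_score: float | None = None
    label_volume: LabelVolume | None = None
    lesion_mask: LesionMask | None = None

    def __post_init__(self):
        if not isinstance(self.features, FeatureVector):
            self.features = FeatureVector(np.asarray(self.features, float))

    @property
    def prognosis(self) -> str:
        return prognosis_from_mrs(self.mrs)


def records_frame(records) -> pd.DataFrame:
    """Flatten records to a DataFrame with visit_id, subset, mrs, prognosis,
    pc_aspects and f1..f10 columns."""
    rows = []
    for r in records:
        row = {
            "visit_id": r.visit_id,
            "subset": r.subset,
            "mrs": r.mrs,
            "prognosis": r.prognosis,
            "pc_aspects": r.pc_aspects,
        }
        row.update(dict(zip(FEATURE_NAMES, r.features.values)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integrated-score model
# ---------------------------------------------------------------------------


class LesionBurdenLogit:
    """Ridge-penalized logistic model of poor prognosis on the 10 lesion features.

    The model is  Pr(poor | x) = sigmoid(b + w·x)  with an L2 penalty
    (lam/2)·||w||^2 added to the negative log-likelihood; the intercept is not
    penalized.  The integrated score of a visit is the linear predictor
    b + w·x.

    Parameters
    ----------
    endog : (n,) binary array, 1 = poor prognosis.
    exog : (n, 10) feature matrix.
    penalty : ridge strength lam; default ``1e-4 * n`` so the effective
        per-observation penalty is constant and the fit is invariant to
        duplicating the dataset.
    """

    def __init__(self, endog, exog, penalty: float | None = None):
        self.endog = np.asarray(endog, dtype=int).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        classes = np.unique(self.endog)
        if not np.array_equal(np.union1d(classes, [0, 1]), [0, 1]):
            raise ValueError("endog must be binary 0/1")
        if classes.size < 2:
            raise ValueError("both prognosis classes must be present to fit the score model")
        if self.endog.size < 2:
            raise ValueError("need at least 2 records")
        self.penalty = float(penalty) if penalty is not None else 1e-4 * self.endog.size
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")

    @classmethod
    def from_records(cls, records, penalty: float | None = None) -> "LesionBurdenLogit":
        X = np.vstack([r.features.values for r in records])
        y = np.array([1 if r.prognosis == "poor" else 0 for r in records])
        return cls(y, X, penalty=penalty)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, penalty: float | None = None) -> "LesionBurdenLogit":
        X = df[list(FEATURE_NAMES)].to_numpy(float)
        if "prognosis" in df.columns:
            y = (df["prognosis"].astype(str) == "poor").to_numpy(int)
        else:
            y = df["mrs"].map(lambda m: prognosis_from_mrs(m) == "poor").to_numpy(int)
        return cls(y, X, penalty=penalty)

    def fit(self, maxiter: int = 2000, tol: float = 1e-10) -> "ScoreModelResults":
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(
            C=1.0 / self.penalty,
            solver="lbfgs",
            max_iter=maxiter,
            tol=tol,
        )
        clf.fit(self.exog, self.endog)
        converged = int(clf.n_iter_[0]) < maxiter
        return ScoreModelResults(
            model=self,
            params=clf.coef_.ravel().copy(),
            intercept=float(clf.intercept_[0]),
            penalty=self.penalty,
            converged=converged,
            n_iter=int(clf.n_iter_[0]),
        )


@dataclass
class ScoreModelResults:
    """Fitted weight vector and intercept of the integrated-score model."""

    model: LesionBurdenLogit
    params: np.ndarray
    intercept: float
    penalty: float
    converged: bool
    n_iter: int

    def linear_scores(self, X) -> np.ndarray:
        """Integrated score b + w·x for each row of X."""
        X = np.atleast_2d(np.asarray(X, float))
        return self.intercept + X @ self.params

    def predict_proba(self, X) -> np.ndarray:
        """Pr(poor prognosis) for each row of X."""
        from scipy.special import expit

        return expit(self.linear_scores(X))

    def to_dict(self) -> dict:
        return {
            "weights": {name: float(w) for name, w in zip(FEATURE_NAMES, self.params)},
            "intercept": self.intercept,
            "penalty": self.penalty,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def summary(self) -> str:
        lines = [
            "Integrated prognostic score: ridge logistic regression",
            f"  n obs: {self.model.endog.size}    poor: {int(self.model.endog.sum())}",
            f"  penalty lam: {self.penalty:.6g}    converged: {self.converged} ({self.n_iter} iter)",
            "  " + "-" * 36,
            f"  {'feature':<26}{'weight':>10}",
        ]
        feature_desc = list(STRUCTURES) + ["other_regions"]
        for name, desc, w in zip(FEATURE_NAMES, feature_desc, self.params):
            lines.append(f"  {name + ' ' + desc:<26}{w:>10.4f}")
        lines.append(f"  {'intercept':<26}{self.intercept:>10.4f}")
        return "\n".join(lines)


def fit_score_model(records, penalty: float | None = None) -> ScoreModelResults:
    """Fit the integrated-score model on a list of records or a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return LesionBurdenLogit.from_dataframe(records, penalty=penalty).fit()
    return LesionBurdenLogit.from_records(records, penalty=penalty).fit()


def assign_subsets(n: int, k: int, seed=None) -> np.ndarray:
    """Seeded random partition of n visits into k subsets (ids 1..k) whose
    sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split {n} visits into {k} subsets")
    if k < 2:
        raise ValueError("need at least 2 subsets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    subsets = np.empty(n, dtype=int)
    subsets[order] = np.arange(n) % k + 1
    return subsets


def cross_validated_scores(
    records,
    k: int = 5,
    seed=None,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Out-of-fold integrated scores under k-fold cross-validation by visit.

    Each visit's score comes from the model fitted on the other k-1 subsets;
    existing subset ids on the records are respected, otherwise a seeded
    partition is drawn.  Returns a DataFrame with columns visit_id, subset,
    prognosis, score; every visit is scored exactly once.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    df = df.copy()
    if "prognosis" not in df.columns:
        df["prognosis"] = df["mrs"].map(prognosis_from_mrs)
    if "subset" not in df.columns or df["subset"].isna().any():
        df["subset"] = assign_subsets(len(df), k, seed=seed)
    folds = sorted(df["subset"].unique())
    if len(folds) != k:
        raise ValueError(f"records carry {len(folds)} subset ids but k={k}")

    X = df[list(FEATURE_NAMES)].to_numpy(float)
    y = (df["prognosis"].astype(str) == "poor").to_numpy(int)
    scores = np.full(len(df), np.nan)
    for fold in folds:
        test = (df["subset"] == fold).to_numpy()
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError(
                f"training part of fold {fold} is single-class; re-partition with a new seed"
            )
        res = LesionBurdenLogit(y[train], X[train], penalty=penalty).fit()
        scores[test] = res.linear_scores(X[test])
    assert not np.isnan(scores).any(), "every visit must be scored exactly once"
    out = df[["visit_id", "subset", "prognosis"]].copy()
    out["score"] = scores
    return out
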