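"""Gradient-boosted disease-risk model on accumulated taxonomic features.

The classifier is a least-squares gradient-boosted regression-tree ensemble
fit to 0/1 labels (control = 0, case = 1); its continuous output is read as
a risk score, evaluated by ROC/AUC over repeated stratified 70/30 splits,
and transferred to external cohorts by aligning their genus features to the
training feature list (absent genera scored as zero abundance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from taxrisk.errors import ConfigError, ValidationError
from taxrisk.group_stats import bh_adjust, mann_whitney_u
from taxrisk.taxa_io import SampleMetadata

logger = logging.getLogger(__name__)

#: documented package defaults; the boosting recipe itself is standard
DEFAULT_HYPERPARAMS = {
    "n_estimators": 500,
    "learning_rate": 0.1,
    "max_depth": 3,
    "subsample": 1.0,
}


@dataclass
class ModelBundle:
    """A trained ensemble plus everything needed to score new samples."""

    model: GradientBoostingRegressor
    feature_names: list[str]
    hyperparams: dict
    seed: int
    label_encoding: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names in model bundle")

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return self.model.predict(X)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, d / "ensemble.joblib")
        (d / "features.txt").write_text("\n".join(self.feature_names) + "\n")
        meta = {
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "label_encoding": self.label_encoding,
            "format_version": 1,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        d = Path(directory)
        model = joblib.load(d / "ensemble.joblib")
        features = (d / "features.txt").read_text().splitlines()
        meta = json.loads((d / "meta.json").read_text())
        return cls(model, features, meta["hyperparams"], meta["seed"],
                   meta.get("label_encoding", {}))


@dataclass
class CvResult:
    """Per-iteration AUC records over repeated random splits."""

    iterations: list[dict]  # seed, train_idx, test_idx, auc, roc, operating point

    @property
    def aucs(self) -> np.ndarray:
        return np.array([it["auc"] for it in self.iterations])

    def summary(self) -> dict:
        a = self.aucs
        return {
            "n_iterations": len(a),
            "mean_auc": float(a.mean()),
            "sd_auc": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
            "min_auc": float(a.min()),
            "max_auc": float(a.max()),
        }

    def best_iteration(self) -> dict:
        return max(self.iterations, key=lambda it: it["auc"])


@dataclass
class RiskScores:
    """Continuous predicted risk per sample with group annotations."""

    scores: pd.Series  # index = sample ids
    groups: pd.Series
    threshold: float = 0.5
    group_summary: pd.DataFrame | None = None
    pairwise_tests: pd.DataFrame | None = None


def select_features(profile) -> pd.DataFrame:
    """Drop features with zero variance and no nonzero abundance.

    This is the package's declared feature-selection rule: a feature must
    vary and be present in at least one sample to carry signal.
    """
    values = profile.values if hasattr(profile, "values") and isinstance(
        getattr(profile, "values"), pd.DataFrame) else profile
    if values.shape[1] == 0 or values.shape[0] == 0:
        raise ValidationError("empty profile")
    mat = values.to_numpy()
    keep = (mat.std(axis=0) > 0) & (np.abs(mat).max(axis=0) > 0)
    if not keep.any():
        raise ValidationError("no informative features retained")
    out = values.loc[:, values.columns[keep]]
    logger.info("selected %d / %d features", out.shape[1], values.shape[1])
    return out


def fit_gbm(features, labels, hyperparams: dict | None = None,
            seed: int = 0) -> ModelBundle:
    """Fit the boosted-tree regressor to 0/1 labels."""
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) \
        else [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("labels contain a single class")
    if counts.min() < 2:
        raise ValidationError("need >= 2 samples per class")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite feature values")
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    model = GradientBoostingRegressor(random_state=seed, **hp)
    model.fit(X, y)
    return ModelBundle(model, names, hp, seed, {"control": 0, "case": 1})


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC (ties get half credit) and the ROC curve points."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both classes")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def operating_point(roc: pd.DataFrame) -> dict:
    """Youden-optimal threshold: maximize sensitivity + specificity - 1.

    Ties are broken toward the highest threshold (the more specific
    operating point).
    """
    j = roc["tpr"] - roc["fpr"]
    best = int(np.flatnonzero(j.to_numpy() >= j.max() - 1e-12)[0])
    return {
        "threshold": float(roc["threshold"].iloc[best]),
        "sensitivity": float(roc["tpr"].iloc[best]),
        "specificity": float(1 - roc["fpr"].iloc[best]),
        "youden_j": float(j.iloc[best]),
    }


def _stratified_split(y: np.ndarray, train_frac: float, seed: int,
                      stratify: bool, max_redraws: int = 100):
    idx = np.arange(len(y))
    for attempt in range(max_redraws):
        train, test = train_test_split(
            idx, train_size=train_frac, random_state=seed + attempt,
            stratify=y if stratify else None,
        )
        if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
            if attempt:
                logger.info("redrew split %d time(s)", attempt)
            return train, test
    raise ValidationError("could not draw a split with both classes on each side")


def cross_validate(
    features,
    labels,
    n_iter: int = 30,
    train_frac: float = 0.7,
    base_seed: int = 0,
    hyperparams: dict | None = None,
    stratify: bool = True,
) -> CvResult:
    """Repeated random-split evaluation: 70/30 train/test, 30 iterations.

    Iteration i splits with seed ``base_seed + i`` (stratified by class),
    fits the booster on the training part and records test AUC, the ROC
    curve and the Youden operating point.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not 0 < train_frac < 1:
        raise ConfigError("train_frac must be in (0, 1)")
    iterations = []
    for i in range(n_iter):
        seed = base_seed + i
        train, test = _stratified_split(y, train_frac, seed, stratify)
        cols = features.columns if isinstance(features, pd.DataFrame) else None
        Xtr = pd.DataFrame(X[train], columns=cols) if cols is not None else X[train]
        bundle = fit_gbm(Xtr, y[train], hyperparams, seed)
        scores = bundle.predict(X[test])
        auc, curve = roc_auc(scores, y[test])
        iterations.append({
            "seed": seed,
            "train_idx": train.tolist(),
            "test_idx": test.tolist(),
            "auc": auc,
            "roc": curve,
            "operating_point": operating_point(curve),
            "bundle": bundle,
        })
    return CvResult(iterations)


def importance(
    bundle: ModelBundle,
    method: str = "impurity",
    data=None,
    labels=None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature importance: impurity accumulation or permutation AUC drop.

    ``impurity`` reads the ensemble's total impurity-reduction shares
    (non-negative, summing to 1).  ``permutation`` measures the mean drop
    in held-out AUC over ``n_repeats`` seeded shuffles of each column and
    may be negative for irrelevant features.
    """
    if method == "impurity":
        imp = bundle.model.feature_importances_
        return pd.DataFrame(
            {"importance": imp, "sd": np.zeros_like(imp), "method": "impurity"},
            index=bundle.feature_names,
        ).sort_values("importance", ascending=False)
    if method != "permutation":
        raise ConfigError(f"unknown importance method {method!r}")
    if data is None or labels is None:
        raise ConfigError("permutation importance needs held-out data + labels")
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) \
        else np.asarray(data, dtype=float)
    y = np.asarray(labels)
    base_auc, _ = roc_auc(bundle.predict(X), y)
    rng = np.random.default_rng(seed)
    drops = np.zeros((len(bundle.feature_names), n_repeats))
    for j in range(X.shape[1]):
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            auc_p, _ = roc_auc(bundle.predict(Xp), y)
            drops[j, r] = base_auc - auc_p
    return pd.DataFrame(
        {"importance": drops.mean(axis=1), "sd": drops.std(axis=1, ddof=1),
         "method": "permutation"},
        index=bundle.feature_names,
    ).sort_values("importance", ascending=False)


def align_features(bundle: ModelBundle, external_profile) -> tuple[pd.DataFrame, float]:
    """Reorder an external cohort's features to the model's feature list.

    Model features absent from the cohort are filled with zero (absent
    taxon = zero abundance); cohort-only features are dropped.  Returns the
    aligned matrix and the coverage fraction (shared / model features).
    """
    values = external_profile.values if hasattr(external_profile, "values") and \
        isinstance(getattr(external_profile, "values"), pd.DataFrame) \
        else external_profile
    shared = [f for f in bundle.feature_names if f in values.columns]
    coverage = len(shared) / len(bundle.feature_names)
    if coverage == 0:
        raise ValidationError("no model feature present in the external cohort")
    logger.info("feature alignment coverage: %.1f%% (%d/%d)",
                100 * coverage, len(shared), len(bundle.feature_names))
    aligned = values.reindex(columns=bundle.feature_names, fill_value=0.0)
    return aligned, coverage


def score_cohort(
    bundle: ModelBundle,
    external_profile,
    metadata: SampleMetadata,
    threshold: float = 0.5,
) -> RiskScores:
    """Score an external cohort and compare risk between its groups.

    Returns per-sample continuous risk scores, per-group quartile
    summaries, and pairwise Mann–Whitney U tests with BH correction across
    group pairs.
    """
    aligned, _ = align_features(bundle, external_profile)
    labels = metadata.labels_for(list(aligned.index))
    levels = [g for g in metadata.levels if g in set(labels)]
    for g in levels:
        if (labels == g).sum() == 0:
            raise ValidationError(f"empty group {g!r}")
    raw = bundle.predict(aligned.to_numpy())
    scores = pd.Series(raw, index=aligned.index, name="risk_score")
    groups = pd.Series(labels, index=aligned.index, name="group")

    summary = scores.groupby(groups).describe()[["25%", "50%", "75%"]]
    summary.columns = ["q1", "median", "q3"]
    summary["frac_above_threshold"] = scores.groupby(groups).apply(
        lambda s: float((np.clip(s, 0, 1) > threshold).mean()))

    pairs, ps = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            u, p = mann_whitney_u(scores[groups == a], scores[groups == b])
            pairs.append((a, b, u, p))
            ps.append(p)
    adj = bh_adjust(ps) if ps else np.array([])
    pw = pd.DataFrame(pairs, columns=["group_a", "group_b", "U", "p_value"])
    pw["adjusted_p"] = adj
    return RiskScores(scores, groups, threshold, summary, pw)
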