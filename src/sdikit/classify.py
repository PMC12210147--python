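"""Group classification from SDI maps with an RBF-kernel SVM.

Stratified k-fold cross-validation with feature selection performed
strictly inside each training fold: the covariate-adjusted group t-map is
computed on training subjects only and Bonferroni-masked; selected regions
are z-scored by training statistics and fed to an RBF SVM (c=10,
gamma=0.1 by default).  Reports per-fold ACC/SEN/SPE/AUC (patient =
positive class) and a feature-stability table across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .stats import bonferroni_mask, group_glm_tmap

__all__ = ["CVConfig", "CVResult", "run_cv", "classification_metrics"]


@dataclass
class CVConfig:
    """Cross-validation and SVM settings."""

    n_folds: int = 10
    c: float = 10.0
    gamma: float = 0.1
    alpha: float = 0.05  # level for in-fold feature selection
    correction: str = "bonferroni"  # or "none" (uncorrected per-region alpha)
    covariates: tuple[str, ...] = ("gender", "mean_fd")
    seed: int = 0
    stability_threshold: int = 8  # folds a region must be selected in
    grid_search: bool = False
    grid_c: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    grid_gamma: tuple[float, ...] = (0.01, 0.1, 1.0)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction '{self.correction}'")


@dataclass
class CVResult:
    """Per-fold and aggregate classification performance."""

    fold_metrics: pd.DataFrame  # fold, acc, sen, spe, auc, n_features, skipped
    selected_features: list[np.ndarray]  # region indices per fold
    stability: pd.DataFrame  # region, n_folds_selected, direction, stable

    @property
    def mean_metrics(self) -> dict[str, float]:
        ok = self.fold_metrics[~self.fold_metrics["skipped"]]
        return {m: float(ok[m].mean()) for m in ("acc", "sen", "spe", "auc")}


def classification_metrics(
    labels: np.ndarray, predictions: np.ndarray, decision_values: np.ndarray
) -> tuple[float, float, float, float]:
    """ACC, SEN (patient recall), SPE (control recall) and rank-based AUC.

    Patients are the positive class (label 1).  AUC uses the midrank
    convention for tied decision values and requires both classes.
    """
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    decision_values = np.asarray(decision_values, dtype=float)
    if labels.size == 0:
        raise ValueError("empty evaluation set")
    acc = float(np.mean(labels == predictions))
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute SEN/SPE/AUC")
    sen = float(np.mean(predictions[labels == 1] == 1))
    spe = float(np.mean(predictions[labels == 0] == 0))
    auc = float(roc_auc_score(labels, decision_values))
    return acc, sen, spe, auc


def run_cv(
    sdi_by_subject: np.ndarray,
    covars: pd.DataFrame,
    config: CVConfig | None = None,
) -> CVResult:
    """Stratified k-fold SVM classification with in-fold feature selection.

    Test subjects never touch the fold's feature-selection t-tests.  A
    fold whose training comparison selects no region is recorded as
    skipped (its metrics are NaN), never silently fit on all features.
    """
    config = config or CVConfig()
    Y = np.asarray(sdi_by_subject, dtype=float)
    labels = covars["group"].to_numpy(dtype=int)
    if Y.shape[0] != len(labels):
        raise ValueError("sdi_by_subject rows must match the covariate table")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    rows = []
    selected: list[np.ndarray] = []
    n_regions = Y.shape[1]
    counts_pos = np.zeros(n_regions, dtype=int)
    counts_neg = np.zeros(n_regions, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(Y, labels)):
        tmap = group_glm_tmap(Y[tr], covars.iloc[tr], config.covariates)
        if config.correction == "bonferroni":
            mask = bonferroni_mask(tmap, config.alpha)
        else:
            sel = tmap.p < config.alpha
            mask = {"mask": sel, "higher": sel & (tmap.t > 0), "lower": sel & (tmap.t < 0)}
        feats = np.flatnonzero(mask["mask"])
        selected.append(feats)
        counts_pos[mask["higher"]] += 1
        counts_neg[mask["lower"]] += 1
        if len(feats) == 0:
            rows.append(
                dict(fold=fold, acc=np.nan, sen=np.nan, spe=np.nan, auc=np.nan,
                     n_features=0, skipped=True)
            )
            continue
        Xtr, Xte = Y[tr][:, feats], Y[te][:, feats]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        if config.grid_search:
            inner = StratifiedKFold(3, shuffle=True, random_state=config.seed)
            search = GridSearchCV(
                SVC(kernel="rbf"),
                {"C": list(config.grid_c), "gamma": list(config.grid_gamma)},
                cv=inner,
            )
            search.fit(Xtr, labels[tr])
            clf = search.best_estimator_
        else:
            clf = SVC(kernel="rbf", C=config.c, gamma=config.gamma)
            clf.fit(Xtr, labels[tr])
        pred = clf.predict(Xte)
        dec = clf.decision_function(Xte)
        acc, sen, spe, auc = classification_metrics(labels[te], pred, dec)
        rows.append(
            dict(fold=fold, acc=acc, sen=sen, spe=spe, auc=auc,
                 n_features=len(feats), skipped=False)
        )
    counts = counts_pos + counts_neg
    direction = np.where(counts_pos >= counts_neg, "patient>control", "patient<control")
    stability = pd.DataFrame(
        {
            "region": np.arange(n_regions),
            "n_folds_selected": counts,
            "direction": np.where(counts > 0, direction, "none"),
            "stable": counts >= config.stability_threshold,
        }
    )
    stability = stability[stability["n_folds_selected"] > 0].reset_index(drop=True)
    return CVResult(
        fold_metrics=pd.DataFrame(rows),
        selected_features=selected,
        stability=stability,
    )
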