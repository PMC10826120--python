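"""Two-step random-forest SNP prioritization.

Stage 1 tunes a random forest (gini splits, maximal trees) over an
mtry x ntree grid by stratified 5-fold cross-validated misclassification
error, scores every SNP with a label-permutation importance p-value
(Altmann-style: the null distribution comes from forests refit on shuffled
labels), and keeps SNPs with p below ``stage1_alpha``.  Stage 2 repeats
tuning and importance testing on the reduced panel at ``stage2_alpha``.

The importance measure is configurable: ``"permutation"`` (model-based
permutation importance of each feature, one shuffle pass) or ``"gini"``
(impurity decrease, much cheaper — the Altmann null makes either measure a
valid test statistic).  The add-one estimator
``p = (1 + #{null >= observed}) / (1 + n_perm)`` keeps p-values in (0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .plinkio import CaseControlLabels, GenotypeMatrix

__all__ = [
    "RFConfig",
    "StageResult",
    "RFSelectionResult",
    "auto_mtry_grid",
    "tune_rf",
    "importance_pvalues",
    "two_step_select",
]

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Hyperparameters of the two-step selection.

    ``mtry_grid="auto"`` builds the grid from the square root of the SNP
    count and its halvings/doublings (see :func:`auto_mtry_grid`).
    ``stage2_alpha`` defaults to 0.05; 0.01 is the stricter choice for
    large panels.
    """

    ntree_grid: tuple[int, ...] = (100, 250, 500, 1000)
    mtry_grid: tuple[int, ...] | str = "auto"
    cv_folds: int = 5
    importance_permutations: int = 100
    importance_measure: str = "permutation"  # or "gini"
    importance_max_samples: int | None = None  # subsample rows when scoring
    holdout_fraction: float = 0.25  # rows held out to score permutation importance
    stage1_alpha: float = 0.05
    stage2_alpha: float = 0.05
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not self.ntree_grid:
            raise ValueError("ntree_grid must be non-empty")
        if self.importance_measure not in ("permutation", "gini"):
            raise ValueError("importance_measure must be 'permutation' or 'gini'")
        if self.importance_permutations < 1:
            raise ValueError("importance_permutations must be >= 1")


def auto_mtry_grid(n_features: int) -> list[int]:
    """mtry grid from sqrt(n_features) and its halvings/doublings.

    grid = {max(1, round(s / 2^k)), k=1..4} U {round(s * 2^k), k=0..3},
    s = sqrt(n_features), clipped to [1, n_features], unique and sorted.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    s = math.sqrt(n_features)
    vals = {max(1, round(s / 2**k)) for k in range(1, 5)}
    vals |= {round(s * 2**k) for k in range(4)}
    return sorted(v for v in vals if 1 <= v <= n_features)


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, GenotypeMatrix):
        ids = X.snp_ids
        X = X.values
    else:
        X = np.asarray(X)
        ids = [f"f{j}" for j in range(X.shape[1])]
    y = y.status if isinstance(y, CaseControlLabels) else np.asarray(y)
    # missing codes (-1) are passed through: trees treat them as a category
    return X.astype(np.float32), y.astype(np.int8), ids


def _forest(mtry: int, ntree: int, seed: int, n_jobs: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        criterion="gini",
        max_depth=None,  # maximal trees
        max_features=mtry,
        random_state=seed,
        n_jobs=n_jobs,
    )


def tune_rf(X, y, cfg: RFConfig) -> tuple[int, int, float]:
    """Grid-search (mtry, ntree) by mean stratified-CV misclassification.

    Ties are broken toward smaller ntree, then smaller mtry.  Returns
    ``(best_mtry, best_ntree, cv_error)``.
    """
    Xa, ya, _ids = _as_xy(X, y)
    classes = np.unique(ya)
    if len(classes) < 2:
        raise ValueError("tuning needs both classes present")
    n_features = Xa.shape[1]
    mtry_grid = (
        auto_mtry_grid(n_features) if cfg.mtry_grid == "auto" else list(cfg.mtry_grid)
    )
    # clip rather than drop: stage 2 may run on fewer features than any grid value
    mtry_grid = sorted({min(max(1, m), n_features) for m in mtry_grid})
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(Xa, ya))
    best = None
    for ntree in sorted(cfg.ntree_grid):
        for mtry in sorted(mtry_grid):
            errs = []
            for f, (tr, te) in enumerate(folds):
                clf = _forest(mtry, ntree, cfg.seed + f, cfg.n_jobs)
                clf.fit(Xa[tr], ya[tr])
                errs.append(float((clf.predict(Xa[te]) != ya[te]).mean()))
            err = float(np.mean(errs))
            key = (err, ntree, mtry)
            if best is None or key < best:
                best = key
    err, ntree, mtry = best
    return mtry, ntree, err


def _importance(
    clf: RandomForestClassifier,
    Xa: np.ndarray,
    ya: np.ndarray,
    measure: str,
    seed: int,
    max_samples: int | None = None,
) -> np.ndarray:
    if measure == "gini":
        return clf.feature_importances_
    kwargs = {}
    if max_samples is not None and max_samples < len(ya):
        kwargs["max_samples"] = max_samples
    res = permutation_importance(
        clf, Xa, ya, n_repeats=1, random_state=seed, n_jobs=1, **kwargs
    )
    return res.importances_mean


def importance_pvalues(
    X,
    y,
    best_mtry: int,
    best_ntree: int,
    n_perm: int = 100,
    seed: int = 0,
    measure: str = "permutation",
    n_jobs: int = 1,
    max_samples: int | None = None,
    holdout_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP importance and label-permutation p-value.

    The observed importance comes from a forest fit on the true labels;
    the null distribution from ``n_perm`` forests fit on label shuffles
    (Altmann scheme).  ``p = (1 + #{null >= observed}) / (1 + n_perm)``
    per SNP.

    With ``measure="permutation"`` the importance is the accuracy drop on
    a held-out row fraction when one feature column is shuffled — the
    holdout plays the role OOB samples play in classic RF permutation
    importance.  Scoring in-sample would be anti-conservative in reverse:
    maximal trees memorize their training rows, so label-shuffled null
    forests would show large in-sample importances for every feature and
    swamp the observed signal.  ``measure="gini"`` uses the impurity
    decrease of the full-data forest (no holdout).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xa, ya, _ids = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    n = len(ya)

    if measure == "permutation":
        n_val = max(2, int(round(holdout_fraction * n)))
        perm_rows = rng.permutation(n)
        val_idx, fit_idx = perm_rows[:n_val], perm_rows[n_val:]
        Xf, Xv = Xa[fit_idx], Xa[val_idx]

        def importance_for(labels_full: np.ndarray, forest_seed: int) -> np.ndarray:
            clf = _forest(best_mtry, best_ntree, forest_seed, n_jobs)
            clf.fit(Xf, labels_full[fit_idx])
            return _importance(
                clf, Xv, labels_full[val_idx], measure, forest_seed, max_samples
            )
    else:

        def importance_for(labels_full: np.ndarray, forest_seed: int) -> np.ndarray:
            clf = _forest(best_mtry, best_ntree, forest_seed, n_jobs)
            clf.fit(Xa, labels_full)
            return _importance(clf, Xa, labels_full, measure, forest_seed, max_samples)

    observed = importance_for(ya, seed)
    exceed = np.zeros(Xa.shape[1], dtype=np.int64)
    for b in range(n_perm):
        y_perm = rng.permutation(ya)
        exceed += importance_for(y_perm, seed + 1 + b) >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return observed, pvals


@dataclass
class StageResult:
    """Diagnostics of one RF stage."""

    snp_ids: list[str]
    best_mtry: int
    best_ntree: int
    cv_error: float
    importances: np.ndarray
    importance_p: np.ndarray
    alpha: float
    selected_ids: list[str] = field(default_factory=list)


@dataclass
class RFSelectionResult:
    """Outcome of the two-step selection; top-level fields mirror the
    final stage that actually ran."""

    best_mtry: int
    best_ntree: int
    cv_error: float
    importances: np.ndarray
    importance_p: np.ndarray
    selected_ids: list[str]
    stage1: StageResult = None
    stage2: StageResult | None = None
    stage2_skipped: bool = False


def _run_stage(X, y, cfg: RFConfig, ids: list[str], alpha: float, seed: int) -> StageResult:
    mtry, ntree, err = tune_rf(X, y, cfg)
    imp, pvals = importance_pvalues(
        X,
        y,
        mtry,
        ntree,
        n_perm=cfg.importance_permutations,
        seed=seed,
        measure=cfg.importance_measure,
        n_jobs=cfg.n_jobs,
        max_samples=cfg.importance_max_samples,
        holdout_fraction=cfg.holdout_fraction,
    )
    # alpha >= 1 disables filtering (the add-one p-value never drops below
    # 1/(n_perm+1) but can equal 1.0, so a strict cut at 1.0 would not)
    selected = list(ids) if alpha >= 1 else [s for s, p in zip(ids, pvals) if p < alpha]
    return StageResult(list(ids), mtry, ntree, err, imp, pvals, alpha, selected)


def two_step_select(X, y, cfg: RFConfig) -> RFSelectionResult:
    """Run both RF stages and return the surviving SNP panel.

    If stage 1 keeps fewer than 3 SNPs the triplet stage downstream cannot
    run on a further-reduced panel, so stage 2 is skipped with a warning
    and the stage-1 selection is returned flagged.
    """
    if isinstance(X, GenotypeMatrix):
        if X.n_snps < 3:
            raise ValueError("need at least 3 input SNPs")
        ids = X.snp_ids
    else:
        X = np.asarray(X)
        if X.shape[1] < 3:
            raise ValueError("need at least 3 input SNPs")
        ids = [f"f{j}" for j in range(X.shape[1])]

    stage1 = _run_stage(X, y, cfg, ids, cfg.stage1_alpha, cfg.seed)
    if len(stage1.selected_ids) < 3:
        msg = (
            f"stage 1 selected only {len(stage1.selected_ids)} SNPs; "
            "stage 2 skipped, returning the stage-1 selection"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        return RFSelectionResult(
            stage1.best_mtry,
            stage1.best_ntree,
            stage1.cv_error,
            stage1.importances,
            stage1.importance_p,
            list(stage1.selected_ids),
            stage1=stage1,
            stage2=None,
            stage2_skipped=True,
        )

    from .plinkio import subset_snps

    if isinstance(X, GenotypeMatrix):
        X2 = subset_snps(X, stage1.selected_ids)
    else:
        keep = [ids.index(s) for s in stage1.selected_ids]
        X2 = X[:, keep]
    stage2 = _run_stage(
        X2, y, cfg, stage1.selected_ids, cfg.stage2_alpha, cfg.seed + 10_000
    )
    return RFSelectionResult(
        stage2.best_mtry,
        stage2.best_ntree,
        stage2.cv_error,
        stage2.importances,
        stage2.importance_p,
        list(stage2.selected_ids),
        stage1=stage1,
        stage2=stage2,
    )
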