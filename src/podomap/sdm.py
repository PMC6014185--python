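"""Environmental-suitability ensemble: boosted trees + random forest.

The ensemble repeatedly splits the weighted training set 80/20, fits both
a gradient-boosted regression-tree model (learning rate 0.005, interaction
depth 4, tree count chosen by early stopping on an internal validation
fold) and a random forest (500 trees, √p features per split), evaluates
each fit on its held-out 20% (AUC, TSS, PCC), discards runs below the
selection thresholds (AUC < 0.8 or TSS < 0.7), and assembles the survivors
into per-cell mean suitability with empirical 2.5/97.5-percentile bands.
A suitability cut-off maximising the mean of sensitivity, specificity and
PCC converts the continuous surface into a binary environmental-limits map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .raster import RasterGrid, RasterStack

__all__ = [
    "ModelRun",
    "EnsembleResult",
    "fit_brt",
    "fit_rf",
    "evaluate",
    "predict_grid",
    "run_ensemble",
    "choose_threshold",
    "partial_dependence",
    "variable_contribution",
]

log = logging.getLogger(__name__)


def _check_two_classes(y: np.ndarray, where: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{where} requires both classes present")


def fit_brt(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    learning_rate: float = 0.005,
    interaction_depth: int = 4,
    max_trees: int = 5000,
    seed: int = 0,
) -> GradientBoostingClassifier:
    """Gradient-boosted trees at a slow learning rate.

    Depth-4 trees allow up to four-way covariate interactions; the number
    of boosting iterations is tuned by early stopping on a 10% internal
    validation fold (capped at ``max_trees``), the usual practice when the
    learning rate is fixed a priori.
    """
    _check_two_classes(y, "fit_brt")
    model = GradientBoostingClassifier(
        learning_rate=learning_rate,
        max_depth=interaction_depth,
        n_estimators=max_trees,
        subsample=1.0,
        validation_fraction=0.1,
        n_iter_no_change=20,
        tol=1e-5,
        random_state=seed,
    )
    model.fit(X, y, sample_weight=sample_weight)
    return model


def fit_rf(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Random forest with the defaults of classification forests:
    500 bagged trees, √p candidate features per split."""
    _check_two_classes(y, "fit_rf")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    model.fit(X, y, sample_weight=sample_weight)
    return model


def evaluate(learner, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Held-out (AUC, TSS, PCC).

    AUC is the rank (Mann–Whitney) statistic with tie correction; TSS and
    PCC are computed at the ROC threshold maximising sensitivity +
    specificity (Youden's J) on the held-out scores.
    """
    _check_two_classes(y, "evaluate")
    scores = learner.predict_proba(X)[:, 1]
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = np.argmax(tpr - fpr)
    tss = float(tpr[j] - fpr[j])
    pred = scores >= thresholds[j]
    pcc = float((pred == (y == 1)).mean())
    return auc, tss, pcc


@dataclass
class ModelRun:
    """One fitted learner plus its held-out evaluation statistics."""

    algorithm: str
    split_seed: int
    learner: object
    auc: float
    tss: float
    pcc: float
    selected: bool = False
    prediction: np.ndarray | None = None  # flattened grid scores


@dataclass
class EnsembleResult:
    mean_suitability: RasterGrid
    ci_low: RasterGrid
    ci_high: RasterGrid
    runs: list[ModelRun]
    threshold: float
    threshold_stats: dict
    limits: RasterGrid
    rep_thresholds: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def selected_runs(self) -> list[ModelRun]:
        return [r for r in self.runs if r.selected]

    def metrics_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "algorithm": r.algorithm,
                    "split_seed": r.split_seed,
                    "auc": r.auc,
                    "tss": r.tss,
                    "pcc": r.pcc,
                    "selected": r.selected,
                }
                for r in self.runs
            ]
        )


def predict_grid(learner, stack: RasterStack, covariates: list[str]) -> np.ndarray:
    """Flattened probability scores over the stack grid (NaN on no-data)."""
    M = np.column_stack([stack[c].data.ravel() for c in covariates])
    out = np.full(M.shape[0], np.nan)
    ok = ~stack.combined_mask().ravel()
    if ok.any():
        out[ok] = learner.predict_proba(M[ok])[:, 1]
    return out


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split so both subsets keep both classes."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, min(len(idx) - 1, int(round(train_frac * len(idx)))))
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def run_ensemble(
    features: pd.DataFrame,
    stack: RasterStack,
    covariates: list[str],
    n_reps: int = 100,
    train_frac: float = 0.8,
    auc_min: float = 0.8,
    tss_min: float = 0.7,
    seed: int = 0,
    algorithms: tuple[str, ...] = ("brt", "rf"),
    brt_max_trees: int = 5000,
    rf_trees: int = 500,
) -> EnsembleResult:
    """Repeated-split ensemble over the full grid.

    For each of ``n_reps`` replicates and each algorithm: draw a stratified
    ``train_frac`` split of the *surveyed* records, fit with the record
    weights, evaluate on the held-out rows, and predict the whole grid.
    Background (pseudo-absence) rows are calibration augmentation, not
    ground truth: they join every training fold and are never evaluated
    against.  Runs failing the selection rule (AUC < ``auc_min`` or TSS <
    ``tss_min``) are disregarded; the assembled surface is the per-cell
    mean of the surviving runs with empirical 2.5/97.5-percentile bands.
    Per-replicate seeds derive from the master seed as
    ``SeedSequence([seed, rep, algo_index])``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    X = features[covariates].to_numpy(float)
    y = features["label"].to_numpy(int)
    w = features["weight"].to_numpy(float)
    _check_two_classes(y, "run_ensemble")
    if "record" in features.columns:
        is_background = (features["record"] == "background").to_numpy()
    else:
        is_background = np.zeros(len(features), dtype=bool)
    survey_idx = np.flatnonzero(~is_background)
    bg_idx = np.flatnonzero(is_background)

    runs: list[ModelRun] = []
    for rep in range(n_reps):
        for ai, algo in enumerate(algorithms):
            ss = np.random.SeedSequence([seed, rep, ai])
            rng = np.random.default_rng(ss)
            split_seed = int(ss.generate_state(1)[0] % (2**31))
            tr_s, te_s = _stratified_split(y[survey_idx], train_frac, rng)
            tr = np.concatenate([survey_idx[tr_s], bg_idx])
            te = survey_idx[te_s]
            if len(np.unique(y[te])) < 2:
                continue
            if algo == "brt":
                learner = fit_brt(
                    X[tr], y[tr], w[tr], max_trees=brt_max_trees, seed=split_seed
                )
            elif algo == "rf":
                learner = fit_rf(X[tr], y[tr], w[tr], n_trees=rf_trees, seed=split_seed)
            else:
                raise ValueError(f"unknown algorithm {algo!r}")
            auc, tss, pcc = evaluate(learner, X[te], y[te])
            run = ModelRun(
                algorithm=algo,
                split_seed=split_seed,
                learner=learner,
                auc=auc,
                tss=tss,
                pcc=pcc,
                selected=(auc >= auc_min and tss >= tss_min),
            )
            if run.selected:
                run.prediction = predict_grid(learner, stack, covariates)
            runs.append(run)

    selected = [r for r in runs if r.selected]
    if not selected:
        raise RuntimeError(
            f"no ensemble member survived selection (AUC >= {auc_min}, "
            f"TSS >= {tss_min}); ensemble is empty"
        )
    log.info("ensemble: %d/%d runs selected", len(selected), len(runs))

    preds = np.stack([r.prediction for r in selected])
    grid = stack.grid
    shape = grid.shape
    mask = stack.combined_mask()
    mean = preds.mean(axis=0).reshape(shape)
    lo = np.percentile(preds, 2.5, axis=0).reshape(shape)
    hi = np.percentile(preds, 97.5, axis=0).reshape(shape)

    # ensemble-mean scores at training communities choose the cut-off
    row, col = grid.xy_to_rowcol(
        features["x_km"].to_numpy(float), features["y_km"].to_numpy(float)
    )
    scores = mean[row, col]
    threshold, stats = choose_threshold(scores, y)
    rep_thresholds = np.array(
        [
            choose_threshold(r.prediction.reshape(shape)[row, col], y)[0]
            for r in selected
        ]
    )
    limits = (mean >= threshold).astype(float)
    limits[mask] = 0.0
    mk = lambda a: RasterGrid(  # noqa: E731
        data=a, west=grid.west, north=grid.north, cell=grid.cell, crs=grid.crs,
        mask=mask.copy(),
    )
    return EnsembleResult(
        mean_suitability=mk(mean),
        ci_low=mk(lo),
        ci_high=mk(hi),
        runs=runs,
        threshold=float(threshold),
        threshold_stats=stats,
        limits=mk(limits),
        rep_thresholds=rep_thresholds,
    )


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """Suitability cut-off maximising (sensitivity + specificity + PCC)/3.

    Candidates are the midpoints between consecutive distinct scores plus
    sentinels below/above the observed range; ties are broken towards the
    lower threshold.  Returns the cut-off and the achieved statistics.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels, "choose_threshold")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    cands = np.concatenate([[uniq[0] - 1e-9], mids, [uniq[-1] + 1e-9]])
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    pred = scores[None, :] >= cands[:, None]  # (cands, n)
    tp = (pred & pos[None, :]).sum(axis=1)
    tn = (~pred & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg
    pcc = (tp + tn) / len(labels)
    crit = (sens + spec + pcc) / 3.0
    best = np.flatnonzero(crit == crit.max())[0]  # lower threshold on ties
    return float(cands[best]), {
        "sensitivity": float(sens[best]),
        "specificity": float(spec[best]),
        "pcc": float(pcc[best]),
        "criterion": float(crit[best]),
    }


def partial_dependence(
    learner, X: np.ndarray, j: int, values: np.ndarray
) -> np.ndarray:
    """Marginal effect of covariate ``j``: for each value v the prediction
    averaged over the training rows with column j replaced by v."""
    X = np.asarray(X, float)
    if not 0 <= j < X.shape[1]:
        raise ValueError(f"covariate index {j} out of range for {X.shape[1]} columns")
    values = np.asarray(values, float)
    n, p = X.shape
    # tile rows once per grid value; single predict_proba call
    rep = np.repeat(values, n)
    tiled = np.tile(X, (len(values), 1))
    tiled[:, j] = rep
    preds = learner.predict_proba(tiled)[:, 1]
    return preds.reshape(len(values), n).mean(axis=1)


def variable_contribution(learner) -> np.ndarray:
    """Relative importance of each covariate, normalised to sum to 100."""
    imp = np.asarray(learner.feature_importances_, float)
    total = imp.sum()
    if total <= 0:
        return np.full_like(imp, 100.0 / len(imp))
    return 100.0 * imp / total
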