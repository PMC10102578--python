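"""Leakage-proof repeated stratified cross-validation with all-relevant
feature selection and an SVM classifier; vertically averaged ROC curves
with bootstrap confidence bands.

Every transform (surrogate-variable adjustment, standardization, feature
selection) is fit on the training split only and frozen before the held-out
samples are scored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .diffstats import build_design, estimate_surrogates

__all__ = [
    "BorutaDecision",
    "boruta_select",
    "CVReport",
    "run_cv",
    "average_roc",
    "bootstrap_band",
]


@dataclass
class BorutaDecision:
    """Outcome of shadow-feature selection."""

    status: np.ndarray  # "confirmed" | "rejected" | "tentative" per feature
    hit_count: np.ndarray
    n_iterations: int
    resolved_tentative: np.ndarray  # features decided by the median fallback

    @property
    def confirmed(self) -> np.ndarray:
        return np.nonzero(self.status == "confirmed")[0]


def boruta_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    rng: np.random.Generator | int | None = None,
    n_trees: int = 300,
    max_runs: int = 100,
    alpha: float = 0.01,
) -> BorutaDecision:
    """All-relevant selection against permuted shadow features.

    Each iteration appends a column-permuted copy of every feature, fits a
    random forest, and records a hit when a real feature's importance
    exceeds the maximum shadow importance. Features are confirmed/rejected
    by a two-sided binomial test (p=0.5) with Bonferroni correction at
    ``alpha``; residual tentatives are resolved by comparing their median
    importance with the median of the shadow maxima.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("y_train must contain both classes")
    n, m = X.shape

    status = np.array(["tentative"] * m, dtype=object)
    hits = np.zeros(m, dtype=int)
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []
    threshold = alpha / m  # Bonferroni over features

    k = 0
    for k in range(1, max_runs + 1):
        shadow = rng.permuted(X, axis=0)
        Xa = np.hstack([X, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xa, y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:m], imp[m:]
        shadow_max = float(shadow_imp.max())
        hits += (real_imp > shadow_max).astype(int)
        imp_history.append(real_imp)
        shadow_max_history.append(shadow_max)

        undecided = status == "tentative"
        p_more = stats.binom.sf(hits - 1, k, 0.5)  # P(X >= hits)
        p_less = stats.binom.cdf(hits, k, 0.5)  # P(X <= hits)
        status[undecided & (2 * p_more < threshold)] = "confirmed"
        status[undecided & (2 * p_less < threshold)] = "rejected"
        if not np.any(status == "tentative"):
            break

    resolved = status == "tentative"
    if np.any(resolved):
        # residual tentatives: median importance must dominate the median
        # shadow maximum AND the hit record must be nominally significant,
        # otherwise an in-sample-lucky noise feature slips through
        med_imp = np.median(np.vstack(imp_history), axis=0)
        med_shadow = float(np.median(shadow_max_history))
        p_more = stats.binom.sf(hits - 1, k, 0.5)
        promote = resolved & (med_imp > med_shadow) & (p_more < alpha)
        status[promote] = "confirmed"
        status[resolved & ~promote] = "rejected"
    return BorutaDecision(
        status=status.astype(str),
        hit_count=hits,
        n_iterations=k,
        resolved_tentative=resolved,
    )


@dataclass
class CVReport:
    """Cross-validation outcome: fold ROC curves, averaged curve, selections."""

    fold_fprs: list[np.ndarray]
    fold_tprs: list[np.ndarray]
    fold_aucs: list[float]
    selected_sets: list[list[int]]
    grid: np.ndarray
    mean_tpr: np.ndarray
    mean_auc: float
    auc_of_mean_curve: float
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None
    auc_ci: tuple[float, float] | None = None
    selection_frequency: np.ndarray | None = None
    n_selected_mean: float = float("nan")
    n_selected_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "auc_of_mean_curve": float(self.auc_of_mean_curve),
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "grid": self.grid.tolist(),
            "mean_tpr": self.mean_tpr.tolist(),
            "band_low": self.band_low.tolist() if self.band_low is not None else None,
            "band_high": self.band_high.tolist() if self.band_high is not None else None,
            "selected_sets": [[int(i) for i in s] for s in self.selected_sets],
            "selection_frequency": (
                self.selection_frequency.tolist()
                if self.selection_frequency is not None
                else None
            ),
            "n_selected_mean": float(self.n_selected_mean),
            "n_selected_sd": float(self.n_selected_sd),
        }


def _interp_fold(grid: np.ndarray, fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    # evaluate the ROC staircase (right-continuous): TPR at FPR f is the
    # best TPR attainable at any FPR <= f; linear interpolation across the
    # steps would be optimistically biased by half a step
    uniq, inv = np.unique(fpr, return_inverse=True)
    best = np.zeros(len(uniq))
    np.maximum.at(best, inv, tpr)
    best = np.maximum.accumulate(best)
    idx = np.searchsorted(uniq, grid, side="right") - 1
    out = best[np.clip(idx, 0, len(uniq) - 1)]
    out[-1] = 1.0
    return out


def average_roc(
    fold_rocs: list[tuple[np.ndarray, np.ndarray]], grid_step: float = 0.01
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Vertical averaging of fold ROC curves on a fixed FPR grid.

    Returns (grid, mean TPR, mean of per-fold trapezoid AUCs, AUC of the
    averaged curve). The first AUC is the reported one.
    """
    if not fold_rocs:
        raise ValueError("need at least one fold curve")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    tprs = np.vstack([_interp_fold(grid, f, t) for f, t in fold_rocs])
    mean_tpr = tprs.mean(axis=0)
    fold_aucs = [float(_trapezoid_auc(f2, t2)) for f2, t2 in (
        (np.concatenate([[0.0], f, [1.0]]), np.concatenate([[0.0], t, [1.0]]))
        for f, t in fold_rocs
    )]
    return grid, mean_tpr, float(np.mean(fold_aucs)), float(_trapezoid_auc(grid, mean_tpr))


def bootstrap_band(
    fold_rocs: list[tuple[np.ndarray, np.ndarray]],
    grid_step: float = 0.01,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
    ci: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Pointwise percentile band and AUC CI by resampling fold curves."""
    if len(fold_rocs) < 2:
        raise ValueError("need >= 2 fold curves to bootstrap")
    rng = np.random.default_rng(rng)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    tprs = np.vstack([_interp_fold(grid, f, t) for f, t in fold_rocs])
    fold_aucs = np.array(
        [
            _trapezoid_auc(np.concatenate([[0.0], f, [1.0]]), np.concatenate([[0.0], t, [1.0]]))
            for f, t in fold_rocs
        ]
    )
    n = len(fold_rocs)
    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_curves = tprs[idx].mean(axis=1)  # n_boot x grid
    boot_aucs = fold_aucs[idx].mean(axis=1)
    band_low = np.percentile(boot_curves, lo_q, axis=0)
    band_high = np.percentile(boot_curves, hi_q, axis=0)
    auc_ci = (float(np.percentile(boot_aucs, lo_q)), float(np.percentile(boot_aucs, hi_q)))
    return band_low, band_high, auc_ci


def _sv_adjust_fold(X_tr, y_tr, X_te, rng):
    """Fit surrogate variables on training only, freeze, and apply to both."""
    design = build_design(y_tr)
    model = estimate_surrogates(X_tr, design, rng=rng)
    if model.n_sv == 0:
        return X_tr, X_te
    full = np.column_stack([design, model.sv_scores])
    beta, *_ = np.linalg.lstsq(full, X_tr, rcond=None)
    b_sv = beta[design.shape[1]:]  # n_sv x features
    X_tr_adj = X_tr - model.sv_scores @ b_sv
    te_scores = model.project(X_te)
    X_te_adj = X_te - te_scores @ b_sv
    return X_tr_adj, X_te_adj


def run_cv(
    matrix: np.ndarray,
    labels,
    n_repeats: int = 10,
    n_folds: int = 10,
    rng: np.random.Generator | int | None = None,
    sva: bool = True,
    boruta: bool = True,
    boruta_kwargs: dict | None = None,
    svm_c: float = 1.0,
    grid_step: float = 0.01,
    n_boot: int = 10_000,
    compute_band: bool = True,
) -> CVReport:
    """Repeated stratified k-fold CV with in-fold selection and linear SVM.

    Per fold: surrogate variables are estimated on the training split and
    projected onto held-out samples through frozen loadings; features are
    standardized with training statistics; shadow-feature selection runs on
    the training split; a linear SVM (C=1, balanced class weights) is
    trained on the confirmed features and scored on the held-out samples
    with decision values.
    """
    ss = np.random.SeedSequence(
        rng if isinstance(rng, (int, np.integer)) else np.random.default_rng(rng).integers(2**31)
    )
    seeds = ss.spawn(3)
    fold_seed = int(np.random.default_rng(seeds[0]).integers(2**31 - 1))
    fold_rng_root = np.random.SeedSequence(int(np.random.default_rng(seeds[1]).integers(2**31 - 1)))
    boot_rng = np.random.default_rng(seeds[2])

    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    y = (labels == "case").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    boruta_kwargs = dict(boruta_kwargs or {})

    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=fold_seed
    )
    fold_seqs = fold_rng_root.spawn(n_folds * n_repeats)

    fold_fprs, fold_tprs, fold_aucs, selected_sets = [], [], [], []
    n_features = X.shape[1]
    sel_counts = np.zeros(n_features)
    for fold_idx, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a fold lost a class; re-stratify")
        frng = np.random.default_rng(fold_seqs[fold_idx])
        X_tr, X_te = X[tr], X[te]
        y_tr, y_te = y[tr], y[te]

        if sva:
            X_tr, X_te = _sv_adjust_fold(X_tr, labels[tr], X_te, frng)

        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X_tr = (X_tr - mu) / sd
        X_te = (X_te - mu) / sd

        if boruta:
            decision = boruta_select(X_tr, y_tr, rng=frng, **boruta_kwargs)
            sel = decision.confirmed
            if len(sel) == 0:
                sel = np.arange(n_features)
        else:
            sel = np.arange(n_features)
        selected_sets.append(sel.tolist())
        sel_counts[sel] += 1

        clf = SVC(kernel="linear", C=svm_c, class_weight="balanced")
        clf.fit(X_tr[:, sel], y_tr)
        scores = clf.decision_function(X_te[:, sel])
        fpr, tpr, _ = roc_curve(y_te, scores)
        fold_fprs.append(fpr)
        fold_tprs.append(tpr)
        fold_aucs.append(float(_trapezoid_auc(fpr, tpr)))

    fold_rocs = list(zip(fold_fprs, fold_tprs))
    grid, mean_tpr, mean_auc, auc_mean_curve = average_roc(fold_rocs, grid_step)
    band_low = band_high = None
    auc_ci = None
    if compute_band and len(fold_rocs) >= 2:
        band_low, band_high, auc_ci = bootstrap_band(
            fold_rocs, grid_step, n_boot=n_boot, rng=boot_rng
        )
    n_sel = np.array([len(s) for s in selected_sets], dtype=float)
    return CVReport(
        fold_fprs=fold_fprs,
        fold_tprs=fold_tprs,
        fold_aucs=fold_aucs,
        selected_sets=selected_sets,
        grid=grid,
        mean_tpr=mean_tpr,
        mean_auc=mean_auc,
        auc_of_mean_curve=auc_mean_curve,
        band_low=band_low,
        band_high=band_high,
        auc_ci=auc_ci,
        selection_frequency=sel_counts / len(selected_sets),
        n_selected_mean=float(n_sel.mean()),
        n_selected_sd=float(n_sel.std(ddof=1)) if len(n_sel) > 1 else 0.0,
    )
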