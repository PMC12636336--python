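"""Genetic-architecture statistics built on the additive models.

Covers cross-validated variance decomposition, stepwise extension of
additive models with pairwise non-additive interactions, the QTL
multimodality (allelic-heterogeneity) test, the pleiotropy permutation
test for genes mapped at single-gene resolution, and principal
components of standardized haplotype effect profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import HaplotypeMatrix
from .qtlmodel import (AdditiveModel, ModelFit, fit_additive_model,
                       forward_select, nested_anova_p)


def _test_variance_explained(haps, y, fit: ModelFit, test_idx: np.ndarray
                             ) -> tuple[float, int]:
    """Out-of-sample variance explained by a fitted haplotype model.

    Computed about the test-set mean: 1 - RSS_test / TSS_test.  Test
    strains with a haplotype level unseen in training are dropped;
    returns the number dropped as the second element.
    """
    y_test = y[test_idx]
    labels = haps.labels[test_idx][:, fit.marker_indices]
    pred = np.full(len(test_idx), fit.intercept)
    ok = np.isfinite(y_test) & (labels > 0).all(axis=1)
    for k in range(labels.shape[1]):
        lab = fit.marker_classes(k, labels[:, k])
        known = np.isin(lab, [fit.ref_levels[k]] + list(fit.col_levels[k]))
        ok &= known
        for j, lv in enumerate(fit.col_levels[k]):
            pred += np.where(lab == lv, fit.beta[fit.col_slices[k]][j], 0.0)
    n_dropped = int((np.isfinite(y_test)).sum() - ok.sum())
    yv, pv = y_test[ok], pred[ok]
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss <= 0:
        return 0.0, n_dropped
    rss = float(((yv - pv) ** 2).sum())
    return 1.0 - rss / tss, n_dropped


@dataclass
class CVResult:
    condition: str | None
    timepoint: float | None
    fold_variance: np.ndarray
    mean: float
    se: float
    per_k_curve: np.ndarray  # mean test VE using the k strongest markers
    interaction_extended_mean: float | None = None
    fold_models: list = field(default_factory=list)  # per-fold ModelFit
    fold_tests: list = field(default_factory=list)  # per-fold test indices
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "timepoint": self.timepoint,
            "fold_variance": [float(v) for v in self.fold_variance],
            "mean": self.mean,
            "se": self.se,
            "per_k_curve": [float(v) for v in self.per_k_curve],
            "interaction_extended_mean": self.interaction_extended_mean,
        }


def _rank_markers_by_type2(haps, y_train, fit: ModelFit) -> np.ndarray:
    """Order of model markers by drop-one (type II) ANOVA p, strongest first."""
    pvals = np.empty(len(fit.marker_indices))
    for k in range(len(fit.marker_indices)):
        rest = np.delete(fit.marker_indices, k)
        if len(rest) == 0:
            used = fit.used
            yv = y_train[used]
            rss0 = float(((yv - yv.mean()) ** 2).sum())
            pvals[k] = nested_anova_p(rss0, 1, fit.rss, fit.rank, fit.n_used)
            continue
        sub = fit_additive_model(haps, np.where(fit.used, y_train, np.nan),
                                 rest)
        pvals[k] = nested_anova_p(sub.rss, sub.rank, fit.rss, fit.rank,
                                  fit.n_used)
    return np.argsort(pvals, kind="stable")


def cv_variance(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    lod_threshold: float = 9.0,
    marker_indices: np.ndarray | None = None,
    condition: str | None = None,
    timepoint: float | None = None,
    per_k: bool = True,
) -> CVResult:
    """K-fold cross-validated variance explained by forward-selected models."""
    y = np.asarray(pheno, dtype=float)
    usable = np.flatnonzero(np.isfinite(y))
    rng = np.random.default_rng(seed)
    order = rng.permutation(usable)
    folds = np.array_split(order, k_folds)
    fold_ve, fold_fits, fold_tests, fold_orders = [], [], [], []
    n_dropped = 0
    for f in range(k_folds):
        test_idx = folds[f]
        y_train = y.copy()
        y_train[test_idx] = np.nan
        model = forward_select(haps, y_train, marker_indices=marker_indices,
                               lod_threshold=lod_threshold)
        if len(model) == 0:
            fold_ve.append(0.0)
            fold_fits.append(None)
            fold_tests.append(test_idx)
            fold_orders.append(np.empty(0, dtype=int))
            continue
        fit = fit_additive_model(haps, y_train, model.marker_indices)
        ve, dropped = _test_variance_explained(haps, y, fit, test_idx)
        n_dropped += dropped
        fold_ve.append(ve)
        fold_fits.append(fit)
        fold_tests.append(test_idx)
        if per_k:
            fold_orders.append(_rank_markers_by_type2(haps, y_train, fit))
        else:
            fold_orders.append(np.arange(len(model.marker_indices)))
    fold_ve = np.array(fold_ve)
    sizes = [len(o) for o in fold_orders]
    k_max = min(sizes) if sizes and min(sizes) > 0 else 0
    per_k_curve = np.zeros(k_max)
    if per_k and k_max:
        for k in range(1, k_max + 1):
            ves = []
            for f in range(k_folds):
                fit = fold_fits[f]
                if fit is None:
                    ves.append(0.0)
                    continue
                top = fit.marker_indices[fold_orders[f][:k]]
                y_train = y.copy()
                y_train[fold_tests[f]] = np.nan
                sub = fit_additive_model(haps, y_train, top)
                ves.append(
                    _test_variance_explained(haps, y, sub, fold_tests[f])[0]
                )
            per_k_curve[k - 1] = float(np.mean(ves))
    return CVResult(
        condition, timepoint, fold_ve, float(fold_ve.mean()),
        float(fold_ve.std(ddof=1) / np.sqrt(len(fold_ve)))
        if len(fold_ve) > 1 else 0.0,
        per_k_curve, None, fold_fits, fold_tests, n_dropped,
    )


# ---------------------------------------------------------------------------
# interaction-extended models


def _interaction_block(labels_s: np.ndarray, labels_t: np.ndarray
                       ) -> np.ndarray:
    """Cell-indicator columns for one marker pair (observed combos)."""
    cell = labels_s.astype(np.int64) * 16 + labels_t
    combos = np.unique(cell)
    return (cell[:, None] == combos[None, :]).astype(float)


def extend_with_interactions(
    cv: CVResult,
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    stop_p: float = 0.001,
) -> CVResult:
    """Greedily add pairwise non-additive terms to each fold's model.

    Within each training fold, every QTL pair's single-interaction
    augmentation of the additive model is ranked by nested ANOVA;
    interactions are added strongest-first until the sequential ANOVA
    improvement is no longer significant, then the test variance is
    recomputed with the extended model.
    """
    y = np.asarray(pheno, dtype=float)
    fold_ve = []
    for f, fit in enumerate(cv.fold_models):
        test_idx = cv.fold_tests[f]
        if fit is None or len(fit.marker_indices) < 2:
            ve = cv.fold_variance[f]
            fold_ve.append(ve)
            continue
        y_train = y.copy()
        y_train[test_idx] = np.nan
        used = fit.used
        yu = y_train[used]
        labels = haps.labels[used][:, fit.marker_indices]
        base_X = fit.X
        k = labels.shape[1]
        pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
        scored = []
        base_beta, _, base_rank, _ = np.linalg.lstsq(base_X, yu, rcond=None)
        base_rss = float(((yu - base_X @ base_beta) ** 2).sum())
        for a, b in pairs:
            block = _interaction_block(labels[:, a], labels[:, b])
            Xa = np.concatenate([base_X, block], axis=1)
            beta, _, rank, _ = np.linalg.lstsq(Xa, yu, rcond=None)
            rss = float(((yu - Xa @ beta) ** 2).sum())
            p = nested_anova_p(base_rss, base_rank, rss, rank, len(yu))
            scored.append((p, (a, b)))
        scored.sort(key=lambda t: t[0])
        X = base_X
        rss_prev, rank_prev = base_rss, base_rank
        chosen = []
        for p_rank, (a, b) in scored:
            block = _interaction_block(labels[:, a], labels[:, b])
            Xa = np.concatenate([X, block], axis=1)
            beta, _, rank, _ = np.linalg.lstsq(Xa, yu, rcond=None)
            rss = float(((yu - Xa @ beta) ** 2).sum())
            p = nested_anova_p(rss_prev, rank_prev, rss, rank, len(yu))
            if p >= stop_p:
                break
            X, rss_prev, rank_prev = Xa, rss, rank
            chosen.append((a, b))
        beta, *_ = np.linalg.lstsq(X, yu, rcond=None)
        # evaluate on the test fold
        y_test = y[test_idx]
        lab_test = haps.labels[test_idx][:, fit.marker_indices]
        ok = np.isfinite(y_test) & (lab_test > 0).all(axis=1)
        pred = np.full(len(test_idx), np.nan)
        cols = [np.ones((int(ok.sum()), 1))]
        sub = lab_test[ok]
        feasible = np.ones(int(ok.sum()), dtype=bool)
        for kk in range(k):
            lab = sub[:, kk]
            known = np.isin(lab, [fit.ref_levels[kk]] + list(fit.col_levels[kk]))
            feasible &= known
            block = np.zeros((len(lab), len(fit.col_levels[kk])))
            for j, lv in enumerate(fit.col_levels[kk]):
                block[:, j] = lab == lv
            cols.append(block)
        for a, b in chosen:
            train_cells = np.unique(
                labels[:, a].astype(np.int64) * 16 + labels[:, b]
            )
            cell = sub[:, a].astype(np.int64) * 16 + sub[:, b]
            feasible &= np.isin(cell, train_cells)
            cols.append((cell[:, None] == train_cells[None, :]).astype(float))
        Xt = np.concatenate(cols, axis=1)
        pred_ok = Xt[feasible] @ beta
        yv = y_test[ok][feasible]
        tss = float(((yv - yv.mean()) ** 2).sum())
        rss = float(((yv - pred_ok) ** 2).sum())
        fold_ve.append(1.0 - rss / tss if tss > 0 else 0.0)
        del pred
    ext_mean = float(np.mean(fold_ve))
    return CVResult(cv.condition, cv.timepoint, cv.fold_variance, cv.mean,
                    cv.se, cv.per_k_curve, ext_mean, cv.fold_models,
                    cv.fold_tests, cv.n_dropped)


# ---------------------------------------------------------------------------
# multimodality


def kmeans_1d_two(values: np.ndarray) -> np.ndarray:
    """Optimal two-cluster split of 1-D values (global 2-means).

    Scans every split of the sorted values and minimizes the total
    within-cluster sum of squares; ties break toward the smallest
    split, which makes the assignment deterministic.
    """
    order = np.argsort(values, kind="stable")
    sv = values[order]
    n = len(sv)
    if n < 2:
        raise ValueError("need >=2 values to split")
    best_cut, best_ss = 1, np.inf
    for cut in range(1, n):
        left, right = sv[:cut], sv[cut:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss, best_cut = ss, cut
    assign = np.empty(n, dtype=int)
    assign[order[:best_cut]] = 0
    assign[order[best_cut:]] = 1
    return assign


def _pooled_design(labels: np.ndarray, focal: int, recode: dict | None
                   ) -> tuple[np.ndarray, list]:
    """Intercept + haplotype-dummy design over complete-label strains.

    ``recode`` optionally maps the focal marker's labels to coarser
    classes.  Returns the design and the column indices belonging to
    the focal marker.
    """
    n, k = labels.shape
    cols = [np.ones((n, 1))]
    focal_cols: list[int] = []
    start = 1
    for j in range(k):
        lab = labels[:, j].astype(int)
        if j == focal and recode is not None:
            lab = np.array([recode[v] for v in lab])
        levels, counts = np.unique(lab, return_counts=True)
        ref = levels[np.argmax(counts)]
        others = [lv for lv in levels if lv != ref]
        block = np.zeros((n, len(others)))
        for c, lv in enumerate(others):
            block[:, c] = lab == lv
        cols.append(block)
        if j == focal:
            focal_cols = list(range(start, start + len(others)))
        start += len(others)
    return np.concatenate(cols, axis=1), focal_cols


@dataclass
class ModalityResult:
    marker: str
    effects: np.ndarray  # (8,) NaN where haplotype count < min_n
    binary_classes: np.ndarray  # (8,) 0/1, -1 where NaN
    mean_ve_full: float
    mean_ve_binary: float
    p_raw: float
    p_holm: float | None = None
    polymodal: bool | None = None
    flags: list = field(default_factory=list)


def multimodality_test(
    model: AdditiveModel,
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    min_n: int = 50,
    n_splits: int = 100,
    seed: int = 0,
    paired: bool = True,
) -> list[ModalityResult]:
    """Allelic-heterogeneity test for each QTL of an additive model.

    The 8 haplotype effect estimates at a QTL (haplotypes with fewer
    than ``min_n`` strains set to missing) are binarized by two-means
    clustering; over random 90:10 train:test splits the additional
    test variance explained (relative to the model lacking the QTL) is
    compared between the full 8-level and the binary encoding with a
    one-sided t-test (paired over splits by default).  Holm correction
    across QTL is applied by :func:`apply_holm`, which callers can use
    to pool QTL across conditions.
    """
    if len(model) == 0:
        raise ValueError("model has no QTL")
    y = np.asarray(pheno, dtype=float)
    rng = np.random.default_rng(seed)
    results: list[ModalityResult] = []
    labels_all = haps.labels[:, model.marker_indices]
    for k, midx in enumerate(model.marker_indices):
        lab_k = labels_all[:, k]
        counts = np.bincount(lab_k[lab_k > 0], minlength=9)[1:]
        effects = model.effects[k].copy()
        effects[counts < min_n] = np.nan
        obs = np.flatnonzero(~np.isnan(effects))
        if len(obs) < 2:
            results.append(ModalityResult(
                model.marker_ids[k], effects, np.full(8, -1), 0.0, 0.0, 1.0,
                flags=["untestable_fewer_than_2_haplotypes"],
            ))
            continue
        assign = kmeans_1d_two(effects[obs])
        classes = np.full(8, -1)
        classes[obs] = assign
        # strains usable for this QTL's comparison: labels complete at all
        # model markers, focal haplotype not rare-masked
        usable = np.isfinite(y) & (labels_all > 0).all(axis=1)
        usable &= np.isin(lab_k, obs + 1)
        idx = np.flatnonzero(usable)
        recode_map = {h + 1: c for h, c in zip(obs, assign)}
        # design matrices built once over the usable strains; per split
        # the train-set normal equations come from subtracting the test
        # block, which keeps the 100-split loop cheap
        X_full, focal_cols = _pooled_design(labels_all[idx], k, None)
        X_bin, _ = _pooled_design(labels_all[idx], k, recode_map)
        X_null = np.delete(X_full, focal_cols, axis=1)
        yv = y[idx]
        designs = (X_full, X_bin, X_null)
        xtx_all = [X.T @ X for X in designs]
        xty_all = [X.T @ yv for X in designs]
        dv_full = np.empty(n_splits)
        dv_bin = np.empty(n_splits)
        n_test = max(1, int(round(0.1 * len(idx))))
        for s in range(n_splits):
            perm = rng.permutation(len(idx))
            test_rows, train_rows = perm[:n_test], perm[n_test:]
            yt = yv[test_rows]
            tss = float(((yt - yt.mean()) ** 2).sum())
            ves = []
            for X, xtx, xty in zip(designs, xtx_all, xty_all):
                Xt = X[test_rows]
                xtx_tr = xtx - Xt.T @ Xt
                xty_tr = xty - Xt.T @ yt
                beta, *_ = np.linalg.lstsq(xtx_tr, xty_tr, rcond=None)
                rss = float(((yt - Xt @ beta) ** 2).sum())
                ves.append(1.0 - rss / tss if tss > 0 else 0.0)
            dv_full[s] = ves[0] - ves[2]
            dv_bin[s] = ves[1] - ves[2]
        if paired:
            t_res = stats.ttest_rel(dv_full, dv_bin, alternative="greater")
        else:
            t_res = stats.ttest_ind(dv_full, dv_bin, alternative="greater")
        p_raw = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0
        results.append(ModalityResult(
            model.marker_ids[k], effects, classes,
            float(dv_full.mean()), float(dv_bin.mean()), p_raw,
        ))
    return apply_holm(results)


def apply_holm(results: list, alpha: float = 0.05) -> list:
    """Holm step-down adjustment over a pooled set of modality results."""
    from statsmodels.stats.multitest import multipletests

    testable = [r for r in results if not r.flags]
    if testable:
        reject, p_adj, *_ = multipletests(
            [r.p_raw for r in testable], alpha=alpha, method="holm"
        )
        for r, rej, p in zip(testable, reject, p_adj):
            r.p_holm = float(p)
            r.polymodal = bool(rej)
    for r in results:
        if r.flags:
            r.p_holm = None
            r.polymodal = None
    return results


# ---------------------------------------------------------------------------
# pleiotropy


@dataclass
class PleiotropyResult:
    per_condition_counts: dict
    n_permutations: int
    null_distribution: np.ndarray
    quantile95: int
    significant_genes: list

    def to_dict(self) -> dict:
        return {
            "per_condition_counts": dict(self.per_condition_counts),
            "n_permutations": self.n_permutations,
            "quantile95": self.quantile95,
            "significant_genes": list(self.significant_genes),
        }


def pleiotropy_permutation(
    gene_sets: dict,
    gene_universe: int,
    n_perm: int = 10_000,
    seed: int = 0,
    level: float = 0.05,
) -> PleiotropyResult:
    """Permutation test for genes shared across condition gene lists.

    Each permutation redraws every condition's single-gene list
    uniformly without replacement from the gene universe (sizes
    preserved) and records the maximum number of conditions sharing a
    gene.  The 95% quantile of this null (the smallest count whose
    cumulative null probability reaches 95%) sets the significance
    cutoff; observed genes shared by more conditions are reported.
    """
    sizes = {c: len(set(g)) for c, g in gene_sets.items()}
    if gene_universe < max(sizes.values(), default=0):
        raise ValueError("gene universe smaller than a per-condition list")
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.int64)
    active = [n for n in sizes.values() if n > 0]
    for b in range(n_perm):
        counts = np.zeros(gene_universe, dtype=np.int16)
        for n_genes in active:
            pick = rng.choice(gene_universe, size=n_genes, replace=False)
            counts[pick] += 1
        null[b] = counts.max() if active else 0
    cum = np.cumsum(np.bincount(null)) / n_perm
    quantile = int(np.searchsorted(cum, 1.0 - level))
    share: dict = {}
    for c, genes in gene_sets.items():
        for g in set(genes):
            share[g] = share.get(g, 0) + 1
    significant = sorted(g for g, k in share.items() if k > quantile)
    return PleiotropyResult(sizes, n_perm, null, quantile, significant)


# ---------------------------------------------------------------------------
# haplotype effect-profile PCA


def effect_profile_pca(effect_matrix: np.ndarray,
                       condition_names: list | None = None) -> np.ndarray:
    """Variance fractions of PCs of row-standardized effect profiles.

    Rows are conditions, columns haplotypes; each row is standardized
    to zero mean and unit variance, then the fractions are the squared
    singular values of the standardized matrix over their sum.
    """
    E = np.asarray(effect_matrix, dtype=float)
    if E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("need >=2 conditions and >=2 haplotypes")
    sd = E.std(axis=1, ddof=1)
    if (sd == 0).any():
        which = int(np.flatnonzero(sd == 0)[0])
        name = (condition_names[which] if condition_names
                else f"row {which}")
        raise ValueError(f"constant effect profile for {name}")
    S = (E - E.mean(axis=1, keepdims=True)) / sd[:, None]
    sv = np.linalg.svd(S, compute_uv=False)
    frac = sv**2 / (sv**2).sum()
    return frac
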