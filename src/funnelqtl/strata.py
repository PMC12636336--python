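"""Allele-dependent stratification analyses.

A few master loci can place strains into subpopulations with distinct
genetic architectures.  This module defines subgroups by haplotype at
a master locus (excluding strains whose flanking markers disagree —
a crossover makes the defining haplotype ambiguous), runs
subgroup-restricted scans with their own permutation thresholds,
estimates per-locus variance within subgroups over random splits,
compares global versus subgroup-specific additive models, and tests
higher-order interaction structure among a small set of loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import HaplotypeMatrix
from .linkscan import ScanProfile, ThresholdResult, single_marker_scan, \
    scan_max_lod
from .qtlmodel import fit_additive_model, forward_select, nested_anova_p


@dataclass
class SubgroupSpec:
    """Subgroup membership rule at a master locus.

    Strains belong when their label at the defining marker is in
    ``labels`` and, if a flanking pair is given, the labels at the two
    flanking markers agree (and are not missing).  ``exclude_strains``
    optionally removes named strains (e.g. members of other subgroups).
    """

    name: str
    marker: str  # defining marker id
    labels: frozenset  # required haplotype labels
    flank: tuple | None = None  # (marker_id, marker_id) bracketing the locus
    exclude_strains: frozenset | None = None

    def __post_init__(self) -> None:
        self.labels = frozenset(int(v) for v in self.labels)


def define_subgroup(haps: HaplotypeMatrix, spec: SubgroupSpec
                    ) -> tuple[np.ndarray, int]:
    """Strain indices in the subgroup and the count excluded as ambiguous."""
    lab = haps.column(spec.marker)
    member = np.isin(lab, list(spec.labels))
    ambiguous = np.zeros(haps.n_strains, dtype=bool)
    if spec.flank is not None:
        f1 = haps.column(spec.flank[0])
        f2 = haps.column(spec.flank[1])
        ambiguous = (f1 != f2) | (f1 == 0) | (f2 == 0)
    if spec.exclude_strains:
        member &= ~np.isin(haps.strains, list(spec.exclude_strains))
    members = np.flatnonzero(member & ~ambiguous)
    n_excluded = int((member & ambiguous).sum())
    if len(members) == 0:
        warnings.warn(f"subgroup {spec.name!r} is empty")
    return members, n_excluded


def subgroup_scan(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    strains: np.ndarray,
    n_perm: int = 1000,
    level: float = 0.01,
    seed: int = 0,
    min_size: int = 100,
    marker_indices: np.ndarray | None = None,
) -> tuple[ScanProfile, ThresholdResult]:
    """Scan restricted to a subgroup plus its own permutation threshold.

    The threshold is the (1-level) quantile of genome-wide maximum LOD
    over permutations of the single phenotype of interest.
    """
    strains = np.asarray(strains, dtype=np.intp)
    if len(strains) < min_size:
        raise ValueError(
            f"subgroup of {len(strains)} below minimum {min_size}"
        )
    y = np.asarray(pheno, dtype=float)
    sub = haps.subset_strains(strains)
    ys = y[strains]
    keep = np.isfinite(ys)
    sub, ys = sub.subset_strains(np.flatnonzero(keep)), ys[keep]
    profile = single_marker_scan(sub, ys, marker_indices=marker_indices)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        maxima[b] = scan_max_lod(sub, ys[rng.permutation(len(ys))],
                                 marker_indices=marker_indices)
    thr = ThresholdResult("FWER", level,
                          float(np.quantile(maxima, 1.0 - level)),
                          maxima, n_perm, seed)
    return profile, thr


def locus_variance_in_subgroup(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    strains: np.ndarray,
    marker: str,
    n_splits: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SE of test variance explained by one marker over splits."""
    y = np.asarray(pheno, dtype=float)
    j = haps.markers.index_of(marker)
    strains = np.asarray(strains, dtype=np.intp)
    ok = strains[np.isfinite(y[strains]) & (haps.labels[strains, j] > 0)]
    if len(np.unique(haps.labels[ok, j])) < 2:
        warnings.warn(f"marker {marker!r} monomorphic in subgroup")
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    ves = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(ok)
        n_test = max(1, int(round(0.1 * len(ok))))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        y_train = np.full(y.shape, np.nan)
        y_train[train_idx] = y[train_idx]
        fit = fit_additive_model(haps, y_train, np.array([j]))
        from .archstats import _test_variance_explained

        ves[s] = _test_variance_explained(haps, y, fit, test_idx)[0]
    return float(ves.mean()), float(ves.std(ddof=1) / np.sqrt(n_splits))


@dataclass
class SubgroupComparison:
    """Global vs subgroup-specific model performance on subgroup test sets."""

    names: list
    null_resid_var: dict  # name -> per-split test residual variance
    subgroup_resid_var: dict
    global_resid_var: dict
    pct_change_subgroup: dict  # mean % change vs null (negative = better)
    pct_change_global: dict
    se_subgroup: dict
    se_global: dict
    p_global_vs_null: dict  # paired t-test over splits

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "pct_change_subgroup": self.pct_change_subgroup,
            "pct_change_global": self.pct_change_global,
            "se_subgroup": self.se_subgroup,
            "se_global": self.se_global,
            "p_global_vs_null": self.p_global_vs_null,
        }


def _predict(haps, fit, idx):
    """Model predictions for strains idx; NaN where infeasible."""
    labels = haps.labels[idx][:, fit.marker_indices]
    pred = np.full(len(idx), fit.intercept)
    ok = (labels > 0).all(axis=1)
    for k in range(labels.shape[1]):
        lab = fit.marker_classes(k, labels[:, k])
        known = np.isin(lab, [fit.ref_levels[k]] + list(fit.col_levels[k]))
        ok &= known
        for j, lv in enumerate(fit.col_levels[k]):
            pred += np.where(lab == lv, fit.beta[fit.col_slices[k]][j], 0.0)
    pred[~ok] = np.nan
    return pred


def compare_global_vs_subgroup(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    subgroups: dict,
    n_splits: int = 100,
    seed: int = 0,
    lod_threshold: float = 9.0,
    marker_indices: np.ndarray | None = None,
) -> SubgroupComparison:
    """Fit global (pooled-train) and per-subgroup additive models per split.

    ``subgroups`` maps name -> strain index array (disjoint).  Per
    split each subgroup is partitioned 90:10; a subgroup model, a null
    (train-mean) model, and a global model fit on the pooled training
    strains are all evaluated on each subgroup's test strains as
    residual variance about the prediction; percent changes are
    relative to the null model.
    """
    y = np.asarray(pheno, dtype=float)
    names = list(subgroups)
    all_idx = np.concatenate([np.asarray(v, dtype=np.intp)
                              for v in subgroups.values()])
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("subgroups must be disjoint")
    rng = np.random.default_rng(seed)
    rv_null = {n: np.empty(n_splits) for n in names}
    rv_sub = {n: np.empty(n_splits) for n in names}
    rv_glob = {n: np.empty(n_splits) for n in names}
    for s in range(n_splits):
        train_parts, test_parts = {}, {}
        for name in names:
            idx = np.asarray(subgroups[name], dtype=np.intp)
            idx = idx[np.isfinite(y[idx])]
            perm = rng.permutation(idx)
            n_test = max(1, int(round(0.1 * len(idx))))
            test_parts[name] = perm[:n_test]
            train_parts[name] = perm[n_test:]
        pooled_train = np.concatenate([train_parts[n] for n in names])
        y_pool = np.full(y.shape, np.nan)
        y_pool[pooled_train] = y[pooled_train]
        global_model = forward_select(haps, y_pool,
                                      marker_indices=marker_indices,
                                      lod_threshold=lod_threshold)
        global_fit = (fit_additive_model(haps, y_pool,
                                         global_model.marker_indices)
                      if len(global_model) else None)
        for name in names:
            y_train = np.full(y.shape, np.nan)
            y_train[train_parts[name]] = y[train_parts[name]]
            sub_model = forward_select(haps, y_train,
                                       marker_indices=marker_indices,
                                       lod_threshold=lod_threshold)
            sub_fit = (fit_additive_model(haps, y_train,
                                          sub_model.marker_indices)
                       if len(sub_model) else None)
            t_idx = test_parts[name]
            yt = y[t_idx]
            train_mean = float(np.nanmean(y[train_parts[name]]))
            rv_null[name][s] = float(np.mean((yt - train_mean) ** 2))
            for fit, store in ((sub_fit, rv_sub), (global_fit, rv_glob)):
                if fit is None:
                    store[name][s] = rv_null[name][s]
                    continue
                pred = _predict(haps, fit, t_idx)
                ok = np.isfinite(pred)
                pred = np.where(ok, pred, train_mean)
                store[name][s] = float(np.mean((yt - pred) ** 2))
    pct_sub, pct_glob, se_sub, se_glob, pvals = {}, {}, {}, {}, {}
    for name in names:
        change_s = 100.0 * (rv_sub[name] - rv_null[name]) / rv_null[name]
        change_g = 100.0 * (rv_glob[name] - rv_null[name]) / rv_null[name]
        pct_sub[name] = float(change_s.mean())
        pct_glob[name] = float(change_g.mean())
        se_sub[name] = float(change_s.std(ddof=1) / np.sqrt(n_splits))
        se_glob[name] = float(change_g.std(ddof=1) / np.sqrt(n_splits))
        pvals[name] = float(
            stats.ttest_rel(rv_glob[name], rv_null[name]).pvalue
        )
    return SubgroupComparison(names, rv_null, rv_sub, rv_glob, pct_sub,
                              pct_glob, se_sub, se_glob, pvals)


def four_way_interaction_test(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    loci: list,
    master: str,
    classes: dict,
) -> float:
    """Nested ANOVA for interactions that involve a discretized master locus.

    ``loci`` are four marker ids including ``master``; ``classes`` maps
    each haplotype label at the master locus to one of two classes.
    The full model fits a mean per observed combination of all four
    factors; the reduced model has an additive master effect plus the
    full interaction among the other three loci.  Returns the F-test
    p-value of full vs reduced.
    """
    y = np.asarray(pheno, dtype=float)
    if master not in loci:
        raise ValueError("master locus must be among the four loci")
    cols = {m: haps.column(m).astype(int) for m in loci}
    master_lab = cols[master]
    master_cls = np.array([classes.get(v, -1) for v in master_lab])
    others = [m for m in loci if m != master]
    ok = np.isfinite(y) & (master_cls >= 0)
    for m in others:
        ok &= cols[m] > 0
    if ok.sum() == 0:
        raise ValueError("no usable strains")
    yv = y[ok]
    mc = master_cls[ok]
    for m in loci:
        vals = (mc if m == master else cols[m][ok])
        if len(np.unique(vals)) < 2:
            raise ValueError(f"locus {m} has a single class among strains")
    three = (cols[others[0]][ok] * 81 + cols[others[1]][ok] * 9
             + cols[others[2]][ok])
    full_cell = three * 2 + mc
    rss_full, rank_full = _cell_means_rss(full_cell, yv)
    three_codes, three_enc = np.unique(three, return_inverse=True)
    X = np.zeros((len(yv), 1 + len(three_codes)))
    X[:, 0] = mc
    X[np.arange(len(yv)), 1 + three_enc] = 1.0
    beta, _, rank_red, _ = np.linalg.lstsq(X, yv, rcond=None)
    rss_red = float(((yv - X @ beta) ** 2).sum())
    n_cells = len(np.unique(full_cell))
    if n_cells < rank_red + 1:
        warnings.warn("sparse factor cells; interaction test has few df")
    return nested_anova_p(rss_red, int(rank_red), rss_full, rank_full,
                          len(yv))


def _cell_means_rss(cell: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    codes, enc = np.unique(cell, return_inverse=True)
    n_c = np.bincount(enc)
    s_c = np.bincount(enc, weights=y)
    rss = float(y @ y - np.sum(s_c * s_c / n_c))
    return max(rss, 0.0), len(codes)


def residualize_on_locus(pheno: np.ndarray, haps: HaplotypeMatrix,
                         marker: str) -> np.ndarray:
    """Residuals from the one-marker haplotype-means model."""
    y = np.asarray(pheno, dtype=float)
    lab = haps.column(marker)
    out = np.full(y.shape, np.nan)
    ok = np.isfinite(y) & (lab > 0)
    if len(np.unique(lab[ok])) < 2:
        out[ok] = y[ok] - y[ok].mean()
        return out
    for h in np.unique(lab[ok]):
        sel = ok & (lab == h)
        out[sel] = y[sel] - y[sel].mean()
    return out
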