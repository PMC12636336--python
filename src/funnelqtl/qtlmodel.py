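"""Forward-selection additive genetic models and QTL fine-mapping.

Model building iterates: scan the current residuals over the scaffold
markers, retain the most significant marker per chromosome if its LOD
reaches the threshold (default 9), refit the joint linear model of the
phenotype on haplotype factors at all selected markers, and stop when
no marker passes or a nested ANOVA against the previous iteration's
model is no longer significant (p > 0.001), in which case the newly
added markers are discarded.

Fine-mapping drops one model marker at a time, restores its fitted
effect contribution to the model residuals, rescans the marker's
chromosome over the full (not just scaffold) marker set, and reports
the peak together with the 2-LOD confidence interval (span of markers
within 2 LOD of the peak) and the variance explained at the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneAnnotation, HaplotypeMatrix
from .linkscan import single_marker_scan


# ---------------------------------------------------------------------------
# joint haplotype-factor linear models


@dataclass
class ModelFit:
    """Joint OLS fit of a phenotype on haplotype factors."""

    marker_indices: np.ndarray
    used: np.ndarray  # boolean mask over strains
    X: np.ndarray
    beta: np.ndarray
    rank: int
    rss: float
    intercept: float
    effects: np.ndarray  # (k, n_founders), reference = 0, unobserved NaN
    col_slices: list  # per-marker slice into X's columns
    col_levels: list  # per-marker list of non-reference levels
    ref_levels: list  # per-marker reference haplotype
    recodes: list | None = None  # per-marker label -> class map (or None)

    def marker_classes(self, k: int, labels: np.ndarray) -> np.ndarray:
        """Labels of marker ``k`` mapped through its recoding (if any).

        Labels absent from the recoding map to -1 (infeasible)."""
        if self.recodes is None or self.recodes[k] is None:
            return labels
        return np.array([self.recodes[k].get(v, -1) for v in labels])

    @property
    def n_used(self) -> int:
        return int(self.used.sum())

    def fitted(self) -> np.ndarray:
        return self.X @ self.beta

    def residuals_full(self, y: np.ndarray) -> np.ndarray:
        """Residuals over all strains, NaN where the strain was unused."""
        out = np.full(y.shape, np.nan)
        out[self.used] = y[self.used] - self.fitted()
        return out

    def contribution(self, k: int) -> np.ndarray:
        """Fitted effect contribution of model marker ``k`` (used strains)."""
        sl = self.col_slices[k]
        return self.X[:, sl] @ self.beta[sl]


def fit_additive_model(
    haps: HaplotypeMatrix,
    y: np.ndarray,
    marker_indices: np.ndarray,
    recodes: list | None = None,
) -> ModelFit:
    """OLS of y on haplotype factors at the given markers.

    Strains with a missing label at any selected marker (or missing
    phenotype) are dropped.  ``recodes`` optionally maps, per marker,
    each haplotype label to a coarser class (e.g. a binary recoding);
    None keeps the full 8-level encoding.
    """
    marker_indices = np.asarray(marker_indices, dtype=np.intp)
    y = np.asarray(y, dtype=float)
    labels = haps.labels[:, marker_indices]
    used = np.isfinite(y) & (labels > 0).all(axis=1)
    if used.sum() == 0:
        raise ValueError("no strains usable for the joint fit")
    sub = labels[used]
    cols = [np.ones((used.sum(), 1))]
    col_slices, col_levels, ref_levels = [], [], []
    start = 1
    for k in range(sub.shape[1]):
        lab = sub[:, k]
        if recodes is not None and recodes[k] is not None:
            lab = np.array([recodes[k][v] for v in lab])
        levels, counts = np.unique(lab, return_counts=True)
        ref = levels[np.argmax(counts)]
        others = [lv for lv in levels if lv != ref]
        block = np.zeros((len(lab), len(others)))
        for j, lv in enumerate(others):
            block[:, j] = lab == lv
        cols.append(block)
        col_slices.append(slice(start, start + len(others)))
        col_levels.append(others)
        ref_levels.append(ref)
        start += len(others)
    X = np.concatenate(cols, axis=1)
    beta, _, rank, _ = np.linalg.lstsq(X, y[used], rcond=None)
    resid = y[used] - X @ beta
    rss = float(resid @ resid)
    n_founders = haps.n_founders
    effects = np.full((len(marker_indices), n_founders), np.nan)
    for k in range(len(marker_indices)):
        lab = sub[:, k]
        if recodes is not None and recodes[k] is not None:
            continue  # recoded markers have no per-founder effects
        observed = np.unique(lab)
        effects[k, observed - 1] = 0.0
        for j, lv in enumerate(col_levels[k]):
            effects[k, lv - 1] = beta[col_slices[k]][j]
    return ModelFit(marker_indices, used, X, beta, int(rank), rss,
                    float(beta[0]), effects, col_slices, col_levels,
                    ref_levels, recodes)


def nested_anova_p(rss_reduced: float, rank_reduced: int, rss_full: float,
                   rank_full: int, n: int) -> float:
    """F-test p-value comparing nested OLS fits on the same strains."""
    df1 = rank_full - rank_reduced
    df2 = n - rank_full
    if df1 <= 0 or df2 <= 0 or rss_full <= 0:
        return 1.0
    f = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    return float(stats.f.sf(max(f, 0.0), df1, df2))


# ---------------------------------------------------------------------------
# forward selection


@dataclass
class AdditiveModel:
    """Ordered set of selected markers with per-haplotype effects."""

    condition: str | None
    timepoint: float | None
    marker_indices: np.ndarray
    marker_ids: list
    effects: np.ndarray  # (k, 8) relative to the model intercept
    intercept: float
    lod_threshold: float
    history: list = field(default_factory=list)
    n_used: int = 0
    rss: float = 0.0
    r2: float = 0.0

    def __len__(self) -> int:
        return len(self.marker_ids)

    def refit(self, haps: HaplotypeMatrix, y: np.ndarray) -> ModelFit:
        return fit_additive_model(haps, y, self.marker_indices)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "timepoint": self.timepoint,
            "markers": list(self.marker_ids),
            "effects": [[None if np.isnan(v) else float(v) for v in row]
                        for row in self.effects],
            "intercept": self.intercept,
            "lod_threshold": self.lod_threshold,
            "history": self.history,
            "n_used": self.n_used,
            "r2": self.r2,
        }


def forward_select(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    marker_indices: np.ndarray | None = None,
    scaffold_only: bool = True,
    lod_threshold: float = 9.0,
    anova_stop_p: float = 0.001,
    max_rounds: int = 50,
    condition: str | None = None,
    timepoint: float | None = None,
) -> AdditiveModel:
    """Iterative forward selection of an additive multi-QTL model."""
    y = np.asarray(pheno, dtype=float)
    if marker_indices is None:
        marker_indices = (
            np.flatnonzero(haps.markers.scaffold)
            if scaffold_only
            else np.arange(len(haps.markers))
        )
    marker_indices = np.asarray(marker_indices, dtype=np.intp)
    chroms = haps.markers.chrom
    selected: list[int] = []
    fit: ModelFit | None = None
    history: list[dict] = []
    resid = y
    for it in range(1, max_rounds + 1):
        candidates = np.array(
            [m for m in marker_indices if m not in selected], dtype=np.intp
        )
        if len(candidates) == 0:
            break
        scan = single_marker_scan(haps, resid, marker_indices=candidates)
        new: list[int] = []
        for chrom in pd.unique(chroms[candidates]):
            on = np.flatnonzero(chroms[candidates] == chrom)
            best = on[np.argmax(scan.lod[on])]
            if scan.lod[best] >= lod_threshold and not scan.single_group[best]:
                new.append(int(candidates[best]))
        if not new:
            break
        trial = selected + new
        new_fit = fit_additive_model(haps, y, np.array(trial))
        if fit is not None:
            prev_on_same = fit_additive_model(
                haps, np.where(new_fit.used, y, np.nan),
                np.array(selected),
            )
            p = nested_anova_p(prev_on_same.rss, prev_on_same.rank,
                               new_fit.rss, new_fit.rank, new_fit.n_used)
        else:
            null_rss = float(np.nansum(
                (y[new_fit.used] - np.nanmean(y[new_fit.used])) ** 2
            ))
            p = nested_anova_p(null_rss, 1, new_fit.rss, new_fit.rank,
                               new_fit.n_used)
        if p > anova_stop_p:
            history.append({"iteration": it, "added": [], "anova_p": p,
                            "note": "improvement not significant; discarded"})
            break
        expected_rank = 1 + sum(len(lv) for lv in new_fit.col_levels)
        if new_fit.rank < expected_rank:
            warnings.warn("collinear haplotype factors in joint refit")
        selected, fit = trial, new_fit
        history.append({
            "iteration": it,
            "added": [haps.markers.ids[m] for m in new],
            "anova_p": p,
        })
        resid = fit.residuals_full(y)
    if fit is None:
        return AdditiveModel(condition, timepoint, np.empty(0, dtype=np.intp),
                             [], np.empty((0, haps.n_founders)), float("nan"),
                             lod_threshold, history)
    yv = y[fit.used]
    tss = float(((yv - yv.mean()) ** 2).sum())
    return AdditiveModel(
        condition, timepoint, fit.marker_indices,
        [haps.markers.ids[m] for m in fit.marker_indices],
        fit.effects, fit.intercept, lod_threshold, history,
        fit.n_used, fit.rss, 1.0 - fit.rss / tss if tss > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# fine mapping


@dataclass
class QTL:
    """A model marker with its fine-mapped peak and confidence interval."""

    source_marker: str
    peak_marker: str
    chrom: str
    peak_pos: int
    peak_lod: float
    ci_start: int
    ci_end: int
    ci_width: int
    var_explained: float
    genes: list | None = None
    flags: list = field(default_factory=list)
    condition: str | None = None


def qtl_table(qtls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": q.condition,
                "marker": q.source_marker,
                "chrom": q.chrom,
                "peak_marker": q.peak_marker,
                "peak_pos": q.peak_pos,
                "peak_lod": q.peak_lod,
                "ci_start": q.ci_start,
                "ci_end": q.ci_end,
                "ci_width": q.ci_width,
                "var_explained": q.var_explained,
                "genes": ";".join(q.genes) if q.genes else "",
                "flags": ";".join(q.flags),
            }
            for q in qtls
        ],
        columns=["condition", "marker", "chrom", "peak_marker", "peak_pos",
                 "peak_lod", "ci_start", "ci_end", "ci_width",
                 "var_explained", "genes", "flags"],
    )


def fine_map(
    model: AdditiveModel,
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    lod_drop: float = 2.0,
) -> list[QTL]:
    """Drop-one rescan of each model marker over the full marker set."""
    y = np.asarray(pheno, dtype=float)
    if len(model) == 0:
        return []
    fit = model.refit(haps, y)
    resid = fit.residuals_full(y)
    qtls: list[QTL] = []
    for k, midx in enumerate(model.marker_indices):
        adjusted = resid.copy()
        adjusted[fit.used] += fit.contribution(k)
        chrom = haps.markers.chrom[midx]
        chrom_idx = haps.markers.chrom_indices(chrom)
        scan = single_marker_scan(haps, adjusted, marker_indices=chrom_idx)
        peak = scan.peak()
        peak_lod = float(scan.lod[peak])
        above = np.flatnonzero(scan.lod >= peak_lod - lod_drop)
        pos = haps.markers.pos[chrom_idx]
        ci_start, ci_end = int(pos[above.min()]), int(pos[above.max()])
        flags = []
        if not np.array_equal(above, np.arange(above.min(), above.max() + 1)):
            flags.append("noncontiguous_ci")
        if peak in (0, len(chrom_idx) - 1):
            flags.append("ci_truncated_at_chromosome_end")
        rss0, rss1 = scan.rss0[peak], scan.rss1[peak]
        ve = float(1.0 - rss1 / rss0) if rss0 > 0 else 0.0
        qtls.append(
            QTL(
                source_marker=haps.markers.ids[midx],
                peak_marker=haps.markers.ids[chrom_idx[peak]],
                chrom=chrom,
                peak_pos=int(pos[peak]),
                peak_lod=peak_lod,
                ci_start=ci_start,
                ci_end=ci_end,
                ci_width=ci_end - ci_start + 1,
                var_explained=ve,
                condition=model.condition,
                flags=flags,
            )
        )
    return qtls


def gene_window(start: int, end: int, strand: str, upstream: int,
                downstream: int) -> tuple[int, int]:
    """Strand-aware promoter-inclusive window around an ORF."""
    if strand == "+":
        return start - upstream, end + downstream
    return start - downstream, end + upstream


def annotate_genes(qtl: QTL, genes: GeneAnnotation, upstream: int = 1000,
                   downstream: int = 500) -> QTL:
    """Attach genes whose strand-aware window intersects the CI (closed)."""
    sub = genes.on_chrom(qtl.chrom)
    hits = []
    for r in sub.itertuples(index=False):
        lo, hi = gene_window(r.start, r.end, r.strand, upstream, downstream)
        if lo <= qtl.ci_end and hi >= qtl.ci_start:
            hits.append((r.start, r.gene))
    qtl.genes = [g for _, g in sorted(hits)]
    return qtl


def refine_across_timepoints(
    qtl72: list, qtl24: list, qtl48: list, max_ci: int = 100_000
) -> list:
    """Shrink 72h gene lists using gene overlap with 24h/48h intervals.

    For each 72h QTL with CI < max_ci, each candidate gene scores
    1 + the number of 24h/48h QTL (also CI < max_ci) whose gene lists
    contain it; the genes with the (co-)highest score are retained.
    """
    other = [q for q in qtl24 + qtl48
             if q.ci_width < max_ci and q.genes is not None]
    refined = []
    for q in qtl72:
        if q.ci_width >= max_ci:
            refined.append(q)
            continue
        if not q.genes:
            q.flags.append("empty_gene_list")
            refined.append(q)
            continue
        counts = {
            g: 1 + sum(g in (o.genes or []) for o in other) for g in q.genes
        }
        top = max(counts.values())
        q.genes = [g for g in q.genes if counts[g] == top]
        refined.append(q)
    return refined
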