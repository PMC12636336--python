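"""Haplotype-based LOD linkage scans and permutation significance.

Single-marker scan: at each marker the null model fits one population
mean and the QTL model fits a separate mean for each of the (up to 8)
founder-haplotype subpopulations observed there;
``LOD = (n/2) * log10(RSS0 / RSS1)`` with n the strains used at that
marker.  Strains with a missing label (or missing phenotype) are
dropped for that marker only and RSS0 is recomputed on the retained
subset, keeping the model comparison nested.

Pairwise interaction scan: for a marker pair the additive model fits
joint main effects of both haplotype factors by least squares and the
full model fits a mean per observed haplotype combination; with
Gaussian profile likelihoods the interaction LOD reduces to
``(n/2) * log10(RSS_additive / RSS_full)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import HaplotypeMatrix, MarkerMap

_CHUNK = 256  # markers per block in the vectorized scan


def _scan_blocks(labels: np.ndarray, Y: np.ndarray, n_founders: int = 8):
    """Vectorized per-marker group statistics.

    labels: (n, m) int with 0 = missing; Y: (n, p) float, NaN-free.
    Returns rss0, rss1 of shape (m, p), n_used (m,), n_groups (m,).
    """
    n, m = labels.shape
    p = Y.shape[1]
    Y2 = Y * Y
    rss0 = np.empty((m, p))
    rss1 = np.empty((m, p))
    n_used = np.empty(m, dtype=np.int64)
    n_groups = np.empty(m, dtype=np.int64)
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        block = labels[:, lo:hi]
        valid = (block > 0).T.astype(np.float64)  # (mb, n)
        nv = valid.sum(axis=1)
        sum_y = valid @ Y
        sum_y2 = valid @ Y2
        with np.errstate(invalid="ignore", divide="ignore"):
            rss0_b = sum_y2 - sum_y * sum_y / nv[:, None]
        explained = np.zeros_like(sum_y)
        groups = np.zeros(hi - lo, dtype=np.int64)
        for h in range(1, n_founders + 1):
            mask = (block == h).T.astype(np.float64)
            nh = mask.sum(axis=1)
            sh = mask @ Y
            nz = nh > 0
            groups += nz
            with np.errstate(invalid="ignore", divide="ignore"):
                contrib = sh * sh / nh[:, None]
            explained[nz] += contrib[nz]
        rss1_b = sum_y2 - explained
        rss0[lo:hi] = np.maximum(rss0_b, 0.0)
        rss1[lo:hi] = np.maximum(rss1_b, 0.0)
        n_used[lo:hi] = nv.astype(np.int64)
        n_groups[lo:hi] = groups
    return rss0, rss1, n_used, n_groups


def lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: np.ndarray
                 ) -> np.ndarray:
    """(n/2) log10(RSS0/RSS1), zero where either RSS degenerates."""
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    n = np.asarray(n, dtype=float)
    out = np.zeros(np.broadcast(rss0, rss1).shape)
    ok = (rss1 > 0) & (rss0 > 0)
    nb = np.broadcast_to(n.reshape(-1, *([1] * (rss0.ndim - 1))), rss0.shape)
    out[ok] = 0.5 * nb[ok] * np.log10(rss0[ok] / rss1[ok])
    return np.maximum(out, 0.0)


@dataclass
class ScanProfile:
    """Per-marker LOD trace with the RSS quantities that define it."""

    markers: MarkerMap
    lod: np.ndarray
    rss0: np.ndarray
    rss1: np.ndarray
    n: np.ndarray
    marker_indices: np.ndarray  # indices into the full marker map
    single_group: np.ndarray  # True where <2 haplotypes observed
    condition: str | None = None
    timepoint: float | None = None

    def peak(self) -> int:
        """Index (into the scanned subset) of the max LOD; first = lowest
        (chromosome, position) wins on ties because markers are sorted."""
        return int(np.argmax(self.lod))

    def peak_marker(self) -> str:
        return self.markers.ids[self.marker_indices[self.peak()]]

    def to_frame(self) -> pd.DataFrame:
        idx = self.marker_indices
        return pd.DataFrame(
            {
                "marker_id": self.markers.ids[idx],
                "chrom": self.markers.chrom[idx],
                "pos": self.markers.pos[idx],
                "lod": self.lod,
                "rss0": self.rss0,
                "rss1": self.rss1,
                "n": self.n,
                "single_group": self.single_group,
            }
        )


def single_marker_scan(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    marker_indices: np.ndarray | None = None,
    scaffold_only: bool = True,
    condition: str | None = None,
    timepoint: float | None = None,
) -> ScanProfile:
    """Eight-haplotype one-way LOD scan of a per-strain phenotype vector."""
    y = np.asarray(pheno, dtype=float)
    if y.shape != (haps.n_strains,):
        raise ValueError("phenotype vector does not match strain count")
    if marker_indices is None:
        marker_indices = (
            np.flatnonzero(haps.markers.scaffold)
            if scaffold_only
            else np.arange(len(haps.markers))
        )
    marker_indices = np.asarray(marker_indices, dtype=np.intp)
    keep = np.isfinite(y)
    labels = haps.labels[keep][:, marker_indices]
    rss0, rss1, n_used, n_groups = _scan_blocks(
        labels, y[keep, None], haps.n_founders
    )
    lod = lod_from_rss(rss0[:, 0], rss1[:, 0], n_used)
    single = n_groups < 2
    lod[single] = 0.0
    return ScanProfile(
        haps.markers, lod, rss0[:, 0], rss1[:, 0], n_used,
        marker_indices, single, condition, timepoint,
    )


def variance_explained_at_marker(profile: ScanProfile, mid: str) -> float:
    """Fraction of phenotypic variance explained at one marker: 1 - RSS1/RSS0."""
    full_idx = profile.markers.index_of(mid)
    where = np.flatnonzero(profile.marker_indices == full_idx)
    if len(where) == 0:
        raise KeyError(f"marker {mid!r} not in scan profile")
    i = int(where[0])
    if profile.rss0[i] <= 0 or profile.single_group[i]:
        return 0.0
    return float(1.0 - profile.rss1[i] / profile.rss0[i])


@dataclass
class ThresholdResult:
    kind: str  # "FWER" or "FDR"
    level: float
    threshold: float
    null_distribution: np.ndarray
    n_permutations: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "level": self.level,
            "threshold": float(self.threshold),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "null_distribution": [float(v) for v in self.null_distribution],
        }


def fwer_threshold(
    haps: HaplotypeMatrix,
    phenos: np.ndarray,
    n_perm: int = 1000,
    level: float = 0.05,
    seed: int = 0,
    marker_indices: np.ndarray | None = None,
    scaffold_only: bool = True,
) -> ThresholdResult:
    """Permutation family-wise error threshold across markers and phenotypes.

    ``phenos`` is (n_strains, n_phenotypes); each permutation shuffles
    which strain's joint phenotype vector is associated with each
    haplotype vector (conditions stay linked), rescans everything, and
    records the global maximum LOD.  The threshold is the (1-level)
    quantile of the permutation maxima.
    """
    Y = np.atleast_2d(np.asarray(phenos, dtype=float))
    if Y.shape[0] != haps.n_strains:
        Y = Y.T
    if Y.shape[0] != haps.n_strains:
        raise ValueError("phenotype matrix does not match strain count")
    if n_perm < 20:
        raise ValueError("need at least 20 permutations for a stable quantile")
    if not np.isfinite(Y).all():
        raise ValueError("permutation scan requires complete phenotypes")
    if marker_indices is None:
        marker_indices = (
            np.flatnonzero(haps.markers.scaffold)
            if scaffold_only
            else np.arange(len(haps.markers))
        )
    labels = haps.labels[:, np.asarray(marker_indices, dtype=np.intp)]
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(haps.n_strains)
        rss0, rss1, n_used, n_groups = _scan_blocks(
            labels, Y[perm], haps.n_founders
        )
        lod = lod_from_rss(rss0, rss1, n_used)
        lod[n_groups < 2] = 0.0
        maxima[b] = lod.max()
    threshold = float(np.quantile(maxima, 1.0 - level))
    return ThresholdResult("FWER", level, threshold, maxima, n_perm, seed)


def scan_max_lod(haps: HaplotypeMatrix, phenos: np.ndarray,
                 marker_indices: np.ndarray | None = None,
                 scaffold_only: bool = True) -> float:
    """Genome-wide maximum LOD over markers and phenotype columns."""
    Y = np.atleast_2d(np.asarray(phenos, dtype=float))
    if Y.shape[0] != haps.n_strains:
        Y = Y.T
    if marker_indices is None:
        marker_indices = (
            np.flatnonzero(haps.markers.scaffold)
            if scaffold_only
            else np.arange(len(haps.markers))
        )
    labels = haps.labels[:, np.asarray(marker_indices, dtype=np.intp)]
    rss0, rss1, n_used, n_groups = _scan_blocks(labels, Y, haps.n_founders)
    lod = lod_from_rss(rss0, rss1, n_used)
    lod[n_groups < 2] = 0.0
    return float(lod.max())


# ---------------------------------------------------------------------------
# pairwise interaction scan


def _pair_rss(gs: np.ndarray, gt: np.ndarray, y: np.ndarray,
              n_founders: int = 8) -> tuple[float, float, int]:
    """(RSS_additive, RSS_full, n) for one marker pair via normal equations.

    The additive model fits both haplotype main effects jointly; the
    full model is the mean per observed (s, t) haplotype combination.
    """
    ok = (gs > 0) & (gt > 0) & np.isfinite(y)
    gs, gt, y = gs[ok] - 1, gt[ok] - 1, y[ok]
    n = y.size
    if n == 0:
        return 0.0, 0.0, 0
    K = n_founders
    cell = gs.astype(np.int64) * K + gt
    n_ab = np.bincount(cell, minlength=K * K).astype(float)
    s_ab = np.bincount(cell, weights=y, minlength=K * K)
    yty = float(y @ y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_means_sq = np.where(n_ab > 0, s_ab * s_ab / n_ab, 0.0)
    rss_full = yty - float(cell_means_sq.sum())
    # additive: columns = indicators of s-levels (K) + t-levels 2..K
    n_a = n_ab.reshape(K, K).sum(axis=1)
    n_b = n_ab.reshape(K, K).sum(axis=0)
    s_a = s_ab.reshape(K, K).sum(axis=1)
    s_b = s_ab.reshape(K, K).sum(axis=0)
    xtx = np.zeros((2 * K - 1, 2 * K - 1))
    xty = np.zeros(2 * K - 1)
    xtx[:K, :K] = np.diag(n_a)
    xtx[K:, K:] = np.diag(n_b[1:])
    cross = n_ab.reshape(K, K)[:, 1:]
    xtx[:K, K:] = cross
    xtx[K:, :K] = cross.T
    xty[:K] = s_a
    xty[K:] = s_b[1:]
    beta, *_ = np.linalg.lstsq(xtx, xty, rcond=None)
    rss_add = yty - float(beta @ xty)
    return max(rss_add, 0.0), max(rss_full, 0.0), n


@dataclass
class InteractionScan:
    """Interaction LOD for marker pairs: improvement of full over additive."""

    markers: MarkerMap
    pair_indices: np.ndarray  # (n_pairs, 2) indices into the marker map
    lod_i: np.ndarray
    n: np.ndarray
    rss_additive: np.ndarray | None = None
    rss_full: np.ndarray | None = None
    condition: str | None = None
    timepoint: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_s": self.markers.ids[self.pair_indices[:, 0]],
                "marker_t": self.markers.ids[self.pair_indices[:, 1]],
                "lod_i": self.lod_i,
                "rss_additive": self.rss_additive,
                "rss_full": self.rss_full,
                "n": self.n,
            }
        )


def candidate_pairs(markers: MarkerMap, marker_indices: np.ndarray,
                    min_intra_distance: float | None = None) -> np.ndarray:
    """All marker pairs; by default inter-chromosomal pairs plus
    intra-chromosomal pairs at least ``min_intra_distance`` apart
    (intra pairs are excluded entirely when it is None), since linkage
    inflates short-range interaction statistics."""
    idx = np.asarray(marker_indices, dtype=np.intp)
    chroms = markers.chrom[idx]
    pos = markers.pos[idx]
    ii, jj = np.triu_indices(len(idx), k=1)
    inter = chroms[ii] != chroms[jj]
    if min_intra_distance is None:
        keep = inter
    else:
        keep = inter | (np.abs(pos[ii] - pos[jj]) >= min_intra_distance)
    return np.stack([idx[ii[keep]], idx[jj[keep]]], axis=1)


def pairwise_interaction_scan(
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    marker_indices: np.ndarray | None = None,
    pairs: np.ndarray | None = None,
    min_intra_distance: float | None = None,
    condition: str | None = None,
    timepoint: float | None = None,
) -> InteractionScan:
    """Interaction LOD for every candidate marker pair."""
    y = np.asarray(pheno, dtype=float)
    if marker_indices is None:
        marker_indices = np.flatnonzero(haps.markers.scaffold)
    if pairs is None:
        pairs = candidate_pairs(haps.markers, marker_indices,
                                min_intra_distance)
    lod_i = np.empty(len(pairs))
    n_arr = np.empty(len(pairs), dtype=np.int64)
    rss_a_arr = np.empty(len(pairs))
    rss_f_arr = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        rss_a, rss_f, n = _pair_rss(
            haps.labels[:, i], haps.labels[:, j], y, haps.n_founders
        )
        n_arr[k] = n
        rss_a_arr[k], rss_f_arr[k] = rss_a, rss_f
        lod_i[k] = lod_from_rss(
            np.array([rss_a]), np.array([rss_f]), np.array([n])
        )[0]
    return InteractionScan(haps.markers, np.asarray(pairs), lod_i, n_arr,
                           rss_a_arr, rss_f_arr, condition, timepoint)


def _additive_residuals(gs, gt, y, n_founders=8):
    """Residuals of the joint two-factor additive fit (NaN where invalid)."""
    ok = (gs > 0) & (gt > 0) & np.isfinite(y)
    K = n_founders
    res = np.full(y.shape, np.nan)
    if not ok.any():
        return res
    a = np.eye(K)[gs[ok] - 1]
    b = np.eye(K)[gt[ok] - 1][:, 1:]
    X = np.concatenate([a, b], axis=1)
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    res[ok] = y[ok] - X @ beta
    return res


def interaction_fdr_threshold(
    scan: InteractionScan,
    haps: HaplotypeMatrix,
    pheno: np.ndarray,
    level: float = 0.01,
    seed: int = 0,
) -> ThresholdResult:
    """Empirical FDR threshold for the pairwise interaction scan.

    For each pair the additive-model residuals are permuted once
    (a fresh permutation per pair) and the interaction LOD of the
    permuted phenotype forms the null; the threshold is the smallest
    tau with (#null >= tau) / (#observed >= tau) <= level.
    """
    if len(scan.pair_indices) == 0:
        raise ValueError("empty interaction scan")
    y = np.asarray(pheno, dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty(len(scan.pair_indices))
    for k, (i, j) in enumerate(scan.pair_indices):
        gs, gt = haps.labels[:, i], haps.labels[:, j]
        res = _additive_residuals(gs, gt, y, haps.n_founders)
        ok = np.isfinite(res)
        perm_res = res.copy()
        perm_res[ok] = res[ok][rng.permutation(ok.sum())]
        rss_a, rss_f, n = _pair_rss(gs, gt, perm_res, haps.n_founders)
        null[k] = lod_from_rss(
            np.array([rss_a]), np.array([rss_f]), np.array([n])
        )[0]
    obs_sorted = np.sort(scan.lod_i)
    null_sorted = np.sort(null)
    taus = np.unique(obs_sorted)
    n_obs = len(obs_sorted) - np.searchsorted(obs_sorted, taus, "left")
    n_null = len(null_sorted) - np.searchsorted(null_sorted, taus, "left")
    ok = n_null / n_obs <= level
    threshold = float(taus[ok].min()) if ok.any() else np.inf
    if not np.isfinite(threshold):
        warnings.warn("no interaction exceeds the FDR threshold")
    return ThresholdResult("FDR", level, threshold, null,
                           len(scan.pair_indices), seed)
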