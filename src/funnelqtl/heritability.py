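"""Broad- and narrow-sense heritability for the haploid mapping panel.

Broad sense: H2 = 1 - sigma2_e / sigma2_s, where sigma2_s is the
variance of the population of strain means and sigma2_e is the
sampling variance of those means, obtained from the residual variance
of a one-way random-effects model (strain random intercept, REML)
divided by the harmonic-mean replicate count.

Narrow sense: a single-variance-component mixed model
y = mu + g + e with g ~ (0, K Va), e ~ (0, I Ve); the restricted
likelihood is maximized over the variance ratio via the spectral
decomposition of the genomic relationship matrix, and
h2 = Va / (Va + Ve).  K is the haploid VanRaden-style matrix
Z Z' / sum p(1-p) built from 0/1 allele calls recovered from founder
labels, column-centered by allele frequency, with missing calls
mean-imputed per marker.  The standard error comes from a bootstrap
over strains that re-uses the marker-space decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dataio import HaplotypeMatrix, PhenotypeTable


@dataclass
class HeritabilityEstimate:
    H2: float | None = None
    sigma2_s: float | None = None
    sigma2_e: float | None = None
    h2: float | None = None
    Va: float | None = None
    Ve: float | None = None
    se_h2: float | None = None
    n_bootstrap: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def broad_sense_h2(replicates: PhenotypeTable, condition: str | None = None,
                   timepoint=None) -> HeritabilityEstimate:
    """Broad-sense heritability from replicate-level measurements."""
    df = replicates.frame
    if condition is not None:
        df = df[df["condition"] == condition]
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    df = df.dropna(subset=["value"])
    counts = df.groupby("strain")["value"].count()
    multi = counts[counts >= 2]
    if len(multi) < 2:
        raise ValueError(
            "sigma2_e not estimable: need >=2 strains with >=2 replicates"
        )
    resid_var = _oneway_reml_residual_variance(df)
    harm = len(counts) / np.sum(1.0 / counts.to_numpy())
    sigma2_e = resid_var / harm
    means = df.groupby("strain")["value"].mean()
    sigma2_s = float(means.var(ddof=1))
    H2 = 1.0 - sigma2_e / sigma2_s
    if H2 <= 0:
        warnings.warn("H2 <= 0: strain means indistinguishable from noise")
    return HeritabilityEstimate(H2=float(H2), sigma2_s=sigma2_s,
                                sigma2_e=float(sigma2_e))


def _oneway_reml_residual_variance(df: pd.DataFrame) -> float:
    """REML residual variance of a strain-random-intercept model."""
    import statsmodels.formula.api as smf

    sub = df[["strain", "value"]].copy()
    if sub.groupby("strain")["value"].var(ddof=1).fillna(0.0).max() == 0.0:
        return 0.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ 1", sub, groups=sub["strain"])
            fit = model.fit(reml=True, method="lbfgs")
        return float(fit.scale)
    except np.linalg.LinAlgError:
        # degenerate strain variance (e.g. no between-strain signal):
        # fall back to the pooled within-strain variance, which is the
        # REML residual variance in the balanced case
        n = len(sub)
        k = sub["strain"].nunique()
        within_ss = (
            sub.groupby("strain")["value"]
            .apply(lambda v: ((v - v.mean()) ** 2).sum())
            .sum()
        )
        return float(within_ss / (n - k))


@dataclass
class GRM:
    """Additive genomic relationship matrix with its marker-space factor."""

    strains: np.ndarray
    Z: np.ndarray  # centered allele matrix, (n, m)
    scale: float  # sum over markers of p(1-p)

    @property
    def K(self) -> np.ndarray:
        return (self.Z @ self.Z.T) / self.scale

    def check_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -tol * max(w.max(), 1.0):
            raise ValueError(
                "GRM not positive semidefinite; add diagonal jitter"
            )


def haplotypes_to_alleles(haps: HaplotypeMatrix, founder_alleles: np.ndarray,
                          marker_indices: np.ndarray | None = None
                          ) -> np.ndarray:
    """Convert founder labels back to biallelic calls; NaN where missing.

    ``founder_alleles`` is (n_markers_total, n_founders) in {0, 1}.
    """
    if marker_indices is None:
        marker_indices = np.arange(len(haps.markers))
    labels = haps.labels[:, marker_indices]
    fa = np.asarray(founder_alleles, dtype=float)[marker_indices]
    picked = fa[np.arange(len(marker_indices))[None, :],
                np.maximum(labels - 1, 0)]
    return np.where(labels > 0, picked, np.nan)


def compute_grm(haps: HaplotypeMatrix, founder_alleles: np.ndarray,
                scaffold_only: bool = True) -> GRM:
    """GRM from founder labels converted to major/minor allele calls."""
    idx = (
        np.flatnonzero(haps.markers.scaffold)
        if scaffold_only
        else np.arange(len(haps.markers))
    )
    labels = haps.labels[:, idx]
    fa = np.asarray(founder_alleles, dtype=float)[idx]  # (m, n_founders)
    calls = np.where(labels > 0, fa[np.arange(len(idx)), labels - 1], np.nan)
    freq1 = np.nanmean(calls, axis=0)
    # major allele coded 1 (ties: allele 1 is major)
    calls = np.where(freq1[None, :] >= 0.5, calls, 1.0 - calls)
    p = np.nanmean(calls, axis=0)
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} monomorphic markers from GRM")
    calls, p = calls[:, poly], p[poly]
    Z = np.where(np.isnan(calls), 0.0, calls - p[None, :])
    scale = float(np.sum(p * (1.0 - p)))
    return GRM(haps.strains.copy(), Z, scale)


def _reml_profile(ytil, xtil, d, extra_ss_y=0.0, extra_ss_x=0.0,
                  extra_cross=0.0, extra_n=0):
    """Restricted log-likelihood profiled over the mean and Ve.

    ytil, xtil, d: rotated phenotype, rotated intercept and GRM
    eigenvalues for the explicitly represented spectral components;
    the extra_* terms carry the zero-eigenvalue complement in sum form.
    """
    n = len(d) + extra_n

    def negloglik(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = delta * d + 1.0
        xwx = np.sum(xtil * xtil / w) + extra_ss_x
        xwy = np.sum(xtil * ytil / w) + extra_cross
        ywy = np.sum(ytil * ytil / w) + extra_ss_y
        beta = xwy / xwx
        rss = ywy - beta * xwy
        if rss <= 0:
            return np.inf
        ve = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2.0 * np.pi * ve)
            + np.sum(np.log(w))
            + np.log(xwx)
            + (n - 1)
        )
        return -ll

    return negloglik


def narrow_sense_h2(pheno: np.ndarray, grm: GRM, n_bootstrap: int = 100,
                    seed: int = 0) -> HeritabilityEstimate:
    """REML narrow-sense heritability with a strain-bootstrap SE."""
    y = np.asarray(pheno, dtype=float)
    if y.shape != (len(grm.strains),):
        raise ValueError("phenotype does not match GRM strains")
    if np.isnan(y).any():
        raise ValueError("missing phenotypes among GRM strains")

    def fit_one(Z: np.ndarray, yv: np.ndarray) -> tuple[float, float, float]:
        n, m = Z.shape
        if m < n:
            # marker-space eigendecomposition: K = Z Z'/c has rank <= m
            G = (Z.T @ Z) / grm.scale
            w, V = np.linalg.eigh(G)
            w = np.maximum(w, 0.0)
            keep = w > 1e-12 * max(w.max(), 1.0)
            w, V = w[keep], V[:, keep]
            U = (Z @ V) / (np.sqrt(w * grm.scale)[None, :])
            ytil = U.T @ yv
            xtil = U.T @ np.ones(n)
            extra_ss_y = float(yv @ yv - ytil @ ytil)
            extra_ss_x = float(n - xtil @ xtil)
            extra_cross = float(yv.sum() - xtil @ ytil)
            neg = _reml_profile(ytil, xtil, w, extra_ss_y, extra_ss_x,
                                extra_cross, n - len(w))
        else:
            K = (Z @ Z.T) / grm.scale
            w, U = np.linalg.eigh(K)
            w = np.maximum(w, 0.0)
            neg = _reml_profile(U.T @ yv, U.T @ np.ones(n), w)
        res = minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                              options={"xatol": 1e-8})
        candidates = [(-30.0, neg(-30.0)), (res.x, res.fun)]
        log_delta = min(candidates, key=lambda t: t[1])[0]
        delta = np.exp(log_delta)
        # recover Va, Ve at the optimum
        if m < n:
            wfull = w
            ytil_, xtil_ = ytil, xtil
            wvec = delta * wfull + 1.0
            xwx = np.sum(xtil_ * xtil_ / wvec) + extra_ss_x
            xwy = np.sum(xtil_ * ytil_ / wvec) + extra_cross
            ywy = np.sum(ytil_ * ytil_ / wvec) + extra_ss_y
        else:
            ytil_, xtil_ = U.T @ yv, U.T @ np.ones(n)
            wvec = delta * w + 1.0
            xwx = np.sum(xtil_ * xtil_ / wvec)
            xwy = np.sum(xtil_ * ytil_ / wvec)
            ywy = np.sum(ytil_ * ytil_ / wvec)
        beta = xwy / xwx
        ve = max((ywy - beta * xwy) / (n - 1), 0.0)
        va = delta * ve
        return va, ve, va / (va + ve) if (va + ve) > 0 else 0.0

    va, ve, h2 = fit_one(grm.Z, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    n = len(y)
    for b in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        boots[b] = fit_one(grm.Z[take], y[take])[2]
    return HeritabilityEstimate(
        h2=float(h2), Va=float(va), Ve=float(ve),
        se_h2=float(np.std(boots, ddof=1)), n_bootstrap=n_bootstrap,
    )


def reml_h2_grid(pheno: np.ndarray, K: np.ndarray,
                 grid: np.ndarray | None = None) -> float:
    """Brute-force grid maximizer of the restricted likelihood over h2.

    Independent check of the spectral optimizer on small instances.
    """
    y = np.asarray(pheno, dtype=float)
    n = len(y)
    ones = np.ones(n)
    if grid is None:
        grid = np.arange(0.0, 1.0001, 0.01)
    best_h2, best_val = 0.0, np.inf
    for h2 in grid:
        if h2 >= 1.0:
            continue
        delta = h2 / (1.0 - h2) if h2 > 0 else 1e-13
        V = delta * K + np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, ones)
        xwx = ones @ Vinv_1
        beta = (ones @ Vinv_y) / xwx
        r = y - beta
        rss = r @ np.linalg.solve(V, r)
        ve = rss / (n - 1)
        negll = 0.5 * ((n - 1) * np.log(2 * np.pi * ve) + logdet
                       + np.log(xwx) + (n - 1))
        if negll < best_val:
            best_h2, best_val = h2, negll
    return float(best_h2)
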