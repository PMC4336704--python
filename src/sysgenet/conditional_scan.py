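"""Conditional association and genotype x genotype interaction scanning.

Two-stage epistasis search around known loci: first a polygenic mixed model
``y = mu + sex + batch + g_A + g_B + polygenic(K) + e`` absorbs the two
conditioning loci and the kinship; then, per genome SNP g, the residual e
is regressed on {g, g x g_cond} by ordinary least squares.  The joint
2-degree-of-freedom F test of both terms ranks loci; the interaction-only
t test is reported alongside.  SNPs within an exclusion window around the
conditioning markers are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import (
    MISSING,
    GenotypeMatrix,
    KinshipMatrix,
    NullModelFit,
    fit_polygenic_null,
)

__all__ = ["ConditionalFit", "InteractionScanResult", "fit_conditional_null", "interaction_scan"]


@dataclass
class ConditionalFit:
    """Mixed-model fit conditioning on two named markers; carries residuals."""

    marker_a: str
    marker_b: str
    null_fit: NullModelFit
    residuals: np.ndarray     # y - X beta - BLUP(u), zero mean
    samples: list


@dataclass
class InteractionScanResult:
    """Per-SNP joint (genotype + interaction) and interaction-only p-values."""

    table: pd.DataFrame  # columns: snp, chrom, pos, joint_p, interaction_p, cond_marker
    cond_marker: str

    def __post_init__(self):
        for col in ("joint_p", "interaction_p"):
            p = self.table[col].to_numpy()
            if len(p) and ((p <= 0) | (p > 1)).any():
                raise ValueError(f"{col} outside (0, 1]")


def _dosage(genotypes: GenotypeMatrix, snp_id: str) -> np.ndarray:
    g = genotypes.dosage_of(snp_id)
    if np.isnan(g).all() or np.nanvar(g) == 0:
        raise ValueError(f"conditioning marker {snp_id!r} is monomorphic")
    return np.where(np.isnan(g), np.nanmean(g), g)


def fit_conditional_null(
    phenotype,
    covariates: pd.DataFrame | None,
    kinship: KinshipMatrix,
    genotypes: GenotypeMatrix,
    marker_a: str,
    marker_b: str,
) -> ConditionalFit:
    """Fit ``y = mu + covariates + g_A + g_B + polygenic(K) + e``.

    The additive dosages of the two conditioning markers enter as fixed
    effects; the returned residuals subtract fixed effects and the
    polygenic BLUP, leaving the noise the interaction scan models.
    Symmetric in (A, B).
    """
    ga = _dosage(genotypes, marker_a)
    gb = _dosage(genotypes, marker_b)
    cov = pd.DataFrame(index=range(len(ga)))
    if covariates is not None:
        cov = covariates.reset_index(drop=True).copy()
    cov["_dos_a"] = ga
    cov["_dos_b"] = gb
    fit = fit_polygenic_null(phenotype, cov, kinship)

    # BLUP of the polygenic effect: u_hat = sigma_g2 K V^{-1} (y - X beta)
    r_fixed = fit.residuals
    u_hat = fit.sigma_g2 * (kinship.values @ fit.vinv_dot(r_fixed))
    e = r_fixed - u_hat
    e = e - e.mean()
    return ConditionalFit(
        marker_a=marker_a,
        marker_b=marker_b,
        null_fit=fit,
        residuals=e,
        samples=list(genotypes.samples),
    )


def interaction_scan(
    fit: ConditionalFit,
    genotypes: GenotypeMatrix,
    cond_marker: str,
    exclusion_window_bp: int = 1_000_000,
) -> InteractionScanResult:
    """Regression scan of the stage-one residuals on {g, g x g_cond}.

    ``joint_p`` is the 2-df F test of the genotype and product terms;
    ``interaction_p`` the t test of the product term alone.  When the fit
    carries its mixed model, residuals and design are whitened by the
    fitted V^{-1/2} first, so the residual-stage regression is an exact
    generalized least squares and the tests stay calibrated despite the
    polygenic shrinkage; without a stage-one model the scan is ordinary
    least squares.  The conditioning markers and SNPs within
    ``exclusion_window_bp`` of either are excluded; monomorphic SNPs are
    skipped.
    """
    if list(genotypes.samples) != list(fit.samples):
        raise ValueError("sample mismatch between fit and genotypes")
    e = np.asarray(fit.residuals, dtype=float)
    n = len(e)
    sse_var = float(np.var(e))
    if sse_var < 1e-12:
        raise ValueError("residual variance ~ 0; conditional model is degenerate")
    g_cond = _dosage(genotypes, cond_marker)

    whiten = None
    if fit.null_fit is not None:
        nf = fit.null_fit
        sigma_tot = nf.sigma_g2 + nf.sigma_e2
        W = nf._U @ (nf._U.T / np.sqrt(nf._w * sigma_tot)[:, None])
        whiten = W
        # whitened fixed-effect residual: V^{-1/2} (y - X beta)
        e = W @ nf.residuals

    # exclusion: the conditioning markers plus windows around them
    excl = np.zeros(genotypes.n_snps, dtype=bool)
    sm = genotypes.snpmap
    for m in (fit.marker_a, fit.marker_b):
        j = genotypes.snp_index(m)
        same = sm["chrom"].astype(str) == str(sm["chrom"].iloc[j])
        near = np.abs(sm["pos"] - sm["pos"].iloc[j]) <= exclusion_window_bp
        excl |= (same & near).to_numpy()

    d = genotypes.dosages.astype(float)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])

    ones = np.ones(n)
    if whiten is not None:
        ones_w = whiten @ ones
        g_cond_w = whiten @ g_cond
        d_w = whiten @ d
    else:
        ones_w, g_cond_w, d_w = ones, g_cond, d

    # reduced model (intercept + conditioning-marker main effect); the
    # R-style expansion of e ~ g + g * g_cond keeps g_cond in the model
    X0 = np.column_stack([ones_w, g_cond_w])
    beta0, *_ = np.linalg.lstsq(X0, e, rcond=None)
    rss0 = float(np.sum((e - X0 @ beta0) ** 2))

    rows = []
    for j in range(genotypes.n_snps):
        if excl[j]:
            continue
        g = d[:, j]
        if g.var() == 0:
            continue
        prod = g * g_cond
        prod_w = whiten @ prod if whiten is not None else prod
        X = np.column_stack([ones_w, g_cond_w, d_w[:, j], prod_w])
        # guard: product column collinear with {1, g_cond, g}
        rank = np.linalg.matrix_rank(X)
        if rank < 4:
            continue
        beta, res, *_ = np.linalg.lstsq(X, e, rcond=None)
        rss = float(res[0]) if res.size else float(np.sum((e - X @ beta) ** 2))
        df_resid = n - 4
        if rss <= 0:
            joint_p = np.nan
            inter_p = np.nan
        else:
            # joint 2-df F of the genotype and product terms
            f = ((rss0 - rss) / 2.0) / (rss / df_resid)
            joint_p = float(stats.f.sf(max(f, 0.0), 2, df_resid))
            # t test of the product term
            XtX_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(rss / df_resid * XtX_inv[3, 3])
            t = beta[3] / se if se > 0 else 0.0
            inter_p = float(2.0 * stats.t.sf(abs(t), df_resid))
        rows.append(
            {
                "snp": genotypes.snps[j],
                "chrom": str(sm["chrom"].iloc[j]),
                "pos": int(sm["pos"].iloc[j]),
                "joint_p": min(max(joint_p, 1e-300), 1.0),
                "interaction_p": min(max(inter_p, 1e-300), 1.0),
                "cond_marker": cond_marker,
            }
        )
    table = pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "joint_p", "interaction_p", "cond_marker"]
    )
    return InteractionScanResult(table=table, cond_marker=cond_marker)
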