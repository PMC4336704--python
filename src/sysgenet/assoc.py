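"""Genotype QC, kinship estimation, and mixed-model single-marker association.

The GWAS layer of the pipeline: quality control of SNP genotypes, a genomic
relationship (kinship) matrix, a polygenic mixed-model null fit by REML, a
one-degree-of-freedom score test per SNP against that null (the classical
"mmscore" construction: the genotype term is tested on variance-adjusted
residuals of ``y = mu + sex + batch + polygenic(G) + e``), Benjamini-Hochberg
FDR thresholding, greedy locus definition around peak SNPs, and gene mapping
by interval overlap.

Genotypes are coded as minor-allele dosage {0, 1, 2} with ``-1`` for missing.
Coordinates are 1-based inclusive base pairs throughout (PLINK/VCF
convention); BED input is converted on read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "KinshipMatrix",
    "NullModelFit",
    "AssocResult",
    "Locus",
    "qc_filter",
    "hwe_exact_test",
    "compute_kinship",
    "fit_polygenic_null",
    "score_scan",
    "association_scan",
    "fdr_threshold",
    "define_loci",
    "map_genes",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
    "read_bed",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with a physical SNP map.

    Parameters
    ----------
    samples : list of sample identifiers (rows).
    snps : list of SNP identifiers (columns), unique.
    dosages : int8 array of shape (n_samples, n_snps); entries in
        {0, 1, 2, -1} where -1 marks a missing genotype.
    snpmap : DataFrame indexed like ``snps`` with columns ``chrom``,
        ``pos`` (1-based bp) and optionally ``a1``/``a2`` allele labels.
    """

    samples: list
    snps: list
    dosages: np.ndarray
    snpmap: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP ids")
        if len(self.snpmap) != len(self.snps):
            raise ValueError("snpmap length does not match SNP count")
        if (np.asarray(self.snpmap["pos"]) < 0).any():
            raise ValueError("negative SNP positions")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id) -> int:
        try:
            return self.snps.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def dosage_of(self, snp_id) -> np.ndarray:
        """Dosage column as float with NaN for missing."""
        g = self.dosages[:, self.snp_index(snp_id)].astype(float)
        g[g == MISSING] = np.nan
        return g

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in keep],
            dosages=self.dosages[:, keep],
            snpmap=self.snpmap.iloc[keep].reset_index(drop=True),
        )


@dataclass
class QCThresholds:
    """SNP inclusion thresholds: call rate, minor allele frequency, HWE p."""

    min_call_rate: float = 0.95
    min_maf: float = 0.15
    min_hwe_p: float = 5e-6

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix keyed by sample id."""

    samples: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix not symmetric")
        # symmetrize exactly against round-off
        self.values = 0.5 * (self.values + self.values.T)


@dataclass
class NullModelFit:
    """REML fit of the polygenic null model ``y = X b + u + e``.

    ``u ~ N(0, sigma_g^2 K)``, ``e ~ N(0, sigma_e^2 I)``.  Stores the
    eigen-rotation of the kinship so the score scan can apply the
    inverse-variance projection in O(n m).
    """

    samples: list
    beta: np.ndarray
    beta_names: list
    sigma_g2: float
    sigma_e2: float
    converged: bool
    residuals: np.ndarray          # y - X beta (original scale)
    _U: np.ndarray = field(repr=False, default=None)       # eigenvectors of K
    _w: np.ndarray = field(repr=False, default=None)       # h2*s + (1-h2)
    _Xr: np.ndarray = field(repr=False, default=None)      # U' X
    _yr: np.ndarray = field(repr=False, default=None)      # U' y
    _XtVinvX_inv: np.ndarray = field(repr=False, default=None)

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    def vinv_dot(self, v: np.ndarray) -> np.ndarray:
        """Apply V^{-1} = (sigma_g2 K + sigma_e2 I)^{-1} to a vector."""
        tot = self.sigma_g2 + self.sigma_e2
        vr = self._U.T @ v
        return self._U @ (vr / (self._w * tot))


@dataclass
class AssocResult:
    """Per-SNP score-test results (one row per polymorphic, tested SNP)."""

    table: pd.DataFrame  # columns: snp, chrom, pos, maf, stat, direction, p
    n_skipped_monomorphic: int = 0

    def __post_init__(self):
        p = self.table["p"].to_numpy()
        if len(p) and ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values outside (0, 1]")


@dataclass
class Locus:
    """A significant region: peak SNP plus a symmetric bp window."""

    peak_snp: str
    chrom: str
    peak_pos: int
    start: int
    end: int
    peak_p: float
    member_snps: list
    genes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact test of Hardy-Weinberg equilibrium for a biallelic SNP.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums probabilities <= that of the observed
    configuration (two-sided, Wigginton-style).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_ab = h | allele counts) up to a constant
    logp = (
        hets * math.log(2.0)
        - gammaln(hets + 1)
        - gammaln((rare - hets) // 2 + 1)
        - gammaln((2 * n - rare - hets) // 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_ab][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def qc_filter(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Filter SNPs by call rate, MAF and HWE; return (filtered, report).

    A SNP is retained iff call rate >= ``min_call_rate`` AND minor allele
    frequency >= ``min_maf`` AND HWE exact p >= ``min_hwe_p``.  The report
    lists every SNP with its statistics and, for exclusions, the failed
    checks (``call_rate``, ``maf``, ``hwe`` — semicolon-joined).
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if genotypes.n_snps == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")

    d = genotypes.dosages
    typed = d != MISSING
    n_typed = typed.sum(axis=0)
    call_rate = n_typed / genotypes.n_samples
    dd = np.where(typed, d, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = dd.sum(axis=0) / (2.0 * n_typed)
    alt_freq = np.nan_to_num(alt_freq)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    hwe_p = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        col = d[typed[:, j], j]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hwe_p[j] = hwe_exact_test(n0, n1, n2)

    fails = []
    for j in range(genotypes.n_snps):
        f = []
        if call_rate[j] < thresholds.min_call_rate:
            f.append("call_rate")
        if maf[j] < thresholds.min_maf:
            f.append("maf")
        if hwe_p[j] < thresholds.min_hwe_p:
            f.append("hwe")
        fails.append(";".join(f))
    fails = np.array(fails, dtype=object)
    keep = fails == ""

    report = pd.DataFrame(
        {
            "snp": genotypes.snps,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "excluded": ~keep,
            "reason": fails,
        }
    )
    if not keep.any():
        warnings.warn("QC removed every SNP", stacklevel=2)
    return genotypes.subset_snps(keep), report


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def compute_kinship(genotypes: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """Genomic relationship matrix from SNP dosages.

    ``vanraden`` (default): Z Z' / (2 sum p q) with Z the allele-frequency
    centered dosage matrix; missing entries are imputed at the SNP mean and
    thus contribute zero after centering.  ``ibs``: mean identity-by-state
    proportion over pairwise-complete SNPs.
    """
    if genotypes.n_samples < 2 or genotypes.n_snps < 2:
        raise ValueError("kinship needs at least 2 samples and 2 SNPs")
    d = genotypes.dosages.astype(float)
    d[d == MISSING] = np.nan
    freq = np.nanmean(d, axis=0) / 2.0  # per-SNP alt frequency
    poly = (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; kinship undefined")
    d = d[:, poly]
    freq = freq[poly]

    if method == "vanraden":
        Z = d - 2.0 * freq
        Z = np.where(np.isnan(Z), 0.0, Z)
        denom = 2.0 * np.sum(freq * (1.0 - freq))
        K = (Z @ Z.T) / denom
    elif method == "ibs":
        obs = ~np.isnan(d)
        x = np.where(obs, d, 0.0)
        # IBS share per pair: 1 - |gi - gj| / 2 averaged over complete SNPs
        diff = np.abs(x[:, None, :] - x[None, :, :])
        both = obs[:, None, :] & obs[None, :, :]
        with np.errstate(invalid="ignore"):
            K = 1.0 - (diff * both).sum(-1) / (2.0 * both.sum(-1))
        K = np.nan_to_num(K)
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return KinshipMatrix(samples=list(genotypes.samples), values=K)


# ---------------------------------------------------------------------------
# polygenic null + score scan
# ---------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame | None, n: int):
    """Intercept plus dummy-coded covariates (categoricals expanded)."""
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    names.append(dc)
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
    X = np.column_stack(cols)
    # drop collinear columns (e.g. constant covariate duplicating intercept)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return X[:, keep], [n_ for n_, k in zip(names, keep) if k]


def fit_polygenic_null(
    phenotype: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
    kinship: KinshipMatrix,
) -> NullModelFit:
    """REML fit of ``y = mu + covariates + polygenic(K) + e``.

    Profiles the REML log-likelihood in the heritability ratio
    ``h2 = sigma_g2 / (sigma_g2 + sigma_e2)`` on the eigenbasis of K, then
    recovers both variance components.  Returns residuals and the rotated
    quantities needed by :func:`score_scan`.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n != len(kinship.samples):
        raise ValueError("phenotype length does not match kinship")
    if np.var(y) == 0:
        raise ValueError("phenotype is constant; variance components undefined")
    X, names = _design_matrix(covariates, n)
    p = X.shape[1]
    if n < p + 2:
        raise ValueError("too few samples for the fixed-effect design")

    s, U = np.linalg.eigh(kinship.values)
    if s.min() < -1e-6 * max(1.0, s.max()):
        # bend: clip slightly negative eigenvalues from finite-SNP noise
        if s.min() < -0.05 * max(1.0, s.max()):
            raise FloatingPointError("kinship matrix far from PSD")
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def neg_reml(h2: float) -> float:
        w = h2 * s + (1.0 - h2)
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(r @ (r / w))
        if rss <= 0:
            return np.inf
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * math.log(rss / (n - p))
            + np.log(w).sum()
            + logdet_XtWX
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_reml, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    converged = bool(res.success) and np.isfinite(res.fun)

    w = h2 * s + (1.0 - h2)
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    sigma_tot = float(r @ (r / w)) / (n - p)
    fit = NullModelFit(
        samples=list(kinship.samples),
        beta=beta,
        beta_names=names,
        sigma_g2=h2 * sigma_tot,
        sigma_e2=(1.0 - h2) * sigma_tot,
        converged=converged,
        residuals=y - X @ beta,
        _U=U,
        _w=w,
        _Xr=Xr,
        _yr=yr,
        _XtVinvX_inv=np.linalg.inv(XtWX) * sigma_tot,
    )
    return fit


def score_scan(null_fit: NullModelFit, genotypes: GenotypeMatrix) -> AssocResult:
    """One-df score test of each SNP against the fitted polygenic null.

    The statistic is (g' P y)^2 / (g' P g) with P the projection
    V^{-1} - V^{-1} X (X' V^{-1} X)^{-1} X' V^{-1}; missing genotypes are
    mean-imputed per SNP, monomorphic SNPs skipped.
    """
    if list(genotypes.samples) != list(null_fit.samples):
        raise ValueError("sample mismatch between null fit and genotypes")
    if not null_fit.converged:
        raise ValueError("null model fit did not converge")

    d = genotypes.dosages.astype(float)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    col_var = d.var(axis=0)
    poly = col_var > 0
    n_skipped = int((~poly).sum())

    sigma_tot = null_fit.sigma_g2 + null_fit.sigma_e2
    U, w, Xr = null_fit._U, null_fit._w, null_fit._Xr
    rr = (null_fit._yr - Xr @ null_fit.beta) / w        # W^{-1} (rotated resid)
    G = U.T @ d[:, poly]                                # rotated genotypes
    Gw = G / w[:, None]
    XtWX_inv = np.linalg.inv(Xr.T @ (Xr / w[:, None]))
    B = Xr.T @ Gw                                       # p x m
    num = G.T @ rr                                      # g' W^{-1} r
    gPg = np.einsum("ij,ij->j", G, Gw) - np.einsum("ij,ij->j", B, XtWX_inv @ B)
    gPg = np.clip(gPg, 1e-300, None)
    chi2 = (num ** 2) / (gPg * sigma_tot)
    pvals = np.clip(stats.chi2.sf(chi2, df=1), 1e-300, 1.0)

    freq = col_mean[poly] / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    snps = np.array(genotypes.snps, dtype=object)[poly]
    sm = genotypes.snpmap.iloc[np.flatnonzero(poly)]
    table = pd.DataFrame(
        {
            "snp": snps,
            "chrom": sm["chrom"].to_numpy(),
            "pos": sm["pos"].to_numpy(),
            "maf": maf,
            "stat": chi2,
            "direction": np.sign(num).astype(int),
            "p": pvals,
        }
    )
    return AssocResult(table=table, n_skipped_monomorphic=n_skipped)


def association_scan(
    phenotype,
    covariates: pd.DataFrame | None,
    genotypes: GenotypeMatrix,
    loco: bool = False,
    kinship_method: str = "vanraden",
) -> AssocResult:
    """Genome scan: genome-wide kinship (default) or leave-one-chromosome-out.

    With ``loco=True`` the kinship is rebuilt from all other chromosomes
    per tested chromosome and the polygenic null refitted, removing
    proximal contamination (the tested QTL's own linkage block inflating
    the polygenic term and absorbing its signal).  In a deep F2 from very
    few founder sires, however, family structure correlates dosages across
    chromosomes, so the LOCO null no longer conditions on all confounding
    and the test becomes anticonservative; the genome-wide-kinship scan is
    therefore the default.
    """
    if not loco:
        kin = compute_kinship(genotypes, kinship_method)
        fit = fit_polygenic_null(phenotype, covariates, kin)
        return score_scan(fit, genotypes)

    chroms = pd.unique(genotypes.snpmap["chrom"])
    if len(chroms) < 2:
        raise ValueError("LOCO needs at least 2 chromosomes")
    pieces = []
    n_skipped = 0
    chrom_col = genotypes.snpmap["chrom"].to_numpy()
    for c in chroms:
        on_c = chrom_col == c
        kin = compute_kinship(genotypes.subset_snps(~on_c), kinship_method)
        fit = fit_polygenic_null(phenotype, covariates, kin)
        res = score_scan(fit, genotypes.subset_snps(on_c))
        pieces.append(res.table)
        n_skipped += res.n_skipped_monomorphic
    table = pd.concat(pieces, ignore_index=True)
    return AssocResult(table=table, n_skipped_monomorphic=n_skipped)


# ---------------------------------------------------------------------------
# FDR + loci
# ---------------------------------------------------------------------------

def fdr_threshold(pvalues, fdr_level: float = 0.05) -> float:
    """Benjamini-Hochberg step-up p-value cutoff.

    Returns the largest p_(i) with p_(i) <= (i/m) q, or 0.0 when nothing
    passes.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    ps = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * fdr_level
    ok = ps <= crit
    if not ok.any():
        return 0.0
    return float(ps[np.flatnonzero(ok).max()])


def define_loci(assoc: AssocResult, cutoff: float, half_width_bp: int = 200_000) -> list:
    """Greedy clustering of significant SNPs into peak-centered loci.

    Repeatedly takes the most significant unassigned SNP (ties broken by
    lower bp position) as a peak, absorbs significant SNPs on the same
    chromosome within ``half_width_bp``, and emits the closed window
    [peak - half_width, peak + half_width] clipped at 0.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    sig = assoc.table[assoc.table["p"] <= cutoff].copy()
    loci: list[Locus] = []
    sig = sig.sort_values(["p", "pos"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(sig), dtype=bool)
    for i in range(len(sig)):
        if assigned[i]:
            continue
        peak = sig.iloc[i]
        same = (
            (sig["chrom"] == peak["chrom"])
            & (np.abs(sig["pos"] - peak["pos"]) <= half_width_bp)
            & ~assigned
        )
        members = sig.loc[same, "snp"].tolist()
        assigned |= same.to_numpy()
        loci.append(
            Locus(
                peak_snp=str(peak["snp"]),
                chrom=str(peak["chrom"]),
                peak_pos=int(peak["pos"]),
                start=max(0, int(peak["pos"]) - half_width_bp),
                end=int(peak["pos"]) + half_width_bp,
                peak_p=float(peak["p"]),
                member_snps=members,
            )
        )
    return loci


def map_genes(locus: Locus, annotation: pd.DataFrame) -> list:
    """Genes whose annotated interval overlaps the locus window.

    ``annotation`` needs columns chrom/start/end/gene in 1-based closed
    coordinates (see :func:`read_bed`).  Overlap is any-overlap on closed
    intervals.
    """
    need = {"chrom", "start", "end", "gene"}
    if not need.issubset(annotation.columns):
        raise ValueError(f"annotation missing columns {need - set(annotation.columns)}")
    chroms = set(annotation["chrom"].astype(str))
    if str(locus.chrom) not in chroms:
        raise ValueError(
            f"chromosome {locus.chrom!r} absent from annotation (has {sorted(chroms)})"
        )
    a = annotation[annotation["chrom"].astype(str) == str(locus.chrom)]
    hit = (a["start"] <= locus.end) & (a["end"] >= locus.start)
    return a.loc[hit, "gene"].tolist()


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix: str, pedigree: pd.DataFrame | None = None):
    """Write PLINK text .ped/.map; alleles A (major) / B (minor)."""
    sm = genotypes.snpmap
    with open(f"{prefix}.map", "w") as fh:
        for j, snp in enumerate(genotypes.snps):
            cm = sm["cm"].iloc[j] if "cm" in sm.columns else 0.0
            fh.write(f"{sm['chrom'].iloc[j]}\t{snp}\t{cm:g}\t{int(sm['pos'].iloc[j])}\n")
    ped_info = {}
    if pedigree is not None:
        ped_info = pedigree.set_index("sample_id").to_dict("index")
    code = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(genotypes.samples):
            info = ped_info.get(sid, {})
            row = [
                str(info.get("family_id", "FAM1")),
                str(sid),
                str(info.get("father_id", 0)),
                str(info.get("mother_id", 0)),
                str(info.get("sex", 0)),
                "-9",
            ]
            row += [code[int(g)] for g in genotypes.dosages[i]]
            fh.write(" ".join(row) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK text .ped/.map written in A/B allele coding."""
    mp = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str},
    )
    samples, rows = [], []
    decode = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2}
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            alleles = parts[6:]
            g = [
                decode.get((alleles[2 * j], alleles[2 * j + 1]), MISSING)
                for j in range(len(mp))
            ]
            rows.append(g)
    snpmap = mp[["chrom", "pos", "cm"]].copy()
    return GenotypeMatrix(
        samples=samples,
        snps=mp["snp"].tolist(),
        dosages=np.array(rows, dtype=np.int8),
        snpmap=snpmap.reset_index(drop=True),
    )


def write_vcf(genotypes: GenotypeMatrix, path: str):
    """Write genotypes as a minimal VCF v4.2 text file (REF=A, ALT=B)."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(genotypes.snpmap["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.samples)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snps):
            row = [
                str(genotypes.snpmap["chrom"].iloc[j]),
                str(int(genotypes.snpmap["pos"].iloc[j])),
                str(snp), "A", "C", ".", "PASS", ".", "GT",
            ]
            row += [gt_code[int(g)] for g in genotypes.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (via cyvcf2) into dosage coding on the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snps, chroms, poss, rows = [], [], [], []
    for var in vcf:
        snps.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        dos = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt))
        rows.append(dos.astype(np.int8))
    snpmap = pd.DataFrame({"chrom": chroms, "pos": poss})
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        dosages=np.array(rows, dtype=np.int8).T,
        snpmap=snpmap,
    )


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED gene annotation into 1-based closed intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based closed
    df["end"] = df["end"].astype(int)
    return df
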