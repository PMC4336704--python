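"""QC, kinship, REML null model, score scan, FDR and locus mapping checks,
each against an independent oracle (direct enumeration, OLS, or GLS)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sysgenet as sg
from sysgenet.assoc import MISSING, hwe_exact_test

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_call_rate_maf_and_retention():
    """94% call rate fails the 95% rule; MAF 0.05 fails the 15% rule; a clean
    equifrequent SNP passes all three filters."""
    n = 100
    rng = np.random.default_rng(0)
    good = rng.integers(0, 3, size=n)             # MAF near 0.5, complete
    low_cr = good.copy()
    low_cr[:6] = MISSING                          # 94% call rate
    rare = np.zeros(n, dtype=int)                 # counts (90, 10, 0) -> MAF 0.05
    rare[:10] = 1
    geno = make_genotypes(np.column_stack([good, low_cr, rare]))
    filtered, report = sg.qc_filter(geno)
    rep = report.set_index("snp")
    assert not rep.loc["s1", "excluded"]
    assert rep.loc["s2", "excluded"] and "call_rate" in rep.loc["s2", "reason"]
    assert rep.loc["s3", "excluded"] and "maf" in rep.loc["s3", "reason"]
    assert rep.loc["s3", "maf"] == pytest.approx(0.05)
    assert filtered.snps == ["s1"]


def test_qc_maf_counting_oracle():
    """MAF from genotype counts (AA=9, Aa=1, aa=0) is 1/20 = 0.05 exactly."""
    d = np.array([[0] * 9 + [1]]).T
    geno = make_genotypes(d)
    _, report = sg.qc_filter(geno)
    assert report["maf"].iloc[0] == pytest.approx(0.05)
    assert report["excluded"].iloc[0]


def test_qc_idempotent(f2_cross):
    geno, _ = f2_cross
    once, _ = sg.qc_filter(geno)
    twice, rep2 = sg.qc_filter(once)
    assert twice.snps == once.snps
    assert not rep2["excluded"].any()


def _hwe_brute_force(n_aa, n_ab, n_bb):
    """Enumerate all het counts with the observed allele counts directly."""
    from math import comb

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    probs = {}
    for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0:
            continue
        # multinomial count of genotype configurations x 2^h phase choices
        probs[h] = 2**h * comb(n, aa) * comb(n - aa, h)
    tot = sum(probs.values())
    obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= obs) / tot


@pytest.mark.parametrize(
    "counts", [(20, 50, 30), (90, 10, 0), (5, 0, 5), (68, 28, 4), (0, 10, 0)]
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(_hwe_brute_force(*counts), rel=1e-9)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def test_kinship_duplicate_sample_equals_diagonal():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(20, 60))
    d = np.vstack([d, d[0]])                      # duplicate first sample
    K = sg.compute_kinship(make_genotypes(d)).values
    assert K[0, 20] == pytest.approx(K[0, 0])


def test_kinship_opposite_homozygotes_minimal():
    d = np.array(
        [[0] * 30, [2] * 30, [1] * 30, [0] * 15 + [2] * 15], dtype=np.int8
    )
    K = sg.compute_kinship(make_genotypes(d)).values
    off = K[~np.eye(4, dtype=bool)]
    assert K[0, 1] == pytest.approx(off.min())


def test_kinship_monomorphic_only_rejected():
    d = np.zeros((5, 4), dtype=np.int8)
    with pytest.raises(ValueError):
        sg.compute_kinship(make_genotypes(d))


def test_full_sib_kinship_near_midpoint(f2_cross, f2_kinship):
    """Mean full-sib relatedness sits near the midpoint of self and the
    population average (pedigree expectation for an F2 family)."""
    geno, pedigree = f2_cross
    fam = pedigree.set_index("sample_id").loc[geno.samples, "family_id"].to_numpy()
    K = f2_kinship.values
    same = (fam[:, None] == fam[None, :]) & ~np.eye(len(fam), dtype=bool)
    sib_mean = K[same].mean()
    self_mean = np.diag(K).mean()
    unrelated_mean = K[fam[:, None] != fam[None, :]].mean()
    midpoint = (self_mean + unrelated_mean) / 2
    assert abs(sib_mean - midpoint) < 0.15 * (self_mean - unrelated_mean) + 0.05


# ---------------------------------------------------------------------------
# null model + scan
# ---------------------------------------------------------------------------

def test_identity_kinship_reduces_to_ols():
    rng = np.random.default_rng(3)
    n = 80
    x = rng.standard_normal(n)
    y = 1.0 + 0.5 * x + rng.standard_normal(n)
    kin = sg.KinshipMatrix(samples=list(range(n)), values=np.eye(n))
    fit = sg.fit_polygenic_null(y, pd.DataFrame({"x": x}), kin)
    X = np.column_stack([np.ones(n), x])
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = np.sum((y - X @ beta_ols) ** 2)
    assert fit.beta == pytest.approx(beta_ols, abs=1e-4)
    assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(rss / (n - 2), rel=1e-3)


def test_constant_phenotype_rejected(f2_kinship):
    n = len(f2_kinship.samples)
    with pytest.raises(ValueError):
        sg.fit_polygenic_null(np.ones(n), None, f2_kinship)


def test_heritability_recovery(small_map):
    """REML recovers a simulated h2 = 0.5 within +-0.15 (mean of 3 runs)."""
    ests = []
    for rep in range(3):
        geno, ped = sg.simulate_f2_cross(small_map, sg.PedigreeSpec(n_f2=300), seed=50 + rep)
        kin = sg.compute_kinship(geno)
        pheno, _ = sg.simulate_phenotype(
            geno, kin, sg.QTLSpec(qtls=[], h2=0.5), seed=60 + rep, pedigree=ped
        )
        fit = sg.fit_polygenic_null(pheno["trait"], pheno[["sex", "batch"]], kin)
        ests.append(fit.heritability)
    assert abs(np.mean(ests) - 0.5) < 0.15


def _gls_wald_pvalues(y, X, G, V):
    """Direct matrix-inversion GLS oracle: Wald test per SNP."""
    Vinv = np.linalg.inv(V)
    out = []
    for j in range(G.shape[1]):
        D = np.column_stack([X, G[:, j]])
        C = np.linalg.inv(D.T @ Vinv @ D)
        beta = C @ D.T @ Vinv @ y
        z = beta[-1] / np.sqrt(C[-1, -1])
        out.append(stats.chi2.sf(z**2, df=1))
    return np.array(out)


def test_score_scan_matches_gls_oracle():
    """Score p-values track a direct GLS Wald oracle: same ranking and
    Spearman correlation > 0.99 on a 50-sample instance."""
    rng = np.random.default_rng(7)
    n, m = 50, 30
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    A = rng.standard_normal((n, n))
    K = A @ A.T / n
    K = K / np.diag(K).mean()
    geno = make_genotypes(G.astype(np.int8))
    kin = sg.KinshipMatrix(samples=geno.samples, values=K)
    u = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
    y = 0.5 * G[:, 0] + u + rng.standard_normal(n)
    fit = sg.fit_polygenic_null(y, None, kin)
    res = sg.score_scan(fit, geno)

    V = fit.sigma_g2 * K + fit.sigma_e2 * np.eye(n)
    p_oracle = _gls_wald_pvalues(y, np.ones((n, 1)), G, V)
    rho = stats.spearmanr(res.table["p"], p_oracle).statistic
    assert rho > 0.99
    assert res.table["p"].idxmin() == int(np.argmin(p_oracle))


def test_score_scan_orthogonal_snp_gives_p_one():
    """A genotype exactly orthogonal to the adjusted residuals scores 0
    (p = 1): with identity kinship and an intercept-only model the score
    numerator reduces to the centered dot product with the residuals."""
    y = np.array([1.0, -1.0, 1.0, -1.0, 2.0, -2.0])
    g = np.array([0, 0, 2, 2, 1, 1], dtype=np.int8)   # centered g orthogonal to y
    geno = make_genotypes(g[:, None])
    kin = sg.KinshipMatrix(samples=geno.samples, values=np.eye(6))
    fit = sg.fit_polygenic_null(y, None, kin)
    assert (g - g.mean()) @ fit.residuals == pytest.approx(0.0, abs=1e-12)
    res = sg.score_scan(fit, geno)
    assert res.table["stat"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert res.table["p"].iloc[0] == pytest.approx(1.0)


def test_scan_sample_mismatch_rejected(f2_cross, f2_kinship):
    geno, ped = f2_cross
    pheno, _ = sg.simulate_phenotype(geno, f2_kinship, sg.QTLSpec(qtls=[]), seed=1, pedigree=ped)
    fit = sg.fit_polygenic_null(pheno["trait"], None, f2_kinship)
    other = make_genotypes(np.zeros((3, 2), dtype=np.int8))
    with pytest.raises(ValueError):
        sg.score_scan(fit, other)


# ---------------------------------------------------------------------------
# FDR + loci + genes
# ---------------------------------------------------------------------------

def test_fdr_threshold_step_up_rule():
    assert sg.fdr_threshold([0.001, 0.01, 0.02, 0.5], 0.05) == pytest.approx(0.02)
    assert sg.fdr_threshold([1.0, 1.0, 1.0], 0.05) == 0.0
    with pytest.raises(ValueError):
        sg.fdr_threshold([], 0.05)
    with pytest.raises(ValueError):
        sg.fdr_threshold([0.0, 0.5], 0.05)


def _assoc_result(rows):
    return sg.AssocResult(
        table=pd.DataFrame(rows, columns=["snp", "chrom", "pos", "maf", "stat", "direction", "p"])
    )


def test_define_loci_window_arithmetic():
    """A peak at 43,430,000 with 200 kb half-width spans [43.23, 43.63] Mb."""
    res = _assoc_result([("peak", "8", 43_430_000, 0.4, 50.0, 1, 1e-10)])
    loci = sg.define_loci(res, cutoff=1e-5, half_width_bp=200_000)
    assert len(loci) == 1
    assert (loci[0].start, loci[0].end) == (43_230_000, 43_630_000)


def test_define_loci_clustering_rule():
    """150 kb apart -> one locus with the smaller p as peak; 500 kb -> two."""
    near = _assoc_result(
        [("a", "1", 1_000_000, 0.3, 40, 1, 1e-8), ("b", "1", 1_150_000, 0.3, 30, 1, 1e-6)]
    )
    loci = sg.define_loci(near, cutoff=1e-5, half_width_bp=200_000)
    assert len(loci) == 1 and loci[0].peak_snp == "a"
    assert set(loci[0].member_snps) == {"a", "b"}
    far = _assoc_result(
        [("a", "1", 1_000_000, 0.3, 40, 1, 1e-8), ("b", "1", 1_500_000, 0.3, 30, 1, 1e-6)]
    )
    loci = sg.define_loci(far, cutoff=1e-5, half_width_bp=200_000)
    assert len(loci) == 2
    # distinct peaks are more than half_width apart
    assert abs(loci[0].peak_pos - loci[1].peak_pos) > 200_000
    assert sg.define_loci(_assoc_result([("a", "1", 1, 0.3, 0, 1, 0.9)]), 1e-5) == []


def test_map_genes_overlap_and_mismatch():
    ann = pd.DataFrame(
        {
            "chrom": ["7"] * 6,
            "start": [35_000_000, 35_100_000, 35_200_000, 35_300_000, 35_370_000, 36_000_000],
            "end": [35_020_000, 35_120_000, 35_220_000, 35_320_000, 35_500_000, 36_100_000],
            "gene": ["SPDEF", "RPS10", "PACSIN1", "HMGA1", "C6orf106", "FAR"],
        }
    )
    locus = sg.assoc.Locus(
        peak_snp="x", chrom="7", peak_pos=35_180_000,
        start=34_980_000, end=35_380_000, peak_p=1e-10, member_snps=["x"],
    )
    genes = sg.map_genes(locus, ann)
    # five genes overlap the window, incl. one straddling the right edge
    assert genes == ["SPDEF", "RPS10", "PACSIN1", "HMGA1", "C6orf106"]
    with pytest.raises(ValueError):
        sg.map_genes(
            sg.assoc.Locus("x", "chr7", 1, 0, 2, 1e-3, ["x"]), ann
        )


def test_read_bed_converts_coordinates(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t999\t2000\tGENE1\n2\t0\t500\tGENE2\n")
    ann = sg.assoc.read_bed(str(bed))
    assert ann.loc[0, "start"] == 1000 and ann.loc[0, "end"] == 2000
    assert ann.loc[1, "start"] == 1
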