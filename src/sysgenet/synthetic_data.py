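"""Simulation of an F2 intercross with phenotypes, expression, and networks.

Emulates the genetic architecture of a two-breed pig F2 design: two founder
boars of one breed and 17 founder sows of another are crossed, 59 F1 sows
are mated to 9 F1 boars, and a configurable number of F2 offspring are
genotyped.  Founder breeds are modeled as outbred populations whose per-SNP
allele frequencies diverge under a Balding-Nichols F-model; meiosis follows
the Haldane map function (Poisson crossovers, no interference) on a
centimorgan map.

Phenotypes follow the generative mirror of the mixed model
``y = mu + sex + batch + QTL terms + polygenic(K) + e`` with the non-fixed
variance normalized to 1, so additive effects are interpretable directly as
phenotype-SD units.  Expression data are generated from a known DAG by
linear structural equations with cis-eQTL genotype inputs; trans effects
arise only by propagation along DAG edges.  A scale-free gene network with
planted dense modules and matching GMT gene sets rounds out the inputs the
downstream network statistics expect.

Every generator returns a :class:`SimTruth` fragment recording what was
planted, so recovery tests can score the analysis against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .assoc import MISSING, GenotypeMatrix, KinshipMatrix

__all__ = [
    "GeneticMap",
    "PedigreeSpec",
    "QTLSpec",
    "ExpressionDAGSpec",
    "SimTruth",
    "simulate_f2_cross",
    "simulate_phenotype",
    "simulate_expression",
    "simulate_network_and_sets",
    "write_gmt",
    "read_gmt",
    "write_sif",
    "read_sif",
    "write_edge_list",
    "read_edge_list",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered marker grid: per chromosome, (id, bp position, cM position)."""

    table: pd.DataFrame  # columns: snp, chrom, pos (bp), cm

    def __post_init__(self):
        t = self.table
        for c in ("snp", "chrom", "pos", "cm"):
            if c not in t.columns:
                raise ValueError(f"genetic map missing column {c!r}")
        if len(t) == 0:
            raise ValueError("empty genetic map")
        if (t["cm"] < 0).any():
            raise ValueError("negative cM position")
        for _, grp in t.groupby("chrom", sort=False):
            if not (np.diff(grp["pos"]) > 0).all() or not (np.diff(grp["cm"]) > 0).all():
                raise ValueError("map positions must be strictly increasing per chromosome")

    @classmethod
    def regular(cls, n_chrom: int = 18, snps_per_chrom: int = 650,
                spacing_bp: int = 181_000, cm_per_mb: float = 1.0) -> "GeneticMap":
        """Evenly spaced grid emulating a post-QC 60 K-chip marker set.

        Defaults give 18 autosomes x 650 markers at 181 kb spacing
        (~11.7 K informative SNPs, ~118 cM per chromosome).  Scaled-down
        maps should reduce marker count by widening ``spacing_bp`` so
        chromosomes keep a realistic genetic length (~1 Morgan); very
        short chromosomes behave as single linkage blocks and starve the
        association scan of recombinations.
        """
        rows = []
        for c in range(1, n_chrom + 1):
            for j in range(snps_per_chrom):
                pos = (j + 1) * spacing_bp
                rows.append((f"snp_c{c}_{j + 1}", str(c), pos, pos * 1e-6 * cm_per_mb))
        return cls(pd.DataFrame(rows, columns=["snp", "chrom", "pos", "cm"]))

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def chromosomes(self):
        return list(pd.unique(self.table["chrom"]))


@dataclass
class PedigreeSpec:
    """Breeding design counts and founder-breed allele-frequency divergence."""

    n_founder_sires: int = 2
    n_founder_dams: int = 17
    n_f1_sires: int = 9
    n_f1_dams: int = 59
    n_f2: int = 500
    fst: float = 0.4            # Balding-Nichols divergence of the two breeds
    litters_per_dam: int = 2    # distinct sires per dam (~110 full-sib families)
    ancestral_maf_range: tuple = (0.1, 0.9)
    founder_freqs: tuple | None = None   # explicit per-SNP (breed1, breed2) freqs

    def __post_init__(self):
        for name in ("n_founder_sires", "n_founder_dams", "n_f1_sires", "n_f1_dams", "n_f2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.founder_freqs is not None:
            for f in self.founder_freqs:
                f = np.asarray(f, dtype=float)
                if ((f < 0) | (f > 1)).any():
                    raise ValueError("founder allele frequencies outside [0, 1]")


@dataclass
class QTLSpec:
    """Planted QTL architecture for :func:`simulate_phenotype`.

    ``qtls`` is a list of (marker id, additive effect in phenotype SD,
    dominance effect); ``epistasis`` an optional (marker A, marker B,
    interaction effect); ``h2`` the polygenic share of the non-QTL variance.
    """

    qtls: list = field(default_factory=list)
    epistasis: tuple | None = None
    h2: float = 0.3
    sex_effect: float = 0.2
    batch_effects: tuple = (0.0, 0.3, -0.2)
    mean: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 outside [0, 1]")


@dataclass
class ExpressionDAGSpec:
    """Linear-Gaussian DAG spec for expression simulation."""

    n_genes: int = 30
    edge_density: float = 0.1
    coef_range: tuple = (0.5, 1.0)
    noise_sd: float = 1.0
    n_cis_genes: int = 10
    cis_effect: float = 1.0
    cis_window_bp: int = 1_000_000
    edges: list | None = None        # explicit DAG edges override density

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density outside [0, 1]")
        if self.edges is not None:
            g = nx.DiGraph([(e[0], e[1]) for e in self.edges])
            if not nx.is_directed_acyclic_graph(g):
                raise ValueError("explicit expression spec edges contain a cycle")


@dataclass
class SimTruth:
    """Ground truth planted by the generators; the oracle for recovery tests."""

    qtls: list = field(default_factory=list)          # dicts: snp, chrom, pos, a, d
    epistasis: dict | None = None
    dag_edges: list = field(default_factory=list)     # (parent gene, child gene, coef)
    eqtls: list = field(default_factory=list)         # dicts: gene, snp, effect, kind
    modules: dict = field(default_factory=dict)       # module id -> gene list

    def to_json(self, path: str):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# F2 cross
# ---------------------------------------------------------------------------

def _meiosis(haps: np.ndarray, cm: np.ndarray, chrom_slices, rng) -> np.ndarray:
    """One gamete from a diploid: Haldane crossovers on the cM map.

    ``haps`` is (2, m); crossover count per chromosome is Poisson(length/100)
    with positions uniform in cM, start phase fair.
    """
    gamete = np.empty(haps.shape[1], dtype=haps.dtype)
    for sl in chrom_slices:
        c = cm[sl]
        length = c[-1] - c[0]
        n_x = rng.poisson(length / 100.0)
        phase = np.full(len(c), rng.integers(2), dtype=np.int8)
        if n_x:
            locs = np.sort(rng.uniform(c[0], c[-1], size=n_x))
            phase = (phase + np.searchsorted(locs, c, side="right")) % 2
        gamete[sl] = haps[phase, np.arange(sl.start, sl.stop)]
    return gamete


def simulate_f2_cross(gmap: GeneticMap, ped: PedigreeSpec, seed: int):
    """Simulate the two-breed F2 intercross; returns (GenotypeMatrix, pedigree).

    Founder haplotypes are Bernoulli draws from breed allele frequencies
    diverged by a Balding-Nichols F-model; F1s take one gamete from each
    breed; F2 family sizes are multinomial over the F1 sire x dam matings.
    The pedigree table links every animal to its parents and records
    generation and family.
    """
    rng = np.random.default_rng(seed)
    t = gmap.table
    m = len(t)
    cm = t["cm"].to_numpy(dtype=float)
    chrom_slices = []
    start = 0
    for _, grp in t.groupby("chrom", sort=False):
        chrom_slices.append(slice(start, start + len(grp)))
        start += len(grp)

    # breed allele frequencies: explicit, or drawn under the F-model
    if ped.founder_freqs is not None:
        freq_breed1 = np.broadcast_to(np.asarray(ped.founder_freqs[0], float), (m,))
        freq_breed2 = np.broadcast_to(np.asarray(ped.founder_freqs[1], float), (m,))
    else:
        lo, hi = ped.ancestral_maf_range
        p_anc = rng.uniform(lo, hi, size=m)
        a = p_anc * (1 - ped.fst) / ped.fst
        b = (1 - p_anc) * (1 - ped.fst) / ped.fst
        freq_breed1 = rng.beta(a, b)
        freq_breed2 = rng.beta(a, b)

    def draw_founder(freq):
        return (rng.random((2, m)) < freq).astype(np.int8)

    sires = [draw_founder(freq_breed1) for _ in range(ped.n_founder_sires)]
    dams = [draw_founder(freq_breed2) for _ in range(ped.n_founder_dams)]

    pedigree_rows = []
    sire_ids = [f"S{i + 1}" for i in range(ped.n_founder_sires)]
    dam_ids = [f"D{i + 1}" for i in range(ped.n_founder_dams)]
    for sid in sire_ids:
        pedigree_rows.append((sid, "0", "0", 1, "founder", "F0"))
    for did in dam_ids:
        pedigree_rows.append((did, "0", "0", 2, "founder", "F0"))

    # F1: each founder dam litters with a founder sire; make enough F1s
    n_f1 = ped.n_f1_sires + ped.n_f1_dams
    f1_haps, f1_ids = [], []
    for k in range(n_f1):
        si = k % ped.n_founder_sires
        di = k % ped.n_founder_dams
        hap = np.stack(
            [
                _meiosis(sires[si], cm, chrom_slices, rng),
                _meiosis(dams[di], cm, chrom_slices, rng),
            ]
        )
        fid = f"F1_{k + 1}"
        f1_haps.append(hap)
        f1_ids.append(fid)
        sex = 1 if k < ped.n_f1_sires else 2
        pedigree_rows.append((fid, sire_ids[si], dam_ids[di], sex, "f1", "F1"))

    f1_sires = list(range(ped.n_f1_sires))
    f1_dams = list(range(ped.n_f1_sires, n_f1))

    # matings: each F1 dam litters with litters_per_dam distinct random F1
    # sires (the study design yields ~2 litters per dam, ~110 full-sib
    # families); family sizes drawn multinomially over the dam x sire pairs
    litters = min(ped.litters_per_dam, ped.n_f1_sires)
    pairs = []
    for d_idx in range(len(f1_dams)):
        sires_d = rng.choice(ped.n_f1_sires, size=litters, replace=False)
        pairs.extend((d_idx, int(s)) for s in sires_d)
    fam_sizes = rng.multinomial(ped.n_f2, np.full(len(pairs), 1.0 / len(pairs)))
    f2_geno = np.empty((ped.n_f2, m), dtype=np.int8)
    i = 0
    for fam_idx, (size, (d_idx, s_idx)) in enumerate(zip(fam_sizes, pairs)):
        sire_hap = f1_haps[f1_sires[s_idx]]
        dam_hap = f1_haps[f1_dams[d_idx]]
        for _ in range(size):
            pat = _meiosis(sire_hap, cm, chrom_slices, rng)
            mat = _meiosis(dam_hap, cm, chrom_slices, rng)
            f2_geno[i] = pat + mat
            fid = f"F2_{i + 1}"
            pedigree_rows.append(
                (fid, f1_ids[f1_sires[s_idx]], f1_ids[f1_dams[d_idx]],
                 int(rng.integers(1, 3)), f"fam{fam_idx + 1}", "F2")
            )
            i += 1

    pedigree = pd.DataFrame(
        pedigree_rows,
        columns=["sample_id", "father_id", "mother_id", "sex", "family_id", "generation"],
    )
    f2_ids = pedigree.loc[pedigree["generation"] == "F2", "sample_id"].tolist()
    snpmap = t[["chrom", "pos", "cm"]].reset_index(drop=True)
    geno = GenotypeMatrix(
        samples=f2_ids, snps=t["snp"].tolist(), dosages=f2_geno, snpmap=snpmap
    )
    return geno, pedigree


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix | None,
    qtl: QTLSpec,
    seed: int,
    pedigree: pd.DataFrame | None = None,
    n_batches: int = 3,
):
    """Phenotype + covariates from planted QTLs, polygenic background, noise.

    Returns (phenotype table, SimTruth).  The table has columns sample_id,
    sex, batch and ``trait``.  Additive dosage effects are centered (g - 1)
    so effects are orthogonal to the mean; the genetic + residual variance
    is normalized to 1: with v_q the realized QTL variance, the polygenic
    variance is h2 (1 - v_q) and the residual (1 - h2)(1 - v_q).
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    if not 0.0 <= qtl.h2 <= 1.0:
        raise ValueError("h2 outside [0, 1]")

    if pedigree is not None:
        sex = (
            pedigree.set_index("sample_id")
            .loc[genotypes.samples, "sex"]
            .to_numpy(dtype=float)
            - 1.0
        )
    else:
        sex = rng.integers(2, size=n).astype(float)
    batch = np.arange(n) % n_batches

    g_sum = np.zeros(n)
    truth_qtls = []
    for snp_id, a, d in qtl.qtls:
        g = genotypes.dosage_of(snp_id)
        g = np.where(np.isnan(g), np.nanmean(g), g)
        g_sum += a * (g - 1.0) + d * (g == 1)
        j = genotypes.snp_index(snp_id)
        truth_qtls.append(
            {
                "snp": snp_id,
                "chrom": str(genotypes.snpmap["chrom"].iloc[j]),
                "pos": int(genotypes.snpmap["pos"].iloc[j]),
                "additive": float(a),
                "dominance": float(d),
            }
        )
    truth_epi = None
    if qtl.epistasis is not None:
        snp_a, snp_b, gamma = qtl.epistasis
        ga = genotypes.dosage_of(snp_a)
        gb = genotypes.dosage_of(snp_b)
        ga = np.where(np.isnan(ga), np.nanmean(ga), ga)
        gb = np.where(np.isnan(gb), np.nanmean(gb), gb)
        g_sum += gamma * (ga - 1.0) * (gb - 1.0)
        truth_epi = {"snp_a": snp_a, "snp_b": snp_b, "effect": float(gamma)}

    v_q = float(np.var(g_sum))
    v_q = min(v_q, 1.0)
    sigma_g2 = qtl.h2 * (1.0 - v_q)
    sigma_e2 = (1.0 - qtl.h2) * (1.0 - v_q)

    u = np.zeros(n)
    if sigma_g2 > 0 and kinship is not None:
        K = kinship.values + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(K)
        u = L @ rng.standard_normal(n)
        # scale so the average marginal variance is sigma_g2
        u *= np.sqrt(sigma_g2 / np.mean(np.diag(K)))
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)

    batch_eff = np.asarray(qtl.batch_effects, dtype=float)
    if len(batch_eff) < n_batches:
        batch_eff = np.resize(batch_eff, n_batches)
    y = qtl.mean + qtl.sex_effect * sex + batch_eff[batch] + g_sum + u + e

    pheno = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "sex": sex.astype(int),
            "batch": [f"b{b + 1}" for b in batch],
            "trait": y,
        }
    )
    truth = SimTruth(qtls=truth_qtls, epistasis=truth_epi)
    return pheno, truth


# ---------------------------------------------------------------------------
# expression from a DAG
# ---------------------------------------------------------------------------

def simulate_expression(genotypes: GenotypeMatrix, spec: ExpressionDAGSpec, seed: int):
    """Expression matrix from linear structural equations on a random DAG.

    Genes are laid out on the genotype map; each cis-assigned gene receives
    an additive effect from its nearest marker (within the cis window), and
    trans associations arise only by propagation through DAG edges.  Returns
    (expression DataFrame genes x samples, eQTL table, SimTruth).
    """
    rng = np.random.default_rng(seed)
    ng = spec.n_genes
    genes = [f"gene{i + 1}" for i in range(ng)]

    # random DAG on a random topological order (or explicit edges)
    order = rng.permutation(ng)
    coefs = {}
    if spec.edges is not None:
        name_to_i = {g: i for i, g in enumerate(genes)}
        for edge in spec.edges:
            u, v = edge[0], edge[1]
            c = edge[2] if len(edge) > 2 else rng.uniform(*spec.coef_range)
            coefs[(name_to_i[u], name_to_i[v])] = float(c)
        dag = nx.DiGraph(list(coefs))
        dag.add_nodes_from(range(ng))
        topo = list(nx.topological_sort(dag))
    else:
        for ii in range(ng):
            for jj in range(ii + 1, ng):
                if rng.random() < spec.edge_density:
                    c = rng.uniform(*spec.coef_range) * rng.choice([-1.0, 1.0])
                    coefs[(order[ii], order[jj])] = float(c)
        topo = list(order)

    # gene positions on the marker grid; cis marker = nearest within window
    sm = genotypes.snpmap
    marker_idx = rng.choice(genotypes.n_snps, size=ng, replace=ng > genotypes.n_snps)
    gene_chrom = sm["chrom"].to_numpy()[marker_idx]
    gene_pos = sm["pos"].to_numpy()[marker_idx]

    cis_genes = rng.choice(ng, size=min(spec.n_cis_genes, ng), replace=False)
    cis_marker = {}
    for gi in cis_genes:
        j = int(marker_idx[gi])
        cis_marker[int(gi)] = genotypes.snps[j]

    n = genotypes.n_samples
    X = np.zeros((ng, n))
    parents = {}
    for (u, v), c in coefs.items():
        parents.setdefault(v, []).append((u, c))
    for gi in topo:
        x = rng.standard_normal(n) * spec.noise_sd
        for u, c in parents.get(gi, []):
            x = x + c * X[u]
        if gi in cis_marker:
            g = genotypes.dosage_of(cis_marker[gi])
            g = np.where(np.isnan(g), np.nanmean(g), g)
            x = x + spec.cis_effect * (g - g.mean())
        X[gi] = x

    # truth eQTL table: cis assignments plus propagated trans associations
    eqtls = []
    dag = nx.DiGraph(list(coefs))
    dag.add_nodes_from(range(ng))
    for gi, snp in cis_marker.items():
        j = genotypes.snp_index(snp)
        same_chrom = str(sm["chrom"].iloc[j]) == str(gene_chrom[gi])
        is_cis = same_chrom and abs(int(sm["pos"].iloc[j]) - int(gene_pos[gi])) <= spec.cis_window_bp
        eqtls.append(
            {"gene": genes[gi], "snp": snp, "effect": float(spec.cis_effect),
             "kind": "cis" if is_cis else "trans"}
        )
        for desc in nx.descendants(dag, gi):
            eqtls.append(
                {"gene": genes[desc], "snp": snp, "effect": float("nan"),
                 "kind": "trans"}
            )

    expr = pd.DataFrame(X, index=genes, columns=genotypes.samples)
    eqtl_table = pd.DataFrame(eqtls, columns=["gene", "snp", "effect", "kind"])
    truth = SimTruth(
        dag_edges=[(genes[u], genes[v], c) for (u, v), c in sorted(coefs.items())],
        eqtls=eqtls,
    )
    return expr, eqtl_table, truth


# ---------------------------------------------------------------------------
# background network + gene sets
# ---------------------------------------------------------------------------

def simulate_network_and_sets(
    n_genes: int,
    module_sizes: tuple = (12, 25, 40),
    n_decoy_sets: int = 20,
    decoy_size_range: tuple = (5, 2000),
    module_density: float = 1.0,
    seed: int = 0,
):
    """Scale-free background graph with planted dense modules and GMT sets.

    Returns (networkx Graph, gene-set dict name -> list, SimTruth).  The
    emitted sets contain each planted module plus uniformly drawn decoys
    whose sizes span the enrichment size-filter range.
    """
    if max(module_sizes, default=0) > n_genes:
        raise ValueError("module size exceeds gene count")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_genes, 2, seed=int(rng.integers(2**31)))
    mapping = {i: f"gene{i + 1}" for i in range(n_genes)}
    g = nx.relabel_nodes(g, mapping)
    genes = list(mapping.values())

    modules = {}
    pool = rng.permutation(n_genes)
    offset = 0
    for k, size in enumerate(module_sizes):
        members = [genes[i] for i in pool[offset:offset + size]]
        offset += size
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                if module_density >= 1.0 or rng.random() < module_density:
                    g.add_edge(members[ai], members[bi])
        modules[f"module{k + 1}"] = members

    gene_sets = dict(modules)
    lo, hi = decoy_size_range
    sizes = np.unique(
        np.round(np.exp(rng.uniform(np.log(lo), np.log(min(hi, n_genes)), n_decoy_sets)))
    ).astype(int)
    for k, size in enumerate(sizes):
        idx = rng.choice(n_genes, size=size, replace=False)
        gene_sets[f"decoy{k + 1}"] = [genes[i] for i in idx]

    truth = SimTruth(modules=modules)
    return g, gene_sets, truth


# ---------------------------------------------------------------------------
# plain-text formats
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: dict, path: str):
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


def read_gmt(path: str) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_sif(graph: nx.Graph, path: str, relation: str = "pp"):
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in graph.nodes():
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def read_sif(path: str, directed: bool = False) -> nx.Graph:
    g = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 3:
                g.add_edge(parts[0], parts[2])
            elif len(parts) == 1:
                g.add_node(parts[0])
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_edge_list(graph: nx.Graph, path: str, weight: str | None = None):
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            if weight is not None:
                fh.write(f"{u}\t{v}\t{data.get(weight, 1.0):g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str, directed: bool = False, weight: str | None = None) -> nx.Graph:
    g = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 3 and weight is not None:
                g.add_edge(parts[0], parts[1], **{weight: float(parts[2])})
            elif len(parts) >= 2:
                g.add_edge(parts[0], parts[1])
    g.remove_edges_from(nx.selfloop_edges(g))
    return g
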