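"""End-to-end pipeline orchestration with a single config and manifest.

Runs the stages simulate -> QC -> kinship/association -> loci -> Bayesian
network ensemble -> network statistics -> conditional interaction scan in
dependency order from one :class:`RunConfig`, writing every product as a
plain-text file plus a JSON manifest of parameters, seeds and output
hashes.  The manifest contains no timestamps, so a re-run with identical
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import bayesnet, conditional_scan, netstats, synthetic_data

logger = logging.getLogger("sysgenet")

__all__ = ["RunConfig", "run_pipeline", "default_config", "load_config"]


@dataclass
class RunConfig:
    """All stage parameters; defaults mirror the study's stated constants."""

    out_dir: str = "sysgenet_run"
    seed: int = 1

    # simulation scale (bundled small config: chromosomes keep ~1 Morgan
    # genetic length; marker count is reduced by widening the spacing)
    n_chrom: int = 10
    snps_per_chrom: int = 80
    snp_spacing_bp: int = 1_200_000
    n_f2: int = 500
    fst: float = 0.4
    h2: float = 0.3
    qtl_effects: list = field(default_factory=lambda: [0.45])
    epistasis_effect: float = 0.4

    # QC (call rate, MAF, HWE exact p)
    min_call_rate: float = 0.95
    min_maf: float = 0.15
    min_hwe_p: float = 5e-6

    # association
    fdr_level: float = 0.05
    locus_half_width_bp: int = 200_000

    # bayes net
    n_expr_genes: int = 20
    n_expr_samples_stage: bool = True
    ensemble_runs: int = 25
    consensus_threshold: float = 0.30
    variance_quantile: float = 0.8

    # network statistics
    n_net_genes: int = 300
    module_sizes: list = field(default_factory=lambda: [12, 20])
    n_perm: int = 2000
    d_rule_threshold: int = 50
    set_min_size: int = 11
    set_max_size: int = 1499
    enrich_alpha: float = 0.05

    # conditional scan
    cond_exclusion_bp: int = 1_000_000

    stages: list = field(
        default_factory=lambda: ["simulate", "qc", "assoc", "loci", "bayesnet", "netstats", "cond_scan"]
    )


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig(**data)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sysgenet",
        "config": asdict(config),
        "stages": [],
        "outputs": {},
    }
    produced: dict[str, Path] = {}

    def record(stage: str, files: dict):
        manifest["stages"].append(stage)
        for name, path in files.items():
            produced[name] = Path(path)
        logger.info("stage=%s outputs=%s", stage, sorted(files))

    state: dict = {}
    try:
        if "simulate" in config.stages:
            state.update(_stage_simulate(config, out))
            record("simulate", state["sim_files"])
        if "qc" in config.stages:
            state.update(_stage_qc(config, out, state))
            record("qc", state["qc_files"])
        if "assoc" in config.stages:
            state.update(_stage_assoc(config, out, state))
            record("assoc", state["assoc_files"])
        if "loci" in config.stages:
            state.update(_stage_loci(config, out, state))
            record("loci", state["loci_files"])
        if "bayesnet" in config.stages:
            state.update(_stage_bayesnet(config, out, state))
            record("bayesnet", state["bn_files"])
        if "netstats" in config.stages:
            state.update(_stage_netstats(config, out, state))
            record("netstats", state["ns_files"])
        if "cond_scan" in config.stages:
            state.update(_stage_cond_scan(config, out, state))
            record("cond_scan", state["cs_files"])
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "startup"
        for name, path in produced.items():
            p = Path(path)
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline aborted after stage {stage!r}: {exc}") from exc

    for name, path in sorted(produced.items()):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("manifest=%s", manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> dict:
    gmap = synthetic_data.GeneticMap.regular(
        n_chrom=config.n_chrom,
        snps_per_chrom=config.snps_per_chrom,
        spacing_bp=config.snp_spacing_bp,
    )
    ped = synthetic_data.PedigreeSpec(n_f2=config.n_f2, fst=config.fst)
    geno, pedigree = synthetic_data.simulate_f2_cross(gmap, ped, seed=config.seed)

    rng = np.random.default_rng(config.seed + 1)
    # one additive QTL per listed effect, plus one pure interaction pair;
    # planted markers drawn among well-segregating SNPs (MAF > 0.3)
    d = geno.dosages.astype(float)
    freq = d.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    cand = np.flatnonzero(maf > 0.3)
    if len(cand) < len(config.qtl_effects) + 2:
        cand = np.argsort(-maf)[: len(config.qtl_effects) + 2]
    picks = rng.choice(cand, size=len(config.qtl_effects) + 2, replace=False)
    qtl_markers = [geno.snps[int(i)] for i in picks]
    qtls = [(m, a, 0.0) for m, a in zip(qtl_markers, config.qtl_effects)]
    epi = (qtl_markers[-2], qtl_markers[-1], config.epistasis_effect)
    kin = assoc_mod.compute_kinship(geno)
    pheno, truth = synthetic_data.simulate_phenotype(
        geno, kin, synthetic_data.QTLSpec(qtls=qtls, epistasis=epi, h2=config.h2),
        seed=config.seed + 2, pedigree=pedigree,
    )

    expr_spec = synthetic_data.ExpressionDAGSpec(n_genes=config.n_expr_genes)
    expr, eqtl_table, expr_truth = synthetic_data.simulate_expression(
        geno, expr_spec, seed=config.seed + 3
    )
    net, gene_sets, net_truth = synthetic_data.simulate_network_and_sets(
        config.n_net_genes, module_sizes=tuple(config.module_sizes), seed=config.seed + 4
    )
    truth.dag_edges = expr_truth.dag_edges
    truth.eqtls = expr_truth.eqtls
    truth.modules = net_truth.modules

    files = {}
    assoc_mod.write_plink(geno, str(out / "genotypes"), pedigree=pedigree)
    files["genotypes.ped"] = out / "genotypes.ped"
    files["genotypes.map"] = out / "genotypes.map"
    _write_tsv(pheno, out / "phenotypes.tsv")
    files["phenotypes.tsv"] = out / "phenotypes.tsv"
    _write_tsv(pedigree, out / "pedigree.tsv")
    files["pedigree.tsv"] = out / "pedigree.tsv"
    expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.8g")
    files["expression.tsv"] = out / "expression.tsv"
    _write_tsv(eqtl_table, out / "eqtls.tsv")
    files["eqtls.tsv"] = out / "eqtls.tsv"
    synthetic_data.write_sif(net, str(out / "network.sif"))
    files["network.sif"] = out / "network.sif"
    synthetic_data.write_gmt(gene_sets, str(out / "gene_sets.gmt"))
    files["gene_sets.gmt"] = out / "gene_sets.gmt"
    truth.to_json(str(out / "truth.json"))
    files["truth.json"] = out / "truth.json"

    return {
        "geno": geno, "pedigree": pedigree, "pheno": pheno, "kinship": kin,
        "expr": expr, "eqtl_table": eqtl_table, "network": net,
        "gene_sets": gene_sets, "truth": truth, "sim_files": files,
    }


def _stage_qc(config: RunConfig, out: Path, state: dict) -> dict:
    thresholds = assoc_mod.QCThresholds(
        min_call_rate=config.min_call_rate,
        min_maf=config.min_maf,
        min_hwe_p=config.min_hwe_p,
    )
    geno_qc, report = assoc_mod.qc_filter(state["geno"], thresholds)
    _write_tsv(report, out / "qc_report.tsv")
    return {"geno_qc": geno_qc, "qc_files": {"qc_report.tsv": out / "qc_report.tsv"}}


def _stage_assoc(config: RunConfig, out: Path, state: dict) -> dict:
    geno = state["geno_qc"]
    kin = assoc_mod.compute_kinship(geno)
    pheno = state["pheno"]
    fit = assoc_mod.fit_polygenic_null(
        pheno["trait"], pheno[["sex", "batch"]], kin
    )
    result = assoc_mod.score_scan(fit, geno)
    _write_tsv(result.table, out / "assoc.tsv")
    return {
        "kinship_qc": kin, "null_fit": fit, "assoc_result": result,
        "assoc_files": {"assoc.tsv": out / "assoc.tsv"},
    }


def _stage_loci(config: RunConfig, out: Path, state: dict) -> dict:
    result = state["assoc_result"]
    cutoff = assoc_mod.fdr_threshold(result.table["p"], config.fdr_level)
    loci = (
        assoc_mod.define_loci(result, cutoff, config.locus_half_width_bp)
        if cutoff > 0 else []
    )
    rows = [
        {
            "peak_snp": l.peak_snp, "chrom": l.chrom, "peak_pos": l.peak_pos,
            "start": l.start, "end": l.end, "peak_p": l.peak_p,
            "n_members": len(l.member_snps),
        }
        for l in loci
    ]
    df = pd.DataFrame(rows, columns=["peak_snp", "chrom", "peak_pos", "start", "end", "peak_p", "n_members"])
    _write_tsv(df, out / "loci.tsv")
    return {
        "loci": loci, "fdr_cutoff": cutoff,
        "loci_files": {"loci.tsv": out / "loci.tsv"},
    }


def _stage_bayesnet(config: RunConfig, out: Path, state: dict) -> dict:
    expr = state["expr"]
    eqtl_df = state["eqtl_table"].rename(columns={"effect": "strength"})
    eqtl_df["strength"] = eqtl_df["strength"].abs().fillna(0.0)
    eqtl = bayesnet.EQTLTable(eqtl_df[["gene", "snp", "strength", "kind"]])
    prior = bayesnet.build_priors(eqtl)
    ensemble = bayesnet.build_ensemble(
        expr, prior=prior, n_runs=config.ensemble_runs, base_seed=config.seed + 10
    )
    consensus = bayesnet.build_consensus(ensemble, threshold=config.consensus_threshold)
    consensus = bayesnet.break_cycles(consensus)
    synthetic_data.write_edge_list(consensus.graph, str(out / "consensus_edges.tsv"), weight="frequency")
    sidecar = {
        "n_runs": config.ensemble_runs,
        "threshold": config.consensus_threshold,
        "removed_edges": [list(e) for e in consensus.removed_edges],
        "seeds": ensemble.seeds,
    }
    with open(out / "consensus_meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return {
        "consensus": consensus,
        "bn_files": {
            "consensus_edges.tsv": out / "consensus_edges.tsv",
            "consensus_meta.json": out / "consensus_meta.json",
        },
    }


def _stage_netstats(config: RunConfig, out: Path, state: dict) -> dict:
    net = state["network"]
    truth = state["truth"]
    gene_sets = state["gene_sets"]
    module = next(iter(truth.modules.values()))
    sub = netstats.extract_subnetwork(
        net, module, netstats.SubnetworkSpec(seeds=module, seed_threshold=config.d_rule_threshold)
    )
    coreg = netstats.coreg_permutation_test(
        net, module, n_perm=config.n_perm, seed=config.seed + 20
    )
    enrich = netstats.enrich_gene_sets(
        set(sub.nodes), gene_sets, net.nodes,
        min_size=config.set_min_size, max_size=config.set_max_size,
        alpha=config.enrich_alpha,
    )
    for r in enrich[:3]:
        r.shuffle_p = netstats.shuffle_empirical_p(
            net, sub, set(gene_sets[r.set_id]), n_perm=config.n_perm,
            seed=config.seed + 21,
        )
    _write_tsv(netstats.enrichment_to_frame(enrich), out / "enrichment.tsv")
    coreg_df = pd.DataFrame(
        [{
            "observed_mean_distance": coreg.observed,
            "n_perm": coreg.n_perm,
            "n_below": coreg.n_below,
            "empirical_p": coreg.p,
            "n_pairs": coreg.n_pairs,
            "n_disconnected_pairs": coreg.n_disconnected_pairs,
        }]
    )
    _write_tsv(coreg_df, out / "coreg.tsv")
    return {
        "subnetwork": sub, "coreg": coreg, "enrichment": enrich,
        "ns_files": {"enrichment.tsv": out / "enrichment.tsv", "coreg.tsv": out / "coreg.tsv"},
    }


def _stage_cond_scan(config: RunConfig, out: Path, state: dict) -> dict:
    truth = state["truth"]
    if truth.epistasis is None:
        return {"cs_files": {}}
    geno = state["geno_qc"]
    pheno = state["pheno"]
    kin = state.get("kinship_qc") or assoc_mod.compute_kinship(geno)
    snp_a, snp_b = truth.epistasis["snp_a"], truth.epistasis["snp_b"]
    # conditioning markers must have survived QC; fall back to nearest
    def surviving(snp):
        if snp in geno.snps:
            return snp
        full = state["geno"]
        j = full.snp_index(snp)
        chrom = str(full.snpmap["chrom"].iloc[j])
        pos = int(full.snpmap["pos"].iloc[j])
        cand = geno.snpmap[geno.snpmap["chrom"].astype(str) == chrom]
        if cand.empty:
            raise ValueError(f"no QC-passing SNP on chromosome {chrom}")
        jj = (cand["pos"] - pos).abs().idxmin()
        return geno.snps[int(jj)]

    snp_a, snp_b = surviving(snp_a), surviving(snp_b)
    fit = conditional_scan.fit_conditional_null(
        pheno["trait"], pheno[["sex", "batch"]], kin, geno, snp_a, snp_b
    )
    res = conditional_scan.interaction_scan(
        fit, geno, snp_a, exclusion_window_bp=config.cond_exclusion_bp
    )
    _write_tsv(res.table, out / "conditional_scan.tsv")
    return {
        "cond_result": res,
        "cs_files": {"conditional_scan.tsv": out / "conditional_scan.tsv"},
    }


def setup_logging(verbose: bool = True):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s stage-log level=%(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
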