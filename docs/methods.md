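# Methods

`sysgenet` re-creates, as a tested pipeline on synthetic data, the analysis
chain of a systems-genetics study of a pig F2 intercross: mixed-model SNP
association with a genomic kinship, Bayesian causal-network consensus with
eQTL structure priors, seed-based subnetwork statistics with permutation
nulls, and a conditional genotype×genotype interaction scan.  This note
records the models, the defaults and why they were chosen, and what the
synthetic data does and does not establish.

## The simulated cross

The generator emulates a two-breed F2 design: 2 founder boars of one breed
× 17 founder sows of another → F1, then 59 F1 sows × 9 F1 boars → F2.
Each F1 dam litters with two distinct sires, giving ~118 full-sib families,
matching the roughly 110 families of the design being emulated; family
sizes are multinomial because only totals are known.

* **Founder breeds** are outbred populations, not fixed lines: per-SNP
  allele frequencies for the two breeds are drawn from a Balding–Nichols
  F-model around a common ancestral frequency (uniform on [0.1, 0.9]),
  with divergence `fst = 0.4` by default.  This keeps realistic
  within-breed heterozygosity (the founder sows come from three farms)
  while still producing strongly segregating F2 markers.
* **Meiosis** follows the Haldane model: crossover count per chromosome is
  Poisson(length in Morgans), positions uniform in genetic distance, no
  interference.  This is the standard analytically checkable model; the
  test suite verifies the recombination fraction `r = (1 − e^{−2d/100})/2`
  at 10 cM directly.
* **Marker grid**: the default map is 18 autosomes × 650 markers at 181 kb
  spacing (≈11.7 K SNPs, ≈118 cM per chromosome at 1 cM/Mb), emulating a
  post-QC 60 K-chip marker set.  Scaled-down maps used in tests widen the
  spacing instead of shortening chromosomes: a chromosome much shorter
  than ~1 Morgan behaves as a single linkage block, which makes the
  mixed model absorb any QTL on it and is not representative of a real
  genome.
* **Phenotypes**: `y = μ + sex + batch + Σ QTL terms + u + e` with
  `u ~ N(0, σg² K)`.  Effects are specified in phenotype-SD units; writing
  `v_q` for the realized variance of the summed QTL genetic values, the
  polygenic and residual variances are `h2(1 − v_q)` and `(1 − h2)(1 − v_q)`,
  so the non-fixed variance totals 1 and an additive effect `a` at an
  equifrequent F2 marker explains `a²/2` of it.  Sex is Bernoulli(1/2)
  (taken from the pedigree), batches are assigned round-robin.
* **Expression** comes from linear-Gaussian structural equations on a
  random DAG (or an explicit edge list); cis-assigned genes additionally
  receive a dosage effect from a marker at the gene's position, and trans
  eQTLs exist only through DAG paths.  The emitted eQTL table labels each
  gene–marker pair cis or trans by a 1 Mb window.
* **Networks and gene sets**: a Barabási–Albert scale-free background with
  planted dense modules (default sizes 12/25/40 — all above the
  enrichment size-filter floor of >10 genes, so planted modules are
  testable) and GMT sets containing the modules plus log-uniform-size
  random decoys.

What the generator does **not** emulate: genotyping error and missingness
patterns of a real chip (missingness must be injected explicitly for QC
tests), sex chromosomes, crossover interference, selection, and any
realistic gene-regulatory topology beyond DAG-structured linear effects.
Passing recovery tests therefore show the *statistical machinery* is
correct and powered under the design's family structure — not that the
pipeline would reproduce any particular biological result.

## GWAS layer

* **QC**: a SNP is kept iff call rate ≥ 0.95, MAF ≥ 0.15 and exact-test
  HWE p ≥ 5×10⁻⁶ (the study's stated thresholds; all configurable).  The
  HWE test is a Wigginton-style exact enumeration of the heterozygote
  count given allele counts.
* **Kinship**: VanRaden-type centered-and-scaled genomic relationship
  `ZZ' / (2Σp(1−p))` (missing entries contribute zero after centering),
  with an IBS option.  The emulated tool's internal estimator is not
  documented, so a field-standard estimator is used.
* **Null model**: REML of `y = μ + sex + batch + u + e` profiled in
  `h² = σg²/(σg²+σe²)` on the eigenbasis of K (bounded scalar
  optimization, tolerance 1e-8).  Kinship eigenvalues slightly negative
  from finite-SNP noise are clipped at zero; a matrix far from PSD is an
  error.
* **Score scan**: per SNP, the 1-df score statistic `(g'Py)²/(g'Pg)` with
  `P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹` — the "association on variance-adjusted
  residuals" construction.  Missing genotypes are mean-imputed per SNP
  (QC bounds missingness at 5%), monomorphic SNPs are skipped and counted.
  Under the null F2 simulation (h² = 0.3, n = 400) the empirical size at
  α = 0.05 is ≈0.05.
* **Proximal contamination**: because the tested SNP's linkage block is
  inside K, part of a large QTL's signal is absorbed by the polygenic term
  (the classic cost of a single-kinship mixed model).  A
  leave-one-chromosome-out scan is provided (`association_scan(loco=True)`)
  but is **off by default**: with only two founder sires, family structure
  correlates dosages *across* chromosomes, and the LOCO null then fails to
  condition on all confounding (measured empirical size ≈0.10 at α = 0.05
  under the purely polygenic null).  The genome-wide-kinship scan is
  calibrated and is what all shipped analyses use.
* **FDR and loci**: Benjamini–Hochberg step-up cutoff (the study states
  only "FDR < 5%"); significant SNPs are greedily clustered around peaks
  (ties broken toward lower bp), each locus spanning peak ± 200 kb as a
  closed 1-based interval; genes are mapped by any-overlap with the
  window.

## Bayesian network layer

* **Gene selection**: union of the top-20% variance genes (ties by gene
  id) and genes with an eQTL at or above a strength cutoff.
* **Structure priors**: for each marker, a gene with a cis eQTL there is
  an *allowed* parent of every gene with a coincident (same-marker) trans
  eQTL, and the reverse orientation is *forbidden*.  "Coincident" is read
  as same-marker co-mapping.  Allowed edges earn a log-score bonus
  (default log 10) rather than being forced — a mandatory edge for every
  cis–trans pair would be ill-posed — while forbidden edges are hard
  constraints never proposed.  A gene labeled both cis and trans at one
  marker is treated as cis, with a warning.
* **Scoring and search**: expression is discretized into 3 ordered states
  per gene by deterministic 1-D k-means (quantile-initialized Lloyd; no
  RNG, so run seeds are the only stochastic input), scored by discrete
  BIC; a linear-Gaussian BIC mode is available.  Search is random-restart
  hill climbing over add/delete/reverse moves with a parent limit
  (default 3).  On ≤3 genes the search provably attains the exhaustive
  optimum over all 25 DAGs (tested).
* **Ensemble and consensus**: `n_runs` learners with seeds
  `base_seed … base_seed+n_runs−1`, each on a bootstrap resample of the
  samples (configurable).  The reference procedure uses 1000 runs; the
  package default is 100 for desk-scale runtimes — this is a config
  value, not a fixed constant.  Consensus keeps edges present in
  **strictly more than** 30% of runs.  Remaining directed cycles are
  broken by locating a shortest cycle (deterministic node order) and
  deleting its minimum-frequency edge, ties toward the lexicographically
  smallest pair; removals are logged.
* On a 30-gene, 300-sample synthetic DAG, the 100-run consensus reaches
  undirected precision ≈0.8 and recall ≈0.6, and correct priors never
  reduced directed precision in 10 paired seeds.

## Network statistics

* **Depth rule**: subnetwork neighborhoods use d = 2 when fewer than 50
  in-network seeds are given, else d = 1 (exactly 50 → 1).  Distances and
  neighborhoods are computed on the underlying undirected graph even for
  directed networks, since pairwise "closeness" is symmetric in use.
* **Co-regulation**: average unweighted shortest distance over all
  in-network pairs of a gene set; cross-component pairs are excluded from
  the mean and counted (a pseudo-distance would make the statistic depend
  on an arbitrary constant).  The permutation null draws same-size node
  sets uniformly; the empirical p counts permuted means **strictly
  below** the observed (the procedure-literal rule, so a p of 0 is
  possible and is formatted as "< 1/n_perm"); an add-one-corrected
  variant is a flag.  Distance matrices come from `scipy.sparse.csgraph`
  BFS, precomputed in full below 3000 nodes.
* **Enrichment**: one-sided Fisher's exact test `P(X ≥ k)`, the EASE
  score (same test with the overlap reduced by one, margins unchanged;
  k ≤ 1 → 1), and fold enrichment `(k/n)/(K/N)`.  Collections are
  filtered to in-background size in (10, 1500) exclusive; reporting uses
  Bonferroni α/#tested (B-H by flag).  The label-shuffle empirical p
  permutes node labels and re-reads the fixed subnetwork positions —
  equivalent to a hypergeometric redraw, which the tests exploit as an
  oracle.

## Conditional interaction scan

Stage one fits the mixed model with the two conditioning markers as
additive fixed effects and returns `e = y − Xβ̂ − û` (BLUP subtracted).
Stage two regresses e on the R-style expansion of `e ~ g + g*g_cond`,
i.e. design `[1, g_cond, g, g·g_cond]`, reporting the 2-df F test of
{g, g·g_cond} (the ranking statistic) and the t test of the product term.
Two numerical points matter:

* The regression is performed in the **whitened space** `V^{−1/2}` of the
  stage-one fit.  Plain OLS on BLUP-adjusted residuals is severely
  deflated (measured size ≈0.006 at α = 0.05 — the familiar two-stage
  residual problem), while the whitened regression is an exact GLS and is
  calibrated; it also nearly triples the power to place a planted pure
  interaction at the genome-wide minimum.  If a `ConditionalFit` carries
  no stage-one model, the scan falls back to OLS.
* SNPs within 1 Mb (configurable) of either conditioning marker are
  excluded, and a design whose product column is collinear (e.g. a
  near-constant conditioning genotype) is skipped rather than absorbed.

## Problem sizes and degenerate inputs

Shipped analyses and the acceptance script use scaled study conditions
chosen once: null calibration on a 5,500-marker, n = 400 cross; QTL
recovery on 18 × 60 markers (1.8 Mb spacing), n = 500, 20 replicates;
interaction recovery on 6 × 30 markers (4 Mb), n = 500, 20 replicates;
network recovery on 30 genes × 300 samples × 100 ensemble runs.  The
bundled pipeline config is 10 chromosomes × 80 markers, n = 500, with a
25-run ensemble and 2,000 permutations.

Degenerate inputs are rejected, not silently absorbed: empty maps, h²
outside [0, 1], constant phenotypes, monomorphic-only kinship input,
monomorphic conditioning markers, ~zero conditional residual variance,
and sample mismatches between fits and genotype matrices all raise
errors; QC removing every SNP and seeds missing from a network warn.

## Known limitations

* The structure search is greedy; on larger gene sets it finds local
  optima, and consensus frequencies inherit that bias.  No posterior
  sampling is attempted.
* The score test loses power on very large QTLs through proximal
  contamination (see above); effect sizes near fixation or maps with
  sub-Morgan chromosomes exacerbate this.
* Permutation p-values are lower-bounded by 1/n_perm; multiple-testing
  over many permutation tests is not corrected internally.
* The enrichment layer treats gene sets as flat; no ontology structure
  or term redundancy handling.
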