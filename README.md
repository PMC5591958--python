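# emp-mirnet

Integrative analysis of circulating miRNAs and endothelial damage:
screen plasma miRNA expression for association with PECAM+
endothelial-microparticle (EMP) levels, infer the co-expression network
of the associated miRNAs with a shrinkage Gaussian graphical model
(GGM), rank its hubs, test genomic regions (e.g. the 14q32 / DLK1-DIO3
miRNA cluster) for overrepresentation among the co-expressed miRNAs, and
validate candidates by 2^−ΔΔCt qPCR. A synthetic-data generator with
planted ground truth makes every stage testable end to end.

The package is aimed at researchers analysing feature-by-sample
expression matrices against a scalar vascular readout — here, EMP
counts/μl from flow cytometry in bicuspid (BAV) vs tricuspid (TAV)
aortic-valve cohorts — but the stages are generic.

## The model in brief

* **Screen** — Spearman correlation of each expressed miRNA (detection in
  ≥ 5% of samples) with ln(EMP/μl); candidates at p < 0.05, BH q-values
  reported.
* **Network** — shrinkage correlation estimate with analytic intensity
  λ\* = Σ V̂ar(r_ij) / Σ r_ij²; partial correlations
  ρ_ij = −ω_ij/√(ω_ii ω_jj) from the inverse; two-component empirical
  Bayes model η₀·f0(ρ; κ) + (1−η₀)·U(−1,1) with
  f0(ρ; κ) ∝ (1−ρ²)^((κ−3)/2); an edge is kept when its posterior
  probability 1 − fdr(ρ) exceeds 0.95 (local fdr < 5%).
* **Topology** — degree, betweenness, stress, closeness and radiality on
  unweighted shortest paths; hubs ranked by summed ranks.
* **Enrichment** — upper-tail hypergeometric probability
  P(X ≥ k) for overlap k between a region's K members and the n network
  miRNAs out of N on the platform, in log-space with an exact rational
  cross-check.
* **qPCR** — fold change 2^−ΔΔCt against a U6 endogenous control and a
  TAV reference group, correlated with log-EMP.

See `docs/methods.md` for the full account, including the estimation
choices inside the mixture fit and the generator's coupling model.

## Worked example

Run the full pipeline on a synthetic dataset with planted structure
(a 60-miRNA co-expressed block with a designated hub, an EMP-coupled
feature subset and one enriched genomic cluster):

```python
from emp_mirnet import PipelineConfig, run_all, SyntheticConfig

cfg = PipelineConfig(outdir="demo", seed=7,
                     synthetic=SyntheticConfig.verification())
manifest = run_all(cfg, log=print)
```

prints

```
simulate: 200 features x 1000 samples
filter: 120/200 features expressed
associate: 83 features at alpha=0.05
network: 54 nodes, 74 edges (largest component 54)
topology: top hub miR-SYN-0001
enrich: top region chr14q32-like
qpcr: 6 targets validated
```

Reading the output: 120 of 200 simulated miRNAs pass the 5% detection
filter; 83 correlate with log-EMP at p < 0.05; the GGM keeps 74 edges at
posterior probability > 0.95, forming one 54-node component. The
topology stage identifies `miR-SYN-0001` — the planted hub — as the top
hub, and the enrichment report ranks the planted `chr14q32-like` cluster
first (`demo/enrichment.tsv`):

```
region_or_set  k  K  n   N        p        q
chr14q32-like 13 25 54 200 0.004006 0.040063
     chr5-R05  7 19 54 200 0.223983 0.997443
```

i.e. 13 of the 54 network miRNAs fall in the 25-member planted cluster
(universe 200), upper-tail p ≈ 4·10⁻³, the only region significant after
BH. Every artifact (association table, GraphML/SIF network, topology and
enrichment TSVs, ΔΔCt fold changes, a manifest with SHA-256 checksums)
lands in `demo/`; rerunning with the same seed reproduces identical
checksums.

The same stages are available as subcommands of the `emp-mirnet` CLI
(`simulate`, `filter`, `associate`, `network`, `topology`, `enrich`,
`qpcr`, `run-all`); note the defaults of `SyntheticConfig` emulate the
original study scale (1,205 miRNAs × 24 samples) — at that sample size
the network stage correctly reports that no edge reaches posterior 0.95
(see `docs/methods.md`).

A note on file formats: genomic loci are read from BED (0-based
half-open) with the region label carried in column 7, which BED parsers
tolerate; gene sets use GMT; networks export to GraphML (attributes
preserved) and SIF.

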