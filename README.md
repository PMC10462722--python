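# asmbly

Community-assembly inference for root-associated microbiomes.

`asmbly` re-implements, as a tested and reusable Python pipeline, the
statistical workflow used to dissect how bacterial communities assemble
along the soil → rhizosphere → root endosphere → nodule continuum of a
legume host (soybean) sampled across developmental stages and cultivars:

- **Diversity and variance partitioning** — Chao1 richness, Bray–Curtis and
  binary-Jaccard dissimilarities, one-factor PERMANOVA (pseudo-*F* with
  label-permutation *p*-values), the Mantel test, and Chevan–Sutherland
  hierarchical partitioning of α-diversity variance among design factors.
- **Phylogenetic null-model inference (βNTI)** — abundance-weighted β-mean
  nearest taxon distance (βMNTD) z-scored against a tip-shuffling null;
  |βNTI| ≥ 2 reads as deterministic assembly (negative: homogeneous
  selection; positive: variable selection), |βNTI| < 2 as stochastic.
- **Sloan neutral community model** — the occurrence-frequency vs.
  mean-relative-abundance relationship `freq = 1 − I_d(Nm·p, Nm·(1−p))`
  fitted by nonlinear least squares for the single parameter *N·m*
  (community size × migration rate), with *R²* as the neutrality score and
  a Wilson-band partition of taxa into above/within/below-prediction.
- **Niche breadth and the core microbiome** — Levins index
  `B = 1/Σ_h P_h²` over developmental stages, permutation-null
  generalist/specialist calls, and "core generalists": taxa classified as
  generalists *and* detected at every stage in bulk soil, rhizosphere and
  root endosphere.
- **Bayesian source tracking** — a collapsed-Gibbs mixture model
  (SourceTracker-style, with an adaptive Unknown source) attributing each
  sink community's reads to upstream compartments.
- **Microbe–trait association** — Spearman screen with BH correction and
  the significant-and-strong filter (*p* < 0.05, |ρ| > 0.5), plus
  random-forest out-of-bag permutation importance with
  response-permutation significance.
- **Enrichment decision rule** — BH adjustment and the
  |log₂FC| > 2, *q* < 0.05 call applied to externally supplied per-taxon
  differential statistics.

Because the original sequencing data are not required, the package ships a
**synthetic-community generator** (`asmbly.synth`) that emulates the full
2-cultivar × 4-stage × 4-compartment design with *known* ground truth:
metacommunity, migration rate, phylogenetically conserved selection,
source-mixing chain, planted core taxa and taxon-linked plant traits.
Every estimator is validated by recovering what the generator planted.

## Worked example

```python
import asmbly as A

# a small neutral community with known N*m = 2000 * 0.25 = 500
p = A.simulate_metacommunity(300, sigma_log=1.5, seed=0)
table = A.assemble_neutral(p, N=2000, m=0.25, n_samples=200, seed=1)

fit = A.SloanNCM(table).fit()
print(fit.summary().to_string(index=False))
```

```
        Nm        m      N        d       R2  n_taxa  n_samples  n_above  n_within  n_below
471.203393 0.235602 2000.0 0.000347 0.990749     300        200       39       245       16
```

The fitted `Nm` of 471 recovers the planted 500 within 6%; `R2 = 0.99`
says the occupancy–abundance cloud is as neutral as it was built to be;
245 of 300 taxa sit inside the 95% Wilson band around the neutral
prediction. On a selection-structured community the same call returns a
much lower `R2` and a fitted `m` orders of magnitude smaller — the
comparison `A.compare_fits(fit_neutral, fit_selective)` tabulates exactly
that contrast.

The full pipeline runs from one YAML config:

```bash
asmbly simulate --config sim.yaml --out data/      # or bring your own TSV + Newick
asmbly run --config run.yaml                        # rarefy -> diversity -> bNTI -> NCM -> niche -> sourcetrack -> traits
```

and writes per-stage TSV/JSON results plus a `manifest.json` with the
derived per-stage seeds (every stage is reproducible in isolation).

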