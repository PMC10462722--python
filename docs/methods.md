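# Methods

This note documents the models implemented in `asmbly`, the choices made
where the methodology was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Input processing

The universal input is a samples × ASVs count table with sample metadata
(compartment, developmental stage, cultivar, replicate), a rooted
phylogeny over the ASVs, and an optional per-sample plant-trait table.
Counts must be nonnegative integers; zero-total samples are dropped at
load with a warning. Depth normalization subsamples each library without
replacement (multivariate hypergeometric) to a common depth, by default
`floor(0.95 × min library size)` — a conservative reading of
"95th percentile of the lowest sampling depth" that retains every sample;
any depth can be passed explicitly. ASVs missing from the phylogeny are a
hard error in phylogenetic stages.

## Diversity, PERMANOVA, variance partitioning

Chao1 defaults to the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))`, finite when no doubletons are observed; the
classic form is available. Bray–Curtis is abundance-weighted; Jaccard is
computed on presence/absence, so the two metrics separate abundance-driven
from membership-driven structure.

PERMANOVA is the one-factor Anderson pseudo-*F* on squared distances,
applied factor by factor (each design factor reported with its own
R²/p pair); multi-factor sequential partitioning is intentionally out of
scope. *p*-values use the `(hits+1)/(perms+1)` correction, so p = 0 is
impossible; an exact mode enumerates all label permutations for small
designs. Hierarchical partitioning fits OLS models for every subset of
the dummy-coded factors and averages marginal R² gains over orderings
(Chevan–Sutherland); the independent contributions sum to the full-model
R² exactly, which the tests assert to 1e-10.

## βMNTD / βNTI

For communities *k, m* with relative abundances *f* and cophenetic
distance *D*:

    βMNTD(k,m) = ½ [ Σ_i f_ik · min_{j∈m} D(i,j) + Σ_j f_jm · min_{i∈k} D(i,j) ]

Shared taxa contribute zero (the minimum includes the self-match), the
standard convention. The null shuffles tip labels uniformly over the
**full species pool** — the table's entire ASV column set, not merely the
taxa observed in the samples under test. This matters: communities
restricted to one clade by selection would otherwise be shuffled within
that same clade and the selection signal would vanish identically (we
verified the near-zero z-scores are reproduced by the reference R
implementation when given the reduced pool, confirming pool choice, not
implementation, as the cause). Users should therefore subset tables by
*samples* and keep all columns. βNTI is the per-pair z-score of the
observed βMNTD against 999 randomizations by default; pairs with zero
null spread return NaN with a warning and are excluded (but tallied) from
the stochastic fraction, defined as the share of finite pairs with
|βNTI| < 2. βNTI is exactly invariant to uniform branch-length scaling
(the z-score cancels the factor); the suite asserts this.

## Sloan neutral community model

The detection frequency of a taxon with metacommunity relative abundance
*p* is `1 − I_d(Nm·p, Nm·(1−p))`, the Beta survival function at the
detection limit *d*. We fit log(*N·m*) by bounded least squares on
untransformed frequencies (coarse grid then local refinement — the 1-D
objective is well-behaved), with *N* = mean library depth, *p* estimated
as the mean relative abundance, and frequency as the fraction of samples
with a nonzero count.

**Detection limit.** The conventional choice *d* = 1/*N* treats detection
as a sharp threshold at one read. Real detection through *N* reads is the
soft kernel `P(detect | x) = 1 − (1−x)^N`, whose half-detection point sits
at `x = 1 − 2^(−1/N) ≈ ln 2 / N`. On data generated from the model's own
stationary law (known *N·m*), the sharp 1/*N* limit inflates the fitted
*N·m* by roughly 30% — and an independent fit with the reference R
implementation (minpack.lm) returns the same inflated value, so this is a
property of the convention, not of our optimizer. `asmbly` therefore
defaults to *d* = ln 2/*N*, which recovers planted *N·m* within ~8%;
passing `d=1/N` reproduces the conventional behavior exactly. R² is
reported unclipped and can be negative. Per-taxon partitions use a 95%
Wilson binomial band around the prediction at n = number of samples. A
selection pressure shared by every sample merely reshapes the estimated
metacommunity and is invisible to the fit; the R² contrast appears when
selection varies across samples or habitats, which is how the paired
neutral-vs-selective tests are constructed.

## Niche breadth and core generalists

Levins breadth `B_j = 1/Σ_h P_jh²` is computed from each taxon's summed
reads over the four developmental stages within one microhabitat
(B ∈ [1, 4]). Significance uses a margin-preserving matrix-randomization
null, which per taxon reduces to a multinomial reallocation of its total
reads over stages proportional to stage read depth: generalists are taxa
spread **more evenly than multinomial resampling of themselves** (a
regulated population), specialists more concentrated than chance. A
whole-sample label-shuffle null is also provided
(`null="sample_shuffle"`), but note its structural limitation: for any
taxon whose counts are exchangeable across samples the observed B is
itself a draw from that null, so it can never call such a taxon a
generalist — it is useful mainly for class-structured restriction. The
false-generalist rate under exchangeable data is ~2.5% by construction
with either null (asserted ≤ 4% in the suite).

Core generalists for a cultivar are taxa classified generalist **and**
detected (count > 0 in ≥ 1 replicate) at every stage, in each of bulk
soil, rhizosphere and root endosphere, intersected across the three
microhabitats; nodules are excluded from the definition.

## Source tracking

A collapsed Gibbs sampler over per-read source assignments with Dirichlet
smoothing: known sources are summed per environment; an Unknown source
with latent taxon counts absorbs reads unexplained by any source.
Defaults follow the SourceTracker-2 convention (α₁ = 0.001, α₂ = 0.1,
β = 10, burn-in 100, 100 retained draws thinned by 10, 2 restarts); sinks
are capped at 1000 reads by default for tractability — deeper caps
sharpen the likelihood but also resolve genuine sink-vs-source deviations
more aggressively into the Unknown, so the cap is a fidelity/robustness
trade-off, not merely a speed knob. Which compartments act as sources for
which sinks is a user-supplied map; nothing is hard-coded. The
inner loop is a numba kernel; all randomness comes from pre-drawn uniform
streams, so results are bit-reproducible for a fixed seed (reordering
source environments changes the stream consumption, so equality across
orderings holds in distribution, not bitwise).

## Trait association

Abundances are per-sample relative (no compositional log-ratio transform
— a documented limitation, kept for comparability with the screening
convention this pipeline mirrors). Spearman ρ uses midranks; below n = 10
paired observations the p-value comes from full permutation enumeration
instead of the t-approximation. BH correction is applied within each
trait; the reported filter flags associations with p < 0.05 and
|ρ| > 0.5. The forest step fits a randomized-tree ensemble per trait;
importance is the out-of-bag permutation importance (mean rise in OOB MSE
when the predictor is shuffled, averaged over trees), and per-taxon
significance comes from refitting with the response permuted
(`(hits+1)/(perms+1)`).

## Synthetic-data generator

`simulate_dataset` builds the full 2 × 4 × 4 design in chain order. Bulk
soil samples are drawn from the Sloan stationary law — independent
Beta(Nm·p, Nm·(1−p)) per taxon, renormalized, then a multinomial read
draw — so the fitted *N·m* has a planted truth there. Each downstream
compartment's sampling pool mixes the realized upstream mean profile with
a compartment-specific novel pool per the configured chain
(e.g. nodule ← 0.8 root + 0.2 novel); these mixing fractions are the
ground truth for source tracking, and downstream neutral compartments are
sampled multinomially from their pools — layering additional Beta drift
on a sink systematically routes attribution mass to the Unknown source
and makes the mixing fractions unrecoverable, so drift is deliberately
confined to the primary habitat. Stage structure enters only through the
rhizosphere's novel component (lognormal per-taxon × stage multipliers);
applying stage effects after mixing would silently change the
source-mixing truth, and keeping bulk soil stage-free preserves the
single-metacommunity assumption its NCM score relies on.

**Selection.** Habitat preference is a Brownian-motion trait on a
simulated birth–death tree (standardized across tips); fitness is
Gaussian, `w = exp(−s(trait − optimum)²)`. Selection targeting an
*extreme* trait quantile (default 0.9) is clade-coherent — under Brownian
evolution the trait extreme concentrates in one clade — whereas a mid-range
optimum selects a trait band scattered over several clades and is nearly
invisible to nearest-taxon statistics. The strength *s* can be normalized
per dataset so the favored fraction of the pool is fixed
(`adaptive_selection_strength`, default mass 10%), removing tree-to-tree
luck in effective clade size. Pure selection without drift produces
near-identical communities whose shared taxa sit at zero nearest-taxon
distance under any shuffle — no βMNTD signal at all — so the
homogeneous-selection regimes combine selection with strong drift
(m = 0.005) to generate turnover *within* the favored clade.

**Calibration conditions** (what the acceptance checks run on): the
neutral regime uses 150 taxa, N = 2000, m = 0.25, 20 samples; the
homogeneous-selection regime uses a 1500-taxon pool with an even SAD
(σ_log = 0.5) on an extinction-rich tree (death/birth = 0.7), N = 6000,
m = 0.005 and the adaptive 10% clade mass. The mixed study bundle
(`SynthConfig.mixed_study`) uses 1000 taxa, N = 5000, 5 replicates per
design cell (160 samples), neutral soil/rhizosphere and selected
root/nodule sharing one plant-interior optimum, with the
super-nodulating cultivar under 1.2× selection strength. These sizes were
chosen for statistical power of the recovery checks, and the simulated
libraries have exactly even depth by construction, so rarefaction is an
identity on the bundled study.

**Planted cores** are regulated populations: near-constant per-sample
abundance (0.5% CV) at a floor of ~0.5% relative abundance. This is the
generator's model of a niche-stabilized generalist, and it is also the
statistically honest choice: a taxon sampled exchangeably (multinomially)
across samples is *not identifiable* as a generalist by any permutation
null that conditions on its own totals, so planting cores as plain
multinomial draws would make the recall criterion unattainable by
construction rather than by estimator failure. Plant traits are linear in
the standardized relative abundances of designated core taxa plus
Gaussian noise (effect 2.0, noise SD 0.5 by default).

**What the generator does not emulate:** sequencing error, chimeras,
copy-number variation, compositional bias between compartments, temporal
autocorrelation across stages, or taxonomically structured metadata.
Passing tests demonstrate estimator correctness under the generative
models above, not robustness to those real-data artifacts.

## Numerical and procedural choices

- Per-stage seeds are SHA-256 hashes of (global seed, stage name),
  truncated below 2³¹ — every stage reproducible in isolation.
- Permutation p-values always use the +1 correction.
- βNTI warns below 99 randomizations; 999 is the default.
- The NCM optimizer brackets the 1-D objective on a 60-point log grid
  before bounded refinement (xatol 1e-10); non-convergence raises with
  the best Nm and residual.
- Degenerate inputs: constant vectors give NaN correlations with a
  warning; all-zero taxa are excluded (niche) or error (Levins on a
  single taxon); a group absorbing all samples is a PERMANOVA error.

## Limitations

- PERMANOVA is one-factor by design; interactions and sequential SS are
  out of scope.
- The enrichment module applies decision thresholds to externally
  computed statistics; the bundled log2-of-pseudocount helper is for
  synthetic tests only and is not a substitute for a count model.
- Source-tracking accuracy degrades when the sink community has been
  transformed (e.g. by selection) after mixing; in the bundled study the
  mixing truth is scored on the neutral chain link for exactly this
  reason, and the selected links' attributions are reported without a
  recovery guarantee.
- RCbray-style partitioning of the stochastic fraction (dispersal
  limitation vs. drift) is not implemented; the analysis stops at
  |βNTI| ≥ 2.
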