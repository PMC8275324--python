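# Methods

## The model

`scdoublet` classifies each droplet of a single-cell DNA sequencing (scDNA-seq)
experiment as a **singlet** (one cell) or **doublet** (two cells) from the
variant (`V`) and total (`C`) read-count matrices alone. The signal is the
variant allele frequency (VAF) spectrum: assuming every mutation locus is
diploid in a single cell, a singlet's true VAF at a locus lies on
Σ_singlet = {0, 1/2, 1}, while the pooled DNA of a doublet lies on
Σ_doublet = {0, 1/4, 1/2, 3/4, 1}. Mass near 1/4 or 3/4 — and, after allelic
dropout, near 1/3 or 2/3 — is the doublet fingerprint.

The generative chain per droplet *i* and locus *j*:

1. **Doublet status.** z_i ~ Bernoulli(δ). Where the Poisson capture rate λ of
   the instrument is known, δ = Pois(2; λ) / (Pois(1; λ) + Pois(2; λ))
   (`doublet_prior_from_rate`): empty droplets produce no reads and multiplets
   beyond two cells are negligible at practical loading rates.
2. **Genotypes.** A singlet is wt/het/hom at locus *j* with per-locus
   probabilities μ_j = (μ_wt, μ_het, μ_hom). A doublet holds two cells with
   independent genotypes, so its pre-dropout VAF x aggregates all ordered
   genotype pairs with matching mean — e.g. x = 1/2 collects (het, het),
   (hom, wt) and (wt, hom).
3. **Allelic dropout (ADO).** Each of the 2z+2 allele copies independently
   fails to amplify with probability β. Conditional on at least one retained
   copy (otherwise the entry yields no reads), the post-dropout VAF y is the
   variant fraction of the retained copies; its distribution P(y | x, z) is
   enumerated exactly over all retention patterns. The reachable supports are
   Θ_singlet = {0, 1/2, 1} and Θ_doublet = {0, 1/4, 1/3, 1/2, 2/3, 3/4, 1}.
   For doublet x the copy multiset is the canonical (4x variant, 4−4x
   reference); the mixture over constituent genotype pairs is already resolved
   in step 2, keeping y a function of x alone.
4. **Reads.** Copy errors early in amplification convert templates with rates
   α_fp (ref→var) and α_fn (var→ref), giving a per-copy variant probability
   p = α_fp + (1 − α_fp − α_fn)·y. Allelic imbalance makes read counts
   overdispersed: π ~ Beta(p·s, (1−p)·s) and v ~ Binomial(c, π), i.e. a
   beta-binomial with mean p and precision s. The total depth c carries an
   uninformative prior and cancels from all likelihood ratios.

Marginalising x and y (log-sum-exp over at most 5×7 states) gives
log P(c, v | z) per entry; the matrix Ω of log-likelihood ratios
(doublet minus singlet) is constant given the data, so the maximum a
posteriori assignment is closed-form: droplet *i* is a doublet iff
Σ_j Ω_ij + log(δ/(1−δ)) > 0 (ties resolve to singlet; droplet independence
makes the per-droplet rule globally optimal, which the test suite verifies
against exhaustive 2^n enumeration). The reported posterior is the logistic
transform of that score.

### Numerical choices

* All likelihoods in log space; `scipy.stats.betabinom.logpmf` (log-gamma
  based) keeps counts up to 10^5 overflow-free.
* α_fp and α_fn are floored at 1e-6 and the beta-binomial mean clamped to
  [1e-9, 1−1e-9], so a single stray read at a wt/hom state never contributes
  −∞.
* Entries with c = 0 are missing data and contribute Ω = 0: the uninformative
  depth prior cancels in the ratio, and an unobserved locus carries no doublet
  signal.
* Score exactly 0 → singlet (strict inequality in the decision rule).

## Parameter estimation

All parameters except the ADO rate β are estimated from the count matrices
(`estimate_parameters`); β is an assay property (typically calibrated
per-platform on reference samples) and is taken as input.

1. **Crude genotyping.** Each droplet-locus with depth ≥ `min_depth` (default
   10) is labelled wt (VAF < 0.15), hom (VAF > 0.85) or het; shallower entries
   are missing. The 0.15/0.85 window matches the standard heterozygous VAF
   gate for targeted panels.
2. **Genotype priors μ.** Laplace-smoothed per-locus state frequencies
   (pseudocount 1), **deconvolved through the known dropout confusion**: at
   ADO rate β a het entry reads as wt or hom with probability a = β/(1+β)
   each (one copy lost, conditional on reads), so the observed frequencies q
   satisfy q_het = (1−2a)μ_het, q_wt = μ_wt + a·μ_het, q_hom = μ_hom + a·μ_het.
   Inverting removes the phantom hom mass at het-only loci. Without this step
   the classifier double-counts dropout (once in μ̂, once in P(y|x,z)) and
   misreads imbalanced het VAFs (~1/3) as wt+hom doublets — measured on
   simulations, precision at β = 0.25 falls from ≈0.99 to ≈0.55.
3. **Copy-error rates.** α̂_fp is the pooled variant-read fraction of the wt
   class; α̂_fn the pooled reference-read fraction of the hom class; both
   clamped to [1e-6, 0.4].
4. **Precision s.** Method of moments on the het class: the summed squared
   residuals of v around c·p (p at y = 1/2) are equated to
   Σ c·p(1−p)·(1 + (c−1)/(s+1)) and solved for s, clamped to [1, 1e6]; an
   empty het class falls back to s = 15 with a warning.
5. **Doublet prior δ.** Grid search (0.01…0.50, step 0.01) maximising the
   marginal likelihood Σ_i log((1−δ) + δ·exp(Σ_j Ω_ij)), ties toward smaller
   δ. The δ-profile of the *maximised* joint posterior was evaluated as an
   alternative and rejected: maximising over the latent assignment instead of
   marginalising overestimates the mixture weight whenever the two hypotheses
   overlap (δ̂ ≈ 0.4 at true 0.2 under heavy dropout), a standard pathology of
   max-plugin mixture estimates. Grid search is retained over continuous
   optimisation for exact reproducibility.
6. **Refinement.** Doublets contaminate steps 1–5 — most visibly they inflate
   the het-class variance (ŝ biased from 15 to ≈8) and blur μ̂ at the loci
   that discriminate doublets — so after a first pass the droplets called
   doublets are set aside and everything is re-estimated from the putative
   singlets (one pass by default; more change almost nothing). The refinement
   is skipped if fewer than max(10, 20%) of droplets survive the first pass.

Estimation is fully deterministic given counts and configuration.

## The simulator

`simulate_dataset` emulates a tumour scDNA-seq run with known ground truth:

* **Clone panel.** A random-attachment tree over `n_clones` (default 10)
  genotypes; each SNV is a heterozygous single-copy gain on a uniform random
  edge, inherited by the clade below (infinite sites for SNVs). With
  probability `gamma` a locus also receives a CNA on a random edge: a loss
  with probability `loss_prob` (removing one copy of an allele chosen
  proportionally to the copy state at that clone — possibly causing LOH) or
  otherwise a gain. Clone frequencies are Dirichlet(1).
* **Droplets.** Each of `n_droplets` (default 500) is a doublet with
  probability `delta`; constituent clones are drawn i.i.d. from the clone
  frequencies; a doublet's copy vector is the per-locus sum of its two cells.
  Truth labels record the clones and the doublet taxonomy: *selflet*
  (identical genotype vectors), *nested* (one cell's mutated-locus set a
  proper subset of the other's) or *neotypic* (anything else — a genotype
  absent from the sample).
* **Reads.** Per-copy dropout at rate β; the surviving copy count k sets the
  depth c ~ Poisson(coverage·k/2), so an intact diploid singlet averages
  `coverage` and an intact doublet twice that (doublets carry twice the DNA);
  k = 0 yields c = v = 0. Variant reads follow the copy-error +
  beta-binomial chain of the model, applied to the *true* copy state even
  when CNAs break the diploid assumption — that mismatch is the intended
  robustness stress.

One seeded `numpy.random.Generator` is threaded through panel → droplets →
reads, so a fixed seed fixes every output bit.

`simulate_from_model` additionally samples read counts from the inference
model's own i.i.d.-per-locus chain (no clonal structure); it backs the
parameter-recovery and calibration tests.

### Default scenario parameters

| parameter | default | meaning |
| --- | --- | --- |
| `n_clones` | 10 | clonal genotypes in the sample |
| `m` | 100 | SNV loci (benchmarks use 10/50/100) |
| `n_droplets` | 500 | droplets per experiment |
| `delta` | 0.2 | doublet probability (benchmarks use 0.1/0.2/0.4) |
| `coverage` | 50 | mean depth per diploid locus (10/50/100) |
| `beta` | 0.05 | ADO rate per allele copy (0/0.05/0.25) |
| `s` | 15 | beta-binomial precision |
| `alpha_fp`, `alpha_fn` | 1e-3 | copy/sequencing substitution rates |
| `gamma` | 0 | CNA probability per locus (0/0.1/0.5) |
| `loss_prob` | 0.5 | loss vs gain given a CNA (0.1/0.5) |

The copy-error defaults sit at the per-base substitution-error scale of
modern short-read chemistry. Values an order of magnitude larger are
sometimes *fitted* on real targeted panels, but those fits absorb residual
alignment artefacts, and at s = 15 they would put the wt beta shape
α_fp·s < 1 — a heavy-tailed "jackpot" regime in which ~1% of wild-type
droplet-loci read VAF > 0.15. Under such conditions no decision rule can be
simultaneously precise and sensitive (the package's own PR analysis caps
precision at ≈0.74 for recall 0.78), so they do not describe a regime in
which VAF-based doublet detection is expected to work; the defaults keep the
generator in the realistic low-substitution regime.

### What the simulator does and does not emulate

It reproduces clonal genotype structure, doublet mixing, per-copy dropout,
depth proportional to DNA content, copy errors and amplification
overdispersion — the features the classifier's likelihood is built on. It
does **not** emulate per-locus amplification-efficiency differences (panel
bias), per-cell ADO variation, barcode errors/ambient DNA, triplets, or
read-level artefacts (mapping, strand bias). Passing benchmarks here
therefore demonstrates correctness of the method under its own modelling
assumptions plus CNA misspecification — not performance on any particular
real platform.

## Benchmarks and problem sizes

`run_experiment` wires simulate → estimate → call → score;
`copy_neutral_grid` and `cna_grid` build the study grids (m ∈ {10, 50, 100} ×
β ∈ {0, 0.05, 0.25} × 5 seeds at coverage 50, δ = 0.2; the CNA grid adds
γ ∈ {0, 0.1, 0.5} × loss ∈ {0.1, 0.5}, with γ = 0 run once since the loss
rate is then moot). Each run is 500 droplets; the full copy-neutral grid is
45 runs and completes in well under a minute on one CPU, the CNA grid is 225
runs. Metrics treat doublet as the positive class; precision is reported as
0 (not NaN) when nothing is called, keeping medians defined; per-type recall
is NaN for types absent from a run's truth and is ignored by medians.

Known limitations, measured on the simulator at the default conditions:
selflets are nearly undetectable at low ADO (their genotype is a valid
singlet; only dropout and depth distinguish them) and only partially
detectable at β = 0.25; nested-doublet recall pays a visible cost for
data-driven priors relative to clairvoyant ones (≈0.70 vs ≈0.82 median);
at 10× coverage the classifier is conservative (precision ≈0.96 at recall
≈0.64). Copy-number gains can mimic doublet VAFs and are the known
failure mode of the diploid assumption; losses behave like dropout and are
absorbed.
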