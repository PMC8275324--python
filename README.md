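# scdoublet

Maximum-likelihood doublet detection for single-cell DNA sequencing
(scDNA-seq) read counts.

Droplet-based scDNA-seq occasionally captures two cells under one barcode.
Such **doublets** distort mutation co-occurrence patterns, fabricate
never-existing genotypes and bias clonal-abundance estimates, so they should
be removed before genotyping or phylogeny inference. `scdoublet` is a
standalone caller for medium-to-high-coverage data: it needs only the
variant-read matrix `V` and total-read matrix `C` over droplets × mutation
loci, makes no assumption about the number of clones, their abundances or
the model of evolution, and classifies every droplet in closed form —
no MCMC, no embedding, no discretisation.

It is aimed at people building scDNA-seq analysis pipelines (e.g. on
targeted amplicon panels) and at methods developers who want a fast,
probabilistically explicit baseline plus a ground-truth simulator to test
against.

## The model in brief

Each diploid locus of a singlet has true VAF in {0, ½, 1}; the pooled DNA of
a doublet lies in {0, ¼, ½, ¾, 1}. Three error layers separate that latent
VAF from the data: allelic dropout (each allele copy lost with probability
β, shifting doublet VAFs onto {…, ⅓, ½, ⅔, …}), amplification copy errors
(rates α_fp, α_fn), and allelic imbalance (beta-binomial reads with
precision s). Marginalising the latent VAFs gives, per droplet *i* and locus
*j*, the log-likelihood ratio

    Ω_ij = log P(c_ij, v_ij | doublet) − log P(c_ij, v_ij | singlet)

and the maximum a posteriori call is simply

    z_i = 1  ⟺  Σ_j Ω_ij + log(δ / (1 − δ)) > 0,

with δ the doublet prior. Genotype priors, error rates, precision and δ can
all be estimated from the counts themselves (see `docs/methods.md`); only
the ADO rate β is taken as a known assay property.

The package also ships a truth-labelled simulator (clonal tree with SNVs
and optional copy-number aberrations → doublet mixing → dropout →
overdispersed reads) and evaluation utilities (precision/recall/F1 overall
and per doublet type — selflet, nested, neotypic — plus the
validation-locus NCS score).

## Worked example

```python
from scdoublet import (SimConfig, simulate_dataset, estimate_parameters,
                       omega_matrix, classify, score_calls)

cfg = SimConfig(m=100, beta=0.05, delta=0.2, coverage=50.0, seed=1)
counts, truth, panel = simulate_dataset(cfg)
priors, err = estimate_parameters(counts, beta=cfg.beta)
calls = classify(omega_matrix(counts, priors, err), err.delta)
print(score_calls(truth, calls))
```

Running `python examples/01_simulate_and_call.py` (the same pipeline with
commentary) prints:

```
simulated 500 droplets x 100 loci; 101 true doublets
estimated: alpha_fp=0.0012 alpha_fn=0.0152 s=13.2 delta=0.15  (true delta 0.2)
calls: 74 doublets -> precision=1.000 recall=0.733 f1=0.846
recall by doublet type: {'selflet': 0.0, 'nested': 0.733, 'neotypic': 1.0}
```

Every flagged droplet really held two cells (precision 1.0); every doublet
that created a novel genotype (neotypic) was caught; the misses are
dominated by selflets — two cells of the same clone — which carry no
genotype signal and are only visible through dropout at this low ADO rate.
The other scripts in `examples/` dissect the per-locus evidence, run a
miniature benchmark grid, and demonstrate orthogonal validation with the
NCS score.

## Command line

```bash
scdoublet simulate --m 50 --n-droplets 500 --seed 1 --outdir sim/
scdoublet call --alt sim/alt.tsv --total sim/total.tsv --beta 0.05 --out calls.tsv
scdoublet evaluate --truth sim/truth.tsv --calls calls.tsv --out metrics.json
scdoublet estimate --alt sim/alt.tsv --total sim/total.tsv --beta 0.05 --out params.yaml
scdoublet benchmark --config grid.yaml --outdir bench/
```

Count matrices are TSV with droplet ids in the first column and locus ids in
the header; rows/columns are aligned by label, not position. `call` writes
`droplet_id, score, posterior, call` and is byte-reproducible for identical
inputs and flags.

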