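# espet

Analysis library for cotranscriptional RNA structure probing and its
mutational consequences in *Saccharomyces cerevisiae*-style data.

Chemical probing of elongating transcripts yields paired reads in which
the forward read's 5′ end marks a reverse-transcription (RT) stop one
base 3′ of an acylated (unpaired) nucleotide, and the reverse read marks
the transcription site — the length `L` of the transcriptional
intermediate. From such pair tables this package computes, per
nucleotide and per gene, how folded the nascent RNA is; whether folding
changes as transcription proceeds; how folding relates to R-loop
formation and to the spontaneous DNA mutation rate; and whether the
resulting mutation-rate reduction is large enough for natural selection
to see.

## What it computes

**Single-stranded score.** With library totals `S_DMSO`, `S_NAI` and
per-nucleotide RT-stop counts `n_t(i)`,

    k_t    = (S_DMSO + S_NAI) / (2 S_t)
    N_t(i) = k_t · n_t(i)
    θ(i)   = log2( (N_NAI(i)+1) / (N_DMSO(i)+1) + 1 ),  capped at 7.

Higher θ = more often unpaired. Gene-level structure prevalence is the
negated mean of θ, or the Gini index of θ (more structure concentrates
reactivity: higher Gini).

**Cotranscriptional transitions.** For each nucleotide, its winsorized
RT-stop density across intermediates of increasing `L` is scanned with a
50-length sliding window; window halves are compared by a two-sided
Wilcoxon rank-sum test (windows need ≥ 1 read per half).

**R-loop score.** For site coverage `n` out of track total `m`,
`x = log2((n+1)/m)`; the score is `x(DRIP) − x(input)`.

**Per-site mutation rate.** On a fixed phylogeny (total branch length
`B`), branches are split by Fitch parsimony into changed (`G1`) and
unchanged (`G0`) sets; the expected mutation count `k` maximizes

    L(k) = Π_{i∈G1} (1 − e^{−k b_i / B}) · Π_{j∈G0} e^{−k b_j / B},

accounting for multiple hits on long branches; `k̂/B` is a relative rate
comparable across sites.

**Correspondence statistics.** Among genes: Spearman correlations and
the R-loop-mediated share `1 − ρ²_partial/ρ²` of the structure–mutation
association. Within genes: 2×2 tables (dichotomized at gene means, +1
pseudocount), Mantel–Haenszel common odds ratios with the
Cochran–Mantel–Haenszel chi-squared test and a gene-bootstrap s.d., and
a permutation null that shuffles each variable within each gene.

**Selection model.** Per gene, `x` = ratio of mean mutation rate between
the 50-bp windows with the highest and lowest mean θ (capped at 50);
the fitness advantage of a folding-strengthening mutation is
`s = f_del · target_size · (x−1) · y` (defaults 0.7, 10, 3.3e−10),
compared against the drift barrier `1/Ne` with `Ne = 1e7`.

A fully tested synthetic-data generator (`espet.simulate`) produces all
pipeline inputs with planted ground truth — folding trajectories with
step transitions, NAI/DMSO read tables, DRIP/input counts anticorrelated
with folding, and a Yule phylogeny carrying Poisson mutation counts
coupled to folding and R-loop propensity — so every stage has a
recovery test with no external data.

## Worked example

```python
from espet import AnalysisParams, SimConfig, analyze, simulate_bundle

bundle = simulate_bundle(SimConfig(n_genes=100, gene_length_range=(100, 140),
                                   depth=20.0, n_tips=100, seed=42))
res = analyze(
    bundle.reads, bundle.rloop_counts, bundle.phylo.tree,
    bundle.phylo.genotypes, bundle.phylo.tip_labels,
    bundle.phylo.sites[["gene_id", "pos"]], bundle.gene_lengths,
    AnalysisParams(n_perm=1000, n_boot=1000, seed=0),
)
print(res.gene_correlations.round(3).to_string(index=False))
for key, mh in res.mh.items():
    print(f"{key}: OR = {mh.odds_ratio:.2f} +/- {mh.bootstrap_sd:.2f}, CMH p = {mh.p:.2e}")
```

prints (about 10 s on one CPU):

```
             x     y    rho     p   n
neg_mean_theta rloop -0.278 0.005 100
    gini_theta rloop -0.382 0.000 100
         rloop  rate  0.571 0.000 100
neg_mean_theta  rate -0.262 0.008 100
    gini_theta  rate -0.200 0.046 100

theta~rloop: OR = 6.28 +/- 0.29, CMH p = 0.00e+00
rloop~rate: OR = 4.46 +/- 0.22, CMH p = 1.66e-263
theta~rate: OR = 5.09 +/- 0.26, CMH p = 2.68e-306
```

Reading the output: genes with more prevalent nascent structure (higher
negated mean θ or Gini) have lower R-loop scores and lower mutation
rates, while R-loop score and mutation rate rise together — and the
same three relationships hold within genes, where the combined odds
ratios are all far above 1. These are the planted directions: the
generator couples DRIP intensity negatively, and mutation rate
positively, to site unpairedness. The structure–mutation link weakens
when the R-loop score is controlled (`res.mediation` reports
ρ = −0.262 → partial ρ = −0.131, i.e. ~75% mediated via the R-loop
here), and `res.fold_reductions` gives each gene's fold reduction `x`
with its selection coefficient (median x ≈ 2.5, max s ≈ 2e−8 — far
below 1/Ne = 1e−7, so the modifier is invisible to selection).

The same stages are exposed as a CLI: `espet simulate`, `espet stops`,
`espet scores`, `espet transitions`, `espet rloop`, `espet rates`,
`espet run-all`, `espet selection`.

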