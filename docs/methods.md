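# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and read model

All coordinates are 1-based, inclusive, gene-local, on the sense
strand. A read pair carries the forward read's 5′ position `fwd5` and
the transcription site `txn_site = L` (the intermediate length). The RT
stop implied by a record is `fwd5 − 1`: reverse transcription halts one
base 3′ of the acylated nucleotide. Records with `fwd5 = 1` are mapped
reads (they count toward library totals) but imply no stop — the
polymerase read through to the 5′ end. Records with mapping quality
below 30 or a first-base mismatch are discarded; PCR duplicates are
collapsed on (gene, treatment, fwd5, txn_site, UMI), keeping one record
per key after a stable sort on all columns so the result is independent
of input order. The 3′-terminal 18 nt of every intermediate sit inside
the elongation complex and are never scored (the `footprint`
parameter).

## Single-stranded score

The score contrasts depth-normalized NAI-N3 stop counts with the DMSO
background (formulas in the README). Design points:

- Library totals `S_t` are library-wide (all retained records of a
  treatment), configurable to per-gene totals.
- Nucleotides with zero stops in both treatments receive the formula's
  value θ = 1 but carry a `low_coverage` flag; gene summaries exclude
  flagged sites. Gene-level analyses keep only genes with ≥ 1 average
  RT stop per nucleotide (`min_stops_per_nt`).
- The cap at 7 binds whenever the normalized count ratio exceeds 2⁷;
  the Gini index is computed on raw θ (> 0 by construction) by the
  mean-absolute-difference formula, no re-centering.
- Profile similarity between two score profiles (e.g. nascent versus
  mature states of a gene) is the Pearson correlation over shared
  unflagged positions; a zero-variance profile yields NaN rather than
  an arbitrary value.

## Intermediate matrices and winsorization

For one gene, `raw[L, i]` counts NAI stops at nucleotide `i` among
pairs with transcription site `L`. Each row (one intermediate) is
90%-winsorized: values are clipped at the row's 5th and 95th
percentiles. Clipping bounds use NumPy's default linear quantile
interpolation. Two deliberate deviations from the obvious treatment:

- **No per-row rescaling by default.** Scaling each row to max 1 (or by
  any other row statistic — mean, 95th percentile) looks harmless but
  is not: the statistic is computed over the row's exposed positions,
  and that support grows from 1 nucleotide to `length − 18` as `L`
  increases. A support-dependent normalizer wanders along the
  intermediate-length axis and imprints a shared trend on every
  nucleotide's longitudinal profile, which a rank test then "detects"
  at any depth. Measured on a transition-free synthetic gene, max- or
  mean-scaled densities produce ~50% spurious per-nucleotide transition
  calls, independent of depth; clipped-only densities do not. Max
  scaling remains available (`scale=True`) for display.
- Winsorizing the within-row *fractions* instead of counts is exposed
  as `winsor_on="fraction"`; it differs from counts only by a
  row-constant factor and is equivalent for rank-based downstream
  tests.

## Transition detection

A nucleotide's longitudinal profile is its winsorized density across
the intermediates exposing it, in increasing-`L` order. A 50-length
window slides in steps of 1; halves of 25 are compared by a two-sided
Wilcoxon rank-sum test. The exact null distribution is used when the
pooled window is tie-free and ≤ 60 values; otherwise the normal
approximation with tie correction. A window is evaluable only if both
halves contain at least one raw read; a window of identical values is
trivially non-significant. No multiple-testing correction is applied
per window (α = 0.05), matching apparent per-window usage; a
Benjamini–Hochberg option over a nucleotide's windows exists.

A nucleotide is "transitioning" when any window is significant, and
"informative" when it has at least one evaluable window; a gene's
transition fraction is transitioning/informative. Note the multiplicity
consequence: with dozens of overlapping evaluable windows per
nucleotide, the any-window rule has a per-nucleotide false-positive
rate far above the per-window α (~30% at ~30–80 windows per nucleotide
in the synthetic setting). Recovery of a planted transition fraction is
therefore exercised with the per-nucleotide BH option, under which the
planted fraction is recovered to about one percentage point; with the
uncorrected default the fraction should be read as "nucleotides with at
least one nominally significant window", not as an estimate of the true
transitioning fraction. Real profiles, being coverage-limited to few
windows, sit between these regimes.

## R-loop score

`x = log2((n+1)/m)` per site and track; score = x(DRIP) − x(input).
Sites without coverage keep the formula's value (not missing), so the
score is antisymmetric under swapping the tracks and defined on the
whole site universe. Gene scores aggregate site scores by the mean
(median available).

## Per-site mutation rate on a phylogeny

Ancestral states are reconstructed by Fitch parsimony, vectorized
across sites with bitmask candidate sets (intersection if non-empty,
else union; multifurcations fold children in pairwise). The uppass
keeps the parent's state when it is in the node's candidate set;
otherwise ties are broken by the site's tip-base majority, then
alphabetically. The original description of the estimator uses a
distance-based posterior reconstruction that is not fully specified;
parsimony is used here as a documented approximation — the estimator
consumes only the changed/unchanged branch partition, so any
reconstruction giving the same partition is equivalent.

Given the partition, the stationarity equation
`Σ_{G1} (b_i/B) e^{−k b_i/B} / (1 − e^{−k b_i/B}) = Σ_{G0} b_j/B` has a
strictly decreasing left side, so the root is unique; it is bracketed
by doubling and solved with Brent's method to relative tolerance 1e−9
(`expm1` keeps the ratio stable for small `k b/B`). Non-segregating
sites get rate 0; sites where every branch changed have no finite
maximizer and are flagged (NaN). `k̂` is scale-invariant in the branch
lengths (only `b_i/B` enters) and `k̂/B` is comparable across sites
sharing the tree.

C/G→T/A mutation events are assigned a DNA strand assuming cytosine
deamination dominates: C→T on Watson, G→A = C→T on Crick; relative to
the gene's orientation each event is a coding- or template-strand
deamination, normalized per cytosine count of the respective strand.

## Correspondence statistics

- Among genes: Spearman correlations between structure prevalence
  (negated mean θ, Gini), gene R-loop score, and gene mean site rate.
  The mediated fraction `1 − ρ²_partial/ρ²` uses the first-order
  partial Spearman controlling the R-loop score; it can be negative
  when `|ρ_partial| > |ρ|` (a non-mediating control) and is reported
  as-is for the caller to flag.
- Within genes: sites are dichotomized strictly above the within-gene
  mean (ties go low); 2×2 cells get +1; the Mantel–Haenszel common OR
  and CMH chi-squared (no continuity correction) combine genes;
  pseudocounted cells are used throughout, including inside the test.
  The bootstrap s.d. resamples genes with replacement (1000 draws,
  seeded). The independent cross-check against statsmodels'
  `StratifiedTable` lives in the test suite.
- The permutation null shuffles each of the three site-level variables
  independently within each gene and recomputes the mean within-gene
  Spearman correlations jointly; the empirical p uses the +1 correction
  and is one-sided in each pair's hypothesized direction. Rank moments
  are permutation-invariant, so correlations are computed from
  precomputed rank vectors and vectorized across permutations.

## Selection model

`fold_reduction` slides 50-bp windows by 1 bp; windows must contain at
least one site with rate data; window mean rates use available sites
only. The max-θ window is chosen first and the min-θ window from
non-overlapping candidates (identical windows would force x = 1
degenerately). Division by zero, and any ratio above 50, caps at 50.
Genes need ≥ 5% of sites with rate data and length ≥ 100 nt.
`s = f_del · target_size · (x−1) · y` with defaults 0.7, 10 sites,
y = 3.3e−10 per site per generation; the phase diagram marks the
contour `s = 1/Ne` at `x* = 1 + 1/(Ne f_del target_size y)` (≈ 44.3 at
the yeast-like defaults).

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions used by the recovery tests (200 genes of 100–160 nt, 30 read
pairs per nucleotide per treatment, 190 tree tips — matching a
190-strain population phylogeny; smaller sizes are used where a test
only needs a sign).

- **Folding truth.** Per-gene unpairedness is an autocorrelated field
  (15-nt moving-average Gaussian through a sigmoid), emulating
  alternating stems and loops. Planted transitions step a nucleotide's
  unpairedness by ≥ `transition_effect` (default 0.8) at a length `L*`
  placed so both regimes are observable by a 50-length window; default
  20% of scoreable nucleotides carry one.
- **Reads.** One stop per read; stop weight = `background +
  multiplier · unpaired` on exposed positions. By default the
  (intermediate, stop) pair is drawn jointly proportional to cell
  weight: a sequenced library samples *reads*, so an intermediate
  contributes in proportion to its total stop propensity. This keeps
  per-cell expected counts constant along `L` (longitudinally
  stationary), which the uniform-`L` alternative
  (`intermediate_length_dist="uniform"`, also available) violates by
  diluting depth as intermediates lengthen. NAI record counts equal
  `round(depth · length)` exactly; DMSO samples background only; UMIs
  are random 3-mers; a small fraction of records get mapq < 30 or a
  first-base mismatch to exercise the filters.
- **R-loop and mutation couplings.** Site foldedness `f = 1 − mean
  unpairedness`; DRIP intensity ∝ `exp(rloop_coupling · f)` (default
  −2: folded sites form fewer R-loops), input uniform, both Poisson.
  Planted log mutation rate is linear in centred `f`
  (`mu_fold_coupling = −1.5`) and in the centred latent R-loop
  log-intensity (`mu_rloop_coupling = +1`), normalized to mean
  `mu_mean = 1` expected mutation per site over the tree.
- **Phylogeny.** A Yule (pure-birth) tree on `n_tips` taxa; branch
  lengths are clamped to ≥ 1e−3 × the mean length because the
  simulator can emit zero-length edges. Mutation counts per (site,
  branch) are Poisson(`k_true b_i/B`); any positive count redraws the
  genotype uniformly among the other three bases, so multiple hits
  surface as one observable change — exactly the estimator's change
  model. The site universe for coverage and genotypes is the scoreable
  span 1..length−18 (the footprint zone has no planted folding state).

What the generator does **not** emulate: sequence composition and
ligation biases, RT drop-off physics (stops are drawn per-intermediate,
not by first-adduct scanning from the 3′ end), R-loop thermodynamics,
selection on the simulated lineages, and linkage between sites beyond
the shared tree. Passing recovery tests therefore show that the
estimators invert the generative model they target, not that real
libraries are free of these additional effects.

## Numerical and procedural details

- Every stochastic step flows through `numpy.random.default_rng(seed)`;
  a configuration plus seed fixes all outputs bit-for-bit, and the
  pipeline writes a manifest with parameters and input checksums.
- Empirical permutation p-values use the (1 + extreme)/(n + 1)
  correction; bootstrap and permutation seeds are recorded in results.
- Problem sizes in the test suite (e.g. ~1,000 sites for rate-recovery,
  100 profiles of 250 lengths for detector calibration, 200-gene study
  bundle) were chosen to give the assertions comfortable statistical
  margins on a single CPU.
- Degenerate inputs have defined behavior throughout: empty read
  tables raise with the file named; genes without records warn and
  yield empty matrices; zero-variance vectors make correlations NaN
  rather than raising mid-pipeline.

## Known limitations

- The per-nucleotide any-window transition flag is multiplicity-inflated
  when profiles are long (see above); use the BH option for calibrated
  per-nucleotide calls.
- Fitch parsimony under-counts changes on long branches; the ML step
  corrects the rate for unseen multiple hits on changed branches but
  cannot recover changes parsimony never infers, so `k̂` is biased low
  for very fast sites on sparse trees.
- Mean-dichotomized odds ratios are invariant to affine but not to
  general monotone transforms of the underlying variables.
- The mediated fraction compares squared correlations; it is a
  descriptive decomposition, not a causal mediation estimate.
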