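# Methods

This note documents the models and procedures the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Data model

The universal input is a table of diploid codominant genotypes
(microsatellite allele lengths, stored as unordered pairs; allele code 0 is
the single missing-data sentinel) plus one haploid mitochondrial marker
(`N`/`S`) per individual, and a site table with along-coast distances in
km.  Distances are taken verbatim from the site table; the package never
recomputes geography.  Missing calls are excluded locus-wise; the
individual is retained everywhere else.

**Diallelic reduction.**  Cline fitting and the cytonuclear statistics need
one frequency per locus, but microsatellites are multiallelic.  Each locus
is collapsed onto a composite "northern" allele: alleles whose frequency
differential δ (northern parental pool minus southern) is positive form one
class, negative-δ alleles the complement, and δ = 0 ties belong to neither
class (their copies are dropped; a locus with all δ = 0 is flagged
non-informative).  This pooling preserves the per-locus summary
differential ½Σ|δ| whenever no ties exist.  The pooling rule is this
package's explicit choice; any fixed rule that separates the two parental
backgrounds would serve, and the sign-of-δ rule is the least arbitrary.

## Geographic clines

A cline in along-coast distance x is

    p(x) = p_min + (p_max − p_min) · (1 + tanh(2 (x − c) / w)) / 2

with centre c (inflection) and width w = (p_max − p_min)/max-slope.  Model
variants: `null` (flat, 1 parameter), `I` (c, w free; end frequencies fixed
to supplied constants, by default the observed frequencies at the two
range-end sites), `II` (c, w, p_min, p_max; 4 parameters), `III` (model II
plus exponential tails; 8 parameters).  A tail splices at c − δ_L (left)
with value continuous and initial slope τ_L times the sigmoid slope at the
splice, decaying exponentially toward p_min (mirrored on the right).
τ ∈ [0, 1] keeps tails shallower than the core, which is what introgression
tails mean.

**Likelihood and fitting.**  Binomial site likelihood
Σ k log p + (n − k) log(1 − p) with p clamped to [1e-9, 1 − 1e-9].  Bounded
multi-start L-BFGS-B (default 8 starts: one heuristic start at the
midrange-crossing site plus seeded random draws with log-uniform widths);
bounds c ∈ [min distance − 200, max + 200] km, w ∈ (1, 3000] km.  Fitting
ML rather than the MCMC of the R cline packages is deliberate: the
binomial-count likelihood surface at 13 sites is cheap enough to profile
exhaustively, and results are deterministic given a seed.

**Model choice and uncertainty.**  Lowest AIC = 2k − 2 logL wins; ties go
to the smaller model.  Per-parameter uncertainty is the 2-unit support
interval: the widest contiguous region around the MLE where the profile
log-likelihood (remaining parameters re-optimized) stays within 2 units of
the maximum.  The profile is traced by doubling steps outward then
bisection to ~1e-6 relative tolerance; intervals clipped at a bound are
flagged.  In repeated simulation at the coastal transect design (13 sites,
100 alleles each) the (c, w) pair falls inside its own support limits in
≈95% of replicates, consistent with the ≈95%-CI interpretation of 2-unit
support for one parameter.

**Concordance/coincidence.**  The shared-versus-free cline comparison uses
the scaled-logit shape p = p_min + (p_max − p_min)/(1 + e^{−4(x−c)/w}) —
algebraically identical to the tanh sigmoid without tails, kept as a
separate code path because the two cline-fitting traditions parameterize
differently.  Free model: per-locus (c, w, p_min, p_max).  Constrained:
common (c, w), per-locus ends.  χ² = 2(logL_free − logL_constrained),
d.f. = 2(L − 1).  Free fits are warm-started from the constrained solution
so logL_free ≥ logL_constrained by construction.  Simulated under a shared
cline, the test rejects at ≈5% (the LRT is well calibrated at ≥100 alleles
per site).

**Neutral width.**  w = σ√(2πT) for a neutral diffusion cline of age T
generations with per-generation dispersal σ; at the conventional values
T = 15000 and σ = 2 km this is 614 km.  Fitted widths far below this bound
indicate selection.

## Disequilibrium statistics

**Exact HWE.**  The conditional (Levene) distribution of a genotype table
given its allele counts is sampled by a Markov chain on pairings of the 2n
labelled allele copies: each step swaps two uniformly chosen copy slots.
Uniform distribution over pairings is invariant under such transpositions,
so every proposal is accepted, and uniform pairings induce exactly the
Levene table probabilities.  Chain schedule defaults: 1000 dememorization
steps, 100 batches × 1000 iterations (batch-means standard errors).  The
global p is the probability of tables no more probable (including the 2^H
heterozygosity factor) than the observed one; one-sided deficit/excess
p-values order tables by heterozygote count — an approximation to the
U-score ordering some programs use, chosen for transparency; the two
orderings agree in the diallelic case.  Tests verify the chain against
full-table enumeration for every margin with ≤ 12 sampled copies.

**F_IS** = 1 − H_obs/H_exp with the small-sample-corrected
H_exp = 2n/(2n−1) · (1 − Σp²); positive values mean heterozygote deficit.
Per-(site, locus), matching the grid layout of field studies, rather than
the variance-component F_IS.

**θ (F_ST).**  Weir–Cockerham 1984 variance components summed over alleles
and loci (ratio-of-sums estimator); permutation p by shuffling individuals
between pools, with the +1/(n_perm+1) correction.  Small negative θ is
possible and reported as computed.

**Composite LD.**  Weir's composite disequilibrium Δ_AB = Σ X_A Y_B/(2n) −
2p_A p_B on allele-dose vectors (no phase assumed), aggregated as
X² = n ΣΔ²/((p_A q_A + D_A)(p_B q_B + D_B)) with (k₁−1)(k₂−1) d.f.  The
permutation p (shuffling one locus's genotypes) is the headline value; the
asymptotic chi-square p is reported alongside.  Monomorphic pairs are
flagged degenerate with statistic 0, p = 1.

**Cytonuclear disequilibrium.**  On the composite-diallelic nuclear locus:
allelic D = P(A ∧ northern mito) − p_A p_M, genotypic D1, D2, D3 for
(AA, Aa, aa), which sum to zero identically.  Significance by permuting
mito labels (two-sided on |D|) rather than asymptotic variance formulas —
a documented deviation from the classical program, preferred because the
permutation null is exact at any sample size.  Individuals carrying a
tied (δ = 0) allele have no defined diploid class and are excluded.

**FDR.**  Classical one-stage step-up: sort p ascending, find the largest
i with p_(i) ≤ i·q/m, flag the first i.  This is the standard step-up rule;
whether the cited "classical one-stage method" is exactly this procedure
is not verifiable from the text, so the package implements the step-up
rule and says so.  The flags always contain the Bonferroni flags at the
same q.

## Admixture and parental-site choice

The no-linkage admixture model: allele copy of individual i comes from
cluster z with probability q_iz, then from cluster z's frequency vector.
Point estimation by EM (q rows start uniform; cluster frequencies start at
seeded perturbations of the pooled frequencies, so permuting individuals
permutes the whole trajectory).  The log-likelihood is asserted
non-decreasing every iteration.  EM replaces the MCMC of the classical
structure program (50 000 burn-in / 150 000 iterations was the emulated
protocol); replicate runs differ only through their frequency
initialization, so the replicate spread of logL is optimizer spread, not
posterior spread — the Evanno Δk statistic
|L̄(k+1) − 2L̄(k) + L̄(k−1)|/sd(k) still peaks sharply at the true k on
simulated two-pool data, but Δk is undefined wherever replicate sd = 0
(perfectly diagnostic data); the realistic default marker panel avoids
this.  The mito marker is excluded from admixture (nuclear ancestry only).
Cluster labels anchor geographically: the southernmost site's majority
cluster is cluster 0.

Parental sites flanking the zone: walking inward from each end of the
transect, a site is parental when >50% of its individuals have q < 0.10
(southern flank) or q > 0.90 (northern); the innermost parental site
before admixed-majority sites begin is the flank's parent.  The >50%
majority rule makes a qualitative published criterion concrete.

## Hybrid index

For individual copies a with parental frequencies p_S(a), p_N(a):

    logL(h) = Σ_copies log( h·p_N(a) + (1 − h)·p_S(a) ),

concave in h, maximized on a 0.001 grid then refined by bounded scalar
minimization; 2-unit support by bisecting the concave profile.  Copies are
treated as independent draws from the h-mixture (the codominant model of
the classical hybrid-index estimator); interspecific heterozygosity is out
of scope.  Alleles unseen in both parental samples make the locus
uninformative for that individual (skipped); an allele absent from exactly
one pool gets floor frequency 1/(2n_pool + 1) — transparent, and bounded
by what one more sampled copy could have shown.  Swapping the pools maps
ĥ → 1 − ĥ exactly.  Histograms use bins [0, 0.1), …, [0.9, 1.0].

## Dip test

The dip D is the smallest sup-distance between the sample ECDF and any
unimodal CDF (convex, then concave, an atom at the mode allowed).  The
implementation reduces feasibility at distance d to hull conditions (see
the module docstring): flank feasibility via greatest-convex-minorant /
least-concave-majorant deviations of the d-shifted staircase corners, plus
a junction condition coupling the flanks at the mode through forced-slope
envelopes; D is found by bisection on d (tolerance 5e-14) and floored at
the conventional 1/(2n).  Inputs are rescaled to [0, 1] first, making the
statistic affine-invariant to machine precision.  Tests verify the value
against an independent linear-programming minimizer of sup|F_n − G| for
hundreds of small samples, including heavily tied ones.

The p-value is Monte-Carlo: dips of seeded uniform(0, 1) samples of the
same size, p = (1 + #{D* ≥ D})/(n_null + 1), default n_null = 9999.
Uniform is the classical conservative null.  Classical implementations
interpolate precomputed quantile tables instead; small p-value differences
at the table's grid points are expected.  Calibration is exact: null
p-values are uniform (3000-replicate KS distance 0.014), and power rises
monotonically with mode separation.

## Synthetic data

The generator draws genotype tables with a known truth table under two
ancestry regimes at user-given sites (defaults: the 13-site coastal
transect, 0–1631 km, site sizes 12–50):

* **clinal** — each allele copy is northern with probability p(x) from an
  ancestry cline; mito northern with the same probability.  This is the
  hybrid-swarm regime: hybrid indices at a central site are unimodal.
* **class-mixture** — individuals drawn from {P_S, P_N, F1, F2, BC_S,
  BC_N} with per-site weights; F1 = one gamete from each pool, F2 = two
  F1 gametes (pool label Bernoulli(½) per copy), backcrosses = one F1
  gamete plus one pure gamete.  Mito follows the maternal side (fixed for
  pure classes, configurable probability for hybrid classes).  The
  central-marsh default {P_S: 0.4, P_N: 0.4, F1: 0.1, BC: 0.1} produces a
  bimodal hybrid-index distribution at n = 89.

The default marker panel mixes near-diagnostic and weakly differentiated
loci (δ from ~0.14 to 1.0), shadowing the spread of a real microsatellite
panel.  What the generator does **not** emulate: genotyping error, null
alleles and allele dropout (the screening for which is out of scope),
within-pool geographic substructure, linkage between markers, selection
acting during the sampled generations, and continuous-space dispersal.
Passing tests therefore demonstrate estimator correctness under the
idealized generative model, not robustness to those artefacts.

Fully diagnostic panels quantize the hybrid index onto ~2L+1 atoms; the
dip statistic then measures marker granularity rather than ancestry
structure.  Tests of the clinal (unimodal) regime therefore use the
realistic mixed panel, while the bimodal-regime checks keep diagnostic
loci (where quantization and true bimodality point the same way).

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; identical configuration
and seeds give byte-identical outputs (the CLI writes a manifest with
input hashes and seeds).  Simulation-based checks use 40–400 replicates
and 100–500 alleles or individuals per unit — sizes at which the measured
rates (support coverage, type-I error, rejection rates) have Monte-Carlo
standard errors of 1–3 percentage points, small against the margins being
tested.

## Limitations

* The admixture EM gives point estimates; no credible intervals, no
  correlated-frequencies prior, no linkage model.
* Cline support limits are profile-likelihood based; at parameter bounds
  (e.g. p_min = 0) the interval is clipped and flagged rather than
  extended by reparameterization.
* The concordance test compares only the two extreme models (all shared
  vs all free); per-locus partial sharing is not explored.
* Permutation p-values are conservative in the presence of heavy ties
  (discrete dose lattices at small n).
* The Genepop dialect carries genotype content, site membership, and the
  mito marker, but not sex/year metadata; the CSV dialect is lossless.
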