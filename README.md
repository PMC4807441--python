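# hybridzone

Population-genetic analysis of hybrid zones typed with codominant markers
(microsatellites) plus a diagnostic mitochondrial marker: geographic cline
fitting, disequilibrium statistics, admixture estimation, multilocus hybrid
indices, and a formal test of bimodality.

The package is aimed at researchers characterizing a zone of secondary
contact between two differentiated taxa sampled along a one-dimensional
transect — the motivating system is the Atlantic killifish (*Fundulus
heteroclitus*) hybrid zone along the New Jersey coast, where northern and
southern subspecies meet. The analytical chain answers three questions:

1. **How do allele frequencies change across the zone?**  Each marker's
   frequency is modelled as a sigmoid cline in along-coast distance *x*:

   `p(x) = p_min + (p_max − p_min) · (1 + tanh(2(x − c)/w)) / 2`

   with centre *c* and width *w* (the inverse of the maximum slope).  Four
   variants are fitted by bounded multi-start maximum likelihood on
   binomial site counts — a flat null, fixed vs. estimated end frequencies,
   and optional exponential introgression tails — and compared by AIC.
   Uncertainty comes as 2-unit support limits from the profile likelihood.
   A likelihood-ratio test compares a model in which all loci share one
   centre and width against per-locus clines (χ² with 2(L−1) d.f.).  The
   fitted widths are compared with the neutral-diffusion expectation
   `w = σ√(2πT)` for a zone of age *T* generations and dispersal σ.

2. **Is there disequilibrium inside the zone?**  Exact Hardy–Weinberg
   tests (Markov chain over genotype tables with fixed allele counts,
   Levene conditional distribution), F_IS, Weir–Cockerham θ with
   permutation p-values, composite (phase-free) linkage disequilibrium,
   cytonuclear disequilibrium between mito type and each nuclear locus,
   and one-stage FDR correction.

3. **Is the zone unimodal or bimodal?**  Per-individual hybrid indices ĥ
   (maximum-likelihood ancestry proportions from parental allele-frequency
   differentials δ), binned in 0.10 steps, and tested for departure from
   unimodality with Hartigan's dip statistic *D* and a seeded Monte-Carlo
   p-value against the uniform null.  A bimodal ĥ distribution at the zone
   centre — parental classes common, F1/backcross classes deficient —
   indicates reproductive isolation.

A synthetic hybrid-zone generator with a complete truth table (parental
pools, F1/F2/backcross class mixtures or clinal ancestry, maternal mito
inheritance) makes the whole chain testable without field data.

## Worked example

```python
import numpy as np
from hybridzone import ClineData, ClineModel, fit_cline, neutral_cline_width
from hybridzone.simulate import simulate_clinal_counts, DEFAULT_SITES

truth = ClineModel(centre=1217.0, width=58.0, p_min=0.0, p_max=1.0)
sites = list(zip(DEFAULT_SITES["distance_km"], 2 * DEFAULT_SITES["n"]))
data = ClineData.from_frame(simulate_clinal_counts(truth, sites, seed=1))
fit = fit_cline(data, variant="II", seed=0, support_params=("centre", "width"))
lo, hi = fit.support["centre"]
print(f"centre {fit.model.centre:.2f} km  ({lo:.2f}, {hi:.2f})")
print(f"width  {fit.model.width:.2f} km   AIC {fit.aic:.2f}")
print(f"neutral width {neutral_cline_width(T=15000, sigma=2.0):.0f} km")
```

prints

```
centre 1216.25 km  (1212.57, 1219.97)
width  62.57 km   AIC 521.30
neutral width 614 km
```

The refitted centre and width sit on top of the generating values, the
2-unit support limits bracket the truth, and the fitted width of ~63 km is
an order of magnitude below the 614 km a neutral cline would have reached
after 15 000 generations at σ = 2 km — the signature of selection
maintaining a steep cline.

The same chain is available from the shell:

```sh
hybridzone simulate --preset clinal-zone --seed 7 -o out/
hybridzone pipeline --in out/genotypes.csv --sites out/sites.csv -o out/run/
```

which writes the per-locus cline table (centre, width, end frequencies,
per-variant AIC), the F_IS grid, LD pair counts before/after FDR, admixture
q values, per-site hybrid-index histograms, dip-test results and a
reproducibility manifest.

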