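# standpattern

Stand-structure and spatial point-pattern analysis for per-tree stem maps
of riparian forest plots.

Desert riparian forests — such as the *Populus euphratica* stands fringing
Central Asian inland rivers — are surveyed as rectangular plots (here
50 m × 50 m) in which every stem is mapped with its tree height (TH, m),
diameter at breast height (DBH, cm) and crown diameter (CD, m), and every
plot carries abiotic covariates: distance from the river channel (DR),
groundwater depth (GD), soil moisture (SM), soil conductance (SC) and pH.
This package answers, from such stem maps, the three questions a stand
ecologist asks of them:

1. **What does the stand look like?** DBH is binned into 21 four-cm
   classes and four age grades — young (1, 15], near-mature (15, 30],
   mature (30, 50] and old (50, ∞) cm — and each plot or transect is
   summarised by its stand density index (SDI, trees ha⁻¹), biometric
   means ± sd and crown projection area (CPA, % of the plot covered by
   the union of crown discs). The DBH-class histogram is fitted with two
   candidate curves, a decreasing logistic `a / (1 + b·e^{c·k})`
   (reversed-J, regenerating stand) and a Gaussian bell
   `a·e^{−(k−μ)²/(2σ²)}`; the better fit plus the grade mix labels the
   population trend *growing*, *stable* or *temporarily stable*.

2. **How are the trees arranged?** Ripley's
   `K(r) = (A/n²) Σ_{i≠j} 1{d_ij ≤ r} / w_ij` and the ring-estimator
   pair-correlation function `g(r)` (with Ripley isotropic edge-correction
   weights `w_ij` by default) are compared to rank envelopes from 199
   Monte-Carlo simulations of complete spatial randomness (CSR), labelling
   each plot *aggregated* (g above the envelope), *regular* (below) or
   *random*. Four scalar indices — average nearest neighbour (Clark–Evans)
   ANN, Hopkins–Skellam HSI, David–Moore DMI (quadrat variance-to-mean
   ratio) and Morisita's I_δ — come with standardised scores and
   significance tests, and a 5-m disc-kernel intensity surface maps where
   the trees concentrate.

3. **Does the arrangement track the environment?** Per-plot indices are
   correlated (Pearson, pairwise-complete, two-sided t test) with DR, GD,
   SM, SC and pH.

Because real stem maps of this kind are rarely published, the package
includes a first-class, seeded synthetic-stand generator
(`standpattern.synthetic_stands`) that emulates an 18-plot, three-transect
study: dense random upper-transect stands (~113 trees/plot), mixed middle
stands, sparse clustered lower stands (~66 trees/plot, Thomas cluster
process), grade mixes per transect, power-law TH/CD allometries, and
downstream abiotic gradients. Every pipeline stage is tested against it.

## Worked example

```sh
standpattern simulate --seed 0 --out study/
standpattern analyze --trees study/trees.csv --plots study/plots.yaml \
    --out results/ --nsim 199 --seed 42
standpattern report results/
```

The report prints, among other tables, the per-transect structure summary
(abridged):

```
transect  n_trees  young_pct  sdi  mean_th  mean_dbh  cpa            fit_model  r_squared   trend
   upper      678       29.2  452     9.11     22.73 46.7  logistic_decreasing      0.827  growing
  middle      570       17.9  380    11.07     30.38 25.1             gaussian      0.772  stable
   lower      396       13.6  264    11.24     30.57 13.3             gaussian      0.771  temporarily_stable
```

Reading: the upper transect is densest (452 trees ha⁻¹), has the most
regeneration (29% young trees) and a reversed-J size structure — a growing
population — while the lower transect is sparse, its crown cover has
collapsed, and young trees are too scarce (14%) to sustain the stand.
The pattern tables tell the spatial half of the story: mean g(r) per
transect is 0.98 (upper, plots labelled random), 2.60 (middle, random near
the river and aggregated beyond) and 3.15 (lower, aggregated), and the
ANN index correlates positively with groundwater depth (r = 0.78,
p < 0.001) — drier plots hold more clustered stands.

The same analyses are available as library functions
(`standpattern.pipeline.analyze`, `standpattern.pattern_functions.csr_envelope`,
`standpattern.aggregation_indices.ann_index`, …) on any `(n, 2)` coordinate
array or `PlotData`.

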