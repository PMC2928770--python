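# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `refstab`, and what the synthetic-data generator does and does
not emulate.

## Data model and aggregation

Raw measurements are quantification cycles (Cq) in long format, one row per
technical replicate, with per-sample annotations (strain, tissue, circadian
sacrifice time CT, animal id) kept in a separate table. Technical replicates
are collapsed by the arithmetic mean of Cq; the replicate standard deviation
(sample sd, ddof = 1, defined as 0 for a single replicate) is reported and
rows exceeding a dispersion threshold (default 0.5 cycles) are *flagged, never
dropped* — outlier exclusion is an analyst decision, and automatic filtering
would silently change cohort sizes. Unbalanced replicate counts are supported
everywhere; nothing is subsampled or rebalanced.

CT0 and CT24 are distinct time points at the data layer (they sample the same
circadian phase but different animals); no wrapping is applied.

Samples partition into analysis datasets: one per (strain, tissue) stratum,
labelled A, B, ... in strain-major order, plus one pooled all-strain dataset
per tissue (G for liver, H for adrenal under the default three-strain,
two-tissue design). Pooled datasets are exactly the union of their strata, so
|G| = |A|+|C|+|E| always holds.

Both stability algorithms need a complete gene × sample matrix. When cells
are missing, the run either drops the offending genes (default — keeps cohort
sizes intact) or the offending samples, under an explicit switch, with the
dropped entities reported. Gene panels may differ between tissues; analyses
operate on whatever complete panel a dataset provides.

## Efficiency and quantities

Amplification efficiency E (fold product per cycle, E = 2 is perfect
doubling) comes from an ordinary least-squares fit of Cq on log10 relative
input over a serial dilution: `E = 10^(-1/slope)`. Fits with slope ≥ 0 or
|slope| < 0.5 cycles/decade are rejected as degenerate. Efficiencies are per
gene, not per plate (single-run assumption); externally supplied efficiency
tables are accepted directly, bypassing estimation.

Relative quantities use the efficiency-corrected delta-Cq transform
`Q = E^(Cq_min − Cq)` with the per-gene minimum taken **within the analysis
dataset** by default, because stability analyses run per dataset and Q is
only meaningful relative to its cohort. The anchor choice is exposed (any
sample scope can be passed); note that every statistic downstream of Q is
invariant to per-gene rescaling, so the anchor affects presentation, not
rankings.

## geNorm

Pairwise variation `V_jk` is the sd over samples of `log2(Q_j/Q_k)`;
`M_j = mean_{k≠j} V_jk`; the argmax-M gene is excluded iteratively until two
remain, which share the top rank (the measure cannot order a final pair — any
two-gene set has `M_1 = M_2 = V_12`). Conventions:

- sample sd (n−1 denominator) throughout — the V threshold semantics assume
  it;
- log base 2 everywhere; changing base rescales M and V jointly, so the 0.15
  guideline is base-dependent;
- exact ties on the maximal M exclude the lexicographically later gene and
  are recorded in the result (ties are measure-zero on real data);
- the V threshold (default 0.15) is configuration, not a constant; when no n
  satisfies it, the full panel size is recommended and a flag says the
  threshold was never met;
- circadian time is **not** an input to geNorm; it operates on the pooled
  dataset.

All geNorm statistics are invariant to positive rescaling of any gene row or
any sample column (both are additive shifts of log ratios).

## NormFinder

Log2 quantities are modelled per subgroup as
`y_igj = α_i + β_gj + d_ig + ε_igj`, `ε ~ N(0, σ²_ig)`: gene level, sample
loading, systematic gene-by-group deviation, and gene/group-specific noise.
Subgroups default to the circadian sacrifice time for every dataset; strain
can be chosen instead (see Open design points).

Estimation, per subgroup g with n_g samples over I genes:

1. two-way residuals `r_igj = y_igj − ȳ_ig· − ȳ_·gj + ȳ_··g`;
2. raw variances `v_ig = Σ_j r²_igj / (n_g − 1)`;
3. bias-corrected intragroup variances
   `σ̂²_ig = [I/(I−2)] (v_ig − v̄_g/(I−1))`, floored at 0 (floored cells are
   counted and reported). The correction follows from
   `E[v_ig] = σ²_ig (1 − 2/I) + σ̄²_g / I`; a 2000-replicate Monte-Carlo test
   in the suite pins these constants by checking unbiasedness to within 3% at
   I = 8, G = 4, n_g = 50;
4. group levels `z_ig = ȳ_ig· − mean_i(ȳ_ig·)` and deviations
   `d̂_ig = z_ig − Σ_g n_g z_ig / Σ_g n_g` (n_g-weighted centring; unequal
   group sizes are carried through every variance-of-mean term). By
   construction `Σ_i d̂_ig = 0` in each group;
5. deviation variance `γ̂² = max(0, Σ_ig d̂²_ig/((I−1)(G−1)) −
   mean_ig(σ̂²_ig/n_g))`. The (I−1)(G−1) denominator matches the free
   dimensions of the double-centred deviation array; for balanced designs the
   mean-σ̂²/n subtraction is then exactly the expectation of the sampling
   contribution to Σd̂², heteroscedastic genes included;
6. shrinkage `d̃_ig = d̂_ig · γ̂²/(γ̂² + σ̂²_ig/n_g)` (never increases
   magnitude);
7. stability `ρ_i = (1/G) Σ_g [ |d̃_ig| + sqrt((γ̂²/(γ̂²+σ̂²_ig/n_g)) ·
   σ̂²_ig/n_g) ]`; with a single group, `ρ_i = sqrt(σ̂²_i)` (which then equals
   ranking by two-way residual sd).

ρ is in log2 units (consistent with the geNorm module); published stability
tables with unspecified base are not numerically comparable.

Degenerate regimes worth knowing about: when the data carry no genuine
intergroup structure, γ̂² floors at zero and every ρ collapses to |d̃| = 0 —
the measure is then uninformative rather than wrong (the model says no gene
differs across groups). The variance floor also means σ̂² is *not* unbiased
for genes whose true variance is tiny relative to estimator noise; the
unbiasedness test therefore uses moderate variances (σ 0.2–0.55 log2), where
the floor is inactive.

The best two-gene combination replaces each candidate pair by its log-scale
average (geometric-mean pairing on the raw scale, matching normalization-
factor construction), re-fits, and takes the pseudo-gene's ρ; the minimizing
pair is reported together with whether it beats the best single gene. The
re-fit drops one gene, so the search needs at least 4 candidates.

## Normalization comparison and rhythm summaries

Targets are divided sample-wise by the geometric mean of the chosen reference
set. Profiles are summarized per (strain, time) as mean ± sd with cell counts.
Rhythms come from a least-squares 24 h cosinor on log2 normalized values
(`y = mesor + A·cos(2π(t − φ)/24)`, fitted linearly via cos/sin regressors);
peak time is the acrophase φ and the peak/trough fold is `2^(2A)`. Fitting on
the log scale makes amplitude symmetric in up- and down-regulation; it is a
reporting convenience, not a claim about any particular lab's practice. A
fitted amplitude below 1e-9 log2 marks the profile arrhythmic (peak time
undefined, fold 1). At least 4 distinct time points are required.

Between-strain fold changes are geometric: within each (strain, time) cell
the mean of log2 values is taken, cells are differenced between strains at
shared time points, and the differences averaged before exponentiation. This
makes the headline identity exact in expectation: a reference gene carrying a
strain-specific log2 offset δ, used alone, multiplies the target's apparent
strain fold by 2^δ, while references free of strain × gene interaction leave
it unbiased. Both per-sample values and per-cell summaries are emitted.

## Synthetic-data generator

Each sample's log2 abundance of a gene is

```
a = loading_s + offset(gene, strain) + A·cos(2π(t − φ)/24) + N(0, σ_bio)
```

mapped to cycles via the gene's own efficiency, `Cq = base_cq − a/log2(E)`,
with technical replicates adding `N(0, σ_tech)` in cycles. Noise placement
mirrors the physical layers: biological variation lives in log2 abundance,
pipetting/instrument noise in cycles, and the per-sample loading effect is
shared by all genes of a sample (so it cancels in log ratios, as RNA-input
variation does after normalization). Quantification with the true
efficiencies inverts the simulation exactly.

Default calibration (frozen; chosen once to match the published summaries of
the emulated study):

- design: 3 strains × 2 tissues × 7 time points with the published ragged
  replicate counts — 131 liver + 97 adrenal = 228 samples; inbred liver is
  balanced at 5 per time point;
- panel: 10 reference candidates plus a *Dbp*-like target (amplitude 2 log2
  ≈ 16-fold, acrophase CT12); efficiencies per gene from the published primer
  table (1.64–1.98);
- abundance: *Rn18s* at mean Cq 8.8, *Tbcc* at 28.5, the rest spread over
  18–29;
- instability: *Actb* and *Hmbs* carry background-level strain offsets
  (+4.0 and +2.2 log2 in the two mixed-background strains, which share
  offsets — the two mixed strains rank similarly in the emulated study) and
  large biological sd (1.5 / 1.0 log2), reproducing ~12-cycle ranges across
  the design and the cross-strain normalization bias; *Gapdh* gets a mild
  offset (+0.6);
- stability: the three microarray-selected candidates (*Eif2a*, *Tbcc*,
  *Utp6c*) have σ_bio = 0.25 log2 (< 4-cycle ranges);
- every reference candidate carries a weak circadian modulation (amplitudes
  0.05–0.5 log2, smallest for the most stable genes). This is deliberate:
  circadian time genuinely modulates "housekeeping" expression — that is the
  premise of subgrouping by sacrifice time — and a simulator with strictly
  time-flat references would make the intergroup variance component
  identically zero, collapsing every NormFinder stability value to 0, a
  degenerate output no real circadian tissue produces;
- noise: 3 technical replicates at σ_tech = 0.15 cycles; loading sd 0.15
  log2.

What the generator does **not** emulate: plate/batch effects and inter-run
calibrators, RNA degradation, animal-level pairing of tissues (each tissue is
an independent cohort here), non-Gaussian outliers, and light–dark protocol
differences. Passing tests therefore demonstrate correctness of the
algorithms and their documented statistical behaviour under the stated model
— not robustness to artefacts the model excludes.

Dilution series are generated as `Cq = base − log10(conc)/log10(E) + noise`
with a configurable dilution factor. The default is five-fold with five
points; the factor is configurable because published protocols disagree with
themselves often enough (the emulated study states both five- and six-fold in
different sections).

## Open design points, resolved here

- **Grouping factor for pooled datasets.** For the cross-strain datasets the
  sacrifice-time subgrouping leaves strain offsets invisible to the
  intergroup term (an offset constant across time groups is absorbed by the
  gene level and only inflates σ̂²). Grouping by strain makes the offset the
  intergroup deviation itself and is the analysis that targets
  genetic-background instability. Both are available (`group_by="time_ct"` is
  the default everywhere; `group_by="strain"` recommended for pooled
  datasets); the pipeline-recovery test uses strain grouping on the pooled
  data for exactly this reason.
- **Minimum-Cq anchor scope** for Q: per dataset by default (see above),
  global optional.
- **Technical-replicate outliers:** flagged, never auto-excluded.
- **Tie-breaking** in geNorm exclusion: lexicographic, recorded.
- **Output precision:** writers emit full precision; determinism is
  byte-level for identical seeds.

## Problem sizes used in the test suite

Simulated studies in the suite use the full 228-sample design (fast — a
complete study simulates in milliseconds); oracle-equivalence checks run on
100 random instances up to 6 genes × 12 samples; the estimator
Monte-Carlo uses 2000 replicates at I = 8, G = 4, n_g = 50; the bias
propagation check averages 200 simulated two-strain experiments of 42 samples
each. The whole suite runs in well under a minute.
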