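# Methods

## The estimation problem

Amplicon (16S rRNA gene) time series from incubation experiments are
compositional: read counts carry only relative information, so a taxon's
declining share says nothing about its absolute dynamics.  `asvgrowth`
resolves this by anchoring each sample's composition to an absolute
scale: the relative abundance of ASV *i* in sample *s* (percent) is
multiplied by the total prokaryotic abundance *N(s)* from flow cytometry
and divided by 100, giving a *pseudoabundance* in cells/mL,

    x_i(s) = rel_i(s) · N(s) / 100.

Under exponential growth, ln x_i(t) is linear in time and the ordinary
least-squares slope is the specific growth rate μ (d⁻¹), with the
classical two-sided t-test on the slope providing the significance
gate.

## Dual-window selection

Abundances can saturate near the end of an incubation, flattening the
late part of the curve.  Two regressions are therefore fitted per ASV
and condition — over timepoints t0–t2–t3 and t0–t2–t3–t4 — with
replicate bottles pooled as individual points.  Among fits with slope
> 0 and p < α (default α = 0.05) the steeper slope is kept as the
*maximal* growth rate; ties go to the smaller p, then to the longer
window.  Significance of either window alone is sufficient; requiring
both would only discard information when the saturating window dilutes
an otherwise clean signal.

Records that fail the gate are retained with a status rather than
dropped:

* `discarded_nonsignificant` — no window is significantly positive;
* `discarded_nonpositive` — a significantly negative (or zero) slope.
  Negative slopes are *not* interpreted as death rates: in compositional
  data a constant-density taxon displaced by fast growers acquires a
  spurious negative pseudoabundance trend whenever the bulk cytometry
  totals rise more slowly than the sequenced sub-community grows, and
  the two measurements routinely disagree in that direction;
* `discarded_insufficient` — fewer than 3 positive observations over
  2 distinct timepoints (zeros are dropped, not pseudocounted, since
  ln 0 is undefined and pseudocounts bias slopes).

Slopes with magnitude below 1e-9 d⁻¹ are treated as numerically zero:
in exact-proportion simulations, float rounding gives perfectly flat
series ~1e-16 slopes whose t-tests are otherwise spuriously
significant.

## Companion estimators

* **Bulk rates** apply the same dual-window regression to ln of the
  total cell counts of a condition (`asv_id = "__bulk__"`).  Being an
  abundance-weighted aggregate over growers and non-growers, the bulk
  rate cannot exceed the fastest member's rate.
* **mOTU rates** use only the endpoints (metagenomes exist at t0 and t4
  only): replicate-mean relative abundances are scaled by the cytometry
  totals and converted as μ = ln(fold change) / (t4 − t0) · 24.  This
  equals the regression slope through the two endpoint means.  When
  comparing mOTU and ASV condition means, only taxa that reach >1% of
  the community at some point are included; below that, profiler noise
  dominates the fold changes.

## 16S copy-number correction

Reads are optionally divided by the per-ASV 16S rRNA gene copy number
before renormalisation (multi-copy operons inflate read counts relative
to cells).  Missing copy numbers are imputed from the mean of the finest
assigned taxonomic rank with data, then the global mean, then 1, with
each imputation logged.  Because the correction multiplies each ASV's
trajectory by a constant and the within-sample renormalisation is a
common time-varying factor, corrected and uncorrected slopes differ only
by a shared offset per condition — whether renormalisation happens
before or after scaling to totals is immaterial to the slopes.  The
correction is approximate at best, so it is off by default and exposed
as a flag.

## Downstream analyses

* **Limiting-factor effects**: differences of mean accepted rates
  between treatment pairs — light (CL−CD and PL−PD), grazing (PL−CL and
  PD−CD), viruses (VL−DL), nutrients (DL−PL) — per taxon and season, at
  ASV, family or order level.  A taxon missing a side contributes NA,
  never 0.  The paired light/grazing contrasts are kept separate, with
  an averaged summary available behind a flag.
* **Responsiveness**: responsive means an accepted rate strictly
  > 1 d⁻¹.  Exclusive = responding in exactly one condition;
  relative exclusive divides by that condition's responsive count;
  relative shared divides the pairwise intersection by the smaller of
  the two sets.  The >30% shared-proportion rule used for plot links is
  a report flag, not a data filter.
* **Rarity**: per season, an ASV's maximal accepted rate is compared to
  its in situ relative abundance — most-responsive (> 2 d⁻¹, twice the
  literature-average copiotroph rate), rare (< 1%), very rare (< 0.1%,
  including ASVs undetected in situ, assumed present below detection),
  successful (rare, most-responsive, and exceeding 1% of the community
  at the end of the experiment).  "End of the experiment" is the
  replicate-mean relative abundance at the last timepoint of each
  treatment, maximised over treatments: blooming in any bottle counts.
  All thresholds are strict and configurable.  In situ ranks are
  ordinal by decreasing abundance with ties broken by ASV id;
  undetected ASVs rank after all detected ones.
* **Rank distributions**: groups at a rank need ≥ 2 rates (configurable)
  to be summarised; coverage is the fraction of rates in retained
  groups.  Groups are keyed by the full lineage prefix, with unassigned
  ranks pooled as "unclassified ⟨parent⟩", so groups strictly split
  toward finer ranks and coverage is monotonically non-increasing.
* **Statistics**: normality is screened with Shapiro–Wilk (α = 0.05 by
  default, configurable); correlations use Pearson when both vectors
  pass, else Spearman; group comparisons use ANOVA + Tukey HSD when all
  groups pass, else Kruskal–Wallis + Dunn.  Dunn's pairwise z-tests use
  the tie-corrected rank variance and Holm adjustment (the conservative
  default of the common implementations, which do not fix one).  Groups
  are summarised as a compact letter display via insert-and-absorb.

## The synthetic generator

`asvgrowth.simulate` emulates the full design — 4 seasons × 6
treatments × t0/t2/t3/t4 (0/24/48/72 h, configurable) × 3 replicate
bottles — with known ground truth.  Defaults, chosen once as the study
conditions the package is validated under:

| parameter | default | rationale |
|---|---|---|
| ASV mixture | 30% non-growers, 20% decliners, 50% growers | a large non-growing fraction is typical of seawater communities |
| grower μ | U(0.3, 10) d⁻¹ | the span observed in such experiments |
| decliner μ | U(−2, −0.2) d⁻¹ | bottle mortality scale |
| season scale | winter 1.1, spring 0.7, summer 1.25, fall 0.75 | warm-season maximum, spring/fall minima |
| treatment shifts | PD +0.1, DL +0.4, VL +0.7 d⁻¹ | cumulative release of limiting factors |
| t0 totals | 1.04/1.01/0.73/1.58 ×10⁶ cells/mL | seasonal NW-Mediterranean cytometry values |
| depth | 5×10⁴ reads | MiSeq-scale amplicon depth |
| cytometry CV | 10% | flow-cytometry replicate error |
| initial abundances | lognormal σ = 1, scaled to the t0 total | right-skewed rank-abundance curve |
| copy numbers | integers U{1..15} | the span of rrnDB estimates |

Trajectories are exact exponentials, optionally switching to a logistic
toward K = capacity_factor × density-at-onset after an onset time
(`SaturationSpec`); K = n₀ is a fixed point.  Observation layers:
multinomial read sampling (or an exact-proportions mode where counts =
depth × proportion, enabling 1e-9-level recovery tests), lognormal
mean-one noise on totals, an in situ profile hiding the least-abundant
20% of taxa, and a t0/t4 mOTU table with Dirichlet resampling
(concentration 5000) and a 0.01% detection floor below which abundances
are reported as 0, as metagenomic profilers do.  Random streams are
partitioned per (season, treatment), so extending the design never
perturbs existing draws; a single seed fixes everything.

What the generator does *not* emulate: mechanistic ecology (grazing
functional responses, viral lysis kinetics — treatment effects are
additive rate shifts), PCR/primer bias, chimeras or denoising errors,
copy-number-weighted read sampling, or sequence-level identity between
experimental and in situ ASVs (identity of ids is assumed).  Passing
recovery tests therefore demonstrate correctness of the estimator under
its own model assumptions plus sampling noise, not robustness to every
real-world artifact.

## Problem sizes and numerical choices

Tests run on scaled-down designs (tens of ASVs for unit tests; 500
growers for the noisy-recovery check; 1000 ASVs over the full design in
the acceptance script) — sizes at which the Monte-Carlo properties are
already stable.  TSV output uses 10 significant digits, ensuring
lossless round trips at that precision; missing values are `NA`.
Degenerate inputs fail loudly: zero-depth samples, missing cytometry
totals, non-positive copy numbers and duplicate ids are hard errors
naming the offender, while unknown-taxonomy ASVs and t1 samples are
tolerated with warnings.

## Known limitations

Rates of taxa that vanish from the reads mid-course are right-censored
(insufficient observations), biasing the accepted set toward fast
growers — the same censoring the real method exhibits.  The negative
rates produced by compositional masking mean slow growers cannot be
distinguished from dying taxa; both are discarded.  Copy-number
correction shifts all slopes of a condition by a common offset, so it
reranks nothing within a condition.  The mOTU estimator compresses any
within-window saturation into a two-point average and so underestimates
maximal rates.
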