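# Methods

This note documents the models implemented in `ardrapipe`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer should know.

## 1. The workflow being modelled

A 16S rRNA clone-library survey of a host gut proceeds: PCR with universal
bacterial primers 27f (`AGAGTTTGATCMTGGCTCAG`) and 1472r
(`TACGGYTACCTTGTTACGACTT`), cloning, colony picking, restriction digestion
of each cloned amplicon with HaeIII (recognition site GGCC, blunt cut
GG^CC), polyacrylamide gel electrophoresis, and manual grouping of clones
with identical band patterns into OTU families.  `ardrapipe` replaces the
laboratory steps with explicit, parameterised models:

* **Amplicon extraction.**  Primers are matched as IUPAC-degenerate
  patterns; the reverse primer is matched as its reverse complement on the
  forward strand.  The 5′-most forward match is used (the dominant PCR
  product), paired with the first reverse site starting at or after its
  end; the amplicon includes both primer sites.  Coordinates are 0-based
  half-open internally.
* **Digestion.**  Every occurrence of the recognition site is cut at
  `cut_offset` (GGCC/2 by default); overlapping occurrences are all
  honoured by a one-base scan.  Fragment lengths always sum to the input
  length.
* **Gel model.**  A band pattern is a presence/absence *set*: fragments
  shorter than `min_detectable_len` (default 60 bp) are invisible, and
  visible lengths are binned greedily in ascending order on the log10
  scale — a fragment joins the open band while its log10 length is within
  `log_tolerance` (default 0.01) of the band's smallest member, which also
  names the band.  The defaults approximate the resolving power of 6%
  PAGE with a GelCompar-style position tolerance; no published numeric
  resolution exists for this step, so both are configuration parameters.
  Band intensity (fragment multiplicity) is deliberately not modelled:
  ARDRA scoring is pattern-based.
* **OTU assignment.**  Manual "same pattern" calls are replaced by two
  reproducible modes.  `exact` (default, parameter-free): OTU = equivalence
  class of identical band sets.  `cut`: UPGMA on 1 − Dice distances, tree
  cut at height (1 − threshold)/2.  UPGMA uses size-weighted average
  linkage with merge height = distance/2 and deterministic lexicographic
  tie-breaking; the resulting tree is ultrametric by construction.  OTU ids
  are ordered by each family's smallest clone id, so output is stable.

Because identical sequences produce identical patterns, the pipeline caches
the digestion per unique sequence, and the dendrogram written by a run is
computed over one representative pattern per OTU (identical patterns would
join at height zero anyway); this keeps a 567-clone study instantaneous.

## 2. Diversity statistics

All statistics act on the integer count vector of one library.  The
classical formulas overload `n`/`N`; internally the names are `count_i`
(clones of OTU i), `N` (total clones), `F1` (singletons), `F2`
(doubletons).

* Good's coverage `C% = (1 − F1/N)·100`.
* Chao1: classic `S_obs + F1²/(2F2)`; the bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))` is selectable and is used automatically when
  `F2 = 0`.  The 95% CI uses the log-normal method on the estimated number
  of unseen OTUs `T = est − S_obs` (the convention of the EstimateS
  program): with `K = exp(1.96·√ln(1 + var/T²))`, the interval is
  `[S_obs + T/K, S_obs + T·K]`.  Note this interval is anchored at
  `S_obs` from below — its lower bound can never fall under the observed
  richness, so "coverage" of a true richness equal to `S_obs` is only
  achieved when `F1 = 0` (interval collapses).  When `F1 = 0` the estimate
  and both bounds equal `S_obs`.
* Analytic rarefaction: `E[S_d] = Σᵢ [1 − C(N−nᵢ,d)/C(N,d)]` with the exact
  variance including pairwise covariance terms
  `C(N−nᵢ−nⱼ,d)/C(N,d) − qᵢqⱼ`.  Binomial coefficients are evaluated with
  log-gamma arithmetic, so no `N` overflows.  95% bands are
  `E ± 1.96·√var`, clamped to `[0, S_obs]`.
* Shannon `H′` in nats; Simpson reciprocal `1/Σpᵢ²`; evenness
  `E = H′/log_b S` with base e by default (Pielou's J, ≤ 1).  A base-10
  mode divides nats by log10(S) and reproduces the historical convention
  under which evenness values above 1 occur; the base used is recorded in
  the report metadata.  Evenness is undefined (NaN in reports) for
  `S_obs < 2`.

## 3. Comparison statistics

Sorensen `Cs = 2j/(a+b)` on incidence sets (presence = count ≥ 1), reported
in percent with the raw fraction available; no abundance weighting.
Sorensen is not a metric and no triangle-type property is asserted.  Venn
tallies for 2 or 3 labelled sets are exact membership enumerations; region
counts partition the union.  Class composition is percent of clones per
class per library; in simulated runs each OTU's class is the majority class
of its member clones' true taxa (ties broken alphabetically), so a band
pattern shared by two classes degrades the profile gracefully rather than
failing.  `axis_trend` reports each fish's IB→MI→PI trajectory for one
class plus weak/strict monotonicity flags; a constant trajectory is weakly
monotone in both directions.

Between-fish comparisons can be made per compartment (same compartment,
two fish) or on pooled-per-fish incidence sets; both views are provided
because legacy reports are often ambiguous about which was used.

## 4. Compartment-effect inference

The repeated-measures design is a complete balanced fish × compartment
matrix.  The one-way within-subject ANOVA removes the between-fish sum of
squares and tests `F = MS_treatment/MS_error` with
df `(k−1, (k−1)(n−1))`.  No sphericity correction is applied (with k = 3
compartments and n = 3 fish there is little power to estimate one); the
report metadata records this.  Tukey comparisons use
`q = |mᵢ − mⱼ|/√(MS_error/n)` against the studentized range distribution
with `(k, df_error)`; compact letters come from the insert-and-absorb
algorithm, and the letter-sharing relation equals the non-significance
relation exactly (this is property-tested).  Class-abundance responses are
analysed untransformed by default, matching common practice in the legacy
literature; an arcsine-square-root option exists because proportions near
0/1 violate normality.  A Friedman wrapper is included as the
non-parametric fallback.

With zero residual variance the F statistic is degenerate; the
implementation returns F = 0, p = 1 when the treatment SS is also zero and
F = ∞, p = 0 otherwise.

## 5. The synthetic-data generator

The generator emulates the *statistical design* of a small gut survey —
3 fish × 3 compartments, ~63 clones per library (≈ 566 clones/9
libraries), skewed abundance distributions, and class-level composition
gradients along the gut axis — with known ground truth:

* **Abundances.**  Geometric ranked series (ratio k = 0.5) by default,
  because such libraries are typically dominated by a single taxon per
  class; log-normal (μ, σ) and uniform models are options.
* **Sequences.**  Each taxon's reference is: realized forward primer
  (M→A, Y→C fixed, so amplicon matching is exercised on degenerate
  patterns against unambiguous templates) + a core evolved from one random
  ancestor + the reverse-complemented reverse primer site.  The per-site
  mutation rate is calibrated so two taxa differ at ≈ the requested
  fraction of core sites (default 0.10, of the order of between-genus 16S
  divergence).  Default amplicon length 1445 bp matches the 27f–1472r
  span.  No chimeras, PCR errors or quality scores are modelled — every
  clone is a verbatim copy of its taxon's reference.
* **Gradients.**  A gradient spec maps class → one abundance per
  compartment; the default has Bacilli (0.50, 0.20, 0.03) and
  Gammaproteobacteria (0.17, 0.40, 0.87) across (IB, MI, PI), with the
  per-compartment remainder split equally over four flat background
  classes.  All cells share one taxon pool (sequences generated once), so
  OTUs are comparable across libraries.
* **Fish-to-fish variability.**  One log-normal multiplicative factor per
  (fish, class) — default σ = 0.1 — scales that class's whole trajectory
  and is renormalized per compartment.  Because the factor is shared
  across a fish's compartments, it rescales but never reorders a monotone
  trajectory: realized ground truth keeps the designed gradient in every
  fish, while observed (sampled) compositions fluctuate multinomially.
  Real inter-individual variability in gut surveys is considerably larger
  and less structured than this one-parameter model.
* **Sampling.**  Clones are drawn i.i.d. multinomially at the designed
  library size (default 63).  All randomness descends from one root seed
  via named `SeedSequence` substreams, so studies are bit-reproducible.

What passing tests on this generator demonstrate: correctness of the
formulas and algorithms, end-to-end determinism, and that the pipeline
recovers designed gradients and similarity orderings *under the stated
model*.  What they do not demonstrate: robustness to PCR/cloning artefacts,
chimeras, primer mismatch bias, intragenomic 16S heterogeneity, or gel
scoring noise — none of which are modelled.

## 6. Validation experiments and problem sizes

The acceptance suite fixes its problem sizes as follows:

* UPGMA vs a brute-force average-linkage oracle on 1000 random matrices of
  up to 8 leaves; analytic rarefaction vs exhaustive subsample enumeration
  (N ≤ 12) and vs 10 000-draw Monte-Carlo subsampling (N = 30, 3 MC SEs);
  RM-ANOVA vs definitional sums of squares on random 3×3 fixtures.
* Chao1 calibration: 200 libraries of 2000 clones from 40-taxon log-normal
  communities with σ = 0.8, requiring ≥ 85% CI coverage of the true 40.
  σ = 0.8 gives a genuinely skewed community (~25-fold abundance range)
  whose unseen tail is small enough that the log-normal CI is near its
  nominal level.  Heavier skew (σ ≈ 1–2.5) pushes Chao1 into its known
  under-coverage regime — partly because the CI's lower bound cannot fall
  below `S_obs` (see §2), so libraries that happen to observe all 40 taxa
  while retaining singletons count as misses.  That behaviour is a
  property of the estimator, not of this implementation.
* Type-I error of the ANOVA stage: 2000 null simulations of the 3×3
  design, rejection rate required in [0.03, 0.07] at α = 0.05.
* Gradient recovery: 20 seeded runs of the default study; per-fish
  compositions averaged over the runs must fall (Bacilli) and rise
  (Gammaproteobacteria) monotonically, and the seed-averaged within-fish
  IB-vs-PI Sorensen must sit below IB-vs-MI.  Averaging over runs is the
  appropriate scale for this qualitative claim: at 63 clones per library a
  single multinomial draw reverses one adjacent step in roughly 3% of
  runs, which is sampling noise, not a pipeline failure.

## 7. Known limitations

* One enzyme per digestion; composite multi-enzyme ARDRA is out of scope.
* The gel model's greedy log-binning is anchored per pattern; two nearly
  identical fragment lengths from *different* clones only share a band if
  they fall in bins with the same anchor.  Exact-pattern OTU calling is
  therefore strict; use `cut` mode for tolerant grouping.
* No ordination (PCoA/NMDS), UniFrac, ACE/jackknife richness, or
  mixed-model machinery.
* The evenness base-10 mode exists to reproduce a historical convention;
  for new analyses Pielou's J (base e) is the sensible choice.
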