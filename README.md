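# ardrapipe

In-silico **ARDRA** (amplified ribosomal DNA restriction analysis) typing and
clone-library diversity analysis for gut bacterial communities.

Before deep amplicon sequencing, small surveys of host-associated microbiota
were done with 16S rRNA **clone libraries**: amplify the 16S gene with
universal primers (27f / 1472r), clone the amplicons, pick colonies, digest
each cloned insert with a 4-cutter restriction enzyme (HaeIII, GG^CC), and
group clones whose polyacrylamide-gel band patterns match into **OTU
families**.  Richness, diversity and between-sample similarity are then
estimated from the OTU count table.  `ardrapipe` re-implements that entire
workflow computationally, aimed at anyone who wants to analyse legacy clone
libraries, teach classical diversity statistics, or study the statistical
behaviour of the ARDRA/clone-library design itself — e.g. for communities
sampled along the proximal–distal axis of the zebrafish intestine
(intestinal bulb **IB**, mid-intestine **MI**, posterior intestine **PI**).

## What it computes

Given clone sequences (or an OTU count table directly):

* **ARDRA typing** — degenerate-primer amplicon extraction, in-silico
  restriction digestion, a gel model (detection floor + log-scale
  co-migration), Dice similarity `2|A∩B|/(|A|+|B|)` between band patterns,
  UPGMA dendrograms, and OTU assignment (exact-pattern or dendrogram-cut).
* **Per-library statistics** — observed richness `S_obs`; Good's coverage
  `C = [1 − F1/N]·100`; Chao1 richness `S_obs + F1²/(2F2)` with a 95%
  log-normal CI; analytic (hypergeometric) rarefaction
  `E[S_d] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)]` with exact variance; Shannon
  `H′ = −Σ pᵢ ln pᵢ`; Simpson reciprocal `1/D = 1/Σ pᵢ²`; evenness
  `E = H′/log S` (base e or base 10).
* **Between-library comparison** — Sorensen similarity `Cs = 2j/(a+b)` (in
  percent), 2/3-set Venn tallies of shared OTUs, class-level composition
  profiles and monotone-trend summaries along the gut axis.
* **Compartment effects** — one-way repeated-measures ANOVA with fish as
  the subject factor, Tukey multiple comparisons on the studentized range
  distribution, and compact-letter displays.
* **Synthetic studies** — a generator for ground-truth communities on a
  fish × compartment grid with class-level abundance gradients, 16S-like
  reference sequences carrying both primer sites, and multinomial clone
  sampling, so the full pipeline can be exercised and validated without any
  external data.

## Worked example

Simulate the default study — 3 fish × (IB, MI, PI) × 63 clones from a
63-taxon community in which Bacilli fall (50% → 20% → 3%) and
Gammaproteobacteria rise (17% → 40% → 87%) along the gut axis — and run the
whole pipeline:

```python
from ardrapipe import PipelineConfig, run_pipeline

rep = run_pipeline(PipelineConfig(out_dir="demo", seed=17))
print(rep.diversity[["N", "S_obs", "coverage_pct", "chao_est",
                     "shannon_H", "simpson_recip"]].round(2))
```

```
          N  S_obs  coverage_pct  chao_est  shannon_H  simpson_recip
library
F1|IB    63     18         85.71     38.25       2.34           6.63
F1|MI    63     21         84.13     37.67       2.63          10.00
F1|PI    63     10         90.48     25.00       1.39           2.58
F2|IB    63     16         87.30     44.00       2.24           6.21
F2|MI    63     14         96.83     14.67       2.41           9.52
F2|PI    63     13         85.71     53.50       1.65           3.38
F3|IB    63     15         87.30     31.00       2.08           5.40
F3|MI    63     15         93.65     19.00       2.35           7.80
F3|PI    63      8         95.24     12.50       1.48           3.49
```

Each row is one clone library: of the 63 clones in `F1|PI` only 10 distinct
band patterns (OTUs) were seen, its coverage of 90.5% says ~1 new OTU is
expected per 10 further clones, and Chao1 extrapolates ~25 total taxa.  The
posterior intestine is consistently the least diverse compartment (lower
`S_obs`, `H′` and `1/D`), as expected when one taxon dominates it.  The
recovered class gradient and similarity structure:

```python
print(rep.composition[["Bacilli", "Gammaproteobacteria"]].round(1))
print(rep.within_fish_sorensen().groupby("pair")["cs_pct"].mean().round(1))
a = rep.anova["class:Bacilli"]
print(a.F, a.p, a.letters)
```

```
         Bacilli  Gammaproteobacteria
F1|IB       68.3                 17.5
F1|MI       27.0                 34.9
F1|PI        1.6                 93.7
...
pair            IB-MI  70.6
                IB-PI  57.2
                MI-PI  41.9
186.34  0.0001  {'IB': 'a', 'MI': 'b', 'PI': 'c'}
```

Bacilli fall and Gammaproteobacteria rise monotonically in every fish; the
IB library is less similar to PI than to MI; and the repeated-measures
ANOVA on Bacilli abundance (F(2,4) = 186, p = 1e-4) separates all three
compartments (letters a/b/c).

The same run is available from the shell, along with per-stage commands:

```bash
ardrapipe pipeline simulate --preset zebrafish-gut --seed 17 --out demo
ardrapipe ardra run --fasta demo/clones.fasta --site GGCC --out demo_ardra
ardrapipe diversity report --otu-table demo_ardra/otu_table.tsv --out demo_div
ardrapipe pipeline run --config my_config.yaml
```

All outputs are TSV (plus FASTA for clones and Newick for dendrograms), and
every run writes its fully resolved configuration next to its results; a
run is a pure function of (config, seed).

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
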