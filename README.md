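# rhythmhic

Temporally resolved 3D-genome analysis around the circadian cycle.

Circadian gene expression in tissues such as the liver is accompanied by
chromatin-conformation changes at several genomic scales: megabase A/B
compartments that switch between active and inactive states at different
hours of the day, topologically associating domains (TADs) whose boundaries
stay put while their compartment assignment oscillates, and promoter
contacts that peak at a gene's time of maximal transcription. `rhythmhic`
implements the full analysis chain for such experiments — Hi-C sampled at
ZT0/ZT6/ZT12/ZT18 (Zeitgeber time, hours after lights-on) with replicates,
promoter-capture interaction tables, and replicated expression — as a
tested, reusable Python package, together with a seeded synthetic generator
that plants every structure the pipeline measures so each stage can be
validated against known ground truth.

## What it computes

- **Compartments / OCCs** — per-chromosome PC1 of the Pearson correlation
  of the observed/expected contact map (100-kb bins), sign-anchored to an
  activity track; A iff PC1 > 0. Oscillatory chromatin compartments (OCCs)
  are bins whose replicate PC1 is significant in a per-bin one-way ANOVA
  across timepoints (Benjamini-Hochberg) **and** whose merged-track sign
  switches; each OCC carries a category string such as `AABA` (A at
  ZT0/6/18, B at ZT12).
- **TADs** — insulation score (mean contact in the square window straddling
  each bin), boundaries at sub-threshold local minima, sharing between
  timepoints by the >80% overlap rule, rescaled-TAD and point-anchored O/E
  metaplots.
- **Circadian expression** — per-gene one-way ANOVA on log2(FPKM+1) across
  the four ZTs, q < 0.01; acrophase = ZT of highest mean FPKM;
  diurnal/nocturnal classing.
- **Circadian TADs** — gene-to-TAD assignment by TSS, phase-sharing
  statistics against the closed-form expectation `sum_i p_i^k`, and
  cTAD-over-OCC enrichment via equal-size non-cTAD resampling.
- **Interactome** — dynamic vs stable contact classification by a negative
  binomial likelihood-ratio test with moment/shrinkage dispersion, split
  into <=150 kb / >150 kb distance regimes; matched permutation nulls that
  preserve each other-end's (fragment length, bait distance) exactly;
  eRNA-contact enrichment; diurnal/nocturnal phase coherence; core-clock
  vs output-gene interactome comparison.
- **Networks** — promoter-promoter graphs (networkx) with circadian
  induced-edge z-scores and edge-support comparisons against resampled
  non-circadian node sets.
- **Virtual 4C** — single-viewpoint raw-count tracks and washU-longrange
  arc export from capture tables or matrices.

Formats: BED3/6 (optional phase column), bedGraph, ibed, washU longrange,
COO matrix TSV with a bins sidecar. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

```python
import json
from rhythmhic import PipelineConfig, run_all

report = run_all(PipelineConfig(seed=1))
d = json.loads(report.to_json())
print("OCC regions:", d["compartments"]["n_occ_regions"],
      "| genome fraction:", round(d["compartments"]["occ_genome_fraction"], 3),
      "| sensitivity:", d["compartments"]["recovery"]["sensitivity"])
print("TADs at ZT0:", d["tads"]["n_tads"]["ZT0"],
      "| shared ZT0-ZT12:", round(d["tads"]["shared_fraction_ZT0_ZT12"], 2))
print("circadian genes:", d["expression"]["n_circadian"],
      "| detection power:", d["expression"]["recovery"]["power"])
print("dynamic contacts:", d["interactome"]["n_dynamic"], "of",
      d["interactome"]["n_tested"])
```

prints, for the default synthetic study (2 chromosomes x 20 Mb, 4 ZTs,
3 Hi-C + 4 RNA replicates):

```
OCC regions: 67 | genome fraction: 0.17 | sensitivity: 1.0
TADs at ZT0: 75 | shared ZT0-ZT12: 0.97
circadian genes: 91 | detection power: 1.0
dynamic contacts: 259 of 1024
```

Reading: 67 merged OCC regions cover 17% of the toy genome and every
planted compartment switch was recovered; 75 TADs were called at ZT0 and
97% of them are shared with ZT12 (TAD structure is planted as
time-invariant); 91 of 300 genes are called circadian (all 90 planted
rhythmic genes plus one false positive at q<0.01); 259 of 1024 tested
promoter contacts are classified dynamic. The core-clock section of the
same report shows the planted asymmetry — fewer contacts per core-clock
promoter (7.7 vs 10.9) but a higher dynamic fraction (50% vs 23%).

The same run is available from the shell:

```
rhythmhic run --seed 1 --out out/          # full pipeline + JSON report
rhythmhic simulate --seed 1 --out data/    # write the synthetic dataset
rhythmhic io validate features.bed --genome chr1:20000000
rhythmhic v4c --ibed data/interactions.ibed --bait chr1:102000 \
    --window 1000000 --genome chr1:20000000,chr2:20000000
```

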