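# adtopt

Titration analysis and panel optimization for oligo-conjugated antibody
(ADT) panels in droplet-based single-cell experiments (CITE-seq and related
cytometry-by-sequencing assays).

Unlike flow cytometry, where signal is free, every ADT UMI is a sequencing
read someone paid for — and free-floating antibody left over from staining
ends up in the vastly more numerous *empty* droplets, where it can consume a
large fraction of a lane's reads without carrying any biology. `adtopt`
quantifies that background from the empty droplets themselves, measures each
antibody's response to dilution, classifies every marker into one of five
actionable response categories, and turns the result into concrete
concentration recommendations plus reagent- and sequencing-cost accounting.

## What it computes

Given per-barcode UMI count matrices (ADT, and optionally HTO and RNA), a
panel sheet with staining concentrations (µg/mL), and a pair of staining
conditions (a reference and a diluted panel):

1. **Droplet partition.** Barcodes are split into cell-containing and empty
   droplets at the inflection point of the RNA barcode-rank curve — the
   steepest descent of log₁₀(total) against log₁₀(rank) — followed by QC
   (≥ 60 detected genes, < 15% mitochondrial reads) and ratio-based HTO
   demultiplexing.
2. **Per-antibody metrics.** For each marker *m*: total cell UMIs; the 90th
   percentile UMI count within its expressing cell cluster (q90); a
   detection threshold *T* = the 99th percentile of its empty-droplet
   counts; positive fraction #{count > T}/#cells; signal-to-noise
   Δmedian = median(positives) − median(negatives) in UMIs; percent of
   panel cell-UMIs used per positive cell; background percentage
   100·Σempty/(Σempty+Σcells); and the cell/empty frequency ratio
   (freq_cells/freq_empty).
3. **Titration response.** log₂((ref + 1)/(diluted + 1)) for the total and
   q90 signal; a marker in its linear concentration range responds ≈
   log₂(dilution factor) (two "logs" for fourfold dilution), a saturated or
   background-obscured marker responds ≈ 0.
4. **Categories A–E and recommendations.** Ordered, fully configurable
   rules: **D** ubiquitous target (reduce / consider dropping), **E** dead
   marker (increase, review), **A** no response with high background
   (reduce fourfold), **B** responds with intact separation (halve), **C**
   separation erodes on dilution (keep, or trim slightly). The adjusted
   panel and an audit trail are written out.
5. **Cost model.** Reagent cost = Σ concentration × volume × price
   (default 32.5 USD/µg), read allocation across markers and compartments,
   chip super-loading arithmetic, and fold/percent comparison statistics.
6. **Simulator.** A bundled generative model (equilibrium antibody binding
   with depletion, shared ambient pool from post-wash free antibody, finite
   sequencing depth) produces full experiments with ground truth, so the
   entire pipeline is testable without any data download.

## Worked example

Simulate a hashed titration lane (reference DF1 + fourfold-diluted DF4, ten
archetype markers, 500 cells among 5,500 droplets) and run the pipeline:

```python
from adtopt import *
from adtopt.adt_metrics import metrics_table, titration_response

lane = simulate_titration_lane(SimConfig(seed=1), archetype_panel(), default_conditions())
experiments = {}
for cid, (exp, truth) in lane.items():
    partition_droplets(exp); qc_filter(exp); demux_hto(exp)
    experiments[cid] = exp

metrics, responses, records = metrics_table(experiments)
for marker in experiments["DF1"].adt.feature_ids:
    rec = titration_response(records["DF1"][marker], records["DF4"][marker], 4.0)
    print(marker, classify_marker(rec), round(rec.log2_response["q90_expressing"], 2))
```

prints (abridged):

```
MK-A1 A -0.03     # 10 µg/mL, no epitopes: flat response, ~91% of its UMIs in empty droplets
MK-B1 B 1.61      # linear range, separation intact at both conditions
MK-C1 C 1.49      # diluted signal drops to ~4 UMIs, separation collapses
MK-D1 D 1.61      # ubiquitous: 100% positive cells, 55% of panel cell-UMIs
MK-E1 E 0.00      # dead marker: dim at both conditions, 0.02% of panel UMIs
```

Each marker's category matches the simulator's ground truth, the A marker's
background percentage is ~91% versus ~5% for D, and the empty-droplet
frequency ratio separates ambient-dominated (≪1) from epitope-driven (≫1)
markers. The same pipeline runs from the shell:

```bash
adtopt simulate --out sim --seed 1
adtopt run --config config.yaml --out run/   # partition, metrics, categories, costs, figures
```

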