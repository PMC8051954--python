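# Methods

## The measurement problem

Oligo-conjugated antibody (ADT) signal is counted by sequencing, so signal
intensity has a direct cost, and background has a peculiar geometry: residual
free antibody from the staining reaction distributes over *all* droplets of a
lane. Because empty droplets vastly outnumber cell-containing ones, a marker
stained at high concentration against a rare or absent epitope can spend most
of its sequencing reads in droplets containing no cell at all. The package
therefore treats the empty droplets as the background measurement: every
detection threshold, background percentage and frequency ratio is derived
from them rather than from isotype controls or manual gates.

## Droplet partition

Cells are separated from empties on the RNA barcode-rank curve. The detector
smooths log10(total) with a centered moving average (default window 11
ranks), finds the most negative forward difference of the smoothed curve
against log10(rank) within `[min_cells, max_cells]`, then refines to the most
negative *unsmoothed* forward difference within one window of that location.
Ties in totals are broken lexicographically by barcode so the partition is
deterministic. `max_cells` defaults to half the barcodes with signal: the
deep tail of the curve is so compressed in log-rank space that a one-count
step among the last barcodes would otherwise out-slope the true knee; callers
who know their expected cell yield should pass roughly five times that
number. A curve whose steepest slope is shallower than `slope_threshold`
(default 1.0 log10-total per log10-rank) has no knee and the detector asks
for a manual cutoff rather than guessing.

QC (default: at least 60 detected genes, mitochondrial fraction strictly
below 15%) runs *after* the partition and relabels failing cells `removed`,
so they contaminate neither the cell pool nor the empty (background) pool.
The alternative — counting removed barcodes as empty — is a documented
switch, since reasonable pipelines differ here. Cross-sample doublets and
HTO-negative cells are likewise excluded from all metric computations but
retained in the partition output.

## Metric definitions and conventions

* Quantiles use linear interpolation between order statistics (stated
  because quantile conventions differ across ecosystems).
* The detection threshold is `max(floor, Q_0.99(empty counts))` with
  `floor = 1`; with fewer than 100 empty droplets the floor is used and a
  warning issued. A cell is positive when its count strictly exceeds the
  threshold.
* Signal-to-noise is a difference of medians (positive − negative), in UMI
  units, not a ratio — at the few-UMI signal levels typical of well-titrated
  panels, ratios of small medians are unstable.
* The expressing cluster for the q90 statistic is the cell type with the
  highest *mean* (not median) marker count, tolerating bimodal clusters; a
  per-marker override lives in the panel sheet.
* `umis_per_positive_pct` divides the marker's share of the panel's cell
  UMIs by its number of positive cells (a library-balance measure); a
  marker-only denominator is available by config.
* The per-marker background percentage is the marker's empty-droplet share
  of its own UMIs, `100·Σempty/(Σempty+Σcells)`; this is one of several
  defensible denominators and is flagged as a convention.
* Titration responses use pseudocount 1 inside the log2 ratio, since zero
  counts are common at low depth; the linearity deviation is measured
  against log2(dilution factor).

## Classification

The five categories are operationalized as ordered rules over the paired
(reference, diluted) record; the first match wins, which resolves overlaps
deliberately (a ubiquitous, linearly responding marker is D, not B):

1. **D** if positive fraction ≥ `u_min` (0.90) and snr ≥ `s_min` (5 UMIs);
2. **E** if snr < `s_min` at both conditions and the marker's share of panel
   cell-UMIs < `e_max` (0.002);
3. **A** if |log2 q90 response| < `r_min` (0.5) and (dim at both conditions
   or background ≥ `b_high` (50%));
4. **B** if response ≥ `r_min` and snr ≥ `s_min` at both conditions;
5. **C** if response ≥ `r_min`, snr(ref) ≥ `s_min`, and separation erodes
   (snr(dil) < `s_min`) or the diluted threshold falls to ≤ `t_low` (3 UMIs);
6. otherwise **review** — the rules never raise.

The published assignments were made by expert inspection; these boundaries
are explicit defaults chosen to reproduce the qualitative descriptions
(`s_min` = 5 UMIs sits just below the typical 7–11 UMI median positive
signal; `r_min` = 0.5 log2 separates "minimal response" from real response).
Every threshold is config. With multiple tissues, categories are computed
per tissue and reconciled with priority D > B > C > A > E — a marker that
separates positive from negative anywhere is not dead. Recommended
multipliers (A: ×0.25, B: ×0.5, C: ×1 or ×0.8, D: ×0.25 + drop suggestion,
E: ×3 + review) are likewise configurable; drops are applied only when
confirmed.

The distinction between A ("obscured") and E ("non-functional") is partly a
matter of prior biological expectation that no classifier can see; the rules
use background share and panel share as proxies and route genuinely
ambiguous records to `review`.

## Equalization

Cross-condition comparability uses three levellers. Cell-type equalization
keeps, per shared type, the minimum count across conditions (uniform
sampling without replacement, seeded). Embedding-based matching greedily
pairs each cell of the smaller sample with its nearest unused Euclidean
neighbor in the larger one, in a seed-shuffled order — greedy rather than
optimal assignment, matching common practice; the embedding is an input, not
computed here. Sequencing-depth equalization thins a count matrix to an
exact UMI total by multivariate hypergeometric subsampling, which preserves
entrywise bounds and composes (thinning twice equals thinning once, in
distribution). The original read-level down-sampling operates on FASTQs;
this package starts at count matrices, so UMI-level thinning is the default
and a two-stage read-level mode (zero-truncated Poisson reads per UMI, read
thinning, re-collapse) is provided for saturation-sensitive comparisons.
Sequencing saturation is 1 − UMIs/reads, the 10x convention.

## The simulator

One mechanism generates all four phenomena the titration design manipulates.
Each marker binds a pooled epitope reservoir by single-site equilibrium with
ligand depletion: with total antibody `C_tot` (µg/mL), total epitope
`R_tot` (cells stained × copies per cell, converted to µg/mL equivalents via
a 150 kDa IgG molecular weight), and dissociation constant `Kd`, the free
concentration is the nonnegative root of

```
C_free² + (R_tot + Kd − C_tot)·C_free − Kd·C_tot = 0
```

solved in closed form (cancellation-safe branch selection; checked against
bisection to ~1e-15 relative) with occupancy θ = C_free/(C_free + Kd). This
single equation yields the saturation plateau (C ≫ Kd), the linear range
(C ≪ Kd: fourfold dilution gives a fourfold signal drop; note θ at
C = Kd/10 already sits 9% below C/Kd, so responses slightly undershoot two
logs even in the "linear" range — a real effect, not a simulator artifact),
the staining-volume effect (halving volume doubles R_tot, costing occupancy
only where θ·R_tot is comparable to C_tot, i.e. low-concentration antibodies
against abundant epitopes), and its rescue by staining fewer cells.

Counts are Poisson: each cell draws specific molecules at rate
epitopes(type)·θ·capture_efficiency and *every* droplet — cell or empty —
draws ambient molecules at rate `ambient_scale · wash_retention · C_free`,
modelling background as residual post-wash free antibody. Finite depth is a
per-molecule detection probability 1 − exp(−reads_per_umi) applied as
binomial thinning (a Poisson-reads approximation). All draws come from one
seeded generator stream, so a seed fully determines the experiment.

Hashed conditions pooled into one lane share one ambient pool: the
lane simulator averages C_free across conditions and drives every
condition's ambient rate with it. This is what makes obscured markers look
titration-insensitive — their "signal" is the shared background, which does
not dilute with any single condition. Each condition's experiment receives
its own draw of `n_empty` empty droplets from that shared pool (a lane's
empties are not literally split by sample); per-sample ambient pools are not
modelled. The mean (volume-unweighted) pooling is a simplification —
conditions stained in larger volumes contribute more free antibody to a real
pool.

Defaults: 500 cells and 5,000 empty droplets (empties outnumber cells
tenfold, a super-loaded lane in miniature), four immune cell types
(T 45%, B 20%, Mono 20%, NK 15%), 1e6 cells stained in 50 µL,
wash_retention 0.05, ambient_scale 130 molecules per droplet per µg/mL
(together placing a 10 µg/mL epitope-less marker at ≈ 40 ambient
UMIs/droplet, the regime where background dominates a lane),
capture_efficiency 0.02, reads_per_umi 3 (95% molecule detection). RNA is a
deliberately minimal two-component mixture — 120 uniform genes (six
mitochondrial) at ~1,000 UMIs/cell vs ~10 UMIs/empty — sufficient to
exercise rank-curve partitioning and QC, with no transcriptional structure;
cell-type labels and embedding coordinates are emitted as inputs, as they
would come from an upstream clustering. Passing tests on this generator
therefore demonstrates the pipeline's correctness under its mechanistic
assumptions, not robustness to real-data pathologies (doublet clusters,
Fc-receptor binding, per-cell epitope variability, sample-skewed ambient
pools).

The ten-marker archetype panel encodes each response category's mechanism
(two markers per category): A = 5–10 µg/mL with no epitopes (pure shared
ambient, ≈ 91% background); B = C ≈ Kd/10 against 4–5×10⁴ copies on a
restricted subset; C = the same regime but only 5–6×10³ copies, so the
diluted signal lands at 2–4 UMIs; D = 0.6–1×10⁵ copies on every type;
E = ≤ 0.1 µg/mL with no epitopes. Parameters were fixed by expectation
arithmetic (Poisson medians and quantiles against the classifier
boundaries) so that each archetype's category follows from its mechanism
with margin.

## Numerical and determinism choices

Counts are stored sparse (CSR) and validated as nonnegative integers;
matrices are features × barcodes internally with barcode strings as the
public key; modalities are aligned by barcode intersection (dropped counts
logged). Vendor conjugate suffixes (e.g. `-TotalSeqC`) are stripped before
panel matching. Figure count axes use log10(count + 1) to admit zeros, and
every figure writes a sidecar CSV of its plotted values so rendering is
testable without image comparison. CSV artifacts are byte-stable for a fixed
config and seed; the run log echoes config, seed and version, which suffices
to reproduce a run exactly. Presentation rounding (whole percents,
one-decimal folds) happens only in human-readable output, never in stored
values.

## Problem sizes

The test and acceptance workloads use lanes of 150–500 cells with 1,200–5,000
empty droplets, 20 replicate lanes for the titration-regime means, and 10
replicate lanes (100 marker-replicates) for classifier recovery — small
enough to run in seconds while leaving the Poisson sampling error on each
asserted mean an order of magnitude below its tolerance.

## Known limitations

Binding kinetics (time, temperature) are outside the model; only
equilibrium is simulated. Ambient intensity is proportional to post-wash
free concentration with a single retention parameter — wash count and
resuspension volume are not resolved. The classifier cannot distinguish
"absent epitope" from "non-functional antibody" (both are E) nor recover a
positive population truly erased by background (A), mirroring the underlying
ambiguity of the assay. Normalization (CLR/DSB) is deliberately out of
scope: all metrics operate on raw UMI counts, as titration decisions should.
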