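# Methods

This note records what `plexquant` computes, the assumptions behind each
stage, the defaults and why, and what the synthetic benchmarks do and do
not demonstrate.

## Data model and stage order

Every PSM carries its reporter intensities at four explicit stages: raw
(extracted), impurity-corrected, interference-corrected (RCC), and
normalized. The pipeline order is fixed: extraction → impurity correction
→ RCC (if enabled) → reporter-level normalization (if in the strategy) →
PSM ratios → peptide ratios (+ peptide-level normalization) → protein
ratios (+ protein-level normalization). Ratios are computed and aggregated
on the linear scale throughout; no log transform is applied anywhere.

## Identification filtering

Records carrying q-values are kept when `q ≤ threshold` (default 0.01).
Otherwise the filter sorts by posterior probability and keeps the longest
prefix whose model-based FDR, `mean(1 − p)` over the prefix, stays under
the threshold — the standard reading of TPP-style posteriors. The same
procedure runs independently at protein level, and PSMs all of whose
proteins failed the protein-level cut are dropped. A `1e-12` tolerance on
the comparison absorbs float cancellation in `1 − p` at the boundary.

## Reporter extraction and impurity correction

Extraction takes the most intense peak within ±`reporter_tolerance_th`
(default 0.002 Th) of each channel's reporter m/z — most-intense rather
than nearest-m/z because it is robust to small calibration error. A
tolerance that makes neighbouring channel windows overlap (the TMT-10 N/C
pairs sit 0.0063 Th apart) is rejected as a configuration error rather
than silently mis-assigning peaks.

The impurity matrix `M` holds in column `j` the fractions of channel `j`'s
true signal observed in each channel; the CSV layout is the
reagent-certificate convention of −2/−1/+1/+2 percentages, with the
diagonal `1 − Σ(impurities)` and leaks outside the plex dropped from the
matrix but retained in the diagonal deficit. Correction solves
`M·x = observed` exactly (the matrices are diagonally dominant and
well-conditioned; condition numbers above 1e12 are fatal) and clamps
negative components to zero in a single pass. A non-negative least-squares
refit would be a possible refinement; the single-pass clamp is
deterministic and matches widespread practice. Preset plex names load an
*identity* matrix with a prominent warning: manufacturer impurity values
are lot-specific and inventing them would silently corrupt data. The
bundled `*_synthetic_example.csv` files are clearly-labelled synthetic
stand-ins used by the tests and demos.

## Signal-to-interference and ratio-compression correction

S2I is the fraction of ion signal inside the precursor isolation window
belonging to the target: peaks matching `target_mz + k·1.00335/charge`
(`k = 0..3`, 10 ppm tolerance) summed over the window, divided by the
total window signal, computed on both flanking MS1 scans and linearly
interpolated in retention time to the MS2 (preceding-only fallback; S2I = 1
with a warning when no usable MS1 or precursor exists, which makes the
correction a no-op rather than an error). Isotope extent, spacing and
tolerance are configurable; the defaults cover tryptic 2+/3+ precursors.

RCC subtracts `(1 − S2I) · Σ(reporter intensities)` from the channels,
**split equally**. The equal split is the module's key assumption: it is
the only split consistent with co-isolated interference that is mixed 1:1
across channels, which is also the regime in which ratio compression is
maximally harmful. Channels are clamped at zero; when no channel clamps,
the output total equals `S2I ×` the input total exactly (noise
conservation), a property the tests assert.

## Ratio kernels

PSM ratio = numerator/denominator channel intensity, undefined (and
excluded, with a count in the run log) unless both are strictly positive.
A PSM ratio's weight is the sum of the two selected channels' intensities
— chosen over the all-channel sum because it tracks the information
content of that particular ratio; the all-channel variant is available via
`psm_weight_mode="all"`. A peptide's weight is the median of its PSM
weights.

Peptide kernels: `LinearRegression` is the least-squares slope through the
origin, `Σxy/Σx²` over (denominator, numerator) intensity pairs — the
origin is forced because a free intercept would decouple the slope from
the ratio; `SumPsmIntensity` is the ratio of channel sums;
`MedianPsmRatio` and `WeightedPsmRatio` aggregate the PSM ratios. Protein
kernels either pool all the protein's PSMs (`SumPsmIntensity`,
`MedianPsmRatio`, `WeightedPsmRatio`, `TrimmedMeanPsmRatio` with
`floor(0.2·n)` removed per side, which always leaves a non-empty core) or
aggregate peptide ratios computed by the chosen peptide kernel
(`MedianPepRatio`, `WeightedPepRatio`). Because the four PSM-pooling
protein kernels ignore the peptide kernel, the 336-point lattice collapses
to `(4 + 2·4) × 14 = 168` distinct protein-level outputs — verified by
brute-force equality in the tests.

Shared peptides: by default only PSMs resolving to a single protein group
contribute to protein ratios (unique-peptide mode); an option admits all
assignments. Charge states of the same modified sequence are merged into
one peptide (the peptide key is sequence + modification string).

## Normalization

Three levels, composed into exactly seven strategies (none; reporter;
peptide; protein; reporter+peptide; reporter+protein;
reporter+peptide+protein — peptide/protein without the reporter anchor are
deliberately not offered beyond these). Reporter-level normalization
multiplies each channel so all channel medians (zeros excluded — a missing
reporter is absence of evidence, not evidence of zero) equal the median of
channel medians. The target choice is ratio-neutral: any common target
changes all channels by one global factor and leaves every downstream
ratio untouched, a property asserted in the tests. Channel medians are
computed over the FDR-passing PSMs at the current stage (after impurity
correction and RCC when enabled). Ratio-level normalization divides
peptide (protein) ratios by their median so the normalized median is 1.
Both operations are idempotent to float precision.

## Evaluation

With calculated `x_i` and ideal `y_i` over the `m` (protein, channel-pair)
entries: ARE = `mean(|x_i − y_i|/y_i)`, restricted to the standard or
background class for ARE_Std/ARE_Bg; RMSE = `√(Σ(x_i − y_i)²/m)`;
AUCCD integrates coverage (the fraction of entries with relative deviation
≤ `d`) over `d ∈ [0, 1]` by the trapezoid rule on a 0.01 grid, normalized
by the unit range so perfect ratios score exactly 1. Deviation is
*relative* (`|x − y|/y`), consistent with ARE and with coverage-at-10/20/30%
conventions; absolute deviation would be meaningless across ideal ratios
spanning 0.25–4. `summarize` reports the sample (n−1) mean/SD of ratios at
one ideal value. Differential candidates are entities with
`max(ratio) > 1.5` — the literal rule; a symmetric option
(`min(ratio) < 1/1.5`) exists but is off by default since the
selecting-above-threshold convention does not state it.

## Synthetic benchmarks

The generator emulates spiked-standard designs: background proteins mixed
1:1 and standard proteins at known fold changes. Defaults (the conditions
under which the acceptance checks run): 50 proteins, 3 peptides × 3 PSMs
each, TMT-6, 10% multiplicative log-normal peak noise (mean-1
parameterization), no interference, seed 42. The six standard proteins
carry the six cyclic rotations of a 4:2:1:1:0.5:0.25 pattern — one protein
per rotation — so every channel receives the same total amount. That
balance is what real benchmark mixtures engineer deliberately, and it is
the condition under which median normalization is valid; without it,
channel-median scaling is systematically biased by the spike design itself
(observable by passing an unbalanced `true_ratios`).

Reporter signal per PSM is `base × channel abundance × noise`, blended
with a flat 1:1 interference vector contributing exactly
`interference_fraction` of the summed signal, then forward-mixed through
the impurity matrix. MS1 scans flank every MS2 (the scan layout alternates
MS1/MS2 with one trailing MS1, each MS1 carrying the clusters of both
adjacent MS2s) with an isotope cluster and one off-isotope interfering ion
sized against the *in-window* cluster signal so the measured S2I equals
`1 − interference_fraction` exactly. Precursor m/z values cycle a 3.1 Th
grid so windows of adjacent scans never overlap. Base intensities are
log-normal (σ = 0.5 between peptides, 0.3 between PSMs of a peptide)
around 1e5 counts, a plausible orbitrap-style dynamic range.

Because the interference component mirrors the correction model's own
assumption (flat 1:1 co-isolation), RCC is *exactly* right in expectation
on these data. Passing tests therefore validate the implementation of the
model, not the model's adequacy for real co-isolation, where interference
composition varies and RCC corrects only partially. Other features of real
data the generator does not emulate: chromatographic peak shapes, charge
envelopes, fragment ions beyond reporters, missing channels, decoys and
search-engine score distributions (identifications carry probability 1).

## Numerical choices and degenerate inputs

Empty isolation window → S2I = 1 with a warning. PSMs with all-zero
reporters are excluded and counted. Undefined ratios (non-positive
numerator or denominator) are dropped per pair and counted, never imputed.
An all-zero channel is fatal for reporter normalization (named in the
error). Ties in medians follow the standard mean-of-central-pair rule.
Output tables are sorted by accession/peptide/PSM id and written with a
fixed float format, so identical inputs yield byte-identical files.

## Problem sizes

The default test suite and the acceptance script run on generated datasets
of 50 proteins × 9 PSMs (450 PSMs, ~900 spectra); a full 336-combination
sweep over five channel pairs completes in a few seconds. These sizes give
ARE estimates with a standard error well under 0.01, which is adequate to
separate the effects being tested (compression of 2–4-fold ratios, the
RCC trade-off) from noise.

## Known limitations

- mzML support covers the centroided subset this package writes and the
  common instrument-export layout (ms level, scan times, isolation
  windows, selected ions, 32/64-bit float arrays, zlib or none); profile
  spectra, chromatograms and exotic CV usage are out of scope. mzXML,
  pepXML and protXML go through pyteomics.
- The equal-split interference model cannot recover channel-specific
  interference; MS3 and dual-isolation acquisition schemes are out of
  scope.
- No significance testing on ratio differences, no protein inference
  (groups come from protXML or the protein table), and no
  variance-stabilizing normalization.
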