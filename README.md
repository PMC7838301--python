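# plexquant

Isobaric-labeling quantitation for shotgun proteomics: from centroided MS2
spectra and validated peptide-spectrum matches (PSMs) to protein abundance
ratios between reporter channels, with every standard processing stage made
explicit and swappable.

In an iTRAQ/TMT experiment each sample is tagged with an isobaric label
whose MS2 reporter ion encodes that channel's abundance. Turning reporter
intensities into protein ratios involves a chain of algorithmic choices —
how to roll PSM ratios up to peptides and proteins, whether and where to
normalize, and whether to correct the systematic compression of ratios
caused by co-isolated peptides. `plexquant` implements the full lattice of
these choices so they can be compared on equal footing, plus the metrics to
score them against a known ground truth.

## What it computes

**Preprocessing.** Identifications are filtered to 1% FDR at PSM and
protein level (q-values when present, otherwise the running mean of
`1 − posterior`). Reporter ions are extracted as the most intense peak
within ±0.002 Th of each channel's reporter m/z, and isotope impurities are
removed by solving `M·x = observed` for the manufacturer's
cross-contamination matrix `M` (negative solutions clamped at zero).

**Ratio compression correction (RCC).** Co-isolated peptides contribute
near-1:1 reporter signal that biases every ratio toward 1. The
signal-to-interference ratio S2I — precursor-cluster signal over total
signal in the isolation window, measured on the flanking MS1 scans and
interpolated in retention time — bounds that contamination, and
`(1 − S2I) · Σ(reporter intensities)` is subtracted, split equally across
channels.

**Ratio rollup.** Four peptide kernels (origin-forced regression slope
`Σxy/Σx²`, ratio of summed intensities, median of PSM ratios,
intensity-weighted mean of PSM ratios) × six protein kernels (the four
PSM-pooling analogues plus 20%-trimmed mean, and median / weighted mean of
peptide ratios) × seven normalization strategies (none, and every
combination of reporter-median, peptide-ratio-median and
protein-ratio-median scaling that the reporter level anchors) × RCC on/off:
336 combinations, enumerable and sweepable in one call.

**Evaluation.** With calculated ratios `x_i` and ideal ratios `y_i`:
ARE = mean `|x_i − y_i| / y_i` (ARE_Std / ARE_Bg per protein class),
RMSE = `√(Σ(x_i − y_i)²/m)`, and AUCCD — the area under the curve of
coverage (fraction of ratios within relative deviation `d`) against
`d ∈ [0, 1]`. Differential-candidate lists (max ratio above 1.5) are
compared with the Jaccard index.

**Synthetic benchmarks.** A generator produces fully self-contained
datasets — mzML spectra with flanking MS1 scans realizing a designed S2I,
PSM/protein tables, impurity matrix, ground truth — with controlled true
ratios, log-normal peak noise, impurity mixing and co-isolation
interference, so every stage of the pipeline can be validated against
known answers.

## Worked example

```python
import plexquant as pq

# a 50-protein benchmark: 44 background proteins at 1:1 and 6 standards
# cycling a 4:2:1:1:0.5:0.25 abundance pattern, 10% peak noise, 30% co-isolation
spec = pq.SyntheticSpec(seed=42, interference_fraction=0.3)
ds = pq.generate_dataset(spec)

prep = pq.prepare_dataset(ds.spectra, ds.psms, ds.protein_groups, ds.matrix, plex="TMT-6")
pairs = [pq.ChannelPair("127", "126")]
truth = ds.truth.truth_table(pairs)

for rcc in (False, True):
    combo = pq.AlgorithmCombination("LinearRegression", "MedianPepRatio", "none", rcc)
    result = pq.run_pipeline(prep, combo, pairs)
    ev = pq.build_evaluation_input(result.protein_values, truth, pairs)
    print(f"RCC {'on ' if rcc else 'off'}  ARE_Std={pq.are(ev, 'standard'):.3f}  "
          f"ARE_Bg={pq.are(ev, 'background'):.3f}  AUCCD={pq.auccd(ev):.3f}")
```

prints

```
RCC off  ARE_Std=0.329  ARE_Bg=0.029  AUCCD=0.935
RCC on   ARE_Std=0.038  ARE_Bg=0.041  AUCCD=0.960
```

Without correction, 30% co-isolation compresses the spiked standards'
ratios so badly that their average relative error is 33%; subtracting the
inferred interference restores them to within 4% of truth. The same
subtraction slightly *worsens* the 1:1 background proteins (ARE_Bg 0.029 →
0.041) because it amplifies relative noise around ratio 1 — the
characteristic trade-off of this correction.

The same run from a shell:

```bash
plexquant synth --out data --seed 42
plexquant quant --spectra data/spectra.mzML --identifications data/psms.tsv \
    --proteins data/proteins.tsv --matrix data/matrix.csv --plex TMT-6 \
    --pairs 127/126 --rcc --out-dir out
plexquant sweep --spectra data/spectra.mzML --identifications data/psms.tsv \
    --proteins data/proteins.tsv --matrix data/matrix.csv --plex TMT-6 \
    --ground-truth data/ground_truth.tsv --out-dir out   # 336 metric rows
```

Impurity-matrix CSVs follow the reagent-certificate layout
(`channel, minus2, minus1, plus1, plus2` in percent); the bundled
`*_synthetic_example.csv` files are invented demonstration values, not
manufacturer data — loading a bare plex name uses the identity matrix and
warns that correction is a no-op.

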