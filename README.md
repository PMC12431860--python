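# aggrequant

Quantification pipeline for **aggrephagy imaging** — the selective
autophagic clearance of protein aggregates — built around a tandem
mCherry–GFP (dual-colour) aggregation reporter. GFP is quenched in the
acidic lysosomal lumen, so an aggregate is *white* (green **and** red)
while cytosolic and turns red-only after lysosomal delivery. The package
implements, as a tested library with a thin CLI, every quantitative
readout such an experiment needs, together with synthetic-data
generators that produce each input with known ground truth.

## What it computes

**Puncta flux (`aggrequant.puncta`, `aggrequant.kinetics`).** Each
channel is segmented with a morphological white top-hat (disc element,
default radii 10 µm green / 100 µm red), the filtered output is
normalized by the frame's intensity range and thresholded at the colour
threshold (default 0.7). The white-area fraction is

    w(t) = area(green ∩ red) / area(red),

and the degradation rate is the negative OLS slope of ln w(t) against
time, k = −d ln w / dt (h⁻¹). Aggregate-formation time courses (e.g.
HTT-polyQ puncta counts) are summarised by their trapezoidal AUC, and
FRAP traces are normalized to the mean pre-bleach intensity.

**Receptor clustering by SMLM (`aggrequant.smlm`).** From raw blinking
movies: temporal-median background subtraction, 2-D Gaussian spot
localization, Gaussian reconstruction rendering and block-wise
cross-correlation drift correction. Within each aggregate ROI the
*local density* of molecule *i* is

    D_i = #{ j ≠ i : ‖x_i − x_j‖ ≤ r },   r = 5 · d̄,

where d̄ is the aggregate's mean nearest-neighbour distance. Molecules
with D_i > 40 are cluster members; clusters are connected components of
members linked within r with ≥ 3 members. Per aggregate it reports
localization density, cluster count and in-cluster density.

**Aggregate compaction (`aggrequant.compaction`).** Grey-value
cross-sections through aggregates are normalized to their own mean;
the pooled spread (SD of normalized values ≈ coefficient of variation)
separates compact from loose aggregates.

**Synthetic data (`aggrequant.synthetic`).** Deterministic, seeded
generators for dual-colour time-lapses (two-state dual → red-only Markov
conversion at rate `k_deg`, optional fragmentation), clustered
localization fields, blinking raw movies, cross-section profiles and
FRAP traces — each returning a `GroundTruth` record.

## Worked example

```sh
aggrequant simulate timelapse --n-aggregates 30 --duration 6 --seed 1 \
    --out-dir demo
aggrequant quantify demo/green.tif demo/red.tif --pixel-size-um 1.5 \
    --out-dir demo
aggrequant kinetics demo/white_fraction.csv --out demo/kinetics.csv
```

prints

```
rate=0.1459 r2=0.945 -> demo/kinetics.csv
```

i.e. a degradation rate of 0.146 h⁻¹ recovered from a short noisy
movie simulated at the true rate 0.1 h⁻¹ (short movies carry large
waiting-time sampling error; the goodness statistic r² is the variance
of ln w explained by the log-linear fit). The same stages are available
as library calls — `simulate_aggrephagy_timelapse`,
`white_fraction_timeseries`, `degradation_rate` — which is what the
tests and the acceptance script use.

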