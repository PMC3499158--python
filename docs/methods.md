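# Methods

This note records the models, estimators and numerical choices behind
`flowqa`, what the synthetic-data generator does and does not emulate, and
the limitations a user should know about.

## Data model

An FCS acquisition is held as a `Sample`: an `n_events × n_channels`
float64 matrix on the raw instrument scale, channel short names, marker
(stain) labels, the verbatim TEXT keywords, and the index of the
acquisition-time column (a channel named "Time", case-insensitively,
unless set explicitly). FCS support is a deliberate subset — list mode,
datatypes F/D/I, single data segment, both byte orders on read, FCS 3.1
float little-endian on write; anything else raises an explicit
unsupported-feature error rather than guessing. Integer data are masked to
the bit width implied by `$PnR`. Times are used as given and never rescaled
by `$TIMESTEP`: the spike statistic needs only event order and relative
spacing.

A `GatingHierarchy` is the gate tree applied to one sample. Events are
stored once; every node keeps a boolean mask with `child ⊆ parent`
enforced by construction (`mask = parent.mask AND in_gate(...)`). The
masks are deliberately stored per node even though they are redundant
given the chain — it makes an independent chain-recomputation oracle
meaningful in tests and keeps per-node statistics O(1) after gating. A
`GatingSet` applies one template to many samples; node paths render as
`/A/B/C`.

## Transforms and compensation

Compensation replaces the detector block of the event matrix with
`observed @ spill⁻¹`; spillover matrices must be square, unit-diagonal and
well-conditioned (condition number < 1e12, otherwise an error carrying the
diagnostic).

The display transform is the logicle family parameterized by top-of-scale
`T`, total decades `M`, linearization width `W` and extra negative decades
`A` (defaults 262144 / 4.5 / 0.5 / 0). The inverse (display → raw) is the
closed-form biexponential; the forward direction inverts it numerically by
vectorized bisection on the normalized display coordinate (60 halvings of
a verified bracket, < 1e-10 normalized units, well inside the documented
1e-6 round-trip tolerance; a bracket failure raises rather than returning
garbage). Display values are reported in decades with `forward(T) = M`
for every `A`. The `W = 0, A = 0` case degenerates to a sinh scale that is
one decade per factor of ten far from zero; the residual sinh correction
at `T/100` is ≈ 4e-6 decades and shrinks a hundredfold per decade — the
tolerance used in its test comes from evaluating the closed form, not from
an aspiration.

`QuantizedTransform` emulates tabulated display transforms: the exact
curve is sampled at `n_bins` equally spaced display values (default 4096)
and linearly interpolated in between; raw values outside the table clamp
to the boundary knot, and those clamped events are what the margin gates
count as boundary events. The end knots are pinned to the exact instrument
domain so top-of-scale pile-up is classified without round-off slack. With
4096 knots the interpolation error is ~3e-7 decades, so gating through the
exact versus quantized transform moves essentially no events across gate
boundaries and the per-population count CVs sit at zero to well below 1%;
coarser tables grow the error monotonically (verified over 256→4096).

The two-count concordance CV uses the two-point *sample* standard
deviation (divisor n−1): `CV = 100·|a−b|/(√2·mean)`. The population-sd
variant (smaller by √2) is available via `ddof=0`.

## Gate geometry

Rectangle and interval gates are half-open, `min ≤ x < max` per dimension;
polygon membership uses even-odd ray casting with points on an edge
counted inside. These conventions are declared, not inferred from any
interactive tool — they matter only on measure-zero boundaries. The ray
caster is written to handle vertical edges and self-intersecting polygons
without crossing-count flicker; it is validated against an independently
coded per-point reference and against `shapely.covers` on convex hulls.

## Statistics store and QA engine

Population statistics (one proportion and count record per node, one MFI
record per node × gate-dimension channel, one spike record per sample ×
fluorescence channel) go into an embedded sqlite store — a single file on
disk or `:memory:` — keyed by `sample|population|channel|statistic`, so
re-extraction is idempotent and statistics from separately imported
batches accumulate side by side. Metadata rows are stored as JSON
documents keyed by sample, with ISO-8601 dates round-tripped to datetimes.
MFI records are computed on the display scale as the median (default) or
mean over in-mask events.

The stratification formula `y ~ x | g1*g2*…` partitions the filtered
records by the *observed* cross product of the conditioning columns
(unobserved combinations are simply absent; empty conditioning means one
group). Dispatch follows the plot type: `xyplot` makes per-record calls —
thresholds, robust-normal z, or residual calls against a Huber fit of the
statistic on the x variable (dates become days since 1970-01-01) —
while `bwplot`/`densityplot` run the two-level scheme: the boxplot rule
within each level of the x variable and the one-sided log-IQR test across
levels. Groups below 3 records are skipped (a robust scale needs three
points) except for cutoff rules, which run at any size. Re-running a task
replaces its previous calls. Display subsetting on plots never changes
which records are flagged.

## Outlier estimators

* "Robust mean and variance" is the median paired with the
  1.4826-scaled MAD; all cutoffs are strict inequalities; a zero robust
  scale (all values equal) yields zero flags by definition.
* Quartiles use linear interpolation between order statistics at
  `h = (n−1)p + 1` — one fixed convention, matched exactly by the
  brute-force oracle in the tests.
* The between-group test works on `log(IQR_g + ε)`, `ε = 1e-12 × max IQR`,
  so zero-spread groups stay finite; it is one-sided upper — only
  *larger*-than-expected variation is ever flagged. When most groups have
  identical spread the MAD collapses and nothing is flagged; detection
  requires a majority of groups with ordinary spread.
* Huber regression runs IRLS with tuning c = 1.345 (95% normal
  efficiency), residual scale re-estimated each iteration as
  1.4826·median|r|, convergence at max coefficient change < 1e-8 within 50
  iterations (non-convergence is reported, not fatal). Residual outliers
  standardize by the fit's final robust scale. With c → ∞ the solution
  equals ordinary least squares to 1e-8, which the tests verify against
  the closed form; the whole fit is cross-checked against an independent
  IRLS implementation from the statsmodels library.

One calibration fact worth stating plainly: standardizing by an
*estimated* MAD inflates tail probabilities relative to the known-σ
normal. On 10⁵ ungrouped null draws the z = 3 rule flags 0.27% as
nominal; grouped into cells of 1000 the realized rate is ≈ 0.32%, and at
group size ~10 the per-record false-positive rate of a 3-z rule is a few
percent. This is a property of every MAD-z procedure, not of this
implementation; the grouped behaviour is asserted at its measured band in
the tests.

## The spike statistic

Events are ordered by time and split into `n_bins` windows of near-equal
event count (default 100 windows, at least 20 events each; fewer events
coarsen the binning to `floor(n/20)` windows) — equal *count*, not equal
time, so flow-rate variation cannot starve a window. Each window
contributes its median display-scale fluorescence of the compensated
signal (compensation matters: spillover from bright neighbours otherwise
dominates the low display range and masks spikes). Window medians are
standardized by their own median/MAD and aggregated through a hinge:
`statistic = mean_b max(0, |z_b| − 1)`.

Properties: exactly zero for constant fluorescence (MAD = 0 sets all z to
0); invariant to affine rescaling of the channel; non-decreasing in
injected spike magnitude. The null is *not* tightly concentrated — the
shared MAD couples the windows, so on stable 10⁴-event acquisitions the
statistic fluctuates around 0.17 (sd ≈ 0.05, occasional values to ~0.36),
and bimodal fluorescence mixtures with small window occupancy push it
higher still (mean ≈ 1.1 at 25 events per window). The default spike QA
task therefore uses a threshold of 0.85 — the ≈ 99.9th percentile of the
mixture null at the nominal 10⁴-event acquisition — rather than a cohort
z-rule, and sub-nominal acquisitions (which inflate the score for purely
statistical reasons) are the event-count task's business. A slow linear
drift spreads |z| over many windows and is deliberately not claimed as a
spike; drift is detected by the MFI-versus-date regression task.

## Synthetic studies

The generator emulates a multi-panel longitudinal study: subjects
contribute aliquots (`coresampleid`) stained with three 5-colour panels
(tubes) and acquired on dates spanning 120 days; the default study is
4 subjects × 2 aliquots × 3 panels = 24 files of 10⁴ events — seconds to
gate, while `events_per_sample`/`n_subjects` scale it up to clinical-trial-sized
studies outside the test suite. Scatter events are drawn as
debris/mononuclear/granulocyte Gaussian clouds placed ≥ 4σ clear of the
template's WBC and MNC gate boundaries, so the gated white-cell fraction
recovers the configured value to binomial precision. Fluorescence is
drawn in display space as a negative/positive mixture (negative at 0.9
decades, positive at 3.2, positive fraction 0.35), mapped to the raw
scale through the inverse logicle and then mixed forward through a fixed
spillover matrix — the gates are meaningful by construction and
compensation is exercised for real. Panels share stains deliberately
(CD3 appears in every tube, most other markers in two): redundant
staining is how clinical panels are designed, it is what the
aliquot-consistency checks exist for, and it gives each channel×stain
stratum 8–24 samples.

Sample-to-sample staining variation is modelled as *bounded* (uniform,
±0.05 decades on the positive mean): the null study represents an
in-control process, and out-of-control deviations are exactly what the
anomaly specifications inject. With heavy-tailed (normal) between-sample
jitter the 3-z MAD rules would flag a few percent of clean records at
these stratum sizes purely by construction, which would say nothing about
the pipeline. Consequently the passing end-to-end tests demonstrate
correct recovery of injected anomalies against a controlled background;
they do not certify false-positive rates on real instruments, whose
between-sample variation is heavier-tailed and correlated.

Anomalies are applied at generation time and logged to a truth table:
`low_lysis` sets the white-cell fraction (default 0.70 vs the 0.8 QC
threshold); `mfi_drift` shifts a channel by `slope × days` in display
units (default ±0.004/day over 120 days ≈ half a decade); `spike` lifts a
5%-wide time window by 2 decades (a fluidics-transient-scale artifact; it
also briefly saturates bright events, which is why the margin-gate
threshold tolerates 2% off-scale); `low_count` truncates acquisition to
2 500 events; `aliquot_inconsistency` offsets one sample's channel by 0.6
decades; `boundary_excess` pins an exact 5% of events at top of scale.
Everything is deterministic given the seed, down to byte-identical FCS
files.

Not emulated: instrument noise physics, doublets, time-varying flow
rates, non-linear drift, debris beyond a single Gaussian component, and
any correlation between channels beyond spillover.

## Report

The report is a pure function of the store and the task list: an index
page grouping tasks by QA level with per-task failing-file counts and
tables, one summary SVG per task (panelled scatter with the robust line,
boxplots with flagged boxes/points in red, or per-group densities), and
per-sample detail SVGs (gate plots when the gated data is in memory,
otherwise the sample highlighted against its group's distribution).
Flagged points carry hyperlinks, so every flagged call is reachable from
the index in at most two clicks. SVGs embed their data coordinates in a
`<metadata>` element and are rendered with a fixed hash salt and no
timestamps, making regeneration byte-identical — asserted in the tests.

## Known limitations

* FCS: no ANALYSIS segments, no multi-dataset files, no delimiter-escape
  pathologies beyond doubled delimiters; keyword values are stored as
  text.
* Gating: no ellipse or quadrant gates, no automated gate placement.
* The store is single-writer; concurrent pipelines should use separate
  files.
* The spike score is comparable only between acquisitions of similar
  event count (see above).
* Robust-z calls at stratum sizes below ~10 records have materially
  inflated false-positive rates; the grouped calibration numbers above
  quantify this.
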