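# Methods

## Model overview

oryzasim simulates a rice plant as a dated tree of growth units — node,
internode, sheath and leaf bundles on the main stem and tillers, plus
panicle and root segments — whose event times all derive from the
emergence of main-stem leaves on a thermal-time clock.

### Thermal time

The clock is accumulated growing degree days:
`gdd_cum[i] = Σ_{j≤i} max(0, T_j − base_temp)` on daily mean
temperatures, with no upper cutoff. `base_temp` defaults to 10 °C, the
standard base for rice. Day↔GDD conversion is linear interpolation on
the accumulated series; day-denominated rules (heading span, internode
fixing) are mapped through it so the simulator keeps one time axis.

### Leaf age and the phyllochron

Leaf age — the number of main-stem leaves emerged — is realized with a
constant phyllochron in GDD (default 100 °C·d per leaf): leaf *n*
emerges when the accumulation first reaches `n · phyllochron`. The
phyllochron in real plants drifts across phases; a constant is the
simplest model consistent with leaf-age arithmetic, and it makes the
synchrony rules exactly testable. If the season's total GDD cannot
reach `LN` leaves, only reachable ranks are scheduled and the schedule
carries a truncation flag.

### Synchrony rules

At the emergence of main-stem leaf *n*: sheath *n* and leaf *n*+1
elongate; internode *n*−2 elongates; the tiller at node *n*−3 shows its
first leaf and the node *n*−4 tiller its second; the root on leaf
segment *n*−3 starts, segment *n*−4 gains order-1 branches, segment
*n*−5 order-2 branches. Rules indexing a rank below 1 emit nothing —
those positions do not exist early in development. Because branch
order *k* of segment *s* triggers at leaf *s*+3+*k*, each branching
order lags its parent by exactly one leaf interval.

Internodes below rank `LN − m + 1` never elongate: with the jointing
stage at leaf age `LN − m + 3` and the leaf-*n* rule triggering
internode *n*−2, the first unfrozen internode is reached exactly at
jointing, so the freeze rule and the jointing equation are one
constraint expressed two ways. The uppermost internode has no leaf to
trigger it; it is scheduled one phyllochron after the flag leaf (one
leaf cycle, matching the observation that its fixing interval roughly
equals a leaf cycle). Heading starts with that elongation, spans 5
days, and the internode fixes 7–9 days after the start (default 8,
configurable).

Tiller leaves track the main stem 1:1: leaf *k* on the node-*v* tiller
appears with main-stem leaf *v*+2+*k* (so leaf 1 at *v*+3, leaf 2 at
*v*+4, consistent with the two tiller rules). Whether tillers keep
their own phyllochron thereafter is genuinely open; 1:1 tracking is the
choice that introduces no new parameter. Tiller-of-tiller recursion is
not modelled.

The root-node count is `LN − m + offset` (default offset 0): nodes
whose internodes elongate are lifted above the soil and bear no roots.
The offset absorbs convention differences in counting the coleoptile
and incomplete-leaf segments.

### Organ geometry

Blade length follows the logistic
`LL_n/(1 + La·e^{−Lb·(GDD−IGDD_n)/ΔGDD_n}) · min(FN, FW)` with
La = 8.65, Lb = 6.26. A logistic never reaches zero, so lengths below a
visibility fraction (default 1% of `LL_n`) render as 0; at
`GDD = IGDD_n` the blade is `LL_n/(1+La) ≈ 0.104·LL_n`, i.e. the
initial GDD marks visible emergence, not zero length.

Blade width is a profile along the vein, measured from the tip so both
branches vanish there: `P·x/WLR` for ranks 1 and `LN`, `WPd·x² + WPe·x`
for middle ranks, clamped at zero where the quadratic goes negative.
Reading the width equation as a profile (rather than a max-width model)
is what the trapezoid segmentation requires; the interpretation is
isolated behind `width_profile()` so it can be swapped.

Leaf area cuts the blade into `N_sp` equal vein intervals; each
segment is two symmetric trapeziums on the half-widths at the interval
ends. This is the composite trapezoid rule on the half-width profile:
exact for linear profiles, an `O(N_sp⁻²)` underestimate for concave
ones — hence simulated area (and LAI) rises monotonically with `N_sp`,
and `N_sp = 10` is the recommended working granularity (finer levels
change LAI by well under 1%).

Sheaths, internodes and roots are cylinders expanding with the same
logistic form toward configured final dimensions (defaults: sheath
18 × 0.5 cm, internode 12 × 0.6 cm, root 15 × 0.12 cm), with the
midpoint half-way through a two-phyllochron growth window.

### Tillering

Daily tiller number follows
`APPSTN_i = APPSTN_{i−1} + Tv·ΔPPSTN_i·FL·min(NF, WDF)` from
`APPSTN_0 = 1` (the main culm; the initial value is not fixed by the
model's source and 1 is the smallest biologically meaningful choice).
The potential daily increase `ΔPPSTN_i` is cultivar-calibrated outside
this package; a built-in logistic-pulse generator (sigmoid increments,
default 12 potential tillers peaking 30 days after emergence over an
~8-day width) stands in for it so the recursion is testable. APPSTN is
tracked as a real number; the geometric realization floors it. Tiller
senescence after jointing is out of scope — the recursion only adds.

Tillers are allocated to basal nodes earliest-eligible-first with a
seeded shuffle breaking ties among equally timed nodes; requests beyond
the eligible nodes cap there and set an overflow flag.

### Population generation and meshes

Populations are exact `rows × cols` grids (default 5 × 5 at 0.30 m).
Varied parameters are drawn uniformly from `[M − d, M + d]` — the
literal range reading; although `d` is nominally a standard deviation,
a truncated normal could be plugged in at the same seam — and every
plant gets a uniform random rotation about the vertical axis. All
randomness flows from one `numpy` Generator per scene, so a seed
reproduces the scene byte-for-byte.

Meshes use a right-handed frame, +z up, ground at z = 0, meters.
Leaves are flat triangulated ribbons built from the width profile;
panicle a tapered cylinder placeholder; roots straight cylinders with
branch counts from the phenology rules. Decimation is vertex
clustering: vertices snap to a uniform grid refined fine→coarse, and
the finest grid whose face count fits `ceil(fraction · faces)` wins, so
face count never increases and geometry is kept as far as the budget
allows. LOD is a piecewise-constant nonincreasing map from viewpoint
distance to face fraction (full detail ≤ 2 m, half ≤ 5 m, quarter
≤ 10 m, 0.1 beyond).

### LAI pipeline and evaluation

LAI at a chosen GDD sums blade area over all visible main-stem leaves
and over the leaves of the tillers present at the corresponding day,
then divides by `row_spacing × col_spacing`. Yellow (senescent) leaves
count by default — destructive measurements discard them, which is the
known cause of simulated LAI exceeding measured LAI — and an
`exclude_senescent` flag drops leaves older than a configured lifespan
(default 900 °C·d past their initial GDD).

Evaluation: `RE = 100·|O−S|/O %` per pair; RMSE, MAE and
`R² = 1 − SS_res/SS_tot` against the observed mean. R² is deliberately
the coefficient-of-determination form, not squared Pearson correlation:
on the packaged reference comparison the two differ materially (0.86 vs
≈ 0.998) because the simulated values carry a systematic positive
offset, and only the former reflects it.

## The packaged reference table

`src/oryzasim/data/lai_reference.csv` holds a published field
comparison for two cultivars (YD6, W14) at tillering, jointing and
flowering: measured LAI and simulated LAI at `N_sp` ∈ {5, 10, 20, 30}
with printed relative errors. The measured values are inputs, never
recomputed. `table1_report()` recomputes each RE cell from its own
row; 23 of 24 match to the printed 2 decimals, and the one that does
not (YD6, jointing, `N_sp` = 5: printed 9.09, recomputed 9.03 — evidently
derived from an unrounded simulated value) is flagged rather than
silently matched. The headline RMSE 0.56 / MAE 0.55 / R² 0.86 attach to
the `N_sp` = 10 column, the granularity the reference analysis adopts.
The cultivar parameter sets and season weather behind those simulated
values are not published, so end-to-end regeneration of the simulated
column is not possible; the fixture-based recomputation is the
reproducible surface.

## Synthetic data

`synth_cultivar(seed)` draws `LN` ∈ [14, 18], `m` ∈ [4, 7], phyllochron
∈ [85, 115] °C·d, a unimodal final-length profile peaking 2–3 ranks
below the flag leaf (max 35–55 cm), and width/tillering coefficients in
ranges giving realistic blade widths (~1–1.5 cm mid-blade maxima).
`synth_weather` is a seasonal sinusoid (mean 25 °C, amplitude 5 °C)
with bounded uniform noise. These emulate a temperate rice season and
a japonica-like architecture; they do not emulate measurement noise,
nitrogen/water stress dynamics (factors default to non-limiting), leaf
curvature, or tiller senescence — so passing tests demonstrate the
model mechanics and contracts, not field-level predictive skill.

## Problem sizes and determinism

Tests and the acceptance script use a 220-day synthetic season, 5 × 5
populations and `N_sp ≤ 1000`, sizes at which every stage runs in
seconds while still exercising full seasons and full grids. Property
tests run 100–250 randomized cases each under fixed hypothesis seeds.
All stochastic stages (cultivar synthesis, weather, allocation,
population variation) take explicit integer seeds and are reproducible
bit-for-bit.

## Known limitations

- Constant phyllochron; no photoperiod or vernalization response.
- Tiller geometry reuses main-stem leaf parameters with a scale factor;
  the tiller-vs-main-stem quantitative relationship is not calibrated.
- Stress factors (FN, FW, FL, NF, WDF) are user inputs, not computed
  from soil/management state.
- Panicle, root and unexpanded-leaf geometry are placeholders
  (cylinders/ribbons), adequate for area and topology, not for render
  realism.
- No organ senescence or shrinkage; LAI is nondecreasing up to
  flowering by construction.
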