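# oryzasim

A functional–structural simulator of rice plant morphology driven by
thermal time, for crop-phenomics researchers who want to generate
virtual rice plants and canopies and to predict leaf area index (LAI)
without destructive field sampling.

## What it models

Rice development is clocked by accumulated **growing degree days**
(GDD): daily mean temperature above a base (default 10 °C), summed over
days. On this clock the simulator applies the organ **synchronization
rules** of rice: when main-stem leaf *n* emerges, sheath *n* and leaf
*n*+1 elongate, internode *n*−2 elongates (lower internodes stay frozen
until the jointing stage, which for a cultivar with *LN* leaves and *m*
elongated internodes falls at leaf age *LN* − *m* + 3), the tiller at
node *n*−3 shows its first leaf, the root on leaf segment *n*−3 starts
growing, segment *n*−4 branches once and segment *n*−5 twice.

Each leaf blade elongates along a logistic curve

```
LL_n(GDD) = LL_n / (1 + La·exp(−Lb·(GDD − IGDD_n)/ΔGDD_n)) · min(FN, FW)
```

with La = 8.65, Lb = 6.26, and carries a width profile along the vein
(linear for the first and flag leaves, quadratic `WPd·x² + WPe·x` for
middle ranks). Leaf area is computed by cutting the blade into `N_sp`
segments perpendicular to the vein, each two symmetric trapeziums:
`S = 2·Σ (|A_iB_i| + |C_iD_i|)·|A_iC_i| / 2`. Daily tiller number
follows the recursion `APPSTN_i = APPSTN_{i−1} + Tv·ΔPPSTN_i·FL·min(NF,
WDF)`. LAI is total per-plant blade area (main stem plus tillers)
divided by the land area one plant occupies. Simulated LAI is compared
to measurements with the relative error `RE = 100·|O−S|/O %`, RMSE,
MAE, and `R² = 1 − SS_res/SS_tot`.

The package also assembles 3D meshes (Wavefront OBJ) for single plants
and for populations on a planting grid, with seeded per-plant parameter
variation in `[M−d, M+d]`, random rotations, vertex-clustering mesh
decimation and distance-based level of detail.

## Worked example

```python
import oryzasim as o

params = o.synth_cultivar(seed=1)            # synthetic cultivar parameter set
temps  = o.synth_weather(220, seed=1)        # a 220-day season
gdd    = o.accumulate_gdd(temps, params.base_temp)

rec = o.simulate_lai(params, gdd, n_segments=10, at_gdd=1600.0, seed=1)
print(f"LAI {rec.lai:.2f} from {rec.n_leaves} leaves on "
      f"{rec.n_tillers} tillers + main stem")

rep = o.table1_report()                       # packaged field reference table
print(f"RMSE {rep.metrics.rmse:.2f}  MAE {rep.metrics.mae:.2f}  "
      f"R2 {rep.metrics.r2:.2f}  flagged cells {len(rep.flagged_cells)}")
```

prints

```
LAI 2.21 from 82 leaves on 11 tillers + main stem
RMSE 0.56  MAE 0.55  R2 0.86  flagged cells 1
```

The LAI is the simulated leaf area index of the synthetic cultivar at
1600 °C·d. The second line recomputes the evaluation metrics of the
packaged reference comparison (two cultivars, three growth stages,
`N_sp` = 10): root-mean-square error 0.56 and mean absolute error 0.55
in LAI units, coefficient of determination 0.86, and one reference
relative-error cell flagged as inconsistent with its own printed
inputs.

A CLI wraps the same pipeline:

```
oryzasim simulate-plant --seed 1 --gdd 800 --gdd 1600 --out out/
oryzasim simulate-lai --seed 1 --out out/
oryzasim build-population --rows 5 --cols 5 --spacing 0.30 --out out/
oryzasim eval --pairs observed_simulated.csv --out out/
```

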