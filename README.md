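# s2map

Position-aware inequality analytics for single-cell secretion-signal maps.

Label-free imaging (e.g. plasmonic biosensing) can record, frame by frame,
the spatial pattern of protein secreted by one living cell. Two cells with
identical totals can secrete very differently: uniformly in all directions,
or anisotropically toward a neighbor. `s2map` turns each 2-D intensity
frame into two scalars that capture that spatial character, tracks them
over time, and compares/clusters cells by their temporal trajectories —
a spatial phenotyping of secretion ("secretio-types"). It is aimed at
groups doing single-cell secretion imaging who need quantitative,
rotation-robust summaries instead of visual inspection.

## The metrics

For a 1-D profile `x(1..n)` with Lorenz prefix shares
`L(k) = Σ_{i≤k} x_i / Σ x`:

* **Degree of inequality** — `DI = (2/n) Σ_k (L(k) − k/n)`, a *signed,
  unsorted* Lorenz deviation in [−1, 1]: positive when mass sits at low
  indices, negative at high indices, 0 for uniform profiles. Unlike a Gini
  coefficient it keeps position information.
* **Center-weighted SNR** — from the derivative
  `∂DI(k) = x(k)/Σx − 1/n`, pixels split into signal (`∂DI > 0`) and noise
  units; `CWSNR = (C_signal/C_noise) · Σ_i max(∂DI, 0)_i · W_i` with a
  semicircular weight `W` (1 at the axis center, 0 at the endpoints).

A 2-D map is projected onto its axes (column sums, row sums) and the
per-axis values combine as Euclidean norms:

* **SII** (signal inequality index) `= √(DIx² + DIy²)` — dissymmetry about
  the center; exactly invariant under 90° rotations/transposition and
  robust under arbitrary rotation and rescaling.
* **SCI** (signal coverage index) `= √(CWSNRx² + CWSNRy²)` — how much
  above-average signal sits near the center.

The package also ships the diffusion-model simulators used to validate the
metrics, five comparator concentration indices (Shannon, Theil, HHI,
Simpson, Atkinson), a full time-series pipeline (parsing, block
aggregation, window averaging, per-pixel baselining, noise cutoff, Pearson
comparison, hierarchical clustering), and multi-layer map rendering
(RBF-interpolated heatmap, contour layers, peak-seeded velocity
streamlines, 3-D panels).

## Worked example

A point source at the center of a 51×51 grid translated 9 cells to the
right (the translation model at its third time point):

```python
from s2map import SimulationSpec2D, simulate_2d, map_metrics, rotation_sweep

m = simulate_2d(SimulationSpec2D(model="translation"), 3)
mm = map_metrics(m)
print(f"SII = {mm.sii:.4f}")
print(f"DIx = {mm.axis_x.di:.4f}, DIy = {mm.axis_y.di:.4f}")

df = rotation_sweep(SimulationSpec2D(model="translation"), 3)
print(df.loc[["mean", "variance"], ["DIx", "SII"]])
```

```
SII = 0.3529
DIx = -0.3529, DIy = 0.0000
                       DIx           SII
rotation_deg
mean          1.850372e-17  3.529412e-01
variance      6.794589e-02  3.921894e-33
```

Read: the off-center point scores `SII = 0.35` — all of it carried by the
x-axis (`DIx = −0.35`, negative because mass sits right of center,
`DIy = 0`). Sweeping the pattern through twelve 30° rotations, per-axis DI
averages to zero with large variance (it cannot see a shift once the
pattern rotates), while SII stays at 0.35 with variance ~1e−33: the 2-D
composite is rotation-robust where the 1-D metric fails.

The same numbers from the shell:

```
$ s2map simulate --model translation --t 2 --out d2.txt
$ s2map metrics d2.txt
sample_id,time_min,SII,SCI
d2,0.0,0.19607843137254902,0.027450980392156862
```

Other commands: `s2map analyze --input series.txt --mode delta
--cutoff-fraction 0.1 --block 5 --window 1 --out cell.csv` (full pipeline
on a stacked time series), `s2map compare a.csv b.csv --metric sii`,
`s2map cluster *.csv --metric sci`, `s2map render --input series.txt --out
map` and `s2map benchmark --dims 400,800 --reps 3 --seed 0`. See
`s2map --help`.

## Layout

```
src/s2map/inequality.py   DI, ∂DI, SNR, center weights, CWSNR, comparators
src/s2map/mapmetrics.py   projections, SII, SCI, metric time series
src/s2map/simulate.py     1-D/2-D models, rotation machinery, benchmark
src/s2map/pipeline.py     parsing, aggregation, baselining, compare, cluster
src/s2map/visualize.py    RBF surfaces, multi-layer map rendering
src/s2map/cli.py          the `s2map` command group
docs/methods.md           model details, conventions, limitations
```
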