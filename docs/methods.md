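# Methods

## The problem

A single immune cell secreting a cytokine produces a spatial intensity
pattern on a sensor surface that evolves over minutes. Two cells with the
same total secretion can differ sharply in *where* the signal goes —
isotropically in all directions, or anisotropically toward one side. The
package quantifies that spatial character with two scalar indices per time
point and uses their temporal trajectories to compare and group cells
("secretio-types").

## The metrics

### Degree of inequality (DI)

For a non-negative 1-D profile `x(1..n)` with prefix shares
`L(k) = Σ_{i≤k} x(i) / Σ x`, the degree of inequality is

    DI = (2/n) · Σ_{k=1..n} ( L(k) − k/n ).

This is a Lorenz-curve deviation computed **in pixel order, without
sorting**: a classic Gini coefficient would erase positions, whereas DI is
signed — positive when mass sits at low indices, negative at high indices —
and zero for any uniform profile. A single unit at 1-based position `p`
gives `DI = (n + 1 − 2p)/n`, so the attainable range is
`[−(n−1)/n, (n−1)/n] ⊂ [−1, 1]`. DI is invariant under positive rescaling
of the values and under pixel replication (resolution changes), and is
negated by reversing the profile.

Degenerate convention: an all-zero profile has `DI = 0` (with `∂DI = 0`,
`SNR = 0`, `CWSNR = 0`). Zero is the unique limit consistent with scale
invariance.

### DI derivative, SNR, and CWSNR

The discrete derivative of the DI prefix terms is
`∂DI(k) = x(k)/Σx − 1/n`; it sums to zero whenever the profile has mass.
Pixels with `∂DI > 0` carry above-average signal ("signal units"); the rest
are "noise units". With counts `C_signal` and `C_noise`,
`SNR = C_signal / C_noise` (if no noise unit exists the ratio is capped at
`C_signal` and a warning is emitted; the cap preserves ordering without
infinities).

The center-weighted SNR multiplies the SNR by the semicircle-weighted sum
of the positive derivative units:

    CWSNR = SNR · Σ_i V(i) · W(i),   V = max(∂DI, 0),
    W(i) = sqrt(1 − (o_i/h)²),  o_i = i − (n+1)/2,  h = (n−1)/2.

`W` is 1 at the exact center and 0 at both endpoints. For even `n` the two
central pixels share the continuous-semicircle value
`sqrt(1 − (1/(n−1))²)`; we keep the continuous profile (which pins the
endpoints to exactly zero) rather than a separate even-`n` formula, the two
differing only at O(1/n²).

### 2-D composites: SII and SCI

A map is projected onto its axes (x = column sums, y = row sums; both
conserve total mass), and

    SII = sqrt(DIx² + DIy²),   SCI = sqrt(CWSNRx² + CWSNRy²).

SII measures dissymmetry about the map center: 0 for centrally symmetric
maps, `sqrt(2)·(n−1)/n` when all mass sits in a corner of an n×n grid. We
do **not** clamp SII to [0, 1]: both axis DIs can approach ±1
simultaneously, so the theoretical maximum is sqrt(2). SCI measures how
concentrated above-average signal is near the center. Both indices are
exactly invariant under 90° grid rotations and transposition (these permute
or swap the projections) and are robust under arbitrary-angle rotations and
resolution changes (pixel-replication upsampling by 2 moves SII by at most
2/n).

### Comparator indices

Shannon entropy (`−Σ p log2 p`), Theil (`(1/n) Σ ((x+ε)/μ) ln((x+ε)/μ)`,
`ε = 0.01` guards the log at zero pixels; `μ` is the mean of the *shifted*
values so perfect equality scores exactly 0), HHI (`Σ p²`), Simpson
(`1 − Σ p²`) and Atkinson (aversion 0.5) are provided for benchmarking.
All five are permutation-invariant, hence blind to signal position — the
property the DI/CWSNR pair exists to supply.

## Simulators

### 1-D scenario catalog (5-pixel axis)

Four models with three stages each; the initial center-unit stage is shared
by the shifting, spreading and propagating models, leaving **ten distinct
scenarios**:

* shifting: `[0,0,1,0,0] → [0,0,0,1,0] → [0,0,0,0,1]`
* shaping: `[0,0,3,2,1]`, `[0,0,2,2,2]`, `[0,0,1,2,3]`
* spreading: `[0,0,1,0,0] → [0,1,1,1,0] → [1,1,1,1,1]`
* propagating: `[0,0,1,0,0] → [0,1,0,1,0] → [1,0,0,0,1]`

The shaping stages are not uniquely determined by the qualitative
description "varying value distributions in the right 3 pixels"; the
decreasing/uniform/increasing triple chosen here is the only natural
assignment that reproduces the documented CWSNR ordering
(uniform > decreasing > increasing). The (DI, CWSNR) pair separates 9 of
the 10 scenarios; the collision is uniform spreading vs endpoint
propagation, which both score exactly (0, 0) — uniformity yields no signal
units, and endpoint mass receives zero center weight.

### 2-D diffusion models (51×51 grid)

An odd grid (default 51, center (25, 25)) is used so the exact center pixel
the formulas assume exists. At t=1 every model is a point source of
amplitude 5000 at the center. For t ≥ 2, with step 4:

* **circular propagation**: uniform amplitude `5000/outer` on the annulus
  of cells at Euclidean distance in `[4(t−1), 5(t−1)]`;
* **circular with direction**: the same annulus with its center shifted
  right by `4(t−1)`;
* **circular sector**: the annulus masked to `dx ≥ dy` and
  `dx ≥ −(dy+1)` (a sector pointing right);
* **translation**: the point source moved right to displacement
  `d(t) = 5 + 4(t−2)` (i.e. 5, 9, 13), the first move landing on the outer
  edge of the inner-4/outer-5 band — the same outer distance at which the
  decayed amplitude `5000/(5(t−1))` is defined — and each later move
  advancing by the step. Off-grid signal is dropped.

The translation displacements were the one genuinely open reconstruction
choice: the verbal description ("moved 4 grid units … spanning grids 4 to
5") admits several integer footprints. The outer-edge reading is the one
consistent with the model's own amplitude rule and reproduces the reference
rotation table (SII = 0.196, 0.353, 0.510 at t = 2, 3, 4, printing as
0.19/0.35/0.51 to 2 dp) and its DIx-vs-angle profile (≈ −SII·cos θ).

### Rotation

Multiples of 90° are exact index permutations (`np.rot90`). Arbitrary
angles forward-map each nonzero cell's offset from the designated center
and splat its mass onto the target grid — bilinearly by default, or to the
nearest cell (`method="nearest"`). Forward splatting was chosen over
inverse-mapping resampling because the reference patterns are sparse: an
inverse nearest-neighbor lookup can miss a single-pixel source entirely at
some angles (total mass → 0), while forward splatting conserves mass
exactly whenever the pattern stays on-grid. Bilinear weights additionally
make the projection mass-center exactly rotation-equivariant, so the SII of
a rotated point source is constant across angles to machine precision;
nearest-neighbor reproduces the small rotation jitter of discrete mass
units. The rotation sweep (12 angles, 30° apart) reports per-angle DIx,
CWSNRx, SII, SCI plus their mean and sample variance.

A known residual discrepancy: the reference table's CWSNRx/SCI magnitudes
(≈ 0.04–0.09) are roughly twice what the Eq.-chain construction yields on
any footprint we could reconstruct (≈ 0.02–0.03 for the single translated
pixel). The SII and DIx rows, which carry the rotation-robustness claim,
are reproduced; the coverage rows should be compared qualitatively only.

## Secretion pipeline

Fixed stage order: read → crop/aggregate → window-average → baseline →
cutoff → delta metrics.

* **Input**: plain-text matrices, whitespace- or comma-delimited; a single
  n×n frame or x stacked frames as an (x·n)×n matrix. Parse errors name
  the offending line.
* **Crop & aggregate**: centered square crop (default 250) then
  non-overlapping block-**sum** pooling (default 5×5 → 50×50). Sums rather
  than means: they conserve photon-count-like mass, and every downstream
  metric is scale-invariant anyway.
* **Window average**: each requested time point t is the mean of frames in
  the half-open window (t − 1 min, t].
* **Baseline**: per pixel, `baseline = min(frame_0, frame_t)`;
  `output = frame_t − baseline`. The per-pixel (not per-frame-mean)
  reading guarantees non-negative outputs, which the Lorenz machinery
  requires.
* **Cutoff**: entries ≤ the threshold are zeroed. A fractional cutoff
  resolves to fraction × the peak clipped delta over the whole series (one
  threshold per cell; 10% of a 4440 peak gives 444).
* **Delta metrics**: frame_t − frame_{t−1} (first frame vs zero), clipped
  at zero, then SII/SCI per time point.

Two cells are compared by the Pearson correlation of their temporal SII
(or SCI) vectors, with the two-sided p-value from the t distribution with
n − 2 degrees of freedom (at least 3 aligned time points, non-constant
series). Several cells are grouped by agglomerative hierarchical
clustering on the Euclidean distances between metric vectors;
average linkage is the default (the distance, not the linkage, is the
specified part — linkage is a keyword argument). The merge tree exports
to newick.

## Visualization

The per-time-point secretion-signal map stacks: an RBF-interpolated
heatmap of the delta signal (Gaussian kernel by default; multiquadric,
inverse multiquadric, linear, cubic, quintic and thin-plate available;
interpolation via `scipy.interpolate.RBFInterpolator` with zero smoothing,
64 nearest neighbors, degree-1 polynomial tail, shape parameter 1 grid
unit); contour layers for delta and/or cumulative signal with a cumulative
cutoff; and a velocity layer of streamlines seeded at the top-n surface
peaks (3×3 non-maximum suppression) following the negative gradient
(central differences) from peaks toward valleys. Two small 3-D panels show
the cumulative surface (grey baseline + red delta) and the delta surface.
Rendering never mutates its inputs; PNG and SVG are written.

## Synthetic data and what the tests show

All fixtures are generated programmatically: the scenario catalog, the 2-D
diffusion models, and seeded uniform-random grids. The simulators emulate
idealized point/annulus/sector sources with exact decay rules; real
sensor data additionally carries shot noise, drift, uneven illumination
and cell-shaped signal footprints, none of which are modeled. Passing
tests therefore establish the metrics' mathematical properties (symmetry,
invariance, separability) and the pipeline's bookkeeping, not detection
performance on noisy recordings. The real-world correlation magnitudes
reported for cytokine-secreting cells depend on data not packaged here and
are deliberately not asserted anywhere; the correlation *computation* is
validated against the closed-form t-transform instead.

## Numerical choices and problem sizes

* All-zero profiles: DI = ∂DI = SNR = CWSNR = 0 (warning emitted where a
  proportion-based comparator is asked for).
* SNR cap at `C_signal` when no noise units exist (warning).
* Metric-pair distinguishability uses values rounded to 10 decimals; the
  only collision in the catalog is exact (0, 0) vs (0, 0).
* Scalability is asserted as a trend only — best-of-5 timings across grids
  400→3200 must grow sub-quadratically in the dimension; absolute times
  are hardware-dependent and never asserted. These sizes keep the default
  suite fast while spanning an 8× dimension range (64× pixel count).
* Rotation sweeps use the default bilinear splatting; variance across the
  12 angles is compared against the 1e−4 bound.

## Known limitations

* The translation footprint and the shaping stages are reconstructions
  from verbal descriptions; third-significant-figure agreement with the
  reference table is not expected everywhere.
* The CWSNR/SCI magnitude discrepancy described above.
* The sector mask is evaluated in array coordinates (x = columns,
  y = rows); a flipped y-axis convention mirrors the sector but leaves all
  metrics unchanged by their transpose/rotation invariance.
* RBF interpolation with 64 neighbors is approximate far from the nodes on
  very large grids; at the pipeline's 50×50 working resolution it
  interpolates the samples to ~1e−6.
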