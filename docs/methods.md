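# Methods

## Problem and model

Voxel-level functional-connectivity analysis treats every gray-matter
voxel of an fMRI acquisition as a graph node and connects pairs of voxels
whose time courses are strongly correlated. At native resolution this
means on the order of 10^4–10^5 nodes and 10^9–10^10 pairwise
correlations, so the estimator's cost per pair dominates the whole
pipeline. `fastfc` implements two estimators over the identical graph
pipeline:

* **Pearson's r** on the continuous series,
  r = Σ(s_v,k − s̄_v)(s_w,k − s̄_w) / sqrt(Σ(s_v,k − s̄_v)² · Σ(s_w,k − s̄_w)²),
  with per-voxel means and centered norms precomputed once and the
  pairwise cross-products evaluated in configurable blocks.

* **Tetrachoric r_t** on median-dichotomized series. Each series is
  binarized at its own sample median (value ≥ median → 1). Under
  bivariate normality a median split fixes both marginals of the 2×2
  contingency table at 1/2, and the tetrachoric correlation — the latent
  correlation whose quadrant probabilities reproduce the table — then has
  the closed form

      r_t = −cos(2π · n11 / T),

  where n11 is the number of time points at which both binary series are
  1. No numerical integration is needed; n11 alone determines the
  estimate.

The binary series are bit-packed (little-endian bit order: time index k
sits at bit k mod w of word ⌊k/w⌋, w ∈ {8, 32, 64}; padding bits zero),
so n11 for a pair is a bitwise AND followed by a popcount over
⌈T/w⌉ words, and r_t is read from a table of −cos(2πn/T) indexed by n11.
The cosine is evaluated T+1 times per dataset, never per pair. Because
n11 is an integer in a bounded range, r_t can only attain the discrete
values {−cos(2πn/T)}; under tie-free median splits the attainable n11 are
0…T/2 (T even) or 1…(T+1)/2 (T odd). The lookup table nevertheless covers
0…T so that tied data (which can push per-series ones-counts above T/2)
never index out of range; counts above ⌈T/2⌉ trigger a warning.

Both builders store only the upper triangle (i < j) in row-major linear
order — position i(2V−i−1)/2 + (j−i−1) — halving memory and making the
two estimators byte-compatible on disk (flat float64 array + JSON
sidecar).

## Graphs and degree maps

Correlation matrices are thresholded at a target **density**
κ = 2|E|/(V(V−1)) rather than at a fixed correlation, so graphs are
comparable across subjects: the round(κ·V(V−1)/2) largest correlations
become edges. Ties are broken by (i, j) lexicographic order, which makes
graphs reproducible and edge sets nested across densities; the realized
correlation threshold θ is reported as the smallest correlation included.
(The alternative convention — θ as the largest value with enough strictly
greater entries — cannot coexist with an exact density under ties; the
top-|E| rule was chosen as the deterministic resolution.) Pairs involving
a degenerate (constant) series are missing and can never become edges.

Node degree k_i (incident-edge count) is the hub metric; degrees are
z-scored per subject with the population (n-denominator) standard
deviation, the conventional reading of "standardized", giving mean 0 and
unit variance per subject. Group maps average the standardized degrees
voxel-wise over the subjects whose mask covers each voxel; voxels
supported by fewer than 20% of subjects (the `support_fraction` default)
are discarded. Subject grids must already be aligned — spatial
normalization is delegated to external neuroimaging suites and is out of
scope here.

## Simulation study

The validity of r_t as a surrogate for r is quantified on synthetic
bivariate-normal data: for each ρ on the grid {−0.99, −0.98, …, 0.99}
(199 values), 10000 samples of size T are drawn (T = 100 and 300,
bracketing typical resting-state scan counts); r is computed on each
continuous pair and r_t after median dichotomization of each margin. Per
bin we report mean, SD and the mean signed difference
MSD(ρ̂, ρ) = mean(ρ̂) − ρ (an empirical bias), plus 199×199 joint
histograms with bin centers at the grid values (edges at midpoints,
outermost bins extending to ±1, half-open [low, high) with the last bin
closed) and a Deming regression of r on r_t.

Expected behaviour, all reproduced by the acceptance suite:
sampling SDs at ρ=0 are ≈ 1/√(T−1) for r (0.101 / 0.058 at T=100/300)
and ≈ π/(2√T) for r_t (0.158 / 0.091) — the dichotomized estimator pays
roughly a π/2 efficiency factor; SDs shrink toward the range limits;
MSD(r, ρ) tracks the classical small-sample approximation
E(r) − ρ ≈ −ρ(1−ρ²)/(2T), and MSD(r_t, ρ) shows the same sign pattern
with larger amplitude; grid-wide correlations between estimates and truth
reach ≈0.99 and the two estimators correlate ≈0.99 with each other.

**Deming regression** is used for the (r_t, r) relation because both
variables carry sampling error; ordinary least squares would attenuate
the slope. The error-variance ratio δ defaults to 1 (orthogonal
regression) since both estimators target the same ρ on the same scale;
δ is exposed as a parameter. The closed-form slope is
(s_yy − δs_xx + sqrt((s_yy − δs_xx)² + 4δs_xy²)) / (2s_xy).

**RNG**: `numpy.random.default_rng` (PCG64) with the seed recorded in the
result object and all output metadata; every public sampling entry point
takes an explicit seed.

## Synthetic data generator

`fixtures` plants correlated clusters in otherwise independent noise:
every voxel of a cluster with target correlation ρ is
√ρ·shared + √(1−ρ)·idiosyncratic with standard-normal components, so
within-cluster pairwise correlation is exactly ρ in expectation and unit
variance is preserved. The NIfTI writer places the V nodes at the first V
grid positions in C order with GM probability 0.9 (background 0.05),
matching the loader's deterministic C-order node mapping, and writes a
JSON ground-truth sidecar.

Defaults: V=200 voxels, T=275 scans at TR=1.5 s (a common high-sampling
resting-state protocol; the slower TR=3 s, T=119 regime is reached by
changing the spec), one 20-voxel cluster at within-correlation 0.7 — a
strong, spatially compact hub such as degree mapping is meant to find.
V=200 is sized so that the κ=0.01 edge budget, round(0.01·19900) = 199
edges, can contain the 190 within-cluster pairs: a recovery experiment in
which the graph cannot even hold the planted subgraph would measure the
edge-selection lottery, not estimator concordance. Under these conditions
both estimators' κ=0.01 graphs concentrate essentially all edges inside
the cluster, the cluster members are the top-degree nodes for both, and
the two degree profiles correlate above 0.99.

What the generator does **not** emulate: hemodynamic autocorrelation,
1/f noise spectra, motion artifacts, spatial smoothness of real BOLD
data, and anatomical variability between subjects. Passing tests on these
fixtures therefore demonstrates the correctness of the estimators,
thresholding and degree pipeline, and the in-principle concordance of the
two estimators — not preprocessing robustness on real acquisitions. An
optional band-pass flag passes generated series through the 0.01–0.1 Hz
filter to emulate preprocessed spectra; it is off by default so unit
tests stay analytic.

## Preprocessing

The loader keeps voxels whose gray-matter probability is ≥ θ_GM = 0.2 and
extracts their time series in deterministic C-order. Band-pass filtering
(0.01–0.1 Hz, the customary resting-state band) uses a 4th-order
Butterworth applied forward and backward (`sosfiltfilt`), i.e. zero-phase
with effective 8th-order magnitude response; filter type and order are a
package choice since only the band itself is scientifically meaningful
here, and the filter sits upstream of the estimators. Cutoffs above the
Nyquist frequency 1/(2·TR) are rejected.

## Numerical choices and edge cases

* Pearson values are clipped to [−1, 1] to absorb last-ulp excursions;
  triangle identity across block sizes is tested at 1e-6 absolute
  (summation-order differences), bit-exactness is *not* claimed for r.
  The tetrachoric builder is bit-exact against the unpacked oracle
  because n11 is integer arithmetic.
* Constant (zero-variance) series: dichotomization yields all ones (every
  value "is at least" the median) with a degeneracy flag and warning;
  both matrix builders report every pair involving a flagged node as
  missing (NaN) rather than fabricating a value — r is equally undefined
  there, so the estimators behave symmetrically.
* Ties at the median map to 1 ("at least" rule taken literally);
  ones-counts may then exceed T/2 and n11 may exceed the tie-free
  attainable maximum, which is computed anyway with a warning.
* p11 is computed as n11/T for odd T as well (no marginal adjustment).
* `density_threshold` errors when missing pairs make the requested edge
  count infeasible.

## Problem sizes

The package's own validation runs at desk scale: correlation-builder
oracle checks use V ≤ 100, T ∈ {99, 100, 119, 275}; the recovery
experiment uses the generator defaults above; acceptance-suite simulation
checks use 10000 replicates for the single ρ=0 bin and 2000 replicates
per bin for full-grid runs, with Monte-Carlo tolerances scaled by
√(10000/2000). `scripts/acceptance.py` runs the full study (199 bins ×
10000 replicates, both T) in about a minute.

## Known limitations

* The closed form for r_t holds only for median splits; other
  dichotomization thresholds would require numerical tetrachoric
  estimation and are out of scope.
* Weighted graphs and graph metrics beyond degree are out of scope.
* No SIMD/popcount intrinsics or multithreading: the numpy word-wise
  pipeline already processes 64 time points per operation, and the
  package's contracts are about results, not throughput.
* Group averaging assumes pre-aligned grids; no spatial normalization,
  motion correction or segmentation is performed.
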