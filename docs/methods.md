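# Methods

This note records the models, conventions and numerical choices behind
`chanprox`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Localization maps and rasterization

A localization table is an event list (x, y in nm; frame; photon count;
channel label).  Events with fewer than 50 photons are treated as noise
and discarded; the boundary value 50 is retained (the filter drops
strictly-lower counts).  Events are binned onto a square grid of 20-nm
pixels — chosen to match the annulus ring width and the ~16 nm lateral
localization accuracy of the modality being emulated — with half-open
pixel intervals `[k·p, (k+1)·p)` and row-major (y, x) indexing.  Both
the threshold and the pixel size are parameters.

Bleed-through between spectral channels is quantified the standard way:
the event count detected in the wrong channel divided by the count in
the correct channel, measured on single-fluorophore preparations.

## Segmentation

Binary maps are smoothed with a *count-thresholded closing* on the
8-neighborhood (the "close with N counts" operation of ImageJ-style
binary options): one iteration is a dilation in which a background pixel
turns foreground iff ≥ N of its 8 neighbors are foreground, followed by
an erosion in which a foreground pixel turns background iff ≥ N of its
8 neighbors are background.  The default is 1 iteration with N = 5.
Because the original macro semantics are not published, this exact
definition is the package's documented, testable choice; with N = 1 it
reduces to textbook 3×3 closing (verified against `scipy.ndimage`).
Border convention: outside-image neighbors count as background for the
dilation and as foreground for the erosion, so an all-foreground field
is a fixed point and nothing grows in from outside.  A practical
consequence of N = 5 is that isolated one- and two-pixel specks (e.g.
sparse bleed-through events) are erased.

Touching clusters are separated by a watershed on the negated Euclidean
distance transform.  Seeds are EDT local maxima with a minimum
separation of 2 pixels; plateau maxima merge into one seed; final labels
are renumbered by their lowest linear pixel index, which makes label
maps deterministic.  Bit-for-bit agreement with any particular ImageJ
watershed is not claimed — only the invariants (labels partition the
foreground; disjoint components are never merged; overlapping discs are
split near their geometric halves).

Cluster areas are exact pixel counts times the pixel area (nm²); the
*median* area is the headline size statistic because cluster-area
distributions are strongly right-skewed, and a Kruskal–Wallis rank test
is exposed for group comparisons.

## Proximity statistics

All distances are Euclidean between pixel centers on the rendering grid
(no subpixel boundary interpolation, consistent with 20-nm rendering).
The distance of a target cluster to the reference is the minimum over
its pixels of the distance-to-reference map — an edge-to-edge distance
by construction, 0 for overlap.  A per-pixel variant is available
behind a flag.

The annulus occupancy profile uses concentric rings of 20 nm width
around the reference mask out to 300 nm by default; ring 0 is the
reference mask itself (overlap), ring k collects footprint pixels with
edge distance in ((k−1)·20, k·20] nm.  Percentages are per-ring target
occupancy; rings with no pixels report missing (NaN), never 0.  The
profile is computed over the whole footprint (whole cell), not selected
ROIs.

Radius conventions are fixed and deliberate: a reference cluster is
*isolated* when no target pixel lies at ≤ 200 nm (strictly farther);
a target cluster is *near* when its nearest edge distance is < 200 nm;
the within-radius cluster count uses ≤ 50 nm.  Distances are measured
from cluster boundaries, not centroids.  The Gaussian fit to the
distance histogram reports both FWHM and HWHM because "half width" is
ambiguous in common usage.

## Randomization null

The null hypothesis is spatial independence of the target clusters from
the reference.  Each observed target cluster is rigidly translated to a
uniformly random position whose pixels all lie inside the footprint;
per-cluster pixel sets are preserved exactly (checked to integer
equality in the tests).  Placement rules, all recorded in the ensemble
provenance:

* target clusters may overlap the *reference* mask (observed maps show
  non-zero overlap at distance 0, so a null forbidding it would be
  bias-inducing); a flag forbids it;
* target clusters may not overlap *each other* (they are distinct
  physical objects); 
* rotation is off by default ("same shape" read conservatively);
  90°-rotation is available.

Monte-Carlo p-values use the add-one estimator
`p = (1 + #{null at least as extreme}) / (n_reps + 1)`, with the
extremity direction per statistic chosen so that small p means
enrichment near the reference.  The default 100 repetitions balance
envelope stability against runtime; calibration tests use up to 200.

## Synthetic scenes

Clusters are filled ellipses with axis ratio drawn uniformly in [1, 2]
(area exact, placement tractable; real BK clusters are irregular, which
the shape-preserving null handles but the generator does not emulate).
Default conditions are a scaled-down whole-cell field: 6×6 µm, 12
reference ("red") and 30 target ("green") clusters, log-normal areas
with median 1600 nm² and σ_log = 0.8 — the median matches typical
reported cluster-area medians for such maps; the dispersion is a
modeling choice wide enough to span the 400–2800 nm² medians seen
across preparations, since no dispersion is reported.  A fraction
(default 0.8) of green clusters is *associated*: each picks a red
partner uniformly at random (several greens may share one red) and is
placed along a random direction so that the realized edge-to-edge gap
matches a draw from the gap distribution (default |N(20, 15)| nm) to
better than 0.1 nm, via a directional-radius construction with a
numeric boundary-distance refinement.  Remaining greens are uniform.
Same-channel overlap is excluded with a conservative bounding-circle
test; cross-channel overlap is allowed.

Events are uniform inside each ellipse, jittered by isotropic Gaussian
localization noise (default σ = 16 nm), given log-normal photon counts
(median 1900, σ_log = 1.0) and a uniform random frame index.
Sub-threshold events are flagged in the table, not dropped, so the
detection filter is independently testable.  Bleed-through copies a
binomial fraction of each channel's events into the other channel's
table (defaults 0.092 green→red, 0.008 red→green, the asymmetry typical
of the Alexa-568/647 pair).

Ground truth retains the ellipse parameters, rasterized true catalogs,
per-green association labels and realized gaps, and two derived scalars
(isolated-green fraction beyond 200 nm; mean greens within 50 nm per
red) recomputed from the catalogs with the package's own proximity
functions — so generator truth and pipeline estimates share one metric
convention.

What the generator does *not* emulate: irregular cluster shapes,
blinking/photophysics and frame-correlated re-localizations, drift,
detector-edge effects, 3D structure.  Passing recovery tests therefore
demonstrate correctness of the analysis chain under the stated
statistical model, not robustness to every artifact of real
acquisitions.

### Calibration conditions

Two test-design points deserve emphasis.  First, bleed-through is a
*real* source of apparent colocalization: copied events sit exactly on
the other channel's clusters.  With the default 9.2% green→red fraction,
association-free scenes genuinely violate the independence null (about
a quarter show ring enrichment at p ≤ 0.01) — a property of the physics,
not a miscalibration.  Null-calibration tests therefore use
contamination-free scenes.  Second, at sparse default densities the
near-ring occupancy is dominated by whole clusters entering or missing
the first rings, so its Monte-Carlo p-value is heavily discrete (a large
atom at p = 1 when no cluster is near).  Calibration sweeps use denser
scenes (40 reference / 150 target clusters in the 6-µm field) where the
statistic is effectively continuous; there the p-values are uniform
(KS) and the null profile is flat at the global target density.

## Electrophysiology

Currents convert to chord conductances as G = I/(V − E_rev); points at
the reversal potential are excluded with a warning.  Reversal
potentials come from the Nernst equation at a default 295.15 K (22 °C,
room-temperature recording); with 2 mM external and 100 nM internal
Ca²⁺ this gives +126 mV.  Activation curves are fitted with a single
Boltzmann G/Gmax = 1/(1 + exp(−(V − V_mid)/slope)) by least squares,
initialized at the half-max voltage with the slope from the 25–75%
span; Gmax is fitted, then curves can be normalized.  Positive slope is
required at the optimum (activation convention).  The activation
threshold is the closed form V_mid + slope·ln(level/(1 − level)) at
level = 0.05, cross-checked against numeric inversion of the fitted
curve to 10⁻⁹ mV.  No series-resistance correction is applied; fits
accept a voltage-range mask instead.

Activation kinetics use a rising mono-exponential
baseline + A·(1 − exp(−(t − t₀)/τ)) with t₀ fixed at the fit-window
start.  Single-channel records are idealized by half-amplitude
multi-level thresholding (level k for samples within ±½ unitary
amplitude of k·u above baseline) — a deliberately simple, replaceable
strategy — and NPo = Σₖ k·tₖ/T.  NPo is invariant to baseline offset
and joint amplitude rescaling; a warning/error fires when the unitary
amplitude is below twice the noise SD.  The trace generator draws
alternating exponential dwells (mean open dwell as given; mean closed
dwell scaled so the stationary open probability is p) and reads channel
state at sample centers, avoiding dwell-rounding bias.

## Nanodomain calculations

The linearized single-mobile-buffer approximation gives the length
constant λ = √(D_Ca/(k_on·[B])) and the steady-state point-source
profile [Ca](r) = i/(4π·z·F·D_Ca·r)·exp(−r/λ) + [Ca]_rest (z = 2).
Registry defaults: D_Ca = 220 µm²/s; k_on = 2.7×10⁶ M⁻¹s⁻¹ (EGTA) and
4×10⁸ M⁻¹s⁻¹ (BAPTA), after Naraghi & Neher (1997) and Neher (1998);
all overridable.  At 10 mM these give λ ≈ 90 nm (EGTA) vs ≈ 7.4 nm
(BAPTA) — the order-of-magnitude 100 nm / 10 nm separation that makes
the buffer pair a molecular ruler.  The exact round numbers depend on
the rate constants assumed, which the registry documents; no
reaction–diffusion PDE is solved.

## Problem sizes and reproducibility

Every stochastic component takes an explicit seed and is bit-reproducible
given it; pipeline reports contain the full configuration and no
timestamps, so a rerun reproduces the report byte for byte.  The test
suite runs its heavier checks at deliberately scaled problem sizes —
100 random instances per brute-force oracle, 200 scenes for p-value
calibration, 20 seeds × 199 repetitions for power/specificity, 10³
shuffles for conservation, 10⁵ events for the FWHM check — sizes at
which every tested interval is already decisive.
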