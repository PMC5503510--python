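# chanprox

Quantitative tools for asking whether two ion-channel populations cluster
next to each other on the plasma membrane — and for the electrophysiology
that makes the question matter.

Large-conductance calcium-activated potassium (BK) channels need both
depolarization and tens-of-micromolar local calcium to open at
physiological voltages.  They get that calcium from voltage-gated calcium
(CaV) channels, but only if the two channels sit within the calcium
nanodomain — closer than ~100 nm, sometimes closer than ~10 nm.
Two-color single-molecule localization microscopy (SMLM) can resolve this
arrangement: each channel type is rendered as a binary pixel map, the
maps are segmented into clusters, and the spatial statistics of the
target clusters (e.g. CaV1.3) around the reference clusters (e.g. BK)
are compared against a Monte-Carlo null in which the target clusters are
re-placed at random while keeping their number, sizes and shapes.

`chanprox` implements that whole workflow on synthetic data with known
ground truth, plus the supporting quantitative electrophysiology.

## What is in the box

| module | purpose |
| --- | --- |
| `chanprox.synthetic` | two-channel clustered scenes with a tunable proximity bias, line structures for resolution checks, Boltzmann G-V series and multi-level single-channel traces — all with retained ground truth |
| `chanprox.locmap` | localization-table I/O (ThunderSTORM-style CSV), the 50-photon detection floor, rasterization to 20-nm pixel maps, bleed-through quantification |
| `chanprox.segmentation` | count-thresholded binary closing (close with 5 counts), distance-transform watershed, cluster catalogs with areas in nm², transverse-profile FWHM fits |
| `chanprox.proximity` | edge-to-edge nearest distances, 20-nm annulus occupancy profiles, isolation/nearness fractions at 200 nm, mean cluster counts within 50 nm, pixel overlap, Gaussian fits to distance histograms |
| `chanprox.randomization` | shape-preserving cluster randomization, null envelopes and Monte-Carlo p-values |
| `chanprox.ephys` | Nernst potentials, G = I/(V − E_rev), single-Boltzmann G-V fits, 5%-activation thresholds, blocker subtraction, activation time constants, NPo from idealized single-channel records |
| `chanprox.nanodomain` | mobile-buffer length constants λ = √(D/(k_on·[B])) (EGTA vs BAPTA) and steady-state point-source [Ca](r) profiles |
| `chanprox.pipeline` / `chanprox.cli` | one-config end-to-end runs with bit-reproducible JSON reports; `chanprox` console command |

## The statistics at the core

The activation of a channel population is summarized by a Boltzmann
conductance-voltage curve

    G/Gmax = 1 / (1 + exp(−(V − V_mid)/slope))

and its "activation threshold" is the interpolated voltage at 5% of
maximal conductance, `V_mid + slope·ln(0.05/0.95)`.

Spatial coupling is summarized by the occupancy profile: concentric
rings of 20 nm width are drawn around the reference clusters (ring 0 is
the reference mask itself) and the percentage of each ring occupied by
target-positive pixels is compared with the same profile after
shape-preserving randomization of the target clusters.  Enrichment in
the first rings that exceeds the randomized envelope is the signature of
preferential proximity.

## Worked example

```python
from chanprox.pipeline import RunConfig, run_pipeline
from chanprox.synthetic import SceneSpec

report = run_pipeline(RunConfig(scene=SceneSpec(seed=3), n_reps=99, seed=5))
stats = report["statistics"]
print(stats["observed"]["near_ring_occupancy"], stats["p_values"]["near_ring_occupancy"])
print(report["flags"]["significant_enrichment"])
```

prints

```
26.509971509971507 0.01
True
```

The scene placed 80% of its "green" clusters with a small edge-to-edge
gap next to a random "red" cluster; the observed occupancy of the first
three rings (≤60 nm) is ~27%, far above the randomized null, and the
Monte-Carlo p-value is at its floor of 1/(99+1), so the report flags
significant enrichment.  With `SceneSpec(seed=4, association_fraction=0,
bleedthrough_green_into_red=0, bleedthrough_red_into_green=0)` the same
pipeline reports `significant_enrichment: False`.

On the electrophysiology side:

```python
from chanprox.ephys import activation_threshold, nernst_potential
print(round(activation_threshold((-37.0, 4.0), level=0.05), 1))   # -48.8 (mV)
print(round(nernst_potential(2, 2e-3, 100e-9), 0))                # 126.0 (mV)
```

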