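# Methods

This note records the models, estimators and numerical choices behind
`astrocal`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Synthetic movies

The generator renders a movie as

    signal(t, r, c) = background + Σ_i b_i · disk_i(r, c) · (1 + Σ_j a_j g_j(t))

with hard-edged disk cells of baseline intensity `b_i` (micropatterned
circular attachment sites), multiplicative ΔF/F contributions `a_j g_j(t)`
and a Gaussian temporal kernel `g_j` of width `sigma_t` centred on the peak
time. Hard disks (rather than Gaussian blobs) make footprint ground truth
unambiguous for precision/recall scoring, and the Gaussian kernel gives the
downstream FWHM fit a closed-form truth, `FWHM = 2√(2 ln 2)·sigma_t`.
Waves rasterize their polyline path at quarter-pixel arc steps; each path
pixel receives the kernel delayed by `arc_length·pixel_size/speed`, with
the earliest arrival winning where samples coincide.

Noise is Poisson shot noise (`counts ~ Poisson(signal·gain)/gain`, so the
temporal variance equals `mean/gain`) followed by additive Gaussian read
noise; both streams are spawned from one integer via
`numpy.random.SeedSequence(seed).spawn(2)`, making every movie a pure
function of (specs, seed). Negative post-noise intensities are clipped at
zero with a warning; the default background of 30 units keeps clipping
negligible at the preset noise levels.

Defaults: 256×256 frames, 1.0 μm pixels, 0.5 s frame interval, 240 frames
(2 min) per condition movie — desk-scale sizes that keep a full
three-condition pipeline run under a minute while leaving tens of frames
on either side of every transient.

### Condition presets

The three culture conditions differ qualitatively: astrocyte monocultures
(`A_alone`) show rare activity that sweeps most of a cell; astrocytes
co-cultured with neurons in one chamber (`NA_same`) show frequent,
spatially restricted microdomain events; astrocytes with neurons in the
adjacent chamber (`N_A_adjacent`) behave like `NA_same` but with lower
ΔF/F amplitude. No quantitative per-condition rates or amplitudes are
published, so the preset numbers are free parameters chosen once to
realize these orderings with comfortable margins at realistic scales:

| preset | rate (cell⁻¹ min⁻¹) | footprint radius (px) | amplitude (ΔF/F) | sigma_t (s) |
|---|---|---|---|---|
| `A_alone` | 0.5 | 14–18 | 1.2–1.8 | 1.5–2.5 |
| `NA_same` | 3.0 | 3–5 | 1.6–2.4 | 0.8–1.6 |
| `N_A_adjacent` | 3.0 | 3–5 | 0.6–1.0 | 0.8–1.6 |

Eight astrocytes (radius 22 px, baseline 120) populate the green channel;
six neuron somata (radius 9 px) populate the red channel in the co-culture
conditions. Event counts per cell are deterministic (`rate × duration`,
at least 1) so the preset orderings hold for every seed; times, positions,
footprints and amplitudes are drawn from the seeded generator. The
monoculture's wave-like activity is represented by large-footprint events
(the OR-projection a propagating wave would leave); travelling waves with
explicit speed are available separately via `WaveSpec` for kymograph work.
Gaussian read noise SD is 5 units, so preset event amplitudes are tens of
noise SDs at the pixel level — detection failures in tests indicate
pipeline defects, not borderline SNR.

The generator deliberately omits optical blur (PSF), photobleaching,
motion, neuropil contamination, cell-shape irregularity and
signal-dependent baseline drift. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to every artifact of real recordings.

## Baseline and event detection

Per-pixel baseline statistics come from the raw traces: the mean over each
pixel's lower-quartile frames (values at or below its 25th percentile) and
SD = 1.4826 × the median absolute deviation of the full trace. Both are
robust to sparse transients, so no event-free epoch needs to be marked.
The lower-quartile mean is biased low by ≈1.27 SD on a pure-noise trace;
this is intentional slack in the same direction for every pixel and is the
reference level the ΔF/F definition itself uses.

Detection flags voxel (t, r, c) when the spatially Gaussian-filtered
(σ = 2 px default; the low-pass cutoff is unspecified in the field and
exposed as a parameter) baseline-subtracted movie exceeds `k·SD(r, c)`
(k = 2 default). Filtering is applied to the *baseline-subtracted* image;
by linearity this equals comparing the filtered movie against the filtered
baseline mean, and it avoids a subtle artifact of the naive order of
operations: subtracting an unfiltered mean from a filtered movie leaves a
permanently suprathreshold ring where the filter bleeds each hard cell
edge outward. Temporal filtering is deliberately omitted to keep event
timing unbiased.

Flagged voxels are grouped under 26-connectivity in (x, y, t) (6 available)
and components below `min_voxels` are dropped. The default `min_voxels` is
20: measured on the preset movies, spatially correlated filtered-noise
excursions form single-frame components of up to ~11 voxels, while the
smallest genuine events exceed several hundred (a footprint of tens of
pixels lasting several frames), so 20 separates the two populations by
more than an order of magnitude on each side. Components are never split
in time: one connected component is one ROI, so two true events that
overlap in space and time merge, and detection scoring uses coverage
matching (a truth event is recovered if some component covers ≥ 50% of its
footprint with temporal overlap) rather than one-to-one assignment.

Two consequences worth knowing: detected ROI areas exceed true footprint
areas by the low-pass halo (a bright event's filtered skirt also crosses
threshold), and averaging ΔF/F over that enlarged ROI dilutes measured
amplitudes relative to the generator's per-pixel truth. Orderings and
distributions across conditions are preserved; absolute areas and
amplitudes are threshold- and filter-dependent, as in any
threshold-based ROI definition.

## Traces, FWHM and condition summaries

`F0` is the mean of the frames with `F` at or below the linearly
interpolated 25th percentile, ties included — the literal reading of the
lower-quartile baseline, stable on short traces. The background region
defaults to the lowest-decile mean-intensity pixels outside all ROIs (the
cell-free PEG surface on patterned substrates) and can be overridden; a
non-positive `F0` is rejected with a diagnostic rather than producing
unbounded ΔF/F.

Event fits minimize least squares for `a·exp(−(t−μ)²/2σ²) + b` over the
detected event interval padded by 3 frames. The offset `b` is included
because real baselines drift even though the ideal transient has none;
initialization is `a = max−min`, `μ = argmax`, `σ = window/6`. Fits with
`a ≤ 0` or without convergence are excluded. Each event is fit
independently in its own window; no multi-Gaussian joint fit is attempted.
Both the per-ROI maximum ΔF/F over the whole series and the per-event
window maximum are emitted, since "maximum ΔF/F per ROI" is ambiguous
between the two.

ECDFs are right-continuous step functions; the two-sample KS distance
`sup|F₁−F₂|` is descriptive only — no hypothesis testing is performed,
matching the practice of reporting distributions rather than p-values.

## Wave speed

The kymograph resamples the path at 1-px arc steps and averages a
`width`-pixel segment perpendicular to the local tangent (bilinear
interpolation). Per position, ΔF/F uses the lower-quartile baseline of
that position's own trace, making the estimator invariant to intensity
scaling. Arrival (default rule) is the first half-maximum crossing of the
rising phase — found by walking back from the peak to the last sub-level
frame — so an isolated early noise spike cannot fake an arrival; `peak`
and `onset-2sd` rules are available. Speed is `1/|slope|` of the
least-squares regression of arrival time on arc-length position, using all
positions whose peak exceeds 4 robust SDs of their trace; regression over
many positions rather than two-point differencing buys noise robustness,
and fits with `r² < 0.8` should be treated as unreliable. A slope smaller
than half a frame interval across the whole path is reported as undefined
("simultaneous activation") rather than as a huge speed.

On generator waves with amplitude 10× the noise SD, the median recovery
error across 2–20 μm s⁻¹ is below 1% (20 seeds per speed); at high SNR the
error saturates at the frame-quantization floor (~0.5%).

## Transport model

The device is modelled as two chambers (default 750 μm long × 300 μm wide
× 100 μm deep) joined through a 100-μm wall pierced by 13 grooves
(10 μm wide, 5 μm deep, 50 μm pitch, centred on the wall). The chamber
depth is not a molded-groove dimension and is rarely reported; 100 μm is a
typical thick-resist device layer and is exposed in the geometry config.
The vertical dimension is depth-averaged: the solver treats

    ∇·(h D ∇c) − h u·∇c = 0

on a 2D grid whose local depth `h` is the chamber depth in chambers, the
groove depth in grooves and zero in the wall. Flow is plug flow
`u = Q/(width·depth)` along each chamber; grooves carry no pressure-driven
flow (equal chamber heads during imaging), so they transport solute by
diffusion only. Boundary conditions: Dirichlet concentrations at the two
chamber inlets, advective outflow at the outlets, no-flux walls.

Discretization is cell-centred finite volumes with harmonic-mean face
depths and first-order upwind advection — unconditionally stable at the
chamber Péclet number of the default conditions (Pe = uL/D = 250 at
u ≈ 16.7 μm s⁻¹, D = 50 μm² s⁻¹) at the cost of numerical diffusion along
the flow. The default 2.5 μm grid puts 4 cells across each groove; the
direct sparse solve reaches machine-precision residuals (~10⁻¹⁵ relative).
Verification: the solver matches the 1D advection–diffusion closed form
`c(x) = (e^{Pe·x/L} − e^{Pe})/(1 − e^{Pe})` to < 0.1% L2 error at Pe = 5,
satisfies the discrete maximum principle on every converged solution, and
changes fixed-point groove concentrations by < 0.3% when the grid is
halved. A symmetric no-flow device puts exactly 0.5 mM at the groove
midpoint, and a zero-groove device keeps the chambers at exactly 1 and
0 mM.

### What this closure predicts — and what it cannot

Under these boundary conditions the high-concentration chamber is
advectively pinned at its inlet concentration: the diffusive loss into all
13 grooves is ~6×10⁻⁴ of the advective supply, so the chamber sits at
1 mM everywhere, including against the wall. The model therefore predicts
≈ 0.98 mM in the first interior groove cell, an almost linear profile down
the groove, ≈ 0.017 mM in the last interior cell (the low side is swept by
the adjacent chamber's flow), and < 10⁻⁶ mM at the cell-attachment sites
175 μm into the low chamber — i.e. essentially complete fluidic isolation,
which is the device-design conclusion.

A groove-entrance concentration substantially below the source value
(e.g. ≈ 0.5 mM) can only arise when roughly half of the total transport
resistance lies upstream of the groove mouth — a near-wall depletion zone
inside the high chamber. That requires concentration boundaries far from
the wall with weak or no advective pinning (for instance a planar 2D
domain with reservoir-edge Dirichlet boundaries, or a transient washout
snapshot), not an inlet-fed plug-flow chamber: no choice of chamber
dimensions, depth or grid within this closure produces it, and a 1D
analysis shows no through-groove flow Péclet number can either. Reported
groove-entrance values should therefore always be read together with the
boundary-condition closure that produced them.

The model is steady-state only; no transient washout, 3D Stokes flow,
uptake/reaction terms, or particle-size-specific transport beyond changing
`D` in the config.

### Arithmetic helpers

`chamber_turnover(volume, flow) = volume/flow` (0.6 μl at 0.03 μl min⁻¹
→ 20 min); `dilution(volumes, concentrations) = Σvc/Σv` (100 μl of 100 μM
into an equal volume → 50 μM); `peclet` reports `uL/D` per chamber and 0
for grooves by construction.

## Problem sizes in tests

The test suite regenerates everything programmatically: three 240-frame
256×256 condition movies (shared across tests via a session fixture),
80 small wave movies (4 speeds × 20 seeds), Monte-Carlo baseline/FWHM
checks at 2000 frames / 50 replicates, and transport solves at 2.5 μm
(~74k cells) plus one 1.25 μm grid-convergence solve (~296k cells). These
sizes were chosen so the full suite completes in about a minute on one
core while keeping every Monte-Carlo margin comfortably away from its
threshold.
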