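# astrocal

Analysis tools for calcium imaging of compartmentalized neuron–astrocyte
co-cultures, together with a depth-averaged transport model of the
two-chamber microfluidic devices these cultures grow in.

The package is aimed at labs that record dual-channel GECI movies (e.g.
GCaMP6 in astrocytes, R-GECO in neurons) from micropatterned microfluidic
chips and want a scripted, reproducible version of the standard analysis:
cell segmentation, automatic detection of astrocyte microdomain calcium
events, ΔF/F traces with event kinetics, calcium-wave speed from
kymographs, and a fluidic-isolation simulation of the device itself.
Because raw recordings are rarely shareable, a synthetic-movie generator
with complete ground truth is a first-class component: every stage of the
pipeline is validated by parameter recovery on movies whose answer is known.

## The quantities computed

- **ΔF/F** per ROI: `(F − F0)/F0`, where `F` is the background-subtracted,
  spatially averaged fluorescence in the ROI and `F0` is the *lower-quartile
  baseline* — the mean of the frames whose `F` lies at or below the 25th
  percentile of the series.
- **Event ROIs**: voxels of the spatially low-pass-filtered movie that
  exceed the per-pixel baseline mean by `k` baseline standard deviations
  (default k = 2; SD = 1.4826 × MAD of the pixel trace) are grouped into
  connected components in (x, y, t). Each component is one event; its 2D
  OR-projection (union of all frame slices) is the ROI whose area is
  reported in μm².
- **Event kinetics**: each event's ΔF/F transient is fit with a Gaussian
  `a·exp(−(t−μ)²/2σ²) + b`; duration is summarized as
  `FWHM = 2√(2 ln 2)·σ`.
- **Condition comparison**: empirical CDFs of ROI size, max ΔF/F and FWHM
  per culture condition (astrocytes alone `A/-`, co-culture in one chamber
  `NA/-`, adjacent chambers `N/A`), with two-sample Kolmogorov–Smirnov
  distances as a descriptive separation measure.
- **Wave speed**: a pseudolinescan (kymograph) is extracted along a
  user-drawn path; the arrival time at each position is its first
  half-maximum crossing, and the speed is `1/|slope|` of the least-squares
  line of arrival time versus arc length.
- **Fluidic isolation**: steady solute transport in two chambers joined by
  shallow microgrooves (13 grooves, 100×10×5 μm by default), solved as a
  depth-averaged finite-volume model of `∇·(hD∇c) − h u·∇c = 0` with plug
  flow `u = Q/(width·depth)` along each chamber and diffusion-only grooves.

## Worked example

Generate the co-culture condition, detect astrocyte events and summarize
them, scoring against the generator's ground truth:

```python
import numpy as np
from astrocal import synth, detection, traces, benchmark

movies, truth = synth.generate_condition_set("NA_same", seed=7)
green = movies["green"]                      # astrocyte (GCaMP6-like) channel

baseline = detection.estimate_baseline(green)
events = detection.detect_events(green, baseline)
table = traces.summarize_events(green, events)

astro_truth = [e for e in truth.events if e.cell_id < 100]
precision, recall = benchmark.score_detection(events, astro_truth,
                                              green.frame_interval)
print(f"detected events : {len(events)} (truth: {len(astro_truth)})")
print(f"precision/recall: {precision:.2f} / {recall:.2f}")
print(f"median ROI size : {table.roi_size_um2.median():.0f} um^2")
print(f"median FWHM     : {table.fwhm_s.median():.2f} s "
      f"(truth {np.median([e.fwhm for e in astro_truth]):.2f} s)")
```

prints

```
detected events : 37 (truth: 48)
precision/recall: 1.00 / 1.00
median ROI size : 229 um^2
median FWHM     : 2.99 s (truth 2.88 s)
```

Every true microdomain event is recovered and nothing spurious is reported
(37 < 48 because events overlapping in space and time merge into one
connected component, which still covers both). The detected ROI size
exceeds the true footprint area because the low-pass halo of a bright event
also crosses threshold; the fitted FWHM recovers the generator's kinetics
within a few percent.

The same stages are available from the shell:

```bash
astrocal synth condition --name NA_same --seed 7 --out scratch/na
astrocal detect --movie scratch/na/NA_same_green.tif --out scratch/na_results
astrocal transport --out scratch/transport     # fluidic-isolation simulation
```

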