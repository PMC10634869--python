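# midzone

Quantitative analysis of the anaphase spindle midzone — the antiparallel
microtubule array between segregating chromosomes — aimed at researchers
quantifying *C. elegans* (or similar) mitosis from electron-tomography
tracings and light-microscopy movies.

The package covers five measurement families behind one library + CLI:

1. **Filament-network geometry** (`midzone.geometry`) — on traced 3D
   microtubule polylines (nm): an *interaction* is a stretch of one
   microtubule lying within a center-to-center distance *d*<sub>max</sub>
   (default 100 nm) of another for at least *l*<sub>min</sub> (default
   100 nm) of arc length.  The module reports per-interaction length,
   minimum distance and angle, plus network statistics (density in
   MT/µm³, length and nearest-neighbor means ± population SD,
   distance-bin fractions), with a grid spatial index that accelerates
   the scan without changing its result.
2. **Microtubule polarity** (`midzone.polarity`) — the statistic
   P = |n⁺ − n⁻| / (n⁺ + n⁻) over plus-end orientations (1 = parallel,
   0 = balanced antiparallel), a declared SHG/two-photon imaging model
   (TP = αρ, SHG = β(ρP)²) with its inversion
   P = √(SHG / (κ·TP²)), κ = β/α², axial polarity profiles, and the full
   width of the central polarity dip as the antiparallel overlap width.
3. **Spindle tracking** (`midzone.tracking`) — 8-bit conversion, embryo
   watershed segmentation, pole detection (top-25% band, 191–255) and
   chromatid leading edges (top-50% band, 127–255), anaphase onset as the
   last frame before persistent visible segregation, segregation and
   spindle-elongation rates over the first 40 s after onset,
   rotation-aligned kymographs and pole-oscillation traces.
4. **Intensity dynamics** (`midzone.dynamics`) — background-normalized
   midzone intensity, half-intensity profile widths, EB-comet counting on
   kymograph segments (4.5 µm / 10% threshold), and FRAP mobile-fraction
   fits F(t) = F₀ + (F∞ − F₀)(1 − e^(−kt)).
5. **Single molecules** (`midzone.singlemol`) — speed (path length /
   time), run length, brightness-speed association, and bait-prey
   co-appearance fractions from single-molecule pull-down logs.

Every input the analyses consume can be generated by `midzone.synth` as
seeded synthetic data with attached ground truth, so the whole pipeline is
testable at desk scale.

## Worked example

Generate a synthetic two-channel anaphase movie (pole-pole distance
elongating at 0.09 µm/s and chromatid leading edges separating at
0.13 µm/s from onset at t = 30 s) and run the tracking pipeline:

```python
from midzone import synth, tracking as trk

movie, truth = synth.make_mitosis_movie(seed=42)
trace = trk.track_movie(movie)
print("onset_frame:", trace.onset_frame)
print("segregation_rate: %.4f um/s" % trk.segregation_rate(trace))
print("elongation_rate: %.4f um/s" % trk.pole_separation_rate(trace))
```

```
onset_frame: 29
segregation_rate: 0.1271 um/s
elongation_rate: 0.0876 um/s
```

Onset is called at frame 29, the last frame before visible segregation
(the generator separates the masses from t = 30 s).  The measured rates
sit within ~3% of the generating 0.13 and 0.09 µm/s; the small deficit is
the one-frame onset quantization over the 40 s rate window.

Interaction analysis of a designed filament network — three isolated
antiparallel pairs, 60 nm apart, fully overlapping over 500 nm:

```python
from midzone import synth, geometry as geo, filaments as fio

net, _ = synth.make_overlap_pairs(n_pairs=3, spacing=60, overlap_length=500, seed=0)
net = fio.filter_short(net, 100.0)                      # tracing length cutoff
its = geo.detect_interactions(net, d_max=100.0, l_min=100.0, resample_step=20.0)
stats = geo.network_stats(net, its)
print("n_interactions:", stats.n_interactions)
print("mean_interaction_length_nm: %.1f" % stats.mean_interaction_length_nm)
print("mean_nn_distance_nm: %.1f" % stats.mean_nn_distance_nm)
```

```
n_interactions: 6
mean_interaction_length_nm: 500.0
mean_nn_distance_nm: 60.0
```

Six interactions are ordered-pair records (two per mutually overlapping
pair); the recovered mean interaction length and neighbor distance equal
the designed 500 nm overlap and 60 nm spacing.

The same operations are available from the shell, e.g.:

```sh
midzone synth mitosis-movie --seed 42 --out demo/
midzone track --input demo/movie.tif --px 0.25 --dt 1.0
midzone net-stats --input net.am --dmax 100 --lmin 100 --step 20
```

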