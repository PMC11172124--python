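# nucshell

Concentric 3D-shell radial profiling of nuclear marker intensity in
confocal Z-stacks.

Many nuclear-envelope (NE) proteins — the SUN-domain proteins of the LINC
complex among them — are not uniformly distributed through the nucleus:
their signal is enriched near the envelope, and treatments that perturb
their oligomeric state can change that radial distribution. `nucshell`
quantifies this. Given single-channel 3D fluorescence stacks of stained
nuclei, it:

1. **segments** each nucleus (Gaussian smoothing → Otsu threshold →
   morphological refinement → connected components → removal of objects
   touching the lateral image borders, keeping objects clipped only at the
   first/last Z plane);
2. computes an **exact Euclidean distance transform** `I_dt` of the binary
   nucleus mask `I_seg` — each foreground voxel gets its shortest distance
   to the nearest background voxel, with axis steps weighted by the
   physical voxel spacing (default 0.21 × 0.05 × 0.05 µm in Z, Y, X);
3. partitions each nucleus into **K = 24 equally-spaced concentric 3D
   layers**: with `d_max` the nucleus's maximum distance and normalized
   depth `nd = d / d_max`, a voxel's layer is
   `ℓ = K + 1 − ⌈K · nd⌉`, so layer 1 sits at the nuclear centre and layer
   24 abuts the envelope;
4. records the **mean raw intensity per layer per nucleus**, groups layers
   into six **regions of interest** (RO-1 = layers 1–4 … RO-6 = layers
   21–24), and compares two conditions per layer or per RO with an
   unpaired two-sample *t*-test (nuclei are the statistical units; results
   as mean ± SEM with significance at *p* ≤ 0.05).

Because suitable public image data for this assay are scarce, the package
ships a first-class **synthetic phantom generator**: ellipsoidal or folded
nuclei at realistic anisotropic voxel spacing, a configurable
centre-to-periphery generating profile, punctate staining blurred by an
anisotropic PSF, Poisson + Gaussian noise, and voxel-level ground truth
(mask, true depth, true layer labels, true RO means and fold ratios). The
whole pipeline is validated end-to-end against this ground truth and
against brute-force oracles for its geometric primitives.

## Worked example

```python
import nucshell as ns

# a disc-shaped (MCF10A-like) synthetic nucleus with peripheral enrichment,
# default photon + read noise
img, truth = ns.mcf10a_like(seed=7)

labels, profiles, dmax = ns.analyse_volume(img)   # segment + 24 shells
(p,) = profiles
ro = ns.nucleus_ro_values(p, ro_size=4)

print("nuclei:", labels.n_objects, " d_max (um):", dmax)
print("RO means:", ro.round(1))
print("RO-6/RO-1 fold: %.2f  (generating truth: %.2f)"
      % (ro[5] / ro[0], truth.fold()))
```

prints

```
nuclei: 1  d_max (um): {1: 1.68}
RO means: [ 97.2 106.9 132.8 175.9 219.8 236.9]
RO-6/RO-1 fold: 2.44  (generating truth: 2.44)
```

One nucleus survives segmentation; its deepest voxel lies 1.68 µm from the
envelope. Mean intensity rises monotonically from the innermost RO (97.2,
arbitrary units) to the outermost (236.9): the staining is peripherally
enriched ~2.4-fold, and the estimate matches the phantom's generating
truth to two decimals.

The same analysis runs from the shell on real TIFF stacks:

```sh
nucshell phantom demo/ --preset mcf10a --n 5 --seed 1 --condition minusDTT
nucshell segment demo/mcf10a_*.tif mask.tif --spacing 0.21 0.05 0.05
nucshell run config.yaml          # batch: profiles, RO summary, t-tests, manifest
```

`nucshell run` writes `layers.csv` (one row per nucleus × layer),
`ro_summary.csv` (group mean ± SEM per RO), `comparisons.csv` (t, p and a
significance flag per layer and per RO when exactly two conditions are
present), and `manifest.json` (full configuration echo, per-image nucleus
counts, d_max per nucleus, software version) from which every output is
reproducible.

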