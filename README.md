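# telo3d

Quantification of telomere number, length and volume in 3D wide-field
fluorescence microscopy of interphase nuclei — with a synthetic
microscope that makes every stage of the pipeline verifiable by
parameter recovery.

## The problem

A normal diploid human cell in G0/G1 carries exactly 92 telomeres (two
per end of its 46 chromosomes).  In qFISH imaging, each telomere is a
sub-resolution point source whose integrated fluorescence is
proportional to its length in kb, so a z-stack of a nucleus contains,
in principle, the complete per-telomere length distribution of one
cell.  In practice the readout is limited by camera offset and uneven
illumination, by out-of-focus light, and by the diffraction limit: two
telomeres closer than ~200 nm laterally (3x worse axially) fuse into
one spot, so the observed spot count `O` falls below the expected count
`E = 92` and the deficit `(E − O)/E` itself becomes a measurement of
telomere clustering.

`telo3d` implements the full workflow for people who study telomere
biology with an ordinary wide-field microscope:

* **synthetic_nuclei** — simulates two-channel z-stacks (telomere probe
  + DNA stain) of nuclei with known telomere positions, lengths and
  clustering, plus matching dark-frame/flat-field calibration images
  and sub-resolution bead stacks, with full ground truth.
* **restoration** — dark/flat shading correction
  `M (raw − dark)/(flat − dark)` and Richardson–Lucy deconvolution
  (the Poisson maximum-likelihood iteration; 50 iterations by default).
* **foci2d** — ImageJ-style 2D counting on maximum projections:
  prominence-based Find-Maxima with noise-tolerance calibration against
  the expected karyotype, Otsu thresholding, marker watershed,
  per-focus area/intensity.
* **spots3d** — 3D detection via an anisotropic Laplacian-of-Gaussian
  "quality" filter, ellipsoidal spots with the fixed 3:1 axial ratio,
  intensity sums, and bead-based resolution calibration (the smallest
  resolvable spot volume, (π/6)·0.22²·0.66 ≈ 0.017 µm³).
* **nuclei** — DNA-channel segmentation and G1 gating by DNA content
  (S/G2 cells would double the expected count and are excluded).
* **telo_stats** — condition summaries: counts, intensity-sum length
  ratios, volume statistics and CVs, volume-vs-intensity R²,
  count-deficit clustering estimates `(E−O)/E` and `(E−O)/O`,
  log-volume bimodality, and reference arithmetic (e.g. telomeres are
  only ~1/4000–1/6000 of the genome).
* **cli_io** — a `telo3d` command line (`simulate`, `correct`,
  `detect2d`, `detect3d`, `analyze`, `report`) over strict YAML
  configs, multi-page TIFF stacks, CSV tables and JSON reports.

## Worked example

Simulate two conditions — normal fibroblast-like nuclei (lognormal
telomere lengths, mean 5.3 kb) and a telomerase-extended line
(mean 18.9 kb, i.e. a 3.57-fold true length ratio) — then run the full
pipeline (correction, deconvolution, calibrated 3D detection, gating,
statistics):

```bash
telo3d simulate --config example_config.yaml --out demo_ds
telo3d analyze  --config example_config.yaml --dataset demo_ds
```

With 2 replicates x 2 nuclei per condition (seed 7) this prints

```
Hs68: mean 3D count 92.0 over 4 cells
Hs68_hTERT: mean 3D count 92.0 over 4 cells
```

and `demo_ds/analysis/report.json` contains, per condition:

```
Hs68:        count 92.0±0.0, vol 0.056 µm³, intensity-sum 15836, R² 0.91, unresolved 0.0%
Hs68_hTERT:  count 92.0±0.0, vol 0.054 µm³, intensity-sum 57216, R² 0.94, unresolved 0.0%
ratio: 3.61 ± 0.05
```

Reading the numbers: both conditions were simulated with well-separated
(≥ 1 µm) telomeres, so the calibrated pipeline recovers the full
diploid complement of 92 spots and the count deficit is zero; the
intensity-sum ratio 3.61 ± 0.05 recovers the simulated 3.57-fold length
difference — the relative-length readout the method exists for; mean
spot volumes (~0.055 µm³) are diffraction-scale ellipsoid volumes, a
relative size measure, not physical telomere sizes.  Simulating with
`cluster_fraction: 0.4` instead places 40% of telomeres in
sub-resolution pairs and the report's unresolved fraction moves to
~20% — the count-deficit signature of clustering.

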