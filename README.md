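# condquant

Quantification toolkit for optogenetic-condensate imaging experiments:
single-molecule FISH spot detection and subpixel localization, mRNA →
condensate recruitment statistics, single-particle tracking with MSD-based
diffusion estimation, binding-event analysis, FRAP mobile-fraction fitting,
reporter-decay kinetics, saturation-concentration (phase-boundary)
estimation, a ternary regular-solution coexistence calculator, and
dendritic-spine volume quantification — together with a synthetic-data
module that generates matched microscopy data with recoverable ground truth
for every estimator.

## Layout

| module | contents |
|---|---|
| `condquant.core` | `ImageStack` carrier (named axes + physical metadata), TIFF + JSON sidecar I/O |
| `condquant.synthgen` | synthetic scenes, movies, FRAP/reporter traces, phase scans, spine stacks, bead pairs — all seeded and bit-reproducible |
| `condquant.imgprep` | flat-field estimation/correction, rolling-ball background subtraction, DoG band-pass, bleach correction, bead-based channel registration, drift correction, walking average, kymographs |
| `condquant.puncta` | condensate segmentation, spot detection (median + k·MAD), 2D-Gaussian localization, max−min window amplitude, z-chain collapse |
| `condquant.colocal` | nearest-condensate distances, recruitment classification (330 nm / 2 z-planes), count- and amplitude-weighted recruitment fractions |
| `condquant.motion` | trajectory linking, time-averaged MSD, diffusion fit (MSD points 2–4, slope/4), distance traces, hysteresis binding-event detection |
| `condquant.phase` | clustered/dilute classification, logistic saturation-concentration fit with bootstrap CI, condensate composition ratios, Flory–Huggins free energy, convex-hull coexistence and binodals |
| `condquant.readouts` | reporter normalization and half-life fits, FRAP analysis, Phansalkar-threshold spine volumes, nuclei segmentation + per-cell translation intensity, puncta counting per cell, pooled two-sample t test |

## CLI

```bash
condquant simulate fish --seed 1 --out scene/
condquant simulate frap --mobile-fraction 0.6 --seed 1 --out frap.csv
condquant simulate phasescan --csat 100 --seed 1 --out scan.csv
condquant detect  --image scene/stack.tif --channel fish --out spots.csv
condquant recruit --image scene/stack.tif --out recruitment.csv
condquant msd     --traj traj.csv --pixel-size-nm 110 --dt 0.05 --out msd.csv
condquant csat    --scan scan.csv --out csat.json
condquant frap    --trace frap.csv --out frap.json
```

Images travel as multi-page TIFF with a JSON metadata sidecar
(`stack.tif` + `stack.tif.json`: axes, pixel size, z-step, frame interval,
channel names, provenance). Tables are plain CSV.

## Conventions

- 0-based indices; the center of pixel (row i, col j) is at continuous
  coordinate (i, j); physical position = index × pixel size.
- Every generator takes an explicit integer seed; identical seed + config
  produces bit-identical output.
- Distance thresholds are stored in nm and converted through image metadata;
  z separations are counted in planes.
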