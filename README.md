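# laminarkit

Layer-specific cortical analysis on synthetic cortical phantoms: data-driven
laminar compartmentalization of 21-depth quantitative-T1 profiles, automated
low-myelin border detection on triangulated surface patches, phase-encoded
BOLD depth-response metrics and 1-D population-receptive-field fitting,
psychophysics scoring, mouse calcium/histology quantification, and the
permutation-test utilities that tie the group analyses together.

All inputs the pipeline consumes can be generated by the built-in synthetic
module (`laminarkit.synth`), which emits ground truth alongside every dataset
so that every analysis is testable closed-loop without downloads.

## Modules

| module | contents |
| --- | --- |
| `laminarkit.surface` | `SurfaceMesh`, geodesic shortest paths (Dijkstra on the edge graph), equally spaced parallel path families, overlay sampling, PLY/GIFTI/TSV I/O |
| `laminarkit.laminar` | equivolume depth fractions, three-compartment segmentation of qT1 depth profiles from first-derivative extrema, layer-specific thickness |
| `laminarkit.borders` | path-signal detrending, prominent-peak detection, cross-path nearest-neighbour grouping into borders, classification and featurization |
| `laminarkit.funcsignal` | forward/reverse run averaging, Fourier response amplitude with F-ratio, calibrated depth-response profiles with AUC peak/decay metrics, coarse-to-fine 1-D Gaussian pRF fit, Spearman–Brown noise ceiling, rectified-correlation eigenvector centrality |
| `laminarkit.psychophys` | 3-down/1-up staircase thresholds, d′, two-point discrimination (logit fit), skin-indentation conversion, precision-grip time-on-target |
| `laminarkit.mouse` | ΔF/F with percentile baseline, whisker-pad movement labeling, double-vs-single stimulation response classes, depth-binned histological densities |
| `laminarkit.stats` | Monte-Carlo permutation Welch t-test (equal-tail p, permutation CI), τ = 2/π·arcsin(r), Theil–Sen regression |
| `laminarkit.synth` | cortical strip phantoms (cohort-parameterized plateaus, septa, correlated noise), phase-encoded BOLD generators, psychometric observers, GCaMP-like traces |

## CLI

A single `laminarkit` entry point groups all commands:

```bash
# generate a phantom with a septum at y = 12 mm, then detect borders on it
laminarkit simulate phantom --cohort younger --seed 3 --septum 12 --out ph
laminarkit layers --profiles ph_profiles.tsv --out compartments.json
laminarkit borders --mesh ph.ply --overlay-table ph_overlays.tsv \
    --seeds 1640,1720 --out borders.json

# phase-encoded BOLD: simulate, then depth profile and pRF fits
laminarkit simulate bold --design cohort2 --seed 1 --out bold
laminarkit profile --series bold_forward.h5 --rest bold_rest.h5 \
    --compartments compartments.json --out profile.tsv

# behavior and statistics
laminarkit simulate behavior --threshold 3.6 --out log.tsv
laminarkit psychophys staircase --log log.tsv
laminarkit stats permtest --a a.tsv --b b.tsv --n 100000 --seed 7
```

`laminarkit simulate phantom --print-spec` prints the full phantom
specification with all defaults.

## Conventions

- Depth index 0 is the CSF/GM boundary (superficial), index 20 the GM/WM
  boundary; profiles carry 21 depths and laminar analyses drop the two
  deepest before taking derivatives.
- Coordinates are right-handed millimetres; on phantom strips the y axis
  runs inferior→superior (path direction) and the x axis
  anterior→posterior (path-family direction).
- Path signals are resampled to a uniform 0.25 mm arc-length grid before
  peak analysis.
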