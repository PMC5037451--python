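# stretchplate

High-content analysis of an *in vitro* neuronal stretch-injury assay in
96-well format. Human iPSC-derived neurons grown on silicone-bottomed
plates are rapidly stretched over an array of posts; four hours later
each well is imaged (Hoechst nuclear stain plus calcein-AM viability
stain, or Hoechst + MAP2 + synaptophysin immunofluorescence) and the
injury phenotype is quantified well by well. `stretchplate` implements
the computational side of that experiment:

* **Strain calibration** — each well's mechanical insult is measured
  from a stamped fiducial dot. With shear negligible, the axial
  Green–Lagrange strains are E = u/X + ½(u/X)², computed from the dot's
  width (E_xx) and height (E_yy); the well strain **E** is their mean
  (the field is equibiaxial). Per-plate maps, across-well statistics,
  and the displacement–strain line are provided.
* **Cell morphometry** — segmentation of the two live-cell channels
  into viable cells (calcein⁺ body containing a Hoechst⁺ nucleus),
  dead cells (nucleus without calcein), and rejected artifacts (injury
  beads: calcein⁺ blobs that are too small and contain no nucleus).
  The remaining calcein⁺ area is skeletonized into a neurite graph,
  giving nine per-well injury metrics: viable cells/image, dead
  cells/image, neurite length/cell, processes/cell, branches/cell, and
  their totals, plus cell viability as a percentage of a reference
  count.
* **Dose–response fitting** — every metric y follows a generalized
  (four-parameter) logistic in strain,

      y(E) = y_f + (y_0 − y_f) / (1 + exp(k·(E − E_t))),

  where y₀ is the zero-strain plateau, y_f the high-strain asymptote,
  k the rate constant, and E_t the transition strain at which the
  metric is halfway between the two. Fits use Levenberg–Marquardt with
  asymptotic 95% confidence intervals and R².
* **Synapse compartment analysis** — MAP2 is thresholded with the
  Background method (2× histogram mode) into a cell mask; erosion
  isolates the somata and a 3-pixel dilation-and-subtraction isolates
  the neurites; synaptophysin is thresholded per compartment by
  maximum-correlation thresholding (1-px Gaussian smoothing) and
  density is the positive-area fraction; groups are compared with
  Welch t-tests at the Bonferroni-corrected level 0.05/3.
* **Synthetic data** — the raw data of such an experiment are emulated
  with known ground truth: dot deformations exactly inverting the
  strain formula (post = pre·√(1+2E)), well-level metric tables drawn
  from the logistic with R²-calibrated noise, and rendered fluorescence
  channels of parametric cultures whose neurites shorten, thin, bead,
  and die as the injury level rises.

The intended users are people building or validating high-content
stretch-injury (or neurotoxicity) pipelines who need every stage
testable against ground truth.

## Worked example

Simulate a five-plate dose–response experiment (152 injured wells over
five stage-displacement amplitudes plus 8 unstretched controls) and fit
all nine metrics:

```python
from stretchplate import synthetic_data as syn
from stretchplate.dose_response import fit_all_metrics

table = syn.simulate_experiment(seed=42)
report = fit_all_metrics(table)
print(report[["y0", "yf", "k", "E_t", "r_squared"]].round(3))
lo, hi = report.attrs["E_t_range"]
print(f"E_t range: {lo:.3f} - {hi:.3f}")
```

```
                                y0        yf       k    E_t  r_squared
metric
neurite_length_per_cell    146.544    25.302  10.276  0.349      0.869
cell_viability              77.549    18.759  20.849  0.362      0.860
processes_per_cell           3.262     1.350  23.223  0.344      0.842
total_neurite_length     43092.831  2857.915  17.580  0.317      0.841
branches_per_cell            2.449     0.279  15.142  0.327      0.798
total_processes           1089.253   112.732  25.373  0.317      0.799
viable_cells_per_image     308.785    76.477  23.560  0.364      0.754
total_branches             780.013    58.616  19.179  0.286      0.651
dead_cells_per_image       259.632   508.814  28.075  0.350      0.651

E_t range: 0.286 - 0.364
```

Each row is one injury metric: the fitted zero-strain value y₀,
high-strain asymptote y_f, rate constant k, transition strain E_t, and
R². The transition strains cluster around 0.3–0.36 — the neurons flip
from healthy to injured at roughly 30–36% Lagrangian strain, and every
metric agrees on that transition within a narrow band.

There is also a command-line pipeline:

```bash
stretchplate strain  --seed 3 --out runs/strain    # per-well strain map
stretchplate injury  --seed 2 --out runs/injury    # metrics + nine fits
stretchplate synapse --seed 1 --out runs/synapse   # compartment densities
```

Each subcommand reads an optional YAML config (inputs may be measured
CSVs/TIFFs or the synthetic generator) and writes CSV/JSON outputs
stamped with the seed and a config hash.

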