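# taskcpca

Task-based multivariate functional connectivity for event-related fMRI:
constrained principal component analysis (CPCA) of FIR-modeled BOLD
variance, with network-level statistics and brain–behavior correlation.

## Who this is for

Researchers who want to move beyond voxelwise univariate task fMRI and ask
which *whole-brain networks* are engaged by a task, how their hemodynamic
responses unfold over poststimulus time, and how network activity differs
between groups (e.g., stroke patients performing hand grips with the
affected hand versus healthy controls) and relates to behavior. The package
implements the full analysis chain as a tested library plus numbered
analysis drivers, exercised end to end on a synthetic multi-subject cohort
with known ground truth.

## The method

Each subject's preprocessed 4D time series `Y` (scans × voxels) is cleaned
of nuisance variance (rigid-body motion first, then polynomial drift and
intercept) by least-squares projection. Task structure enters through a
finite impulse response (FIR) design `G`: one indicator column per
(condition, poststimulus scan), so the hemodynamic response (HDR) shape is
estimated without assuming its form. With TR = 3.25 s and 6 poststimulus
scans the modeled window spans 19.5 s. Subjects are stacked with `G`
block-diagonal, and the task-related variance is isolated by multivariate
regression followed by an SVD of the predicted portion:

    C = argmin ‖Z − G C‖²,   G C = U D Vᵀ

Component loadings `V D` are per-voxel network weights; varimax rotation
simplifies their structure (scores are counter-rotated, so the
reconstruction `scores · loadingsᵀ` is invariant). Regressing each rotated
score column back onto `G` yields **predictor weights** indexed by
(subject, condition, poststimulus bin) — subject- and condition-specific
estimated HDR shapes. Downstream:

- **HDR statistics** — per network, a 6 (Poststimulus Time) × 2 (Force:
  10%, 30%) × 2 (Group) mixed ANOVA with Greenhouse–Geisser sphericity
  checks, partial η², and per-bin simple effects under Benjamini–Hochberg
  FDR.
- **Within-network inference** — inside each network's extreme-10% loading
  mask, subject component-expression maps are compared between groups by
  threshold-free cluster enhancement (TFCE, H = 2, E = 0.5,
  26-connectivity) with max-statistic permutation FWE correction.
- **Behavior** — three motor measures (grip strength, NHPT, BBT, each as %
  of the unaffected hand) are collapsed to a first-principal-component
  composite (higher = better performance) and correlated with significant
  cluster activity.
- **Lesion anatomy** — lesion overlap maps and Dice similarity against the
  network masks.

The synthetic-data module generates the full study design — 24 controls +
17 patients, 50 cued isometric grips per subject at two force levels, 3 s
grips, 3–7 s ISIs, TR = 3.25 s — with four planted networks
(attention/visual/motor/default-mode analogs) that differ in spatial
pattern *and* HDR timing, group-dependent amplitudes, AR(1) noise,
polynomial drift, lesion masks, and a planted activity–behavior coupling.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_fit_networks.py    --seed 1
python analysis/04_within_network_inference.py --seed 1 --n-permutations 500
python analysis/05_brain_behavior.py  --seed 1 --n-permutations 500
```

prints (abridged):

```
cohort: 24 controls + 17 patients = 41 subjects
scans per subject: 125-135 (duration 406-439 s)

scree suggests 4 components (rule: chord-elbow); fitting 4
task-variance fractions (%): [19.1 16.4  6.7  5.4]
  attention  -> component 2  |r| = 0.989
  visual     -> component 4  |r| = 0.982
  motor      -> component 3  |r| = 0.977
  dmn        -> component 1  |r| = 0.950

component 1: 1 FWE cluster(s); Dice vs lesion overlap = 0.055
component 3: 2 FWE cluster(s); Dice vs lesion overlap = 0.160

PC1 explains 75.9% of the three motor measures (higher composite = better)
motor-network cluster 1 (control>patient, 61 voxels): r = 0.94, p = 2.7e-08
```

Reading this: the scree of singular values identifies the four planted
networks; every rotated loading map matches its planted template at
|r| ≥ 0.95. Group inference inside the motor network finds an activation
cluster where controls exceed patients (the planted 0.6× patient
multiplier), and activity in that cluster correlates strongly with the
behavioral composite — the planted positive coupling, recovered through
the whole chain. The `taskcpca` console script (`taskcpca all --seed 1
--out run/`) runs the same chain as one pipeline with a reproducibility
manifest.

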