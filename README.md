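# vfarch

Toolkit for analysing binocular visual-field (BVF) loss in glaucoma:

- **24-2 perimetry data model** — eye-specific 54-location grids, validation,
  and binocular integration of same-visit monocular pairs by quadratic
  summation (`B = sqrt(R^2 + L^2)`), yielding a 52-location integrated
  visual field (IVF).
- **Quality control** — reliability filtering (false positives > 10%, or
  false negatives > 10% with fixation losses > 20%), analysis-visit
  selection (≥ 2 reliable visits, most recent used), and a homonymous-defect
  screen based on vertical midline asymmetry and interocular correlation.
- **Archetypal analysis** — fits K archetypes (convex prototypes) to IVF
  matrices by alternating simplex-constrained least squares with seeded
  multi-restart, decomposes fields into simplex weights, 10-fold
  cross-validation over candidate K, and BIC-slope model-order selection.
- **VR-QoL association** — 0–100 questionnaire scoring (43-item default map,
  37 modelled aspects), proportional-odds ordinal regression of each aspect
  on archetype weights (archetype 1 is the reference) adjusted for age,
  gender and binocular foveal sensitivity, Bonferroni control (0.05/43),
  correlation matrices and expected-score prediction.
- **Synthetic data** — generators with full ground truth for every pipeline
  input: monocular pairs whose IVFs are noisy convex mixtures of known
  defect templates, homonymous pairs, reliability indices, and ordinal
  questionnaire responses from a known proportional-odds model.

## Command-line usage

```sh
# generate a synthetic cohort with ground truth
vfarch simulate --n 500 --k-true 4 --noise 1.0 --seed 1 -o data/

# individual stages
vfarch qc --vf data/vf.csv --meta data/meta.csv -o qc_report.csv
vfarch integrate --vf data/vf.csv --meta data/meta.csv -o ivf.csv
vfarch select-k --ivf ivf.csv --k-min 2 --k-max 17 --folds 10 --restarts 100 --seed 7 -o cv.csv
vfarch fit --ivf ivf.csv --k 12 --restarts 100 --seed 7 -o model.json
vfarch decompose --model model.json --ivf ivf.csv -o weights.csv
vfarch associate --weights weights.csv --qol data/qol.csv --covariates covariates.csv -o assoc.csv
vfarch predict --assoc assoc_models.json --weights weights.csv --covariates covariates.csv -o predicted.csv

# or the whole pipeline at once
vfarch run --vf data/vf.csv --meta data/meta.csv --qol data/qol.csv --k 4 --seed 7 -o out/
```

Every command writes a JSON manifest next to its output recording the
package version, seed and parameters; reruns with identical inputs produce
byte-identical artifacts.

All tabular interchange is plain CSV with named headers (see the module
docstrings in `vfarch.io` for column contracts); archetype models and
manifests are JSON, configuration is YAML (`--config`, keys as in
`vfarch.config.PipelineConfig`).

## Layout

```
src/vfarch/core.py        grid geometry, field types, binocular integration
src/vfarch/qc.py          reliability rules, visit selection, neuro screen
src/vfarch/archetypal.py  archetypal engine, CV, BIC model-order selection
src/vfarch/_solvers.py    numba kernels for simplex-constrained least squares
src/vfarch/qol.py         questionnaire scoring, ordinal regression, prediction
src/vfarch/synthetic.py   ground-truth generators
src/vfarch/io.py          CSV/JSON readers and writers
src/vfarch/pipeline.py    composable stages and the end-to-end runner
src/vfarch/cli.py         click CLI (`vfarch`)
tests/                    unit, property and acceptance suites
```
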