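# qmyelin

Synthetic multi-modal myelin-MRI cohorts and the full quantitative
comparison pipeline around them:

* **Phantom cohort** — a parametric nested-ellipsoid head with ground-truth
  tissue parameters, between-subject variation, and focal white-matter
  lesions (count/load statistics typical of relapsing-remitting MS),
  generated co-registered on a common grid.
* **Forward signal models** — extended-phase-graph (EPG) multi-echo CPMG,
  SPGR / IR-SPGR / phase-cycled bSSFP steady states (single- and two-pool
  with exchange), a magnetization-transfer saturation pair, and Rician
  magnitude noise.
* **Voxelwise fitters** — regularized NNLS T2 spectra with refocusing-angle
  search (myelin water fraction, MWF-G), DESPOT1-HIFI (qT1, B1),
  DESPOT2-FM (T2, B0), two-pool stochastic region contraction (MWF-D), and
  MTR.
* **Cohort statistics** — control normative mean/SD maps, patient Z-maps,
  voxelwise inter-method Spearman correlation with per-tissue histograms,
  ROI summaries excluding lesional and perilesional tissue, and
  Mann-Whitney group tests with Bonferroni-Holm correction.
* **Lesion-detection ROC** — per-patient, per-modality ROC/AUC of Z-maps
  against the ground-truth lesion masks, vertically averaged curves, and a
  Friedman + pairwise-Wilcoxon + Holm inter-method comparison.

## CLI

The pipeline runs end to end or stage by stage
(`simulate → fit → zmap → corrmap → roi → roc → compare`), resuming from
on-disk artifacts:

```sh
qmyelin run      --config cohort.yaml --out runs/demo --seed 1
qmyelin simulate --config cohort.yaml --out runs/demo
qmyelin fit      --config cohort.yaml --out runs/demo
qmyelin zmap     --config cohort.yaml --out runs/demo
...
qmyelin compare-auc --config cohort.yaml --out runs/demo
```

The YAML config mirrors the dataclasses in `qmyelin.pipeline.RunConfig`
(cohort geometry/tissues/lesions/SNR, acquisition protocols, NNLS
regularization, SRC search box, ROC directions). Every artifact is a
NIfTI-1 volume, a TSV table, or a JSON summary under the output directory,
with a line-delimited JSON log and a manifest tying outputs to the seed.

## Layout

```
src/qmyelin/
  cohort.py       phantom geometry, tissue params, lesions, cohort generation
  signals.py      forward models (EPG, SPGR, IR-SPGR, bSSFP, two-pool, MT, noise)
  _fastsrc.py     numba kernel for the mcDESPOT signal table
  forward.py      subject-level acquisition simulation
  relaxometry.py  voxelwise fitters and the per-subject map orchestrator
  popstats.py     normative maps, Z-maps, Spearman maps, ROI stats
  lesion_roc.py   ROC/AUC, Friedman, Wilcoxon, Holm, method comparison
  volio.py        NIfTI-1 I/O
  pipeline.py     staged pipeline driver + YAML config
  cli.py          click CLI
tests/            pytest suite (unit, property, and acceptance tests)
scripts/acceptance.py
```
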