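# groupsice

Sparse functional brain sub-networks from multi-subject ROI time series,
with group-constrained topology detection and nested cross-validated
classification.

## Who this is for

Researchers building functional connectivity classifiers from
resting-state fMRI-style data: M subjects, each summarized as an
(n_t × P) matrix of regional mean time series over P atlas regions, with a
binary diagnosis label. Conventional whole-brain correlation networks are
dense, noisy, and differ in topology from subject to subject — all of which
hurts small-sample classifiers. This package implements a two-stage sparse
alternative plus the baselines to compare it against.

## The method

**1. Group-constrained topology.** For each target region p, one predictor
subset E_p shared by *all* subjects is selected by an ℓ2,1-penalized
multi-subject regression

&nbsp;&nbsp;&nbsp;&nbsp;β̂_p = argmin Σ_m ‖x_p^m − X_p^m β_p^m‖₂² + φ‖β_p‖₂,₁ ,

whose row-wise penalty keeps or drops each predictor for the whole group at
once. φ is chosen per target by BIC = Σ_m ln ESS(m) + d·ln(n_t)/n_t.

**2. Sparse inverse covariance (SICE / graphical lasso).** Per subject and
target, the precision matrix of the expanded subset [p, E_p] is estimated
by ℓ1-penalized maximum likelihood,

&nbsp;&nbsp;&nbsp;&nbsp;Θ̂ = argmin_{Θ≻0} −log det Θ + tr(SΘ) + λ‖Θ‖₁ ,

with the penalty on *all* entries. The first column of Θ̂ becomes column p
of the subject's P×P connectivity matrix; flattened, this gives P² features
(8,100 at P = 90).

**3. Nested leave-one-out CV + decision tree.** An inner LOOCV selects λ
end-to-end per outer fold; a Gini decision tree classifies; ACC/SEN/SPE,
ROC and AUC are reported, along with how often each connection is split on
across folds. Four network variants are available: `partial`,
`group-partial`, `sice`, `group-sice`.

A seeded synthetic-cohort generator (Gaussian graphical model with a
shared sparse precision support per group and a few flipped edges between
groups) provides ground truth for every stage. See `docs/methods.md` for
assumptions, parameter defaults, and limitations.

## Worked example

Simulate a 10-subject, 12-region cohort with 4 planted edge differences,
then compare all four network variants under nested LOOCV:

```sh
groupsice simulate --out demo/panel --regions 12 --edges 16 --flip 4 \
    --m-per-group 5 --n-t 150 --seed 11
groupsice compare --in demo/panel --out demo/cmp \
    --lambda-pool 0.1,0.3,0.5 --phi-grid 0.3,0.5,0.7
```

which prints

```
wrote 10 subjects (150x12) to demo/panel
                   acc      sen      spe    auc
mode
partial        80.0000  80.0000  80.0000 0.8000
group-partial 100.0000 100.0000 100.0000 1.0000
sice          100.0000 100.0000 100.0000 1.0000
group-sice    100.0000 100.0000 100.0000 1.0000
```

Each row is one network construction variant evaluated on the identical
cohort, fold order and classifier seed: leave-one-out accuracy, sensitivity
(patient detection rate) and specificity (control detection rate) in
percent, and the area under the ROC curve. On this easy planted cohort the
whole-brain partial-correlation baseline misclassifies two subjects while
the sparse and group-constrained variants separate the groups perfectly;
on harder cohorts (more regions relative to time points) the gap widens —
that regime is exactly what the sparse estimator is for.

The same stages are scriptable from Python:

```python
import groupsice as gs

panel = gs.make_two_group_cohort(seed=11, P=12, n_edges=16, n_flip=4,
                                 M_per_group=5, n_t=150)
sel = gs.select_topology(panel, phi_grid=[0.3, 0.5, 0.7])
cv = gs.nested_loocv(panel, mode="group-sice", lambda_pool=[0.1, 0.3, 0.5],
                     selection=sel)
print(gs.compute_metrics(cv).to_dict())
print(gs.connection_frequency(cv, panel.roi_names).head())
```

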