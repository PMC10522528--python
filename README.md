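# gbmsurv

Preoperative survival-class prediction for glioblastoma (GBM) from
multimodal neuroimaging features, as a tested, reusable pipeline.

GBM is the most aggressive primary malignant brain tumor, with median
overall survival around 14 months. A reliable preoperative estimate of
whether a patient will survive less than one year, one to two years, or
more than two years would inform surgical planning, trial enrollment and
shared decision-making. This package implements such a classifier from
features available before any treatment: age, sex, contralesional cortical
thickness over 34 Desikan–Killiany parcels, and resting-state functional
connectivity among 15 brain networks — and ships a synthetic cohort
generator so the whole analysis is runnable and testable without patient
data.

## The analysis

1. **Connectomics.** Each network's ROI is the top-200 voxels of its
   probability map. Similarity between networks *i*, *j* is the distance
   correlation (Székely's V-statistic) between their voxel blocks,

   dCor(X, Y) = sqrt( dCov²(X, Y) / sqrt(dVar²(X) · dVar²(Y)) ),

   computed from double-centered Euclidean distance matrices; within-network
   similarity averages dCor between each voxel and the remaining voxels as
   one multivariate sample. Over 15 networks this gives 120 labeled
   similarities per subject.
2. **Compression.** A single-hidden-layer autoencoder (20 sigmoid units,
   linear decoder, 80/20 early-stopping split) reduces the 120 similarities;
   near-constant code units are pruned, the survivors become features
   FC1..FCm.
3. **Classification.** A feed-forward network (3 hidden layers × 8 units,
   softmax over the three classes) is trained under nested stratified
   cross-validation — a global stratified holdout, 10 stratified outer
   folds, inner 5-fold selection of weight decay — giving an ensemble of
   fold models. Accuracy is reported for cross-validation, holdout,
   combined, and the score-averaged ensemble.
4. **Attribution.** Permutation feature importance (out-of-fold accuracy
   drop) per input; raw network-pair weights by permuting each pair through
   the trained encoder; per-network means over each network's 15 incident
   pairs; voxel maps as the dot product of network weights with the
   probability maps.
5. **Reporting.** Kaplan–Meier curves and a k-group log-rank test on the
   predicted groups; Chi-squared / Kruskal–Wallis cohort tables.

## Worked example

```python
from gbmsurv.pipeline import RunConfig, run_pipeline
from gbmsurv.synthetic import SimConfig, default_coupling_matrices
from gbmsurv.classifier import ClassifierConfig

config = RunConfig(
    sim=SimConfig(n_subjects=36, n_networks=4, voxels_per_network=8,
                  n_frames=40,
                  coupling_matrices=default_coupling_matrices(
                      4, planted_pairs=((0, 2),),
                      coupling_by_group=(0.8, 0.5, 0.2))),
    classifier=ClassifierConfig(outer_folds=3, inner_folds=0,
                                holdout_size=6, alpha_grid=(1e-4,)),
    seed=0,
)
manifest = run_pipeline(config, "run_out")
print(manifest["stages"]["train"])
print(manifest["stages"]["report"])
```

prints (seed 0):

```
{'cv_accuracy': 0.9, 'combined_accuracy': 0.8888888888888888, 'seconds': 0.65}
{'logrank_chi2': 36.6554077548452, 'logrank_df': 2,
 'logrank_p': 1.0974363474633504e-08, 'seconds': 0.22}
```

i.e. on a 36-subject toy cohort with coupling planted in one network pair,
out-of-fold accuracy is 90% (27/30 subjects), 88.9% counting the 6-subject
holdout, and the survival curves of the three predicted groups separate at
p ≈ 1e-8. `run_out/` then contains the cohort table, the 120-column (here
10-column) connectome table, the autoencoder bundle, per-subject
predictions, the importance tables, KM curves and a checksummed
`manifest.json`; rerunning with the same seed reproduces identical
checksums.

The same stages are available from the shell:

```sh
gbmsurv simulate --out sim --seed 1
gbmsurv connectome --timeseries sim/timeseries --out connectomes.csv
gbmsurv run-all --seed 1 --out run_out
```

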