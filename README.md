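# lipotask

Multitask directed message-passing neural networks for lipophilicity
(logP / logD) prediction, with helper-task regularization,
similarity-biased dataset curation, ensemble uncertainty and
bootstrap-CI evaluation.

## Who this is for

Computational chemists and ML practitioners building octanol–water
partition (logP) and distribution (logD7.4) models from heterogeneous
measurement tables — several public and proprietary datasets for the same
or related endpoints — who want blind-challenge-realistic evaluation
rather than optimistic random splits.

## The model

The core is a **directed message-passing neural network (D-MPNN)** over
the molecular bond graph. Each bond contributes two directed edges
(v→w and w→v). Edge states are initialized from the source-atom and bond
features,

&nbsp;&nbsp;h⁰\_{vw} = ReLU(W\_in · [x\_v ; e\_{vw}]),

and updated for `depth` steps with the reverse edge excluded from the
incoming sum (the "directed" trick that stops messages bouncing straight
back):

&nbsp;&nbsp;m\_{vw} = Σ\_{u∈N(v)\\{w}} h\_{uv},&nbsp;&nbsp;
h\_{vw} ← ReLU(h⁰\_{vw} + W\_msg · m\_{vw}).

An atom readout sums incoming edge states, a pooled molecule vector feeds
a feed-forward head with one output per **task**. Tasks come in two
roles:

- **primary** — the endpoints the model reports (e.g. logP);
- **helper** — auxiliary columns that enter only the masked training
  loss: other datasets' measurements of related endpoints, or *another
  model's predictions* (e.g. a commercial logP/logD calculator). Helpers
  regularize the shared representation, are never emitted at prediction
  time, and are not needed once training ends — so arbitrarily slow or
  licensed helper predictors are tolerable.

Missing labels are handled by a masked mean-squared-error loss: a
molecule contributes to a task's loss only where a measurement exists.
Production models are **ensembles of N independently seeded networks**
(default 10); the prediction is the member mean and its uncertainty the
standard error of the mean (SEM) over members. Metrics (R², RMSE, MAE,
Spearman ρ) come with percentile-bootstrap 95% confidence intervals.

Dataset curation mirrors a blind challenge: test molecules are pool
members with maximum Tanimoto similarity (Morgan radius-3/2048
fingerprints, the ECFP\_6 convention) **> 0.25** to a reference set, and
training molecules with similarity **> 0.4** to any test molecule are
discarded, so no near-duplicates leak across the split. Scaffold-balanced
(Bemis–Murcko) and random splits are also provided.

The network, its analytic backpropagation, the Adam optimizer and the
warmup/decay learning-rate schedule are implemented in NumPy and verified
against finite differences and a dependency-free nested-loop oracle in
the test suite.

## Worked example

Train a three-member ensemble on synthetic molecules whose ground-truth
logP is additive over fragments (`examples/05_ensemble_sem.py`):

```
         id  ... sem_logp_observed
0  syn00157  ...          0.074108
1  syn00162  ...          0.176715
...
ensemble-mean RMSE: 0.513
mean member RMSE:   0.585 (the ensemble mean is never worse — Jensen's inequality)
median SEM: 0.153 — per-compound uncertainty from member disagreement
```

The ensemble mean improves on the average member, and the per-compound
SEM quantifies member disagreement. The matched-pair shift analysis
(`examples/06_metrics_and_shifts.py`) prints:

```
SM42-SM43: experimental shift +0.91, predicted +0.65
SM36-SM37: experimental shift -0.69, predicted +0.69
```

i.e. the logP change of a phenyl → *N*-dimethyl transformation is
captured for one matched pair of challenge compounds but predicted with
the wrong sign for the other — absolute errors and transformation shifts
are different questions, and the shift analysis separates them.

Other examples: `01` molecular graphs and fingerprints, `02` the
synthetic-data generator, `03` similarity-biased curation and scaffold
splits, `04` multitask training with helper tasks.

A thin CLI mirrors the pipeline
(`lipotask synth | curate | split | train | predict | evaluate`); run
`lipotask --help`.

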