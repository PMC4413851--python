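# sparsemotor

A threshold-linear neural-network simulator of sensorimotor transformation:
visually guided wrist movements under multiple forearm postures, learned by
gradient descent on the neuron-to-muscle map while the sparseness of the
population code is controlled by a single threshold parameter at fixed
metabolic cost.

## Model

Each of `N` neurons receives a visual target unit vector `v` and a
proprioceptive posture unit vector `p` through fixed random Gaussian weights
and fires

```
u_i = J_v[i]·v + J_p[i]·p − θ_i
A   = [u]_+ / ‖[u]_+‖        (so AᵀA = 1 on every trial)
```

The unit-norm constraint pins the squared-summed activity (metabolic cost)
at 1, so the threshold `θ` controls how many neurons participate without
changing the total activity budget. Muscle activity is `M = [W A]_+`, the
executed movement is `x = P_k' M` through posture-dependent pulling
directions, and `W` follows the gradient of the squared movement error
(plus an optional squared-muscle-activity penalty) with the rectification
masks applied — see `docs/learning_rule.md`. Rectified-tanh and shifted
logistic activations are available as variants, including comparison
networks where the sensory weights `J` adapt instead of (or along with) `W`.

Analyses: threshold sweeps of converged error and sparseness, PCA of the
condition-wise activity covariance, generalization to novel targets with
frozen weights, and per-neuron classification of tuning as additively vs.
multiplicatively posture-modulated.

## Command line

Every experiment is a subcommand of the `sparsemotor` CLI, configured by a
flat YAML file (unknown keys are rejected) plus a few overriding flags:

```sh
sparsemotor sweep --out runs/sweep --seed 1 --runs 10
sparsemotor train --config config.yaml --out runs/train
sparsemotor generalize --out runs/gen
sparsemotor pca --out runs/pca
sparsemotor tuning --neuron 12 --census --out runs/tuning
sparsemotor compare-nonlinear --neurons 200 --out runs/compare
sparsemotor sparseness-curve --out runs/curve
```

Each command writes CSV tables plus a `manifest.json` carrying the
effective configuration, its hash, the seeds, and the package version, so
any output can be regenerated from its manifest alone. Config keys mirror
`sparsemotor.config.ExperimentConfig` (e.g. `K`, `posture_angles`,
`n_neurons`, `theta`, `theta_heterogeneity_sd`, `activation`, `beta`,
`eta`, `lambda`, `n_trials`, `theta_grid`, `runs`, `seed`).

## Layout

| module | contents |
| --- | --- |
| `sparsemotor.task_model` | targets, postures, muscle pulling geometry, trial sampling, movement execution |
| `sparsemotor.neural_coding` | sensory weights, thresholds, rectified activations, normalization, sparseness |
| `sparsemotor.plasticity` | cost, gradient updates of `W` and `J`, the training loop |
| `sparsemotor.analysis` | theta sweeps, PCA spectra, generalization, tuning/modulation fits |
| `sparsemotor.validation` | finite-difference gradient oracle, frozen tiny fixtures |
| `sparsemotor.config` / `sparsemotor.cli` | strict flat YAML config and the experiment runner |
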