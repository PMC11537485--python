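# rtrbm — temporal assembly dynamics in binary spike rasters

Large-scale neural recordings are commonly decomposed into *neural
assemblies*: groups of neurons whose coordinated activity acts as one
functional unit. Static energy models such as the restricted Boltzmann
machine (RBM) capture which assemblies exist and how often they are
active, but say nothing about how assemblies drive each other over time.
This package implements the **recurrent temporal RBM (RTRBM)** pipeline
for exactly that question: given a binary neurons × time raster, it learns
both the assembly structure and a directed, signed assembly-to-assembly
interaction matrix, and it can identify the timescale on which those
interactions operate. It is written for computational neuroscientists
working with binarized population recordings (e.g. deconvolved calcium
imaging) or simulated rasters.

## Model

The static RBM places binary neurons `v ∈ {0,1}^Nv` and binary assembly
indicators `h ∈ {0,1}^Nh` in a bipartite energy model

    P(v, h) ∝ exp(bv·v + bh·h + hᵀ W v).

The RTRBM chains such models in time: the RBM at step *t* has its hidden
bias shifted by `U r[t−1]`, where

    r[t] = σ(W v[t] + bh + U r[t−1]),     r[1] = σ(W v[1] + binit)

is the mean-field assembly activation. The temporal weights `U` are
directed — `U[i,j] > 0` means assembly *j* excites assembly *i* one step
later. Training is contrastive divergence plus backpropagation through
time (gradients verified against finite differences of the exact
enumerated sequence likelihood on small models); generation and prediction
run the per-step Gibbs samplers described in `docs/methods.md`.

The package contains, as importable modules and CLI subcommands:

| piece | what it does |
|---|---|
| `model_core` | RBM energy/conditionals/Gibbs + exact enumeration oracles |
| `rbm_training`, `rtrbm_training` | CD and CD+BPTT trainers, transfer learning, assembly warm start |
| `simulator` | ground-truth generator: interacting assemblies, Poisson neurons, downsampling |
| `alignment` | permutation/sign matching of estimates to ground truth, cosine similarity |
| `evaluation` | moments, Spearman/bootstrap comparison, nMSE with naive/variance bounds, timescale scan |
| `clustering` | Ward clustering of `Û`, receptive-field extraction |
| `io`, `cli` | HDF5 rasters/checkpoints, run manifests, `rtrbm` command |

## Worked example

Simulate 10 interacting assemblies (200 neurons, ring coupling: assembly
*i* excites *i+1* and inhibits *i−1* at a one-step delay), fit an RTRBM
with the correlation-partition warm start, and compare the learned
temporal weights with the generator's:

```
$ rtrbm simulate --seed 7 --delay 1 --length 3000 -o sim/
wrote 200x3000 raster to sim

$ rtrbm train-rtrbm --data sim/raster.h5 --warm-start \
      --epochs 60 --lr 0.02 --n-hidden 10 --l1 1e-6 --seed 0 -o model/
trained RTRBM; final recon MSE 0.2548

$ rtrbm align --model model/model.h5 --ground-truth sim/ground_truth.h5 -o aligned/
cosine similarity (aligned U vs true U): 0.880

$ rtrbm cluster --model model/model.h5 --threshold 2.0 -o clusters/
6 clusters at threshold 2.0 (w_thr=2.9851)
```

Reading the numbers: the reconstruction MSE of 0.25 is the per-entry
disagreement of a one-sweep Gibbs reconstruction (chance level for this
raster is ≈ 0.45). The cosine similarity of 0.88 between the z-scored
aligned `Û` and the true `U` means the fitted temporal weights recover the
ring's excitation/inhibition pattern almost entirely — hidden units are
matched to assemblies through the learned `W` first, so the score is
invariant to the arbitrary ordering and possible sign inversion of hidden
units. The `cluster` step groups hidden units with similar incoming
temporal weights and writes their receptive fields (strongly connected
neurons) as CSV.

The same machinery identifies interaction timescales: generate data with a
delay of 4 steps, downsample by factors 1–10, train one model per rate
with an equal gradient budget, and the one-step-ahead normalized
prediction error is minimized at rate 4 (with a secondary dip at 8, the
delay's multiple) — see `rtrbm scan-timescale --help` and the
`timescale_scan` function.

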