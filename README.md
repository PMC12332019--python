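# qubofs

Mutual-information QUBO feature selection for small images, with
annealer-style problem reductions and decoder-based reconstruction
evaluation — entirely on classical, CPU-only tooling.

The pipeline selects `k` of `n` pixels by minimizing a binary-quadratic
objective assembled from information-theoretic statistics of a labelled
image dataset:

1. **Discretize** each pixel into 20 quantile bins.
2. **Score**: importance = MI(pixel, label) (negated, on the QUBO
   diagonal); redundancy = MI(pixel, pixel) (on the couplings).
3. **Constrain** the subset size, either with a quadratic penalty
   `alpha * (sum_i x_i - k)^2` (fully connected) or with a
   sparsity-preserving uniform diagonal offset `alpha_l` that is tuned until
   the solution has exactly `k` ones.
4. **Sparsify** for hardware-style budgets: keep the highest-importance
   pixel per non-overlapping 2x2 block (784 -> 196 variables on 28x28
   images) and keep only the 2000 largest-magnitude couplings.
5. **Solve** with in-repo classical solvers: exhaustive enumeration
   (ground-truth oracle for small `n`) or multi-restart simulated annealing
   (the stand-in for an annealer; lowest-energy read wins). External
   samplers can be slotted in through `qubofs.solvers.SOLVERS`.
6. **Evaluate** a selection by training a small convolutional decoder
   (linear -> ReLU -> two stride-2 transposed convolutions -> sigmoid;
   Adam, lr 0.001, 20 epochs, MSE) to reconstruct full images from the
   selected pixel values, reporting test-set MSE mean +/- std over repeats.

Baselines for benchmarking: random masks, evenly spaced grid masks,
L1-coefficient (Lasso-style) ranking, plus thin transformed-feature
comparators (sparse PCA, a learned linear-bottleneck autoencoder sharing
the decoder architecture).

Inputs are MedMNIST-v2-style NPZ archives (`{split}_images` /
`{split}_labels`, 28x28 grayscale; key names overridable) or synthetic
datasets with planted MI structure (class-informative pixels, redundancy
groups driven by shared latents, noise pixels), so every stage is testable
offline. The decoder is implemented directly on NumPy with hand-written
backprop, so no deep-learning framework is required.

## CLI

```sh
qubofs simulate-data --spec spec.yaml --out data.npz
qubofs build-qubo    --data data.npz --out qubo.json
qubofs sparsify      --data data.npz --couplings 2000 --out sparse.json --map-out map.json
qubofs solve         --qubo sparse.json --solver sa --k 25 --penalty linear --seed 1 --out mask.json
qubofs train-decoder --data data.npz --mask mask.json
qubofs benchmark     --config config.yaml --methods random,sampled,qubo_sparsified --out report.csv
```

`config.yaml` holds an `ExperimentConfig` (dataset source, `n_bins`, `k`,
constraint mode, sparsification settings, solver parameters, decoder
settings, repeats, master seed); `--seed` overrides the master seed. All
randomness is derived from explicit seeds, so runs are reproducible.

## Notes

- MI is estimated in nats; the log base only rescales the objective
  uniformly and cannot change its minimizer.
- The quadratic cardinality penalty is implemented as the algebraic
  expansion of `alpha * (sum_i x_i - k)^2` (diagonal `alpha * (1 - 2k)`,
  `2 * alpha` per unordered pair, constant `alpha * k^2`), the only form
  under which the penalty vanishes exactly at weight `k`.
- Linear-penalty tuning brackets then bisects the diagonal offset; if no
  offset yields weight `k` exactly (e.g. tied coefficients), the closest
  solution is greedily repaired and flagged as such in the result.
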