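# hopscape

Attractor-landscape analysis of connectome-coupled graded-response Hopfield
networks: deterministic and stochastic simulation of three threshold
variants, sampling-based reconstruction of the attractor landscape,
energy/entropy characterization, inclusion-match clustering of binary
activation patterns, and BOLD / functional-connectivity-dynamics (FCD)
analysis.

## Models

Each node `i` carries a potential `x_i` with graded output
`A_i = (1 + tanh(G(P x_i - theta_i))) / 2`, driven by
`tau_x dx_i/dt = -x_i + sum_j W_ij A_j` over a symmetric, non-negative,
unit-norm coupling matrix `W`. Three threshold schemes are supported:

- **SL** (static local): `theta_i` = half the node's row sum;
- **SG** (static global): a single threshold, the mean of the SL vector;
- **DG** (dynamic global): a single threshold relaxing toward the mean
  output, `tau_theta dtheta/dt = -theta + mean(A)`, which regulates the
  overall activity density.

Stochastic generalizations add white noise to the potentials and/or the
thresholds (Euler–Maruyama integration).

## Package layout

- `hopscape.connectome` — loading/saving TSV matrices (+ JSON label
  sidecars), unit-norm rescaling (Frobenius / spectral / max-row-sum),
  degree-preserving Maslov–Sneppen randomization, and a synthetic modular
  connectome generator so every stage runs without external data.
- `hopscape.dynamics` — model configuration, single-step and trajectory
  integration, batched relaxation with the relative equilibrium stop rule
  (100 ms window, 1e-6 tolerance, 1 s cap), random binary initial patterns.
- `hopscape.attractors` — random sampling-based attractor search with the
  double dissimilarity dedup rule (Pearson *and* Euclidean similarity
  below 0.9), potential-function and Ising-energy evaluation,
  Boltzmann–Gibbs probabilities/entropy, empirical entropy (bits), gain
  and (P, f0) sweeps, first-bifurcation detection.
- `hopscape.clustering` — binary patterns as active-node sets, inclusion
  match similarity, greedy agglomerative clustering, the double-pass
  (central-reference then majority-smoothing) protocol, cluster cores and
  match t-statistics.
- `hopscape.fcd` — damped-sinusoid hemodynamic kernel, BOLD
  reconstruction (100 Hz block average, causal convolution, 0.5 Hz
  decimation, mean removal), sliding-window FC, FCD matrices,
  attractor-based FC and masked FC comparison.
- `hopscape.cli` — `hopscape` command with subcommands
  `make-connectome`, `randomize`, `sample`, `sweep-g`, `sweep-pf`,
  `cluster`, `fcd`; YAML/JSON config files, flag overrides, and JSON run
  manifests for reproducibility.

## CLI examples

```sh
# synthetic modular connectome, 100 nodes
hopscape make-connectome --n 100 --modules 4 --seed 1 --out runs/conn

# attractor search on it (SL model, high gain)
hopscape sample --connectome runs/conn/connectome.tsv --model sl \
    --gain 900 --densities 0.02:0.03:0.98 --n-per-density 100 \
    --seed 1 --out runs/sample

# gain sweep and (P, f0) sweep
hopscape sweep-g --connectome runs/conn/connectome.tsv --g-grid 5:1:30 \
    --seed 1 --out runs/sweepg
hopscape sweep-pf --connectome runs/conn/connectome.tsv --model dg \
    --p-grid 0.5:0.5:4 --f0-grid 0.1:0.2:0.9 --seed 1 --out runs/sweeppf

# cluster an attractor container and a noisy FCD run
hopscape cluster --patterns runs/sample/attractors.tsv --k 0.8 \
    --core-fraction 0.1 --out runs/clusters
hopscape fcd --connectome runs/conn/connectome.tsv --model dg --gain 900 \
    --scale 0.75 --sigma-x 0.04 --sigma-theta 0.04 --duration-min 15 \
    --seed 1 --out runs/fcd
```

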