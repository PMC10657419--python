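# Full synthetic benchmark grid with the benchmark defaults.
# Runtime scales linearly in trials; reduce `trials` for a quick run
# (e.g. `swdl experiment --config configs/synthetic_benchmark.yaml --trials 2 --out out/`).
algorithms: [ssbss, acsd, swbdl, swsdl]
rho_grid: [4, 5, 6, 7, 8]
nt_grid: [0.3, 0.9]
trials: 150
base_seed: 0
n_subjects: 4
n_atoms: 9
ssbss:
  n_components: 9
  dct_rank: 150
  zeta1: 30
  lambda1: 6.0
  iters: 15
acsd_lambda: 12.0
acsd_iters: 15
swbdl:
  lambda2: 8.0
  alpha: 1.0
  beta: 1.0
  iters: 15
swsdl:
  lambda2: 16.0
  zeta2: 24
  zeta3: 24
  iters: 15
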