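# swdl — subject-wise dictionary learning for multi-subject fMRI

`swdl` decomposes each subject's fMRI data matrix **Y**<sub>m</sub> (N scans × V
voxels) into a dictionary of temporal atoms and a sparse spatial code while
borrowing statistical strength from every other subject in the group. It is
aimed at researchers analysing task or resting-state fMRI who want
subject-level time courses (TCs) and spatial maps (SMs) that remain comparable
— and assemblable — at the group level.

## The model

Each subject's data is represented through **multi-subject base matrices**

&nbsp;&nbsp;&nbsp;&nbsp;D<sub>m</sub> = D<sub>q</sub> A<sub>m</sub>,&nbsp;&nbsp;
X<sub>m</sub> = B<sub>m</sub> X<sub>q</sub>,&nbsp;&nbsp;
Y<sub>m</sub> ≈ D<sub>m</sub> X<sub>m</sub>,

where D<sub>q</sub> ∈ ℝ<sup>N×MP</sup> concatenates the temporal sources of all
M subjects and X<sub>q</sub> ∈ ℝ<sup>MP×V</sup> their spatial sources, both
extracted by a fast sparse spatiotemporal blind source separation step
(**ssBSS**: rank-K SVD features, orthonormal DCT-II temporal basis with an
ℓ0-sparse mixing, soft-thresholded spatial maps). Only the representation
matrices A<sub>m</sub> (MP × K) and B<sub>m</sub> (K × MP) are learned per
subject, with unit-norm effective atoms ‖D<sub>q</sub>a<sub>k</sub>‖₂ = 1:

* **swsDL** (sequential): per-atom rank-1 error-matrix updates with an
  adaptive per-entry soft threshold (λ₂/(2|ξ|)) and ℓ0-restricted least
  squares for the rows of B (‖b<sup>k</sup>‖₀ ≤ ζ₃) and columns of A
  (‖a<sub>k</sub>‖₀ ≤ ζ₂);
* **swbDL** (block): a full-matrix code threshold and least-squares B, then
  an ADMM dictionary update penalising the difference between the atom
  autocorrelation structure and its lag-1 delayed version
  (α‖D D<sup>T</sup> − D₀D₀<sup>T</sup>‖²), projected back into the base;
* **ACSD** (baseline): classical single-subject adaptive consistent
  sequential dictionary learning with rank-1 atom/code pair updates.

Group-level dynamics are obtained by matching each subject's atoms to
reference regressors (modeled hemodynamic responses for tasks, RSN templates
for rest) and taking the leading singular triplet of the averaged matched
rank-1 terms (task) or the mean absolute matched code rows (rest).

A Simtb-style synthetic generator reproduces the evaluation conditions: four
subjects, 300 scans (TR = 1 s), a 50 × 50 voxel grid, nine planted
spatiotemporal sources per subject with a 6/2/1 sharing pattern, Gaussian-blob
maps whose spread ρ controls spatial overlap, and a noisy linear mixture
Y = Σᵢ (tcᵢ + ψᵢ)(smⁱ + φⁱ) with temporal noise variance n_t and spatial
noise variance 0.01. Recovery is scored by absolute Pearson correlation with
ground truth (cTC/cSM) averaged over sources (mcTC/mcSM), subjects
(mmcTC/mmcSM) and trials.

## Worked example

```python
import numpy as np
from swdl import (SynthConfig, make_dataset, SsbssParams,
                  SparseSpatiotemporalBSS, assemble_bases,
                  SubjectwiseSequentialDL, SwsdlParams, evaluate_recovery)

ds = make_dataset(SynthConfig(rho=5.0), seed=7)     # 4 subjects, n_t = 0.3
rng = np.random.default_rng(7)
bases = assemble_bases([
    SparseSpatiotemporalBSS(sub, SsbssParams()).fit(rng=rng)
    for sub in ds.subjects
])
models = [
    SubjectwiseSequentialDL(sub, bases.D_q, bases.X_q, n_atoms=9,
                            params=SwsdlParams()).fit()
    for sub in ds.subjects
]
print(models[0].summary())
print(evaluate_recovery(models, ds.truths).summary())
```

Output:

```
swsdl subject-wise model
----------------------------------------
atoms (K):              9
base size (MP):         36
iterations:             15
final objective:        514447
code sparsity:          0.000
max |1 - ||D_q a_k||_2|: 4.44e-16

recovery report
----------------------------------------
subject 1: mcTC = 0.936, mcSM = 0.885
subject 2: mcTC = 0.922, mcSM = 0.864
subject 3: mcTC = 0.898, mcSM = 0.876
subject 4: mcTC = 0.910, mcSM = 0.832
mean over subjects: mmcTC = 0.917, mmcSM = 0.864
```

Each `mcTC`/`mcSM` is the mean absolute correlation between a subject's nine
recovered time courses / spatial maps and the planted ground truth; values
near 1 mean the subject-wise decomposition found the planted sources despite
the temporal noise and the overlap between activation blobs. `mmcTC`/`mmcSM`
average these over the four subjects.

## Command line

```bash
swdl simulate --subjects 4 --rho 5 --noise-var 0.3 --seed 7 --out data/
swdl ssbss --in data/sub-01.h5 --out sub-01-ssbss.h5
swdl fit --algo swsdl --in data/sub-01.h5 --bases bases.h5 --out model.h5
swdl evaluate --truth data/sub-01.h5 --models model.h5 --out report.json
swdl experiment --config configs/synthetic_benchmark.yaml --trials 2 --out out/
```

`swdl preprocess` additionally handles real 4-D NIfTI volumes (mask
reshaping, DCT high-pass, temporal Gaussian low-pass, column normalisation).

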