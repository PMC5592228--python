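# spinbath

Quantitative magnetization transfer (qMT) with a binary spin-bath model,
end to end: forward physics of the off-resonance saturation experiment,
synthetic brain phantoms, voxelwise model inversion, caudate ROI features,
and fuzzy-cluster stratification of subjects against their Huntington's
disease burden.

## The problem

Conventional magnetization transfer imaging summarizes tissue in a single
ratio (MTR), which confounds true magnetization exchange with relaxation.
Model-based MT instead fits the two-pool ("binary spin-bath") description of
tissue to a saturation spectrum acquired at several off-resonance
frequencies, separating the fundamental parameters: the restricted-to-free
pool size ratio **F** (a proxy for macromolecular load), the exchange rates
**kf**/**kr** (detailed balance, `kf = F·kr`), the restricted-pool **T2r**,
the free-pool **T2f**, and the free-pool spin density **SDf**.  In
Huntington's disease, macromolecular deposits accumulate in the caudate
nucleus long before atrophy is measurable, so these parameters — summarized
over the caudate and fed to a Gustafson–Kessel fuzzy clustering with a PCA
projection — can stratify healthy controls, premanifest mutation carriers,
and manifest patients along the disease burden score
`DBS = age × (CAG − 35.5)`.

The package is for imaging scientists who want a tested, reproducible
implementation of this chain, and for methodologists who need a synthetic
test bed: no clinical data ships with it; a first-class generator simulates
cohorts, ground-truth tissue, and noisy MT image stacks with the statistical
structure the analysis assumes.

## The model

For each saturation offset Δ the steady state of the coupled two-pool Bloch
equations under continuous-wave-power-equivalent irradiation ω₁ is

    Mf(Δ) = [R1f (R1r + kr + Wr) + kr R1r F]
            / [(R1f + kf + Wf)(R1r + kr + Wr) − kf kr]

with `Wr = π ω₁² g(Δ; T2r)` (Gaussian or super-Lorentzian lineshape `g`)
and `Wf = ω₁² T2f / (1 + (2πΔ T2f)²)`.  The measured signal is
`SDf · Mf(Δ)`; `MTR = 100·(M0 − M(1 kHz))/M0`.  Voxelwise inversion is a
bound-constrained Levenberg–Marquardt fit in log-parameter space; see
`docs/methods.md` for the full account, including the identifiability
analysis of exchange rates at a single saturation power.

## Worked example

```python
import numpy as np
from spinbath import (MTAcquisition, TissueParameters, steady_state_signal,
                      fit_voxel, mtr, disease_burden_score)

acq = MTAcquisition()  # 7 offsets, 1-16 kHz, Gaussian pulses, 540 deg
gm = TissueParameters(f=0.12, kr=20.0, t2r=10e-6, t2f=60e-3, t1f=1.2)

signal = steady_state_signal(gm, acq)
print("offsets (kHz):", [f/1000 for f in acq.offsets_hz])
print("Z-spectrum:   ", np.round(signal.normalized, 4))
print("MTR at 1 kHz:  %.1f%%" % mtr(signal.m0, signal.values[0]))

fit = fit_voxel(signal, acq, {"t1f": 1.2, "t2f": 60e-3})
p = fit.params
print("recovered: F=%.4f  kr=%.2f /s  T2r=%.2f us  (%d iterations)"
      % (p.f, p.kr, p.t2r * 1e6, fit.n_iter))
print("DBS(age 40, CAG 45.5):", disease_burden_score(40, 45.5))
```

prints

```
offsets (kHz): [1.0, 2.0, 4.0, 8.0, 10.0, 12.0, 16.0]
Z-spectrum:    [0.4855 0.5483 0.5705 0.5926 0.6062 0.6226 0.6638]
MTR at 1 kHz:  51.4%
recovered: F=0.1200  kr=20.00 /s  T2r=10.00 us  (16 iterations)
DBS(age 40, CAG 45.5): 400.0
```

The Z-spectrum is the normalized signal versus offset: deepest saturation
near resonance (0.49 at 1 kHz, i.e. MTR 51%), recovering toward 1 at 16 kHz.
The fit inverts that spectrum exactly on noiseless input, returning the
generating pool ratio, exchange rate, and restricted-pool T2.  The DBS value
is the cumulative-toxicity index used to rank clusters.

## The full pipeline

The cohort-level chain runs from the command line:

```bash
spinbath all --out artifacts/ --seed 1 -v          # simulate -> report
spinbath cluster --out artifacts/ --config my.json # re-run one stage
```

Stages: `simulate` (cohort CSV + NIfTI stacks, masks, relaxometry maps),
`fit` (voxelwise parameter maps over the caudate masks), `mtr`
(whole-volume MTR maps), `extract` (10-feature subject matrix: T2f, SDf,
kf, kr, T2r × left/right caudate, z-scored), `cluster` (Gustafson–Kessel
with 6 clusters, PCA scores and factor loadings), `report`
(disease-burden-ranked cluster report, group summary table, score and
biplot figures).  Every stage writes a manifest with the config hash and
seeds; identical configs reproduce byte-identical CSV/JSON artifacts.

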