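# glucocest

A Python toolkit for glucose-weighted chemical exchange saturation transfer
(glucoCEST) MRI of the rodent brain. It covers the full in-silico pipeline of
a preclinical dynamic glucose-enhancement study:

- **Forward simulation** — multi-pool Bloch–McConnell modeling of
  continuous-wave saturation experiments (phantom tubes of glucose and other
  metabolites; saturation power / duration / TR optimization series).
- **Z-spectrum processing** — normalization by the unsaturated reference,
  B0 correction from the direct-saturation minimum, and asymmetry analysis
  `MTRasym(0.9 ppm) = [Ssat(−0.9 ppm) − Ssat(+0.9 ppm)] / S0`.
- **Dynamic glucoCEST enhancement (GCE)** — voxelwise MTRasym maps over a
  seven-timepoint glucose-infusion protocol and the enhancement map
  `GCE = mean(map@40 min, map@post-10 min) − map(baseline)`, with ROI time
  courses for total brain, bilateral hippocampus and parietal cortex.
- **DTI maps** — exact log-linear tensor fit from S0 + 6-direction DWI and
  derived ADC (mean diffusivity) and FA maps.
- **Synthetic cohorts** — a seeded generator that emulates an AD-vs-control
  infusion study (n = 6 + 6, animal-level random effects, B0 fields, noise,
  a myo-inositol value linked linearly to each animal's true GCE), so every
  downstream stage is testable without scanner data.
- **Group statistics** — the small-sample decision flow (1.5×IQR outlier
  screening, Shapiro–Wilk + Levene gating into a t-test or Mann–Whitney U)
  and OLS regression for GCE–metabolite associations.

Audience: researchers prototyping or validating CEST/glucoCEST processing
chains, and anyone needing a reproducible, fully synthetic test bed for
dynamic CEST analysis code.

## The model in brief

Each exchanging proton species is a pool with chemical shift Δᵢ, fraction
fᵢ, exchange rate kᵢ and relaxation times T1ᵢ/T2ᵢ. Magnetization evolves
under the Bloch–McConnell equations `dM/dt = A M + b` in the RF rotating
frame, solved exactly per interval via the matrix exponential
`M(t) = M_ss + e^{At}(M₀ − M_ss)`. One repetition is modeled as readout
(spoiled) → recovery for `TR − t_sat` → CW saturation for `t_sat` → readout,
and the Z-spectrum is the readout ratio against the same cycle at the far
off-resonance reference (10 kHz). Hydroxyl exchange is base-catalysed:
`k(pH) = k_ref · 10^(pH − pH_ref)`.

## Worked example

```python
import numpy as np
from glucocest import (glucose_phantom_system, phantom_scheme,
                       simulate_zspectrum, sweep, mtr_asym_at)

system = glucose_phantom_system(25.0, ph=7.4)     # 25 mM D-glucose tube
scheme = phantom_scheme()                          # B1 1.5 uT, t_sat 5 s, TR 5.04 s
spec = simulate_zspectrum(system, scheme)
print(f"MTRasym(0.9 ppm) = {100 * mtr_asym_at(spec):.1f} %")

conc = sweep(system, scheme, "concentration", [25, 50, 75, 100])
print(np.round(100 * np.asarray(conc.mtr_asym), 1))
```

prints

```
MTRasym(0.9 ppm) = 9.9 %
[ 9.9 16.4 20.7 23.4]
```

i.e. a ~10% glucoCEST effect for the 25 mM tube at pH 7.4 that grows,
sublinearly, to ~23% at 100 mM — the saturation-transfer effect scales with
the exchangeable hydroxyl proton pool but saturates as the labeling and
spillover budgets are exhausted.

The same workflow runs from the shell:

```bash
glucocest synth cohort --seed 7 --out cohort/          # 6+6 synthetic animals
glucocest gce run --cohort cohort/ --out gce/          # GCE maps + tidy table
glucocest stats compare --input gce/cohort_table.csv \
    --value-col gce --roi total_brain                  # gated group test
```

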