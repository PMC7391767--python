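# patchkit

Ligand-gating analysis for ion-channel electrophysiology: a Python library
that takes patch-clamp observables — concentration–response curves,
single-channel current traces, stationary macroscopic currents and
fluorescence emission spectra — and turns them into the thermodynamic and
kinetic quantities that describe how a partial agonist binds to and opens a
channel. It was built around the menthol/TRPM8 style of study, where a
ligand with maximum open probability below 1 lets binding and gating be
separated quantitatively, but every operation is generic to the two-state
analysis framework.

## What it computes

**Gating decomposition.** For the scheme `C0 ⇌(Kd) C1 ⇌(L) O`, a fitted
Hill curve with midpoint EC50 and plateau Po_max decomposes as

    EC50   = Kd / (1 + L)        Po_max = L / (1 + L)

so `Kd` (binding) and `L` (the final closed→open equilibrium) follow from a
single curve whenever Po_max < 1.

**Mutant-cycle coupling.** From the four dissociation constants of a
WT/mutant × ligand/analog design,

    LnΩ = Ln( Kd₁·Kd₄ / (Kd₂·Kd₃) )

with coupling energy |LnΩ|·kT; couplings above 1.5 kT (0.89 kcal/mol at
24 °C) indicate a specific short-range interaction.

**Single-channel kinetics and Φ analysis.** Half-amplitude idealization
with retrospective dead-time imposition (default 0.32 ms), exponential-MLE
opening/closing rates (β = 1/mean closed dwell, α = 1/mean open dwell), open
probability from event durations, and the Brønsted slope
Φ = d log₁₀β / d log₁₀K across mutations at one site — the fraction of a
mutation's energetic effect already expressed at the transition state.

**Stationary noise analysis.** `N = I²/(i·I − σ²)` from the mean and
variance of a steady current given the unitary current i, with
`Po = I/(N·i)`.

**Emission-peak shifts.** Skewed-Gaussian (exponentially modified Gaussian)
fits to fluorescence spectra; the ligand-minus-control mode difference is
classified as red/blue/no-change against a 2 nm detection limit.

**Synthetic data.** Every input class has a seeded generator that carries
its ground truth (two-state Gillespie traces at 10 kHz with a 2.9 kHz
low-pass stage, binomial multichannel patches, Hill-shaped dose–response
replicates, exactly collinear Brønsted mutant series, skewed emission
bands), so the whole chain is testable without recordings.

## Worked example

```python
import numpy as np
import patchkit as pk
from patchkit.dose_response import ConcentrationResponse

g_true = pk.decompose_gating(185.4, 0.81)            # Kd 975.8 uM, L 4.26
conc = np.geomspace(18.5, 1854.0, 8)
ds = pk.simulate_dose_response(g_true.k_d, g_true.l_eq, 1.74, conc,
                               noise_sd=0.02, n_replicates=5, seed=42)
fit = pk.fit_hill(ConcentrationResponse(ds.concentrations, ds.responses))
g = pk.decompose_gating(fit.ec50, fit.response_max)
print(fit.ec50, fit.hill_n, fit.response_max, g.k_d, g.l_eq)
```

prints (seed 42)

```
184.9 1.69 0.81 992.9 4.37
```

i.e. from a 5-replicate noisy experiment the fitted EC50 (184.9 µM), Hill
coefficient (1.69) and Po_max (0.81) recover the generating values, and the
decomposition returns the binding constant (993 µM vs true 976) and gating
equilibrium (4.37 vs true 4.26). The `examples/` directory holds one short
narrative script per capability (gating decomposition, mutant cycle,
single-channel Φ, noise analysis, emission shifts, and the full pipeline on
a generated study).

## Command line

A thin CLI wraps the library for shell use:

```bash
patchkit demo --seed 7 --out-dir study        # complete synthetic study + truth
patchkit report study/manifest.json --out-dir study/report --seed 7
patchkit decompose --ec50 185.4 --po-max 0.81
patchkit noise study/patch.f32 --unitary-current 1.0
```

Exit codes: 0 success, 2 validation error, 1 internal failure.

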