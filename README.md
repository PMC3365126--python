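# prestinmem

Electro-viscoelastic constitutive modeling of prestin-containing cell
membranes: power-law (springpot) viscoelastic kernels for the cylindrical
outer-hair-cell composite wall and the isotropic spherical transfected-cell
membrane, coupled to an RC-type prestin charge-transfer kernel. The package
computes the derived responses:

- **Isometric active force** versus frequency (normalized amplitude and
  phase), including the near frequency-invariance over 1–80 kHz produced by
  the cancellation between the growing viscoelastic numerator and the
  growing prestin (low-pass) denominator, and a Kelvin–Voigt comparison
  mode (ν = 1) that instead rises markedly with frequency.
- **Charge time courses** under voltage clamp for step pressure, constant-
  rate pressure, and constant-rate axial strain (volume-conserving
  cylinder), with closed forms cross-validated against a brute-force
  convolution oracle.
- **Parameter estimation**: least-squares fits of (η, ν) to normalized
  force-amplitude sweeps (log-log residuals, multi-start) and of τ_e to
  charge-transfer filter amplitude surfaces, plus seeded synthetic-data
  generators for both.

## Library quick start

```python
import numpy as np
from prestinmem import default_ohc_params
from prestinmem.frequency_response import isometric_force
from prestinmem.charge_dynamics import charge_step_pressure

params = default_ohc_params()          # nu = 0.7, tau_e = 5 us, ...
omega = 2 * np.pi * np.logspace(3, np.log10(8e4), 200)
resp = isometric_force(params, omega)  # amplitude_norm ~ 1 across the band

t = np.linspace(1e-7, 5e-5, 500)
tc = charge_step_pressure(params, dP0=100.0, t_grid=t)  # builds with tau_e
```

Every numeric default carries a source annotation:
`prestinmem.parameters.citation("tau_e")`.

## Command line

```bash
prestinmem params show --geometry cylinder       # defaults + citations
prestinmem force --fmin 10 --fmax 1e5 -n 200 --model power_law --out sweep.csv
prestinmem force --model kelvin_voigt --eta-kv 1e-6 --out sweep_kv.csv
prestinmem charge --loading step_pressure --dP0 100 --tmax 50e-6 -n 500 --out q.csv
prestinmem kernels eval --kind relaxation --out E.csv
prestinmem synth force --noise 0.05 --seed 42 --out synth.csv
prestinmem fit force --data synth.csv --out fit.json
```

Every command that writes output also writes a `<output>.run.json` record
(command line, config hash, seed, version, timestamp); re-running a
stochastic command with the recorded seed reproduces the output
bit-identically.

### Config schema (JSON)

```json
{
  "geometry": "cylinder",
  "mechanical": {"C11": 0.075, "C12": 0.07, "C22": 0.19,
                 "eta": 1.1e-05, "nu": 0.7, "r_c": 5e-06},
  "electrical": {"tau_e": 5e-06, "C_sp": 0.01},
  "coupling": {"alpha1_Csp": -0.10, "alpha2_Csp": 0.03}
}
```

For `"geometry": "sphere"`, `mechanical` carries `K` instead of the
`C_ij` and `coupling` carries a single `alpha_Csp`. All values are SI; an
optional `"units"` mapping (e.g. `{"tau_e": "us", "r_c": "um"}`) declares
per-field convenience units converted on load. Example configs are under
`examples/`.

Sweep CSVs use columns `freq_hz, amplitude_norm[, phase_rad]`; charge
time-course CSVs use `t_s, q_C_per_m2` (units repeated in a `#` header).

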