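# permwalk

Random-walk and semi-analytical solvers for one-dimensional diffusion across
semi-permeable membranes separating compartments of differing diffusivity.

Monte Carlo random walks are the workhorse for simulating diffusion-weighted
MRI (DWI) in tissue: an ensemble of walkers explores a geometry of cells and
interstitium, and the phase they accrue in a diffusion-encoding gradient
predicts the measured signal. In cardiac DWI the diffusion time is of order
1 s, so water exchanges across cardiomyocyte membranes many times during an
experiment and the membranes cannot be treated as impermeable. The numerical
difficulty sits exactly at those membranes: when a semi-permeable barrier
also separates compartments of different diffusivity, the standard transit
rule becomes biased unless the time step is made impractically small.

`permwalk` implements and cross-validates two membrane transit rules for
walkers taking fixed steps `δx = ±√(2 D_i δt)`:

* **reference model** — a walker at distance `δx_i` from a membrane with
  permeability `κ` crosses with probability

      p_ref = 2 κ δx_i / (D_i + 2 κ δx_i)

  applied directly at the membrane. Accurate for `D_i = D_j`, but with a
  diffusivity step it requires `p_ref < 0.01`, i.e. time steps down to
  ~0.002 ms for tissue-like parameters, and at practical step sizes it
  accumulates walkers on the slow side of the interface.

* **hybrid model** — the membrane and the diffusivity step are treated as
  two interactions separated by an infinitesimal gap, with the membrane on
  the slow-diffusivity side:

      p_hyb(i→j) = p_b · p_d,   p_d = min(1, √(D_j / D_i))

  where `p_b` is the membrane factor evaluated in the slow medium (for a
  walker arriving from the fast side its incident distance is first rescaled
  onto the slow side, giving `p_b = 2κδx_i / (√(D_i D_j) + 2κδx_i)`). This
  factorization satisfies detailed balance at uniform density for every κ,
  reduces to the reference rule when the diffusivity is continuous, and to
  the classical `√(D_j/D_i)` acceptance for a bare diffusivity step as
  κ → ∞ — so it lifts the step-size restriction.

Both are validated against two independent solvers of the same
initial-value problem `∂U/∂t = D_i ∂²U/∂x²` with interface condition
`D_i ∂U/∂x|_L = D_j ∂U/∂x|_R = κ (U|_R − U|_L)` and sealed ends:

* an **eigenmode expansion** (`permwalk.eigen`): the propagator
  `U(x,t) = Σ_n e^{−λ_n t} ν_n(x) ν_n(x₀)` with piecewise-trigonometric
  modes, eigenvalues located as roots of a transfer-style characteristic
  function;
* a **conservative finite-volume solver** (`permwalk.fd_oracle`,
  Crank–Nicolson).

On top of these sit membrane-flux analytics (instantaneous, time-averaged
and cumulative flux, with endpoint and time-integrated error metrics), a
histology-based domain synthesizer (alternating cell/interstitium
compartments drawn from measured cell-area statistics), and narrow-pulse DWI
signal and ADC computation
(`S_rw = |⟨e^{−iq·Δx}⟩|`, `S_ana = (ΣL)⁻¹ Σ_n e^{−λ_n Δ} |∫ ν_n e^{iqx}|²`,
`ADC = −ln(S)/b` with `b = q²Δ`).

Units everywhere: µm, ms, µm²/ms (diffusivity), µm/ms (permeability).

## Worked example

The benchmark throughout is a two-compartment domain: two 20 µm
compartments with `D_L = 0.5`, `D_R = 2.5` µm²/ms and a membrane with
`κ = 0.05` µm/ms at x = 20 µm.

```python
import numpy as np
from permwalk import (build_domain, find_eigenvalues, analytical_flux,
                      numerical_flux, endpoint_relative_error, peak_time,
                      SimConfig, run_simulation, steady_density)

domain = build_domain(lengths=[20, 20], diffusivities=[0.5, 2.5],
                      internal_permeabilities=[0.05])
spectrum = find_eigenvalues(domain, lam_max=500.0, n_max=1000)

times = np.arange(1.0, 1001.0)
ana = analytical_flux(spectrum, interface=1, times=times,
                      initial=("delta", 10.0))
print(f"steady density       : {steady_density(domain):.4f} /um")
print(f"analytical peak time : {peak_time(ana):.2f} ms")

seeding = ("uniform", (0.0, 20.0))
config = SimConfig(dt=2.0, T=1000.0, Np=100_000, seed=42, model="hybrid",
                   seeding=seeding, record_flux=True)
result = run_simulation(domain, config)
num = numerical_flux(result.ledger, config.Np, config.dt, interface=1)
ana_grid = analytical_flux(spectrum, 1, num.times, seeding)
print(f"cumulative flux at T : {num.cumulative[-1]:.4f} "
      f"(analytical {ana_grid.cumulative[-1]:.4f})")
print(f"hybrid endpoint error: "
      f"{100 * endpoint_relative_error(num, ana_grid):+.2f} %")
```

prints

```
steady density       : 0.0250 /um
analytical peak time : 58.54 ms
cumulative flux at T : 0.4650 (analytical 0.4657)
hybrid endpoint error: -0.15 %
```

Reading the numbers: the uniform long-time density is `1/ΣL = 0.025` µm⁻¹;
a walker packet released at the centre of the left compartment drives a
membrane flux that peaks 58.5 ms in; walkers released uniformly on the left
transfer 46.5% of the ensemble across the membrane by t = 1 s (on the way to
the 50% equilibrium split), and the hybrid Monte Carlo run reproduces the
eigenmode cumulative flux to a fraction of a percent at a 2 ms step —
a step three orders of magnitude above the reference model's
`p < 0.01` limit (≈0.0026 ms here, see `max_timestep_reference`).

The same workflow is scriptable from the shell:

```sh
permwalk synth-domain --seed 1 --out domain.yaml
permwalk eigen --domain domain.yaml --lmax 500 --nmax 1000 --out spectrum.json
permwalk simulate --domain domain.yaml --model hybrid --dt 1.5 --t 1000 \
    --np 1000000 --seed 1 --seeding delta:24.75 --out run
permwalk flux --domain domain.yaml --spectrum spectrum.json --dt 0.5 \
    --t 1000 --np 100000 --seeding interval:0,20 --out flux.csv
permwalk reproduce steady_state --np 100000 --out steady.csv
```

`permwalk reproduce {steady_state,step_size,perm_sweep,histology,dwi_sweep}`
runs the named experiment grids (step-size sweeps, permeability ×
diffusivity-ratio sweeps, histology-domain transients, DWI permeability
sweeps) and writes tidy CSV tables of the error metrics.

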