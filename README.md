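# hexkin

Single-particle kinetics of insulin hexamer self-assembly from TIRF
microscopy movies.

Insulin is stored and injected as a hexamer but acts as a monomer, and the
monomer–dimer–tetramer–hexamer equilibrium governs how fast a formulation
becomes active.  Surface-immobilized, fluorescently labeled insulin imaged
by total internal reflection fluorescence (TIRF) microscopy makes the
assembly process directly observable: each particle's photon count jumps in
steps of one monomer-equivalent (~46 photons) as species from solution bind
and unbind.  `hexkin` turns such movies — or fully synthetic ones with
known ground truth — into a complete kinetic and thermodynamic description:

1. **Camera calibration** — the pixel-count noise of an EMCCD on a
   particle-free stack follows a Poisson⊛Erlang mixture
   `p(s|s0, γ, E) = δ(s−s0)e^−E + √(γE/x)·e^(−γx−E)·I₁(2√(γEx))`,
   `x = s−s0`; a χ² fit per pixel yields the offset `s0` and inverse gain
   `γ`, and counts convert to photons by `n = (s−⟨s0⟩)·⟨γ⟩`.
2. **Illumination correction and photometry** — the Gaussian excitation
   profile is estimated from the smoothed time average and divided out;
   spots are detected on the time average, refined by 2-D Gaussian fits,
   and integrated in a 9-pixel-diameter ROI with baseline subtraction
   (`f = Σ s − b·N_pixels`).
3. **Trace idealization** — a seven-state hidden Markov model (background
   S0 plus monomer S1 … hexamer S6, frozen Gaussian emissions at
   20/50/100/150/200/250/300 photons) is fit per trace and Viterbi-decoded.
4. **Dwell-time kinetics (CHESS)** — every state change is a transition;
   per (before → after) cluster, the exponential maximum-likelihood rate is
   1/mean(dwell) (dwells > 75 s excluded).  Dissociation rates are reported
   in s⁻¹; association decay rates are divided by the solution
   concentration of the added species (estimated from a five-Gaussian fit
   of the assembly-step histogram) to give bimolecular constants in
   M⁻¹s⁻¹.  The CHESS table (Complete HEatmap of State transitionS)
   collects densities, rate constants and errors for all transitions.
5. **Thermodynamics** — `K_eq = k_ij/k_ji`, `ΔG = −RT ln K_eq`, and the
   transition-state barrier `ΔG‡ = −RT ln(h·k/(k_B·T))` at `T = 298 K`.
6. **Mass-action extrapolation** — the measured constants drive an ODE
   model of assembly in solution (monomer additions, dimer + dimer,
   dimer + tetramer); endpoint oligomer fractions across a concentration
   sweep are summarized by the Hill equation
   `f(x) = B_max·x^n_h/(K^n_h + x^n_h)` whose `K` is the apparent hexamer
   affinity.

A first-class synthetic-data module generates ground-truth state paths
(exact Gillespie simulation), photon traces with the acquisition's
50 ms exposure / 150 ms frame structure, and full camera movies with
realistic EMCCD noise — so every stage of the pipeline is verified by
parameter recovery.

## Worked example

Recover planted rate constants from synthetic traces (10 nM free monomer,
association 5×10⁶ M⁻¹s⁻¹, dissociation 0.05 s⁻¹):

```python
import numpy as np
from hexkin import (SurfaceKineticModel, MovieConfig, simulate_state_path,
                    render_photon_trace, fit_hmm, extract_transitions,
                    build_chess, SolutionComposition, free_energy,
                    equilibrium_constant)
from hexkin.imaging import PhotonTrace

c1 = 10e-9                        # 10 nM free monomer in solution
model = SurfaceKineticModel(
    assoc_rates={(1, 2): 5e6},    # monomer addition, 1/M/s
    dissoc_rates={(2, 1): 0.05},  # monomer loss, 1/s
    solution_conc={1: c1})
cfg = MovieConfig(shape=(4000, 32, 32))   # 4000 frames at 0.15 s/frame

rng = np.random.default_rng(0)
idealized = []
for i in range(60):
    path = simulate_state_path(model, 1, 601.0, seed=int(rng.integers(2**31)))
    photons = render_photon_trace(path, cfg, seed=int(rng.integers(2**31)))
    idealized.append(fit_hmm(PhotonTrace(particle=None, photons=photons),
                             trace_id=i))

records, clusters = extract_transitions(idealized)
comp = SolutionComposition(weights={1: 1.0, 2: 0, 3: 0, 4: 0, 5: 0},
                           concentrations={1: c1, 2: 0, 3: 0, 4: 0, 5: 0},
                           total_monomer_equiv=c1)
chess = build_chess(clusters, comp, seed=0)
for r in chess.itertuples():
    if r.defined:
        print(f"S{r.state_before}->S{r.state_after}: k = {r.rate_constant:.3g} "
              f"({'per M per s' if r.kind == 'assembly' else 'per s'}), "
              f"n = {r.n_dwells}")
k12 = chess.query("state_before==1").iloc[0].rate_constant
k21 = chess.query("state_before==2 and state_after==1").iloc[0].rate_constant
K = equilibrium_constant(k12, k21)
print(f"K_eq = {K:.3g} per M, dG = {free_energy(K)/1e3:.1f} kJ/mol")
```

Output:

```
S1->S2: k = 5.11e+06 (per M per s), n = 754
S2->S1: k = 0.0532 (per s), n = 771
K_eq = 9.62e+07 per M, dG = -45.5 kJ/mol
```

The association constant comes back within 2 % and the dissociation
constant within 7 % of the planted values from ~750 dwells each; the
equilibrium constant of ~10⁸ M⁻¹ corresponds to a binding free energy of
−45.5 kJ/mol.

The same analysis runs from the shell on TIFF stacks:

```bash
hexkin calibrate --control control.tif --out camera.json --n-pixels 400 --seed 1
hexkin locate    --movie movie.tif --camera camera.json --out locations.csv
hexkin trace     --movie movie.tif --camera camera.json \
                 --locations locations.csv --out traces.csv
hexkin qc        --traces traces.csv --out traces_qc.csv
hexkin hmm       --traces traces_qc.csv --out idealized.csv
hexkin kinetics  --idealized idealized.csv --conc 10e-9 --out chess.csv
hexkin ode       --scheme scheme.json --out fractions.csv
hexkin run       --config experiment.yaml   # the whole pipeline
```

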