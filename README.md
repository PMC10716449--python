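# smtrace

Simulation and analysis of single-molecule fluorescence time traces, built
around the measurements used to characterize centromeric (CENP-A
containing) chromatin and its interaction with the centromere-binding
protein CENP-B:

* **smFRET of immobilized chromatin fibers** — donor/acceptor traces with
  alternating direct acceptor excitation (ALEX), corrected FRET
  efficiencies, trace selection, population histograms with
  Gaussian-mixture fits, and donor–acceptor cross-correlation analysis of
  seconds-scale conformational exchange.
* **Colocalization binding kinetics** — bright/dark dwell times of a
  labeled DNA-binding protein at immobilized DNA or chromatin positions,
  with bi-exponential residence-time fits and mono-exponential on-rate
  fits.
* **FRAP in cells** — double-normalized recovery curves and
  single-exponential fits yielding a recovery lifetime and an immobile
  fraction.

Every analysis stage can be exercised end to end against the built-in
simulator (`smtrace.simkit`), which generates kinetic state trajectories
(Gillespie), rendered camera traces with photobleaching and EMCCD-like
noise, binding timelines, FRAP curves, and two-channel TIRF movies — all
seeded, with ground truth retained.

## The quantities at the core

FRET efficiency per frame, corrected for donor bleed-through β and
detection sensitivity γ:

    E_FRET = (F_A − β F_D) / (F_A − β F_D + γ F_D),
    β = F_A,Donly / F_D,Donly,   γ = ΔF_A,bleach / ΔF_D,bleach

with default calibration β = 0.071, γ = 0.463. Efficiency histograms
(bin width 0.02) are fitted with Σᵢ Aᵢ exp(−((x − cᵢ)/σᵢ)²).

Conformational exchange is read out from the averaged donor–acceptor
cross-covariance CC(τ) = ⟨δF_D(t) δF_A(t+τ)⟩/(σ_D σ_A), fitted with
−a·exp(−τ/τ_R) + c; for two-state exchange τ_R = 1/(k₁₂ + k₂₁).

Bright-time survival curves follow y = Σᵢ Aᵢ exp(−t/τ_off,i) (i = 1, 2);
dark times follow y = A exp(−t·k_on,app). FRAP recovery follows
R(t) = M·(1 − exp(−t/τ)) with immobile fraction 1 − M.

## Worked example

Simulate 200 chromatin-fiber FRET traces switching between an open
(E = 0.1) and a compacted (E = 0.5) conformation with a 1.69 s relaxation
time, then recover the exchange timescale from the cross-correlation:

```python
import numpy as np
from smtrace import simkit, fretkit

k = 1 / (2 * 1.69)   # symmetric two-state rates for tau_R = 1.69 s
scheme = simkit.KineticScheme.two_state(0.1, 0.5, k, k)
photo = simkit.PhotophysicsParams()               # 3000 counts/frame
sched = simkit.IlluminationSchedule.uniform(600)  # 60 s at 100 ms frames

seeds = np.random.SeedSequence(7).generate_state(1000) % 2**31
traces = []
for i in range(200):
    path = simkit.simulate_ctmc(scheme, sched.duration, seed=int(seeds[2*i]))
    sim = simkit.render_fret_trace(path, photo, sched, scheme.efret_means,
                                   seed=int(seeds[2*i+1]))
    traces.append(fretkit.FretTrace.from_simulated(sim))

fit = fretkit.cross_correlate(traces, gate=0.2, max_lag_s=10.0)
print(f"traces analyzed: {fit.n_traces}")
print(f"relaxation time tau_R = {fit.tau_R:.2f} +/- {fit.tau_R_stderr:.2f} s")
```

prints

```
traces analyzed: 123
relaxation time tau_R = 1.72 +/- 0.01 s
```

123 of the 200 traces pass the E_FRET > 0.2 gate (the rest sit in the
zero-FRET population or bleach too early), and the fitted relaxation
time recovers the 1.69 s ground truth to within 2%.

The same workflows are available from the shell; each subcommand is a
thin wrapper over the library:

```sh
smtrace simulate --config frap.yaml --out sim/ --seed 1
smtrace analyze-frap --curves sim/frap_curves.csv --out fit.json
smtrace extract --movie sim/movie.tiff --out traces.csv
smtrace analyze-kinetics --trace sim/binding_trace.csv --out kin/
smtrace analyze-fret --traces sim/ --out fret/
```

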