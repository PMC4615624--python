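# stochmi

Time-dependent mutual information in stochastic biochemical networks, and
how cell-to-cell variability depresses it.

Population-level mutual-information (MI) estimates from single-cell
snapshot data are often surprisingly low.  Two mechanisms can make them
under-read the fidelity of individual cells: spread in the cells' initial
states, and slow extrinsic ("global") fluctuations - e.g. cell-to-cell
differences in translation capacity - that make every cell its own channel.
`stochmi` provides the full computational machinery to study this in two
model systems (a simple signaling cascade and an estradiol-inducible
synthetic transcription circuit in yeast):

* **Reaction-network models** with printed parameter sets: the cascade
  (input-activated conversion Y1* -> Y1 driving transcription of My2 and
  translation of Y2), optionally coupled to a birth/death global variable G
  with mean gbar = beta_g/gamma_g that multiplies all translation rates by
  G/gbar, and the synthetic circuit (ADH1-driven factor plus fluorescent
  reporter Y1r, GAL10-driven output Y2) in global and purely intrinsic
  parameterizations.
* **Two-moment closure of the chemical master equation**: propensities are
  expanded to first order about the mean, giving dz/dt = S^T a(z) for the
  means and dC/dt = A C + C A^T + B for the covariance (A = S^T J(z),
  B = S^T diag(a) S), integrated stiffly or solved at stationarity via the
  Lyapunov equation.
* **Distribution reconstruction** by the negative-binomial/normal rule
  (NB when mu < 3 sqrt(C), moment matched; normal otherwise; Poisson on the
  NB boundary).
* **Mutual information** I(x+; y, t) of the step-dose -> snapshot channel
  (uniform input over the dose range, moments linearly interpolated between
  sampled doses), plus joint MI over [y1r, y2], the chain rule
  I(x;[y1 y2]) = I(x;y1) + E[I(x;y2|y1)], slow-variable conditioning
  I(x;[y,G]) = E_G[I(x;y|G)], the response-diversity metric I(y; G, t | x),
  reporter mean-equalization, and the geometric-extrapolation rule for
  choosing the number of dose experiments N.
* **An exact Gillespie simulator** (numba-accelerated) as the brute-force
  oracle for every moment and distribution claim.
* **A synthetic flow-cytometry generator**: per-cell two-channel
  fluorescence tables for the 12-well estradiol protocol
  (100*(2/3)^(c-1) nM) at t = 0, 65, 165, 330, 580 min with >= 3000 cells
  per well, autofluorescence background, and slow-global / fast-global /
  intrinsic generating variants - plus a classifier that recovers the
  variability regime from the dose-response summary statistics.

## Worked example

```python
import stochmi as sm

# slow-global-fluctuation circuit (gbar = 42, gamma_g = 3e-6 /s)
net = sm.build_synthetic_circuit(sm.load_table("table2"), "global")
protocol = sm.StepInputProtocol.estradiol_12()
times = [0, 65, 165, 330, 580]

# measured-fluorescence channel: model moments + autofluorescence background
from stochmi import cytometry
bg = cytometry.default_background("SGF")

pop = sm.make_initial("heterogeneous", net)
surf = sm.build_surface(net, protocol.doses, times, pop, ["Y2"])
surf = sm.add_measurement_background(surf, {"Y2": (bg.y2_mean, bg.y2_sd)})
print(sm.mi_curve(surf).to_frame())
```

```
   time_min      conditioning observables      bits
0       0.0  heterogeneous+bg          Y2  0.000000
1      65.0  heterogeneous+bg          Y2  0.331814
2     165.0  heterogeneous+bg          Y2  0.750234
3     330.0  heterogeneous+bg          Y2  0.923931
4     580.0  heterogeneous+bg          Y2  0.982166
```

The population MI rises and plateaus just under one bit.  Conditioning on a
single initial state instead (`sm.make_initial("S1", net)`, i.e. one cell's
channel) yields 1.66 bits at 580 min on the same channel: the population
average under-reports what an individual cell transmits, because the slow
global variable makes cells quantitatively different channels.

The same machinery generates and analyses synthetic cytometry data:

```python
table = cytometry.generate("SGF", n_cells=3000, seed=7)
summary = cytometry.summarize(table)
print(cytometry.classify_variability(summary)["call"])   # "slow-global"
```

A thin CLI mirrors the library (`stochmi scenario`, `stochmi moments`,
`stochmi ssa`, `stochmi mi`, `stochmi synth`, `stochmi model`); shipped
scenario configs live in `src/stochmi/data/scenarios/`.

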