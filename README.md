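# fretkin

Quantitative analysis of multi-state conformational kinetics in
diffusion-based single-molecule FRET (smFRET) experiments.

Freely diffusing biomolecules carrying a donor/acceptor dye pair report
their conformational state through the FRET efficiency *E* and the donor
lifetime ⟨τ_DA⟩_F of each single-molecule transit. When several states
exchange on the microsecond–millisecond timescale — and especially when
dynamic molecules coexist with pseudo-static ones of identical
efficiencies — no single representation of the photon data identifies
the kinetic network. `fretkin` implements the integrative toolkit for
this problem:

* **kinetics** — transition rate matrices **K** (`dx/dt = Kx`, ms⁻¹),
  equilibrium fractions, spectral decomposition, relaxation times
  `t_R^(l) = −1/λ^(l)`;
* **fretlines** — static line `E = 1 − ⟨τ_DA⟩_F/τ_D0`, binary dynamic
  lines, the dynamic shift `ds(x)` with its closed-form maximum, the
  moment representation, and `Var(E) = (1−E)(E−E_τ)`;
* **occupancy** — the two-state occupancy-time distribution over a
  finite window (pseudo-static deltas + Bessel-function density) and
  mode-based estimation of equilibrium fractions in static backgrounds;
* **fcsmodel / fcsfit / correlate** — analytic color-FCS curves
  `G = (1/N)·G_diff·G_k + 1` for N-state networks with static
  backgrounds, a multi-tau photon correlator with block-wise errors, and
  global curve fitting;
* **tcspc** — donor decay models `f(t) = Σ x_i e^{−t/τ_i}`, synthetic
  Poisson decays, sub-ensemble decays of burst selections;
* **simulate / fixtures** — a photon-level Monte Carlo (Brownian motion
  through a 3D Gaussian volume, exact Markov state switching, per-photon
  micro times) regenerating seven reference scenarios;
* **pda** — dynamic photon distribution analysis: window histograms from
  occupancy theory convolved with binomial counting statistics;
* **ffcs** — filtered-FCS species auto-/cross-correlations from
  micro-time filters, revealing kinetic connectivity;
* **globalfit** — the joint TCSPC+FCS objective
  `χ²_global = χ²_TCSPC + χ²_FCS`, multi-start fitting, MCMC sampling of
  the `p_d·k12·k21 = const` ambiguity manifold, kinetic-scheme
  enumeration and resolution helpers;
* **workflow / cli** — the three-step procedure (model selection →
  rate quantification → validation) and a `fretkin` command-line tool.

## Worked example

```python
import numpy as np
from fretkin.kinetics import (build_rate_matrix, eigen_decompose,
                              equilibrium_fractions, mean_efficiency)
from fretkin.fretlines import max_dynamic_shift
from fretkin.occupancy import occupancy_distribution, invert_mode

# two-state exchange LF <-> MF at 5 ms^-1 each way
net = build_rate_matrix(2, {("MF", "LF"): 5.0, ("LF", "MF"): 5.0},
                        state_labels=("LF", "MF"))
es = eigen_decompose(net)
print(f"relaxation time: {es.relaxation_times[0]*1e3:.0f} us")
print(f"equilibrium fractions: {equilibrium_fractions(net)}")

ds_max, x_max = max_dynamic_shift(0.8, 0.2)
print(f"ds_max = {ds_max:.2f} at x1 = {x_max:.3f}; "
      f"<E> there = {mean_efficiency([x_max, 1-x_max], [0.8, 0.2]):.2f}")

# occupancy over a 2 ms window for rates 3/1 ms^-1: the mode overshoots
# the equilibrium fraction, and the linear inversion recovers it
occ = occupancy_distribution(k12=3.0, k21=1.0, T=2.0)
print(f"window mode x_m = {occ.mode:.3f}; "
      f"inverted equilibrium fraction = {invert_mode(occ.mode, 4.0, 2.0):.3f}")
```

prints

```
relaxation time: 100 us
equilibrium fractions: [0.5 0.5]
ds_max = 0.10 at x1 = 0.667; <E> there = 0.60
window mode x_m = 0.873; inverted equilibrium fraction = 0.757
```

The symmetric 5/5 ms⁻¹ exchange relaxes with t_R = 1/(k12+k21) = 100 µs;
a 0.2/0.8 efficiency pair can shift a dynamic population at most 0.10
off the static FRET-line (at mixing fraction 2/3, mean efficiency 0.6);
and although the modal occupancy of a short window (0.873) badly
overshoots the true equilibrium fraction 0.75, the Bessel-function
intercept of the mode-inversion map corrects it to 0.757.

An end-to-end simulated experiment is one command away:

```sh
fretkin simulate --fixture 2 --seed 1 --duration 20 --out out/
fretkin workflow --stream out/sim2_stream.npz --seed 1
```

which detects the dynamic population, counts one FCS relaxation, admits
the LF ⇌ MF assignment from the dynamic-line position, rejects LF ⇌ HF,
and reports the microscopic rates.

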