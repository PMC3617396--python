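# dynsyn

Dynamic-synapse neural network models, bundled as one reproducible toolbox:

- **`dynsyn.tm_synapse`** — the phenomenological short-term-plasticity
  synapse: a continuous three-state resource model (recovered / active /
  inactive fractions, conserved total) with facilitating release
  probability, integrated event-exactly; plus the one-step discrete map
  used by the binary network, steady-state formulas `u∞(f)`, `x∞(f)`, and
  postsynaptic currents.
- **`dynsyn.attractor_network`** — Monte Carlo simulation of a stochastic
  binary attractor network (parallel Little dynamics, covariance-rule
  weights) with one depression/facilitation variable per neuron. With
  static synapses it is a classical associative memory; with depressing
  synapses stored patterns destabilize and the activity switches
  quasi-periodically between a pattern and its anti-pattern
  ("dynamic memories"). Produces rasters, overlap traces, sublattice
  averages, and dwell-time statistics.
- **`dynsyn.meanfield`** — the vanishing-load order-parameter map of that
  network (fixed points, Jacobian stability, memory / oscillatory /
  no-memory phase diagrams, including the re-entrant facilitation
  structure) and the zero-noise storage-capacity solver. The static-synapse
  limit reproduces `alpha_c ≈ 0.138`; depression lowers capacity and
  strong facilitation recovers it (max ≈ 0.14).
- **`dynsyn.updown`** — a stochastic bistable rate model of cortical
  up–down transitions: Euler–Maruyama integration of coupled rate and
  synaptic-resource equations, the effective potential at frozen resource,
  hysteresis-based state detection, exponential vs power-law dwell-time
  model selection (Clauset-style x_min, Vuong test), and the P/E/C/S
  phase classification over the (D, tau_r) plane — power-law permanence
  times appear only for noisy, slowly recovering synapses.
- **`dynsyn.sr_feedforward`** — feed-forward stochastic multiresonance:
  N Poisson presynaptic trains through dynamic synapses onto a
  leaky integrate-and-fire neuron with an adaptive threshold; weak-signal
  detection measured by the power norm `C0 = <S(t) nu(t)>`. Static
  synapses give one resonance peak in `C0(f_n)`; depressing+facilitating
  synapses give two, with the high-frequency peak position controlled by
  `tau_rec` and the low-frequency one by `tau_fac`.
- **`dynsyn.cli_io`** — CLI entry points, YAML configs, seed management,
  result serialization and fixture generators.

## CLI

All experiments are available through the `dynsyn` command; every run
writes `summary.json` (with provenance: config echo, version, seed,
timestamp) plus tidy CSV tables into `--outdir`.

```bash
# pattern/anti-pattern switching raster and overlap trace
dynsyn simulate-network --n 120 --tau-rec 26 --t 0.025 --steps 10000 \
    --seed 1 --outdir results/net

# zero-noise storage capacity
dynsyn capacity --u 0.2 --tau-rec 4 --tau-fac 1000

# mean-field phase diagram
dynsyn phase --axis1 tau_rec --start1 1 --stop1 40 --n1 10 \
    --axis2 T --start2 0.01 --stop2 0.3 --n2 10 --outdir results/phase

# up-down trajectory + permanence-time fit; P/E/C/S grid
dynsyn updown --tau-r 1000 --u 0.6 --d 0 --t-end 40000 --outdir results/ud
dynsyn updown-phase --outdir results/udgrid

# stochastic multiresonance curve with peak detection
dynsyn sr --tau-rec 400 --tau-fac 1000 --trials 8 --outdir results/sr
```

Flags override values from `--config file.yaml`; configs use the same key
names (see `dynsyn.cli_io` schemas).

## Units

Continuous synapse and SR models: ms, Hz, pA, mV. Binary network and its
mean-field theory: Monte Carlo steps (1 MCS ≈ 5 ms, a refractory period).
Up-down rate model: time in units of the rate time constant `tau_nu`;
`J`, `theta`, `delta` in volts with the rate normalized by `nu_m` inside
the sigmoid (see the module docstring for calibration notes).
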