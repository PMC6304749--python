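# devsnn

A conductance-based leaky integrate-and-fire network model of developing
cortical tissue, together with its firing-rate analysis pipeline.

The model captures four ingredients of early cortical development:

- **GABA_A reversal switch** — inhibitory synapses reverse at −40 mV in the
  *immature* state (depolarizing GABA) and at −70 mV in the *mature* state
  (hyperpolarizing GABA); everything else is held fixed.
- **Distance-dependent wiring** — neurons live on a periodic 1 mm² sheet;
  each receives exactly `K = round(ε·N)` recurrent synapses drawn with
  Gaussian acceptance probability `exp(-r²/2σ_c²)`. Six named scenarios
  (`A-1`, `A-2`, `B-1`…`B-4`) fix the (ε, σ_c) percentage pair. Delays grow
  linearly with distance (0.2 ms synaptic latency, 0.5 m/s conduction).
- **Short-term plasticity** — the utilization/resource recursion with four
  named variants (`STD1`, `STD2`, `STF1`, `STF2`) differing only in their
  (τ_dep, τ_fac) time constants; baseline utilization `U` is configurable
  (0.5 default).
- **Poisson drive** — one independent external Poisson source per neuron
  (5–100 Hz grid), with a strong per-spike conductance increment.

The analysis pipeline measures network-mean spike frequency (MSF) after a
burn-in, percent modulation between control and STP runs with
predicted/unpredicted classification, frequency-band labels, a Gaussian-PDF
(normality) filter over per-trial MSF samples, van Rossum spike-distance
matrices, mapping of MSF values onto in-vitro developmental reference
windows (7.86 ± 1.30 Hz pre-shift; 54.27 ± 7.22 Hz during the shift), and
balanced fixed-effects factorial ANOVA for the sweep tables.

## Layout

| module | contents |
| --- | --- |
| `devsnn.model_core` | neuron/synapse parameters, single-neuron dynamics |
| `devsnn.connectivity` | lattice geometry, Gaussian wiring, scenarios, delays |
| `devsnn.stp` | short-term plasticity recursion, variants, steady states |
| `devsnn.simulator` | numba-accelerated clock-driven engine, factorial sweep |
| `devsnn.analysis` | MSF, modulation, PDF filter, spike distances, ANOVA |
| `devsnn.synthetic_data` | seeded generators + the published MSF-pair catalog |
| `devsnn.records` / `devsnn.io` | plain-text spike events, CSV/YAML artifacts |

## CLI

```bash
devsnn build --scenario B-1 --maturation immature --n 300 --seed 0 --out net/
devsnn run   --scenario B-1 --maturation immature --if-hz 20 --duration 20 \
             --n 300 --seed 0 --out events.txt
devsnn sweep --scenarios B-1,B-2 --stps std1,stf2 --if-hz 5,10,20 \
             --trials 3 --duration 20 --n 300 --out msf.csv   # resumable
devsnn analyze --msf-table msf.csv --out-prefix results/run1
devsnn synth modulation-catalog --out data/modulation_catalog.csv
```

Full-scale settings (N = 3000, 2000 s, 12 trials, the 5–100 Hz grid) are the
`SimulationConfig` defaults; the scaled mode used by tests and examples is
`SimulationConfig.scaled()`.

## Conventions worth knowing

- MSF is the **network-mean per-neuron** rate: spikes after burn-in divided
  by `N · (T − burn_in)`.
- Percent change is `100·(before − after)/before`, positive = reduction,
  reported as a magnitude + direction, rounded half-even to one decimal.
- The first spike from rest transmits the nominal synaptic weight (the STP
  efficacy is normalized by `U`).
- Wiring, initial voltages and external drive are all derived from one seed;
  runs are bit-reproducible.
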