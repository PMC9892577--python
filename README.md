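# exotrace

Simulation and analysis of single-exonuclease nanocircuit recordings.

A single polynucleotide phosphorylase (PNPase, a processive 3'→5'
exoribonuclease) tethered to a silicon-nanowire field-effect transistor
produces a three-level conductance signal while it degrades an RNA
substrate one nucleotide at a time:

* **low** — RNA-free enzyme,
* **mid** (intermediate) — RNA-bound enzyme,
* **high** — the degradation/translocation state, one visit per cleaved
  base.

`exotrace` implements the complete computational workflow for such
recordings, together with a ground-truthed synthetic-trace generator so
every stage is testable without device data:

1. **Simulation** — two-state binding traces whose occupancy follows the
   van't Hoff relation, and degradation reads whose intermediate dwell is
   the sum of two sequential exponential waits (hydrolysis, mean τ₁ +
   nucleoside coordination, mean τ₂(base)), with Arrhenius temperature
   dependence, kinetic-isotope scaling in D₂O, Gaussian noise,
   low-frequency vibration on the high state and transient spike modes.
2. **Idealization** — zero-phase 2 kHz Butterworth filtering, 3-state
   Gaussian-HMM segmentation (EM + Viterbi, low↔high transitions
   forbidden), dead-time merging, event extraction, read segmentation
   and step counting.
3. **Kinetics** — dwell-law fits (single-exponential and hypoexponential
   MLE, with a seven-interval histogram fit as a secondary method),
   van't Hoff ΔH/ΔS, Arrhenius E_a (k = 1/τ₁), kinetic isotope effect
   k_H/k_D, Debye screening length, angular-velocity transition profiles
   and high-state spectra.
4. **Fingerprinting** — per-position 2-D (dwell, current) kernel-density
   fingerprints from complete 30-step reads, classification against
   homopolymer references, and 10-collection seq-logo aggregation into a
   per-position base probability and identification accuracy.

The core model: for each degradation step the intermediate dwell is

```
x = x_hydrolysis + x_coordination,   f(x) = (e^{-x/τ2} - e^{-x/τ1}) / (τ2 - τ1)
```

with τ₁ base-independent (Arrhenius: ln k = ln A − E_a/RT, k = 1/τ₁) and
τ₂ base-dependent — the separation of τ₂ across A/U/C/G, visible in the
fingerprint maps, is what makes single-molecule sequence reading
possible.

## Worked example

```python
import numpy as np
from exotrace import (DegradationModel, TraceConfig, default_nucleoside_table,
                      simulate_degradation_read, lowpass_filter,
                      idealize_states, extract_events, segment_reads,
                      fit_biexponential)

nk, dm = default_nucleoside_table(), DegradationModel()
cfg = TraceConfig(sampling_rate=57600.0, seed=3)
trace, truth = simulate_degradation_read("A" * 30, nk, dm, cfg)

filtered = lowpass_filter(trace)                  # 2 kHz, zero-phase
events = extract_events(idealize_states(filtered), filtered)
reads = segment_reads(events)
print("steps counted:", reads[0].step_count)

rng = np.random.default_rng(0)   # a deeper dwell sample for the fit
d = rng.exponential(8.86e-3, 10_000) + rng.exponential(46.33e-3, 10_000)
fit = fit_biexponential(d * 1e3)
print(f"tau1 = {fit.tau1:.2f} ms, tau2 = {fit.tau2:.2f} ms")
```

prints

```
steps counted: 30
tau1 = 9.31 ms, tau2 = 45.49 ms
```

i.e. the read shows exactly one high-state visit per nucleotide of the
30-mer substrate (single-base resolution), and the two-step maximum-
likelihood fit recovers the hydrolysis and coordination time constants
from the pooled intermediate dwells.

The full sequencing procedure is one call (or `exotrace pipeline` from
the shell):

```python
from exotrace import RunConfig, run_pipeline
res = run_pipeline(RunConfig(sequence="CGAUCUUCAUUGCCAAGCGGCUAGCUCAAA",
                             seed=30))
print(res.consensus, f"{100 * res.accuracy:.1f}%")
```

which simulates 10 collections × 150 reads plus homopolymer references,
idealizes every trace, classifies each position against the reference
fingerprints and reports the consensus sequence with its per-position
identification accuracy.

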