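# Methods

## Signal model

A tethered single PNPase molecule gates the conductance of a silicon
nanowire FET.  The recorded current occupies three levels: low (RNA-free
enzyme), intermediate ("mid", RNA-analog-bound) and high (degradation/
translocation).  Transitions run low ↔ mid ↔ high; direct low ↔ high
conversions do not occur, because the intermediate state governs the
structure-switching route.  One high-state visit corresponds to one
degraded nucleotide, so a complete read of an L-mer — the event train
between two adjacent low states — contains exactly L high visits (the
final visit models terminal release of the last nucleotide; an L-mer
has only L−1 internal phosphodiester bonds).

### Dwell laws

* Low and high dwells are exponential.  The high dwell additionally
  carries a 2 ms minimum (shifted exponential, mean preserved at the
  10 ms default): the mechanical ratchet step and product release cannot
  complete arbitrarily fast, and observed complete reads show no
  sub-resolution steps.  A pure exponential would put ~2% of visits
  below the recording chain's resolution, which contradicts the
  single-base-resolution observable the generator is built to emulate.
* The intermediate dwell before step k is the sum of two sequential
  exponential waits — hydrolysis of the phosphodiester bond (mean τ₁,
  base-independent) and coordination of the next 3'-terminal nucleoside
  at the active site (mean τ₂, base-dependent) — i.e. hypoexponential:
  f(x) = (e^{−x/τ₂} − e^{−x/τ₁})/(τ₂ − τ₁).  The hydrolysis wait has a
  0.5 ms minimum for the same reason as the high state; all fitted time
  constants are ≥ 10× these shifts, so fits of the unshifted law incur
  ≤ ~6% bias on τ₁ and ≤ 1% on τ₂.
* Temperature: τ₁ follows the Arrhenius law with E_a = 87.68 kJ·mol⁻¹
  (Mg²⁺/H₂O) anchored at τ₁ = 8.86 ms, 310.15 K.  τ₂ and the high dwell
  use a milder configurable Arrhenius dependence (default
  E_a = 40 kJ·mol⁻¹); only the hydrolysis activation energy is
  quantitatively constrained, so the secondary value is a design choice
  that preserves the qualitative shortening with temperature.
* Solvent: in D₂O, τ₁ is multiplied by the kinetic isotope effect
  (default 3.08).

Default coordination dwell means (ms): C 34.57 < A 46.33 < U 54.57 <
G 66.18 — the homopolymer-derived two-step constants.

### Currents

Levels default to 1.0 / 2.0 / 3.0 nA with i.i.d. Gaussian noise
(σ = 0.15 nA per raw sample).  The intermediate level is shifted by a
per-base offset (C −0.10, A 0.00, U +0.10, G +0.20 nA).  These offsets
are **synthetic design parameters**: real recordings show base-dependent
current divergence only as 2-D fingerprint density maps, never as
published numbers, so the offsets were chosen once to make the 2-D
fingerprints informative (spacing ≫ the standard error of a per-event
mean current) and are documented as such.  Consequences for
interpretation: passing identification tests demonstrates that the
*procedure* (fingerprint construction, reference comparison, logo
aggregation) is correct under the designed separability — it does not
certify accuracy on physical devices, whose noise floor and level
separations are not reproducible at desk scale.

The high state carries low-frequency sinusoidal vibration (default 40
and 80 Hz at 0.03/0.015 nA), emulating thermal motion of the RNA in the
degradation state.  Transient spike excursions (mode 1 backtrack from
mid toward high, mode 2 premature release toward low, modes 3/4 binding
attempts from low toward mid) are injected at rates that decrease
linearly with temperature; widths are capped at 8 samples, strictly
below the default dead time, so idealization absorbs them unless the
spike detector is enabled.

### Binding-only mode

Two-state alternation low ↔ mid with exponential dwells.  The bound
occupancy obeys R ln K_T = −ΔH/T + ΔS with K_T = p_free/p_bound
(defaults ΔH = −87.15 kJ·mol⁻¹, ΔS = −291.56 J·K⁻¹·mol⁻¹); dwell means
are scaled so the cycle time stays at free_dwell_ref + bound_dwell_ref
(50 ms + 50 ms, the tens-of-ms scale of recorded binding traces).  Note
the K_T convention: for a strictly alternating two-state process the
*event-count* shares are identically ½, so the occupancy entering K_T is
the time share; `state_statistics` reports both conventions and a
`convention` switch exposes the bound/free ratio (which flips the signs
of ΔH and ΔS).

Single-read simulations bracket the read with 10 ms-margin low periods:
these flanks are the experimenter's excision window around one complete
read, not kinetic dwells.  Session simulations use pure exponential
RNA-free periods.

## Idealization

2 kHz low-pass Butterworth (order 4), applied forward–backward
(`sosfiltfilt`) so event boundaries are not phase-shifted; the effective
magnitude response is |H(f)|².  A Gaussian-emission HMM (2 or 3 states)
is initialized from the k tallest modes of the smoothed current
histogram — deterministic, seed-free, and robust to occupancy imbalance,
where quantile or k-means seeding loses states that occupy a few percent
of samples — then refined by EM (15 iterations on a ≤ 200k-sample
contiguous chunk) and decoded by Viterbi over the full trace (chunked
with 50k-sample overlap beyond 4M samples).  low↔high transition
probabilities are pinned to zero and remain zero under Baum–Welch.
Fitted levels closer than 2 emission s.d. raise an explicit
`IdealizationError` with diagnostics rather than returning a silent
result.

Dead time defaults to 10 samples at the configured rate (~0.17 ms at
57.6 kSa/s, ≥ 10× below the shortest fitted time constant).  Runs
shorter than the dead time merge into the flanking state whose Gaussian
emission likes the run's samples better, shortest first; the merge is
idempotent.  Dwell-time conservation (Σ dwells = trace duration) holds
exactly by construction.

## Estimators

* Single-exponential dwell: MLE τ̂ = mean(dwell − dead_time); a
  seven-interval histogram least-squares fit is retained as a secondary
  method for comparability with decay-curve workflows.
* Two-step dwell: hypoexponential MLE via Nelder–Mead on
  (log τ₁, log(τ₂−τ₁)), moment-seeded (mean = τ₁+τ₂,
  variance = τ₁²+τ₂²), with a stable log-density (`log1p` form; Erlang-2
  limit for τ₁ ≈ τ₂).  A likelihood-ratio test against the nested
  single-exponential model (threshold 6.63, the χ²₁ 99% point) flags
  non-identifiable samples and falls back to the single-exponential
  estimate — the behavior of the coordination-deficient R93G/R97G mutant
  scenario.  Samples with τ₂−τ₁ < 25% of τ₂ are flagged near-degenerate
  (the two scales are then poorly identified although their sum is not).
  At n = 10⁴ and the poly(A) constants the MLE's sampling s.d. is ~4.6%
  for τ₁ and ~1% for τ₂.
* van't Hoff / Arrhenius: closed-form linear regressions of R ln K_T on
  1000/T and ln(1/τ₁) on 1/(RT); exact on noise-free inputs.
* KIE = k_H/k_D; values above 2 are annotated as a primary isotope
  effect.
* Debye length: λ_D = sqrt(ε_r ε₀ k_B T / (2 N_A e² I)) for a 1:1
  electrolyte with ionic strength I in mol/L (≈ 0.304/√I nm in water at
  25 °C).  The ionic strength is an explicit input: the ~11.3 nm
  operating point corresponds to I ≈ 0.72 mM, but the composition of a
  100-fold-diluted Tris buffer does not pin I unambiguously, so no
  intermediate value is asserted.
* Angular velocity ω = arctan(Δy/Δx) per adjacent point pair on a
  moving-average-smoothed transition segment (the smoothing replaces a
  published trajectory-clustering fit, which is out of scope); FWHM by
  linear interpolation at half maximum, computed separately for rising
  (binding) and falling (release) transitions.
* High-state spectra: detrended, Hann-windowed periodograms on a common
  FFT grid, averaged over segments ≥ 64 samples; peaks are local maxima
  above a configurable threshold (default 50× the median power), only
  below the filter cutoff.

## Fingerprinting

Only reads with exactly the expected step count are retained (the
completeness prerequisite; retention counts land in the run manifest).
Step k (processing order, k = 1 the 3'-terminal base) reports at 5'-based
position L−k+1; the mapping is an involution.  The last step's dwell is
excluded from hydrolysis-rate summaries (the final cleavage happens one
bond earlier) but retained for fingerprints.

Fingerprints are Gaussian KDEs in (log-dwell, current) space (Scott's
rule; degenerate axes fall back to 1-D KDEs or a delta with a flag),
evaluated on a shared 64 × 32 grid (dwell 0.5–500 ms log-spaced, current
1.4–2.6 nA).  Classification scores a position's observations by their
mean log-density under each base's reference KDE (all observations
contribute, not a summary statistic); a Bhattacharyya-coefficient
overlap between gridded densities is available as an alternative
metric.  Calls with a top-two margin below 0.05 nats become N.
References are pooled over all positions of simulated homopolymer
reads.  Ten disjoint collections are classified independently and
overlaid: each position's probability for a base is votes/collections,
the consensus is the plurality call (ties → N), and accuracy is the
fraction of consensus calls matching the known sequence.

## Problem sizes and runtime choices

Bulk sequencing runs (the 10 × 150-read procedure) are simulated at
7,200 Sa/s — one of the recording rates actually used — which keeps a
ten-collection run within a few minutes on one CPU; single-read
step-counting checks run at the full 57,600 Sa/s.  The reference
library uses 50 homopolymer reads per base (4,500+ pooled observations
per base, far above what the position KDEs need).  EM fits on a 200k-
sample chunk; decoding always covers the full trace.

## What the synthetic generator does and does not show

The generator reproduces the *statistical structure* the analysis
assumes: three levels, the two-step intermediate dwell with
base-dependent τ₂, van't Hoff occupancy, Arrhenius rates, KIE scaling,
noise, vibration and spikes.  It does not reproduce device physics
(gating, screening, drift, 1/f noise), enzyme heterogeneity, secondary-
structure stalls, or the unknown magnitude of real per-base current
divergence.  Green tests therefore establish correctness of the
estimators and of the identification procedure under designed
separability — parameter recovery, not device-level performance claims.

## Known limitations

* The HMM is the only idealizer; no change-point alternatives.
* τ₁/τ₂ identifiability degrades as the scales approach each other; the
  near-degenerate flag marks, but does not repair, such fits.
* Occurrence proportion is reported in both count-share and time-share
  conventions; thermodynamic fits require the time share.
* Mixed-solvent (intermediate D₂O fractions) and pH mechanisms are not
  modeled; conditions are labels whose statistics can be compared.
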