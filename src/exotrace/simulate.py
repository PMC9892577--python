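"""Ground-truthed synthetic current traces.

The generator reproduces the statistical structure of single-exonuclease
nanocircuit recordings:

* binding-only mode: two-level alternation (low = RNA-free, mid = bound)
  with exponential dwells whose occupancy ratio follows the van't Hoff
  relation at the configured temperature;
* degradation mode: one mid -> high cycle per degraded base, the mid
  dwell hypoexponential (hydrolysis tau1 + coordination tau2(base)), the
  high dwell exponential, tau1 Arrhenius in temperature and scaled by the
  kinetic isotope effect in D2O;
* Gaussian per-sample current noise, low-frequency sinusoidal vibration
  superposed on the high state, and four modes of transient sub-dead-time
  spike excursions.

Every simulated trace is returned together with a :class:`GroundTruth`
giving the per-sample state path, event boundaries and the base identity
of every degradation step, so downstream stages can be scored exactly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .models import (
    BASES,
    BindingModel,
    CurrentTrace,
    DegradationModel,
    GroundTruth,
    NucleosideKinetics,
    ReadTruth,
    STATE_HIGH,
    STATE_LOW,
    STATE_MID,
    STATE_SPIKE,
    TraceConfig,
    validate_sequence,
)

# Maximum spike length in samples (below the default 10-sample dead time,
# so spikes are absorbed by dead-time merging unless explicitly detected).
SPIKE_MAX_SAMPLES = 8

# Spike-mode host state and excursion target level key.
# Mode 1: backtrack (from bound toward the degradation level);
# Mode 2: premature release (bound toward RNA-free);
# Mode 3: unsuccessful binding attempt (free toward bound);
# Mode 4: fast complete binding excursion (free toward bound).
_SPIKE_HOST = (STATE_MID, STATE_MID, STATE_LOW, STATE_LOW)
_SPIKE_TARGET = ("high", "low", "mid", "mid")


def _n_samples(dwell: float, fs: float) -> int:
    return max(1, int(round(dwell * fs)))


def _render(event_states: np.ndarray, event_levels: np.ndarray,
            event_nsamp: np.ndarray, config: TraceConfig,
            dm: DegradationModel | None, rng: np.random.Generator,
            metadata: dict) -> tuple[CurrentTrace, np.ndarray, np.ndarray]:
    """Expand per-event arrays into a sampled trace with noise/vibration."""
    state_path = np.repeat(event_states.astype(np.int8), event_nsamp)
    base_current = np.repeat(event_levels, event_nsamp)
    n = state_path.size
    currents = base_current.copy()
    if dm is not None and len(dm.vibration_freqs):
        mask = state_path == STATE_HIGH
        if mask.any():
            t = np.arange(n) / config.sampling_rate
            vib = np.zeros(n)
            for f, a in zip(dm.vibration_freqs, dm.vibration_amps):
                vib += a * np.sin(2 * np.pi * f * t)
            currents[mask] += vib[mask]
    if config.noise_sd > 0:
        currents += rng.normal(0.0, config.noise_sd, size=n)
    boundaries = np.concatenate(([0], np.cumsum(event_nsamp)[:-1]))
    trace = CurrentTrace(currents, config.sampling_rate, metadata)
    return trace, state_path, boundaries


def _inject_spikes(trace: CurrentTrace, state_path: np.ndarray,
                   config: TraceConfig, dm: DegradationModel, T: float,
                   rng: np.random.Generator) -> None:
    """Overlay transient spike excursions in place; label them in the path."""
    rates = dm.spike_rates(T)
    if not rates.any():
        return
    fs = config.sampling_rate
    levels = {"low": config.level_low, "mid": config.level_mid,
              "high": config.level_high}
    n = state_path.size
    for mode, (rate, host, target) in enumerate(
            zip(rates, _SPIKE_HOST, _SPIKE_TARGET), start=1):
        if rate <= 0:
            continue
        host_idx = np.flatnonzero(state_path == host)
        if host_idx.size == 0:
            continue
        n_spikes = rng.poisson(rate * host_idx.size / fs)
        for _ in range(n_spikes):
            start = int(rng.choice(host_idx))
            width = int(rng.integers(2, SPIKE_MAX_SAMPLES + 1))
            stop = min(start + width, n)
            seg = slice(start, stop)
            if np.any(state_path[seg] != host):
                continue  # keep spikes inside a single host event
            state_path[seg] = STATE_SPIKE
            delta = levels[target] - levels["low" if host == STATE_LOW else "mid"]
            trace.currents[seg] += delta


def simulate_binding_trace(binding: BindingModel, config: TraceConfig,
                           T: float, n_cycles: int = 200,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[CurrentTrace, GroundTruth]:
    """Two-state (low <-> mid) alternating trace at temperature ``T``.

    Dwell means are set so the time occupancy of the bound state equals
    the van't Hoff prediction: p_bound = 1/(1+K_T) with
    K_T = exp[(-dH/T + dS)/R], while the total cycle time stays at
    ``free_dwell_ref + bound_dwell_ref``.
    """
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_bound = binding.p_bound(T)
    cycle = binding.free_dwell_ref + binding.bound_dwell_ref
    mean_free, mean_bound = (1 - p_bound) * cycle, p_bound * cycle

    if config.duration is not None:
        n_cycles = max(n_cycles, int(np.ceil(config.duration / cycle)))
    if n_cycles * 2 < 50:
        raise ValueError("duration must cover at least 50 expected transitions")

    free = rng.exponential(mean_free, size=n_cycles)
    bound = rng.exponential(mean_bound, size=n_cycles)
    dwells = np.empty(2 * n_cycles)
    dwells[0::2], dwells[1::2] = free, bound
    states = np.tile([STATE_LOW, STATE_MID], n_cycles)
    levels = np.tile([config.level_low, config.level_mid], n_cycles)
    nsamp = np.maximum(1, np.round(dwells * config.sampling_rate).astype(np.int64))

    metadata = {"temperature": T, "mode": "binding", "p_bound": p_bound}
    trace, path, bounds = _render(states, levels, nsamp, config, None, rng,
                                  metadata)
    gt = GroundTruth(path, bounds, states)
    return trace, gt


def _read_events(seq: str, nk: Mapping[str, NucleosideKinetics],
                 dm: DegradationModel, config: TraceConfig, T: float,
                 solvent: str, rng: np.random.Generator,
                 ) -> tuple[list[int], list[float], list[float], list[str]]:
    """Per-event (state, level, dwell) arrays for one degradation read.

    Processing is 3'->5': step k consumes the base at 5'->3' position
    L-k+1.  The mid dwell of step k is Exp(tau1) + Exp(tau2(base_k)) and
    its level carries that base's current offset.  A final high visit is
    emitted for the terminal-release step so an L-mer shows exactly L
    high-state fluctuations, matching the observable.
    """
    missing = set(seq) - set(nk)
    if missing:
        raise ValueError(f"nucleoside table missing entries for {sorted(missing)}")
    tau1 = dm.tau1(T, solvent)
    t1_min = min(dm.tau1_min, 0.5 * tau1)
    high_mean = dm.high_dwell(T)
    h_min = min(dm.high_dwell_min, 0.5 * high_mean)
    states: list[int] = []
    levels: list[float] = []
    dwells: list[float] = []
    step_bases = [seq[len(seq) - k] for k in range(1, len(seq) + 1)]
    for base in step_bases:
        tau2 = dm.tau2(base, T, nk)
        mid_dwell = (t1_min + rng.exponential(tau1 - t1_min)
                     + rng.exponential(tau2))
        states.append(STATE_MID)
        levels.append(config.level_mid + nk[base].current_offset)
        dwells.append(mid_dwell)
        states.append(STATE_HIGH)
        levels.append(config.level_high)
        dwells.append(h_min + rng.exponential(high_mean - h_min))
    return states, levels, dwells, step_bases


def simulate_degradation_read(seq: str, nk: Mapping[str, NucleosideKinetics],
                              dm: DegradationModel, config: TraceConfig,
                              T: float = 310.15, solvent: str = "H2O",
                              free_dwell_mean: float = 0.2,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[CurrentTrace, GroundTruth]:
    """One complete degradation read flanked by low (RNA-free) dwells."""
    seq = validate_sequence(seq)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    r_states, r_levels, r_dwells, step_bases = _read_events(
        seq, nk, dm, config, T, solvent, rng)
    states = np.array([STATE_LOW] + r_states + [STATE_LOW])
    levels = np.array([config.level_low] + r_levels + [config.level_low])
    # The flanking RNA-free periods are window cut-outs around one read,
    # not complete kinetic dwells: a 10 ms visible margin guarantees the
    # bracketing low states appear in the excised window.
    margin = 0.01
    dwells = np.array([margin + rng.exponential(free_dwell_mean)] + r_dwells
                      + [margin + rng.exponential(free_dwell_mean)])
    nsamp = np.maximum(1, np.round(dwells * config.sampling_rate).astype(np.int64))
    metadata = {"temperature": T, "solvent": solvent, "mode": "degradation",
                "sequence": seq}
    trace, path, bounds = _render(states, levels, nsamp, config, dm, rng,
                                  metadata)
    read = ReadTruth(step_bases, int(bounds[1]), int(nsamp.sum() - nsamp[-1]))
    gt = GroundTruth(path, bounds, states, [read])
    return trace, gt


def simulate_session(reads: int, seq: str | Sequence[str],
                     nk: Mapping[str, NucleosideKinetics],
                     dm: DegradationModel, binding: BindingModel,
                     config: TraceConfig, T: float = 310.15,
                     solvent: str = "H2O",
                     seq_weights: Sequence[float] | None = None,
                     spikes: bool = True,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[CurrentTrace, GroundTruth]:
    """Concatenate ``reads`` complete degradation reads into one session.

    Low (RNA-free) periods with mean ``binding.free_dwell_ref`` separate
    consecutive reads.  When ``seq`` is a list, each read's sequence is
    drawn with probabilities ``seq_weights`` (mixed-sample mode).  Spike
    modes 1-4 are injected at the model's temperature-dependent rates.
    """
    if reads < 1:
        raise ValueError("reads must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if isinstance(seq, str):
        seqs = [validate_sequence(seq)]
        seq_weights = [1.0]
    else:
        seqs = [validate_sequence(s) for s in seq]
        if not seqs:
            raise ValueError("empty sequence list")
        if seq_weights is None:
            seq_weights = [1.0 / len(seqs)] * len(seqs)
        if abs(sum(seq_weights) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    states: list[int] = [STATE_LOW]
    levels: list[float] = [config.level_low]
    dwells: list[float] = [rng.exponential(binding.free_dwell_ref)]
    read_meta: list[tuple[list[str], int]] = []  # (bases, first event index)
    for _ in range(reads):
        i = int(rng.choice(len(seqs), p=np.asarray(seq_weights, dtype=float)))
        r_states, r_levels, r_dwells, bases = _read_events(
            seqs[i], nk, dm, config, T, solvent, rng)
        read_meta.append((bases, len(states)))
        states.extend(r_states)
        levels.extend(r_levels)
        dwells.extend(r_dwells)
        states.append(STATE_LOW)
        levels.append(config.level_low)
        dwells.append(rng.exponential(binding.free_dwell_ref))

    states_a = np.array(states)
    levels_a = np.array(levels)
    nsamp = np.maximum(1, np.round(np.array(dwells)
                                   * config.sampling_rate).astype(np.int64))
    total = int(nsamp.sum())
    if config.duration is not None:
        cap = int(round(config.duration * config.sampling_rate))
        if total > cap:
            raise ValueError(
                f"duration {config.duration}s ({cap} samples) too short for "
                f"{reads} reads ({total} samples); no silent truncation")
    metadata = {"temperature": T, "solvent": solvent, "mode": "session",
                "reads": reads}
    trace, path, bounds = _render(states_a, levels_a, nsamp, config, dm, rng,
                                  metadata)
    if spikes:
        _inject_spikes(trace, path, config, dm, T, rng)
    gt_reads = []
    ends = np.concatenate((bounds[1:], [total]))
    for bases, ev0 in read_meta:
        gt_reads.append(ReadTruth(bases, int(bounds[ev0]),
                                  int(ends[ev0 + 2 * len(bases) - 1])))
    gt = GroundTruth(path, bounds, states_a, gt_reads)
    return trace, gt


def mix_samples(seqA: str, seqB: str, proportions: Sequence[float],
                reads: int, nk: Mapping[str, NucleosideKinetics],
                dm: DegradationModel, binding: BindingModel,
                config: TraceConfig, T: float = 310.15, solvent: str = "H2O",
                rng: np.random.Generator | None = None,
                ) -> tuple[CurrentTrace, GroundTruth]:
    """Session over a two-sequence mixture with the given proportions."""
    return simulate_session(reads, [seqA, seqB], nk, dm, binding, config,
                            T=T, solvent=solvent,
                            seq_weights=list(proportions), rng=rng)


def draw_hypoexponential(n: int, tau1: float, tau2: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` two-step sequential dwells (sum of two exponentials)."""
    return rng.exponential(tau1, size=n) + rng.exponential(tau2, size=n)
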