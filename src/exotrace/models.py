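"""Domain types for single-exonuclease current-trace analysis.

The physical picture: a single processive 3'->5' exonuclease (PNPase) is
tethered to a silicon-nanowire field-effect transistor.  Its conformational
state gates the nanowire conductance, producing a three-level current signal:

* ``low``  -- RNA-free enzyme,
* ``mid``  -- RNA-analog-bound enzyme (the "intermediate" state),
* ``high`` -- the degradation/translocation state, one visit per cleaved base.

Each intermediate dwell before a degradation step is the sum of two
sequential exponential waits: hydrolysis of the phosphodiester bond
(mean ``tau1``, base-independent) followed by coordination of the next
3'-terminal nucleoside at the active site (mean ``tau2``, base-dependent).
The types below carry the parameters of that model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: State codes used in ground-truth state paths and idealized paths.
STATE_LOW, STATE_MID, STATE_HIGH, STATE_SPIKE = 0, 1, 2, 3
STATE_NAMES = {STATE_LOW: "low", STATE_MID: "mid", STATE_HIGH: "high",
               STATE_SPIKE: "spike"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

BASES = ("A", "U", "C", "G")


@dataclass(frozen=True)
class NucleosideKinetics:
    """Per-base kinetic parameters of the coordination step.

    Parameters
    ----------
    base : str
        One of A, U, C, G.
    tau2_mean : float
        Mean of the exponential nucleoside-coordination dwell, seconds,
        at the reference temperature.
    current_offset : float
        Additive shift (nA) of the intermediate-state level while this
        base occupies the active site.  The offsets are synthetic design
        parameters: real recordings show base-dependent current divergence
        only as 2-D fingerprint density maps, not as published numbers.
    """

    base: str
    tau2_mean: float
    current_offset: float

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"unknown base {self.base!r}")
        if self.tau2_mean <= 0:
            raise ValueError("tau2_mean must be positive")


def default_nucleoside_table() -> dict[str, NucleosideKinetics]:
    """Coordination-dwell table from the homopolymer measurements.

    tau2 means (ms): C 34.57 < A 46.33 < U 54.57 < G 66.18.  Current
    offsets (C -0.10, A 0.00, U +0.10, G +0.20 nA) are synthetic, chosen
    so that 2-D fingerprints are informative.
    """
    return {
        "A": NucleosideKinetics("A", 46.33e-3, 0.00),
        "U": NucleosideKinetics("U", 54.57e-3, 0.10),
        "C": NucleosideKinetics("C", 34.57e-3, -0.10),
        "G": NucleosideKinetics("G", 66.18e-3, 0.20),
    }


@dataclass
class DegradationModel:
    """Kinetics of the hydrolysis/translocation cycle.

    tau1 is the hydrolysis dwell mean at ``T_ref``; its temperature
    dependence is Arrhenius with activation energy ``Ea``.  In heavy
    solvent (D2O) tau1 is multiplied by the kinetic isotope effect
    ``kie``.  The coordination dwell (tau2) and the high-state dwell get
    a milder Arrhenius dependence with ``Ea_secondary``.
    """

    tau1_ref: float = 8.86e-3          # s, hydrolysis dwell mean at T_ref
    Ea: float = 87.68e3                # J/mol (Mg2+/H2O condition)
    T_ref: float = 310.15              # K (37 C)
    high_dwell_mean: float = 10e-3     # s, translocation dwell at T_ref
    Ea_secondary: float = 40e3         # J/mol for tau2 and high dwell
    kie: float = 3.08                  # tau1 multiplier in D2O
    # Minimum dwells (shifted-exponential refractory times).  Chemistry and
    # mechanics cannot complete arbitrarily fast: a pure exponential puts
    # finite mass at durations no recording chain can represent, while
    # observed complete reads show no sub-resolution steps.  Means are
    # preserved (the exponential part has mean total - minimum).
    high_dwell_min: float = 2e-3       # s, mechanical translocation + release
    tau1_min: float = 0.5e-3           # s, minimum hydrolysis wait
    vibration_freqs: Sequence[float] = (40.0, 80.0)   # Hz, high state only
    vibration_amps: Sequence[float] = (0.03, 0.015)   # nA
    # Transient sub-dead-time excursions (spike modes):
    # 1 backtrack, 2 release, 3 unsuccessful binding, 4 complete binding.
    spike_mode_rates: Sequence[float] = (0.2, 0.2, 0.3, 0.3)  # events/s at T_ref

    def __post_init__(self) -> None:
        if self.tau1_ref <= 0 or self.high_dwell_mean <= 0:
            raise ValueError("dwell means must be positive")
        if self.Ea < 0:
            raise ValueError("Ea must be non-negative")
        if any(r < 0 for r in self.spike_mode_rates):
            raise ValueError("spike rates must be non-negative")

    def tau1(self, T: float, solvent: str = "H2O") -> float:
        """Hydrolysis dwell mean at temperature ``T`` in the given solvent."""
        t = self.tau1_ref * np.exp(self.Ea / R_GAS * (1.0 / T - 1.0 / self.T_ref))
        if solvent == "D2O":
            t *= self.kie
        return float(t)

    def tau2(self, base: str, T: float,
             table: Mapping[str, NucleosideKinetics]) -> float:
        scale = np.exp(self.Ea_secondary / R_GAS * (1.0 / T - 1.0 / self.T_ref))
        return float(table[base].tau2_mean * scale)

    def high_dwell(self, T: float) -> float:
        scale = np.exp(self.Ea_secondary / R_GAS * (1.0 / T - 1.0 / self.T_ref))
        return float(self.high_dwell_mean * scale)

    def spike_rates(self, T: float) -> np.ndarray:
        """Spike-mode rates, decreasing linearly with temperature.

        The recordings show incomplete-transformation events becoming
        rarer as temperature rises; a linear ramp (factor 1 at T_ref-5 K,
        0.5 at T_ref+5 K) preserves the trend without inventing numbers.
        """
        f = 1.0 - 0.05 * (T - (self.T_ref - 5.0))
        f = float(np.clip(f, 0.0, 1.5))
        return np.asarray(self.spike_mode_rates, dtype=float) * f


@dataclass
class BindingModel:
    """Two-state (RNA-free <-> bound) thermodynamics.

    The equilibrium constant for the free -> bound transformation follows
    the van't Hoff relation R ln K_T = -dH/T + dS with K_T expressed as
    the occupancy ratio p_free/p_bound.  Dwell references set the overall
    cycle timescale at the reference occupancy.
    """

    dH: float = -87.15e3        # J/mol
    dS: float = -291.56         # J/K/mol
    free_dwell_ref: float = 50e-3    # s
    bound_dwell_ref: float = 50e-3   # s

    def __post_init__(self) -> None:
        if self.free_dwell_ref <= 0 or self.bound_dwell_ref <= 0:
            raise ValueError("dwell references must be positive")

    def equilibrium_constant(self, T: float) -> float:
        """K_T = p_free / p_bound = exp[(-dH/T + dS)/R]."""
        if T <= 0:
            raise ValueError("temperature must be positive (K)")
        return float(np.exp((-self.dH / T + self.dS) / R_GAS))

    def p_bound(self, T: float) -> float:
        K = self.equilibrium_constant(T)
        p = 1.0 / (1.0 + K)
        if not (0.0 < p < 1.0):
            raise ValueError(
                f"occupancy {p} outside (0,1) for dH={self.dH}, dS={self.dS}, T={T}")
        return p


@dataclass
class TraceConfig:
    """Acquisition parameters for a simulated recording."""

    sampling_rate: float = 57600.0   # Sa/s; alternates 28800, 7200
    noise_sd: float = 0.15           # nA, i.i.d. Gaussian per sample
    level_low: float = 1.0           # nA
    level_mid: float = 2.0
    level_high: float = 3.0
    duration: float | None = None    # s; None -> sized by the simulator
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (self.level_low < self.level_mid < self.level_high):
            raise ValueError("levels must satisfy low < mid < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def level(self, state: int) -> float:
        return {STATE_LOW: self.level_low, STATE_MID: self.level_mid,
                STATE_HIGH: self.level_high}[state]


@dataclass
class CurrentTrace:
    """Uniformly sampled current-vs-time signal."""

    currents: np.ndarray              # nA
    sampling_rate: float              # Sa/s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if self.currents.ndim != 1:
            raise ValueError("currents must be 1-D")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.currents.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.currents.size / self.sampling_rate

    def __len__(self) -> int:
        return self.currents.size


@dataclass
class ReadTruth:
    """Ground truth for one degradation read (one RNA molecule)."""

    step_bases: list[str]       # 3'->5' processing order (first degraded first)
    start_sample: int
    end_sample: int

    @property
    def n_steps(self) -> int:
        return len(self.step_bases)


@dataclass
class GroundTruth:
    """Per-sample truth emitted alongside every simulated trace."""

    state_path: np.ndarray            # int8 codes per sample
    event_boundaries: np.ndarray      # start index of each event, sorted
    event_states: np.ndarray          # state code of each event
    reads: list[ReadTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.state_path = np.asarray(self.state_path, dtype=np.int8)
        self.event_boundaries = np.asarray(self.event_boundaries, dtype=np.int64)
        self.event_states = np.asarray(self.event_states, dtype=np.int8)
        if np.any(np.diff(self.event_boundaries) <= 0):
            raise ValueError("event boundaries must be strictly increasing")

    @property
    def step_bases(self) -> list[str]:
        """Concatenated step bases over all reads, processing order."""
        out: list[str] = []
        for r in self.reads:
            out.extend(r.step_bases)
        return out

    @property
    def n_events(self) -> int:
        return self.event_boundaries.size


def validate_sequence(seq: str) -> str:
    """Uppercase and check an RNA sequence over {A,U,C,G}; T maps to U."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"unknown base symbol(s): {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s
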