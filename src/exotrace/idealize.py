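"""Three-level idealization of filtered traces and event extraction.

A Gaussian-emission hidden Markov model is fitted by expectation-
maximization and the most probable state path obtained by Viterbi
decoding.  Direct low <-> high transitions are forbidden (the conductance
conversion runs through the intermediate state), visits shorter than the
dead time are merged into the more probable flanking state, and the
resulting path is cut into events and complete degradation reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator


from .models import (
    CurrentTrace,
    STATE_HIGH,
    STATE_LOW,
    STATE_MID,
    STATE_NAMES,
)


class IdealizationError(RuntimeError):
    """EM failed to resolve the requested number of levels."""


@dataclass
class IdealizedPath:
    """Viterbi state path with fitted emission levels."""

    state_per_sample: np.ndarray      # int codes, 0=low .. n_states-1
    level_estimates: np.ndarray       # nA, ascending
    level_sds: np.ndarray             # nA
    sampling_rate: float
    spike_table: pd.DataFrame | None = None

    @property
    def transition_count(self) -> int:
        return int(np.count_nonzero(np.diff(self.state_per_sample)))

    def __len__(self) -> int:
        return self.state_per_sample.size


def run_length_encode(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(starts, lengths, values) of maximal constant runs."""
    x = np.asarray(x)
    if x.size == 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0, x.dtype),)
    change = np.flatnonzero(np.diff(x)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [x.size])))
    return starts, lengths, x[starts]


def merge_short_dwells(states: np.ndarray, currents: np.ndarray,
                       means: np.ndarray, sds: np.ndarray,
                       min_samples: int,
                       record_spikes: bool = False,
                       sampling_rate: float | None = None,
                       ) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Merge runs shorter than ``min_samples`` into a flanking state.

    The receiving flank is the one whose Gaussian emission assigns the
    run's samples the larger total log-likelihood (ties break toward the
    lower state).  Shortest runs merge first; the operation is idempotent
    once no run is below the dead time.
    """
    runs = [[int(v), int(s), int(l)]
            for s, l, v in zip(*run_length_encode(states))]
    spikes: list[dict] = []

    def loglik(run, state) -> float:
        seg = currents[run[1]:run[1] + run[2]]
        return float(-0.5 * np.sum(((seg - means[state]) / sds[state]) ** 2)
                     - run[2] * np.log(sds[state]))

    while len(runs) > 1:
        short = [(l, i) for i, (_, _, l) in enumerate(runs) if l < min_samples]
        if not short:
            break
        _, i = min(short)
        run = runs[i]
        neighbors = []
        if i > 0:
            neighbors.append(runs[i - 1][0])
        if i < len(runs) - 1:
            neighbors.append(runs[i + 1][0])
        target = max(sorted(set(neighbors)), key=lambda s: loglik(run, s))
        if record_spikes and sampling_rate is not None:
            spikes.append({
                "start_s": run[1] / sampling_rate,
                "dwell_s": run[2] / sampling_rate,
                "excursion_state": STATE_NAMES.get(run[0], str(run[0])),
                "merged_into": STATE_NAMES.get(target, str(target)),
            })
        run[0] = target
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] += r[2]
            else:
                merged.append(r)
        runs = merged

    out = np.repeat(np.array([r[0] for r in runs], dtype=states.dtype),
                    [r[2] for r in runs])
    table = pd.DataFrame(spikes) if record_spikes else None
    return out, table


class TraceIdealizer(BaseEstimator):
    """Gaussian-HMM idealizer for two- or three-level traces.

    Parameters
    ----------
    n_states : int
        2 for binding-only traces, 3 for degradation traces.
    dead_time : float or None
        Minimum resolvable dwell in seconds; visits shorter than this are
        merged into the flanking state.  ``None`` uses 10 samples at the
        trace's sampling rate.
    forbid_low_high : bool
        Pin the low <-> high transition probabilities to zero (only
        meaningful for ``n_states=3``).
    n_iter, tol : EM controls passed to :class:`hmmlearn.hmm.GaussianHMM`.
    max_fit_samples : int
        EM runs on a contiguous chunk of at most this many samples;
        decoding always covers the full trace.
    min_separation : float
        Fitted levels closer than ``min_separation`` times the pooled
        emission s.d. raise :class:`IdealizationError`.

    Attributes
    ----------
    means_ : ndarray of shape (n_states,), ascending fitted levels (nA).
    sds_ : ndarray, emission standard deviations.
    transmat_ : ndarray, fitted transition matrix (states in level order).
    """

    def __init__(self, n_states: int = 3, dead_time: float | None = None,
                 forbid_low_high: bool = True, n_iter: int = 15,
                 tol: float = 1e-3, max_fit_samples: int = 200_000,
                 min_separation: float = 2.0, detect_spikes: bool = False):
        self.n_states = n_states
        self.dead_time = dead_time
        self.forbid_low_high = forbid_low_high
        self.n_iter = n_iter
        self.tol = tol
        self.max_fit_samples = max_fit_samples
        self.min_separation = min_separation
        self.detect_spikes = detect_spikes

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _currents(trace) -> np.ndarray:
        if isinstance(trace, CurrentTrace):
            return trace.currents
        return np.asarray(trace, dtype=float).ravel()

    def _init_params(self, x: np.ndarray):
        """Histogram-peak level seeding (deterministic, seed-free).

        The k most prominent, mutually separated modes of the smoothed
        current histogram seed the emission means.  Unlike quantile or
        mass-balancing (k-means) seeds this is insensitive to occupancy
        imbalance — a state occupying a few percent of the samples still
        raises a clear peak at its level.  Samples are then assigned to
        the nearest center for the initial spreads.
        """
        k = self.n_states
        sub = x if x.size <= 100_000 else x[:: x.size // 100_000 + 1]
        lo, hi = np.percentile(sub, (0.1, 99.9))
        if hi <= lo:
            hi = lo + 1e-9
        counts, edges = np.histogram(sub, bins=256, range=(lo, hi))
        kernel = np.ones(5) / 5
        smooth = np.convolve(counts.astype(float), kernel, mode="same")
        centers_grid = 0.5 * (edges[:-1] + edges[1:])
        min_dist = max(1, 256 // (3 * k))      # minimum peak separation, bins
        padded = np.concatenate(([0.0], smooth, [0.0]))  # allow edge peaks
        idx, _ = find_peaks(padded, distance=min_dist,
                            prominence=1e-4 * max(smooth.max(), 1.0))
        idx = idx - 1
        idx = idx[np.argsort(smooth[idx])[::-1]][:k]     # k tallest modes
        means = [float(centers_grid[j]) for j in sorted(idx)]
        while len(means) < k:                  # degenerate data fallback
            means.append(float(np.percentile(sub, 50.0)))
        means = np.sort(np.asarray(means))
        labels = np.argmin(np.abs(sub[:, None] - means[None, :]), axis=1)
        sds = np.empty(k)
        for j in range(k):
            seg = sub[labels == j]
            sds[j] = seg.std() if seg.size > 1 else sub.std()
        sds = np.maximum(sds, 1e-6 * max(sub.std(), 1e-12) + 1e-12)
        return means, sds

    def _transmat_init(self) -> np.ndarray:
        k = self.n_states
        tm = np.full((k, k), 0.01 / max(k - 1, 1))
        np.fill_diagonal(tm, 0.99)
        if k == 3 and self.forbid_low_high:
            tm[STATE_LOW, STATE_HIGH] = 0.0
            tm[STATE_HIGH, STATE_LOW] = 0.0
        return tm / tm.sum(axis=1, keepdims=True)

    # -- sklearn surface ---------------------------------------------------
    def fit(self, trace, y=None):
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        x = self._currents(trace)
        fit_x = x
        if x.size > self.max_fit_samples:
            mid = (x.size - self.max_fit_samples) // 2
            fit_x = x[mid:mid + self.max_fit_samples]
        means, sds = self._init_params(fit_x)
        hmm = GaussianHMM(n_components=self.n_states, covariance_type="diag",
                          n_iter=self.n_iter, tol=self.tol, init_params="",
                          params="stmc")
        hmm.startprob_ = np.full(self.n_states, 1.0 / self.n_states)
        hmm.transmat_ = self._transmat_init()
        hmm.means_ = means.reshape(-1, 1)
        hmm.covars_ = (sds ** 2).reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # hmmlearn logs a spurious non-monotone warning at float
            # round-off scale; EM is effectively converged there.
            logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
            hmm.fit(fit_x.reshape(-1, 1))
        order = np.argsort(hmm.means_.ravel())
        self.means_ = hmm.means_.ravel()[order]
        self.sds_ = np.sqrt(np.array(
            [hmm.covars_[i].ravel()[0] for i in order]))
        self.transmat_ = hmm.transmat_[np.ix_(order, order)]
        self.startprob_ = hmm.startprob_[order]
        self._hmm = GaussianHMM(n_components=self.n_states,
                                covariance_type="diag", init_params="")
        self._hmm.startprob_ = self.startprob_
        self._hmm.transmat_ = self.transmat_
        self._hmm.means_ = self.means_.reshape(-1, 1)
        self._hmm.covars_ = (self.sds_ ** 2).reshape(-1, 1)

        pooled_sd = float(np.max(self.sds_))
        gaps = np.diff(self.means_)
        if np.any(gaps < self.min_separation * pooled_sd):
            raise IdealizationError(
                "levels not resolved: fitted means "
                f"{np.round(self.means_, 4).tolist()} with emission s.d. "
                f"{np.round(self.sds_, 4).tolist()} — data may contain fewer "
                f"than n_states={self.n_states} distinct levels")
        return self

    def predict(self, trace) -> IdealizedPath:
        """Viterbi decode, then dead-time merge; returns an IdealizedPath."""
        if not hasattr(self, "means_"):
            raise RuntimeError("TraceIdealizer is not fitted")
        x = self._currents(trace)
        fs = trace.sampling_rate if isinstance(trace, CurrentTrace) else None
        if fs is None:
            raise ValueError("predict needs a CurrentTrace (sampling rate)")
        states = self._decode(x)
        dead = self.dead_time if self.dead_time is not None else 10.0 / fs
        min_samples = max(1, int(round(dead * fs)))
        merged, spikes = merge_short_dwells(
            states, x, self.means_, self.sds_, min_samples,
            record_spikes=self.detect_spikes, sampling_rate=fs)
        return IdealizedPath(merged.astype(np.int8), self.means_.copy(),
                             self.sds_.copy(), fs, spikes)

    def fit_predict(self, trace) -> IdealizedPath:
        return self.fit(trace).predict(trace)

    def _decode(self, x: np.ndarray, chunk: int = 4_000_000,
                overlap: int = 50_000) -> np.ndarray:
        """Viterbi decoding, chunked with overlap for very long traces."""
        if x.size <= chunk:
            return self._hmm.predict(x.reshape(-1, 1))
        out = np.empty(x.size, dtype=np.int64)
        start = 0
        while start < x.size:
            lo = max(0, start - overlap)
            hi = min(x.size, start + chunk + overlap)
            seg = self._hmm.predict(x[lo:hi].reshape(-1, 1))
            take_lo = start - lo
            take_hi = take_lo + min(chunk, x.size - start)
            out[start:start + (take_hi - take_lo)] = seg[take_lo:take_hi]
            start += chunk
        return out


def idealize_states(trace: CurrentTrace, n_states: int = 3,
                    dead_time: float | None = None, **kwargs) -> IdealizedPath:
    """Fit a Gaussian HMM to ``trace`` and return its idealized path."""
    return TraceIdealizer(n_states=n_states, dead_time=dead_time,
                          **kwargs).fit_predict(trace)


# ---------------------------------------------------------------------------
# Event extraction and read segmentation
# ---------------------------------------------------------------------------

def extract_events(path: IdealizedPath, trace: CurrentTrace) -> pd.DataFrame:
    """One record per maximal state run.

    Columns: state (label), start_s, dwell_s, mean_current_nA.  The mean
    current is taken over the run's samples of the (filtered) trace, and
    the dwells sum exactly to the trace duration.
    """
    if len(path) != len(trace):
        raise ValueError("path and trace are not aligned")
    starts, lengths, values = run_length_encode(path.state_per_sample)
    sums = np.add.reduceat(trace.currents, starts)
    fs = path.sampling_rate
    return pd.DataFrame({
        "state": [STATE_NAMES[int(v)] for v in values],
        "start_s": starts / fs,
        "dwell_s": lengths / fs,
        "mean_current_nA": sums / lengths,
    })


@dataclass
class DegradationRead:
    """Events strictly between two adjacent low states, with >= 1 high visit."""

    read_id: int
    events: pd.DataFrame
    step_events: list[tuple[int, int]] = field(default_factory=list)

    @property
    def step_count(self) -> int:
        return int((self.events["state"] == "high").sum())

    def step_observations(self) -> pd.DataFrame:
        """Per-step (dwell, current) of the mid event preceding each high visit.

        ``step_index`` is 1-based in processing order, i.e. from the
        3'-terminus of the substrate.
        """
        rows = []
        for k, (mid_i, _high_i) in enumerate(self.step_events, start=1):
            mid = self.events.loc[mid_i]
            rows.append({"read_id": self.read_id, "step_index": k,
                         "dwell": float(mid["dwell_s"]),
                         "current": float(mid["mean_current_nA"])})
        return pd.DataFrame(rows)


def segment_reads(events: pd.DataFrame, return_episodes: bool = False):
    """Cut an event table into complete degradation reads.

    A read spans the events strictly between two adjacent low-state
    events.  Gaps with no high visit are binding-only episodes, not
    reads.  Traces containing no low state yield an empty list with a
    warning.
    """
    low_idx = events.index[events["state"] == "low"].to_numpy()
    reads: list[DegradationRead] = []
    episodes: list[pd.DataFrame] = []
    if low_idx.size == 0:
        warnings.warn("no low state present; cannot segment reads")
        return (reads, episodes) if return_episodes else reads
    for a, b in zip(low_idx[:-1], low_idx[1:]):
        inner = events.loc[a + 1:b - 1]
        if inner.empty:
            continue
        if (inner["state"] == "high").sum() == 0:
            episodes.append(inner)
            continue
        step_events = []
        prev_mid = None
        for i, row in inner.iterrows():
            if row["state"] == "mid":
                prev_mid = i
            elif row["state"] == "high" and prev_mid is not None:
                step_events.append((prev_mid, i))
                prev_mid = None
        reads.append(DegradationRead(len(reads), inner, step_events))
    return (reads, episodes) if return_episodes else reads


def count_steps(read: DegradationRead) -> int:
    """Number of high-state visits in a read (= bases degraded)."""
    return read.step_count


def step_length_distribution(reads: list[DegradationRead]) -> pd.Series:
    """Histogram of step counts over reads, indexed by step count."""
    if not reads:
        return pd.Series(dtype=int, name="n_reads")
    counts = pd.Series([r.step_count for r in reads])
    hist = counts.value_counts().sort_index()
    hist.name = "n_reads"
    return hist
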