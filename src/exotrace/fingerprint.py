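"""Fingerprint-based nucleoside identification.

Every degradation step yields a (dwell, current) pair for the
intermediate state preceding its high-state visit.  Pooled over reads,
those pairs form a 2-D density — a fingerprint — for each sequence
position, which is compared against reference fingerprints built from
homopolymer substrates.  Per-position calls from independent read
collections are overlaid into a sequence logo whose per-position
probability is the fraction of collections voting for each base.

Axes: dwell on a log scale (the dwell law is exponential-mixture), the
mean intermediate current linear.  The default similarity metric scores
a position's observations by their mean log-density under each base's
reference kernel-density estimate; a Bhattacharyya-coefficient overlap
between gridded densities is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin

from .idealize import DegradationRead
from .models import BASES


def step_to_position(step_index: int, length: int) -> int:
    """Processing-order step k (1 = 3'-terminal base) -> 5'-based position.

    The mapping is its own inverse: applying it twice restores the input.
    """
    if not 1 <= step_index <= length:
        raise ValueError("step index outside read length")
    return length - step_index + 1


position_to_step = step_to_position


def collect_step_observations(reads: list[DegradationRead],
                              expected_steps: int) -> pd.DataFrame:
    """Pooled per-step (dwell, current) table from complete reads only.

    Reads whose step count differs from ``expected_steps`` are dropped —
    the completeness prerequisite that guards against movement missteps
    and segmentation errors.  Retention counts are recorded in
    ``df.attrs``.  The final step's dwell is retained here (it still
    carries coordination information for fingerprinting) even though
    hydrolysis-rate summaries exclude it.
    """
    kept = [r for r in reads if r.step_count == expected_steps
            and len(r.step_events) == expected_steps]
    if not kept:
        raise ValueError(
            f"no read with exactly {expected_steps} steps retained "
            f"(of {len(reads)} candidate reads)")
    df = pd.concat([r.step_observations() for r in kept], ignore_index=True)
    df.attrs["n_total"] = len(reads)
    df.attrs["n_retained"] = len(kept)
    return df


@dataclass
class FingerprintGrid:
    """Shared evaluation grid: log-spaced dwell x linear current."""

    dwell_min: float = 0.5e-3      # s
    dwell_max: float = 500e-3
    dwell_bins: int = 64
    current_min: float = 1.4       # nA; +-4 noise_sd around the mid level
    current_max: float = 2.6
    current_bins: int = 32

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        logd = np.linspace(np.log(self.dwell_min), np.log(self.dwell_max),
                           self.dwell_bins)
        cur = np.linspace(self.current_min, self.current_max,
                          self.current_bins)
        return logd, cur

    def cell_area(self) -> float:
        logd, cur = self.centers()
        return float((logd[1] - logd[0]) * (cur[1] - cur[0]))


def _make_kde(X: np.ndarray, bw_method=None):
    """KDE over (log-dwell, current); degenerate axes handled.

    Returns (kde, kind): kind '2d', '1d-dwell', '1d-current' or 'delta'
    depending on which axes carry spread.  ``bw_method`` follows
    :class:`scipy.stats.gaussian_kde` (default Scott's rule; pass a
    scalar for an n-independent bandwidth).
    """
    scale = np.maximum(np.abs(X).mean(axis=0), 1.0)
    spread = X.std(axis=0) > 1e-12 * scale
    if spread.all():
        return gaussian_kde(X.T, bw_method=bw_method), "2d"
    if spread[0]:
        return gaussian_kde(X[:, 0], bw_method=bw_method), "1d-dwell"
    if spread[1]:
        return gaussian_kde(X[:, 1], bw_method=bw_method), "1d-current"
    return None, "delta"


@dataclass
class Fingerprint:
    """Normalized 2-D density over (log-dwell, current) for one label."""

    label: str
    density: np.ndarray            # (dwell_bins, current_bins), sums to 1
    grid: FingerprintGrid
    n_obs: int
    degenerate: bool = False


def build_fingerprint(observations: pd.DataFrame, label: str,
                      grid: FingerprintGrid | None = None,
                      min_obs: int = 20, bw_method=None) -> Fingerprint:
    """KDE fingerprint of one position or one reference base.

    ``observations`` needs ``dwell`` and ``current`` columns.  The
    density is evaluated on the shared grid and normalized to sum to 1;
    all-identical observations give a single-cell delta, flagged.
    """
    grid = grid or FingerprintGrid()
    X = observations[["dwell", "current"]].to_numpy(dtype=float)
    if X.shape[0] < min_obs:
        warnings.warn(f"fingerprint {label!r}: only {X.shape[0]} observations "
                      f"(recommended >= {min_obs})")
    Xl = np.column_stack([np.log(X[:, 0]), X[:, 1]])
    kde, kind = _make_kde(Xl, bw_method)
    logd, cur = grid.centers()
    D, C = np.meshgrid(logd, cur, indexing="ij")
    if kind == "2d":
        dens = kde(np.vstack([D.ravel(), C.ravel()])).reshape(D.shape)
    elif kind == "1d-dwell":
        j = int(np.argmin(np.abs(cur - Xl[0, 1])))
        dens = np.zeros(D.shape)
        dens[:, j] = kde(logd)
    elif kind == "1d-current":
        i = int(np.argmin(np.abs(logd - Xl[0, 0])))
        dens = np.zeros(D.shape)
        dens[i, :] = kde(cur)
    else:
        i = int(np.argmin(np.abs(logd - Xl[0, 0])))
        j = int(np.argmin(np.abs(cur - Xl[0, 1])))
        dens = np.zeros(D.shape)
        dens[i, j] = 1.0
        warnings.warn(f"fingerprint {label!r}: degenerate observations")
    total = dens.sum()
    if total > 0:
        dens = dens / total
    return Fingerprint(label, dens, grid, X.shape[0], kind != "2d")


@dataclass
class ReferenceLibrary:
    """One fingerprint and KDE per base, on a shared grid."""

    fingerprints: dict[str, Fingerprint]
    kdes: dict[str, tuple]          # base -> (kde, kind, first_obs)
    grid: FingerprintGrid

    def __post_init__(self):
        missing = set(BASES) - set(self.fingerprints)
        if missing:
            raise ValueError(f"reference library missing base(s) {sorted(missing)}")


def build_reference_library(obs_by_base: dict[str, pd.DataFrame],
                            grid: FingerprintGrid | None = None
                            ) -> ReferenceLibrary:
    """Per-base reference fingerprints pooled over homopolymer reads."""
    grid = grid or FingerprintGrid()
    fps, kdes = {}, {}
    for base in BASES:
        if base not in obs_by_base:
            raise ValueError(f"missing homopolymer observations for base {base}")
        obs = obs_by_base[base]
        fps[base] = build_fingerprint(obs, base, grid)
        X = np.column_stack([np.log(obs["dwell"].to_numpy(dtype=float)),
                             obs["current"].to_numpy(dtype=float)])
        kde, kind = _make_kde(X)
        kdes[base] = (kde, kind, X[0])
    return ReferenceLibrary(fps, kdes, grid)


@dataclass
class PositionCall:
    position: int                  # 1-based from the 5' terminus
    call: str                      # A/U/C/G or N
    scores: dict[str, float]
    margin: float


class FingerprintClassifier(BaseEstimator, ClassifierMixin):
    """Nucleoside classifier against homopolymer reference fingerprints.

    ``fit(X, y)`` takes observations ``X`` of shape (n, 2) with columns
    (dwell s, current nA) and base labels ``y``; it builds one reference
    KDE per base in (log-dwell, current) space.  ``predict`` assigns each
    observation its maximum-log-density base; :meth:`call_position`
    scores a whole set of observations from one sequence position and
    returns N when the top-two mean-log-density margin falls below
    ``margin_threshold`` (nats).
    """

    def __init__(self, metric: str = "logdensity",
                 margin_threshold: float = 0.05,
                 grid: FingerprintGrid | None = None):
        self.metric = metric
        self.margin_threshold = margin_threshold
        self.grid = grid

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        obs_by_base = {}
        for base in np.unique(y):
            sel = X[y == base]
            obs_by_base[str(base)] = pd.DataFrame(
                {"dwell": sel[:, 0], "current": sel[:, 1]})
        self.library_ = build_reference_library(obs_by_base, self.grid)
        self.classes_ = np.array(sorted(obs_by_base))
        return self

    def _log_density(self, base: str, Xl: np.ndarray) -> np.ndarray:
        kde, kind, first = self.library_.kdes[base]
        floor = -745.0                       # log of smallest positive double
        if kind == "2d":
            with np.errstate(divide="ignore"):
                return np.maximum(np.log(kde(Xl.T)), floor)
        if kind == "1d-dwell":
            with np.errstate(divide="ignore"):
                return np.maximum(np.log(kde(Xl[:, 0])), floor)
        if kind == "1d-current":
            with np.errstate(divide="ignore"):
                return np.maximum(np.log(kde(Xl[:, 1])), floor)
        return np.where(np.all(np.isclose(Xl, first), axis=1), 0.0, floor)

    def score_observations(self, X) -> dict[str, float]:
        """Mean log-density of the observations under each reference."""
        X = np.asarray(X, dtype=float)
        Xl = np.column_stack([np.log(X[:, 0]), X[:, 1]])
        return {b: float(self._log_density(b, Xl).mean())
                for b in self.library_.fingerprints}

    def _bhattacharyya_scores(self, X) -> dict[str, float]:
        obs = pd.DataFrame({"dwell": X[:, 0], "current": X[:, 1]})
        fp = build_fingerprint(obs, "query", self.library_.grid, min_obs=1)
        return {b: float(np.sum(np.sqrt(fp.density * ref.density)))
                for b, ref in self.library_.fingerprints.items()}

    def call_position(self, X, position: int = 0) -> PositionCall:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty observations")
        if self.metric == "bhattacharyya":
            scores = self._bhattacharyya_scores(X)
        else:
            scores = self.score_observations(X)
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        margin = ranked[0][1] - ranked[1][1]
        call = ranked[0][0] if margin >= self.margin_threshold else "N"
        return PositionCall(position, call, scores, margin)

    def predict(self, X):
        """Per-observation base assignment (argmax log-density)."""
        X = np.asarray(X, dtype=float)
        Xl = np.column_stack([np.log(X[:, 0]), X[:, 1]])
        ll = np.column_stack([self._log_density(b, Xl) for b in self.classes_])
        return self.classes_[np.argmax(ll, axis=1)]


def classify_position(observations: pd.DataFrame,
                      classifier: FingerprintClassifier,
                      position: int = 0) -> PositionCall:
    X = observations[["dwell", "current"]].to_numpy(dtype=float)
    return classifier.call_position(X, position)


def calls_for_collection(obs: pd.DataFrame, classifier: FingerprintClassifier,
                         n_steps: int) -> list[PositionCall]:
    """Classify every step of one collection; returns calls 5'->3'.

    Step k (processing order, from the 3' terminus) reports at 5'-based
    position n_steps - k + 1.
    """
    calls: dict[int, PositionCall] = {}
    for k in range(1, n_steps + 1):
        sub = obs[obs["step_index"] == k]
        pos = step_to_position(k, n_steps)
        if sub.empty:
            calls[pos] = PositionCall(pos, "N", {}, 0.0)
        else:
            calls[pos] = classify_position(sub, classifier, pos)
    return [calls[p] for p in range(1, n_steps + 1)]


@dataclass
class SeqLogo:
    """Per-position base probabilities aggregated across collections."""

    probs: pd.DataFrame            # index position (5'->3'), cols A,U,C,G,N
    consensus: str
    accuracy: float | None = None
    n_collections: int = 0
    matched: list[bool] = field(default_factory=list)


def aggregate_logo(collections: list[list[PositionCall] | list[str]],
                   truth: str | None = None) -> SeqLogo:
    """Overlay per-position calls from independent collections.

    Each position's probability for a base is (votes for that base) /
    (number of collections).  The consensus is the plurality call (ties
    -> N); with ``truth`` given, a position counts as identified when
    the consensus matches it, and accuracy = identified / length.
    """
    if not collections:
        raise ValueError("no collections")
    as_strings = [[c.call if isinstance(c, PositionCall) else str(c)
                   for c in coll] for coll in collections]
    L = len(as_strings[0])
    if any(len(c) != L for c in as_strings):
        raise ValueError("collections cover different position ranges")
    letters = list(BASES) + ["N"]
    counts = np.zeros((L, len(letters)))
    for coll in as_strings:
        for i, call in enumerate(coll):
            counts[i, letters.index(call)] += 1
    probs = pd.DataFrame(counts / len(as_strings), columns=letters,
                         index=pd.RangeIndex(1, L + 1, name="position"))
    consensus = []
    for i in range(L):
        base_votes = counts[i, :4]
        top = base_votes.max()
        if top == 0 or (base_votes == top).sum() > 1:
            consensus.append("N")
        else:
            consensus.append(letters[int(np.argmax(base_votes))])
    consensus_s = "".join(consensus)
    accuracy = None
    matched: list[bool] = []
    if truth is not None:
        if len(truth) != L:
            raise ValueError("truth length does not match collections")
        matched = [consensus_s[i] == truth[i] for i in range(L)]
        accuracy = sum(matched) / L
    return SeqLogo(probs, consensus_s, accuracy, len(as_strings), matched)


def split_collections(reads: list, n_collections: int,
                      reads_per_collection: int | None = None,
                      rng: np.random.Generator | None = None) -> list[list]:
    """Split bulk reads into disjoint collections by read order.

    Pass an ``rng`` for a seeded shuffle before splitting.
    """
    reads = list(reads)
    if rng is not None:
        perm = rng.permutation(len(reads))
        reads = [reads[i] for i in perm]
    if reads_per_collection is None:
        reads_per_collection = len(reads) // n_collections
    if reads_per_collection * n_collections > len(reads):
        raise ValueError("not enough reads for the requested collections")
    return [reads[i * reads_per_collection:(i + 1) * reads_per_collection]
            for i in range(n_collections)]
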