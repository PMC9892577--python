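"""Fingerprint construction, classification, and seq-logo aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from exotrace.fingerprint import (
    FingerprintClassifier,
    FingerprintGrid,
    PositionCall,
    aggregate_logo,
    build_fingerprint,
    build_reference_library,
    collect_step_observations,
    split_collections,
    step_to_position,
)
from exotrace.models import default_nucleoside_table

TAU1 = 8.86e-3
SIGMA_CURRENT = 0.01   # s.e. of the mean intermediate current per event


def base_observations(base, n, rng, nk=None):
    """Direct draws from the per-base two-step dwell/current model."""
    nk = nk or default_nucleoside_table()
    dwell = rng.exponential(TAU1, n) + rng.exponential(nk[base].tau2_mean, n)
    current = 2.0 + nk[base].current_offset + rng.normal(0, SIGMA_CURRENT, n)
    return pd.DataFrame({"dwell": dwell, "current": current})


@pytest.fixture(scope="module")
def reference_classifier():
    rng = np.random.default_rng(42)
    X, y = [], []
    for base in "AUCG":
        obs = base_observations(base, 1500, rng)
        X.append(obs[["dwell", "current"]].to_numpy())
        y.extend([base] * 1500)
    clf = FingerprintClassifier()
    clf.fit(np.vstack(X), np.array(y))
    return clf


class TestStepPositionMapping:
    def test_examples(self):
        assert step_to_position(1, 30) == 30      # first degraded = 3' end
        assert step_to_position(30, 30) == 1

    def test_involution(self):
        for L in (24, 30):
            for k in range(1, L + 1):
                assert step_to_position(step_to_position(k, L), L) == k

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            step_to_position(31, 30)


class TestCollectObservations:
    def _fake_read(self, read_id, steps, rng):
        from exotrace.idealize import DegradationRead
        states, dwells = [], []
        for _ in range(steps):
            states += ["mid", "high"]
            dwells += [float(rng.exponential(0.05)),
                       float(rng.exponential(0.01))]
        ev = pd.DataFrame({"state": states, "start_s": np.cumsum(dwells),
                           "dwell_s": dwells,
                           "mean_current_nA": 2.0 + rng.normal(0, 0.01,
                                                               len(states))})
        pairs = [(2 * i, 2 * i + 1) for i in range(steps)]
        return DegradationRead(read_id, ev, pairs)

    def test_off_length_reads_excluded(self):
        rng = np.random.default_rng(0)
        reads = [self._fake_read(i, s, rng)
                 for i, s in enumerate([30, 29, 30, 31, 30])]
        obs = collect_step_observations(reads, 30)
        assert obs.attrs["n_retained"] == 3
        assert obs.attrs["n_total"] == 5
        assert set(obs["read_id"]) == {0, 2, 4}

    def test_zero_retained_is_explicit_failure(self):
        rng = np.random.default_rng(1)
        reads = [self._fake_read(0, 29, rng)]
        with pytest.raises(ValueError, match="no read"):
            collect_step_observations(reads, 30)


class TestFingerprint:
    def test_density_normalized(self):
        rng = np.random.default_rng(2)
        fp = build_fingerprint(base_observations("A", 500, rng), "A")
        assert fp.density.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplication_invariance_at_fixed_bandwidth(self):
        rng = np.random.default_rng(3)
        obs = base_observations("U", 300, rng)
        doubled = pd.concat([obs, obs], ignore_index=True)
        a = build_fingerprint(obs, "U", bw_method=0.3)
        b = build_fingerprint(doubled, "U", bw_method=0.3)
        # only the (n-1)/n covariance normalization differs
        assert np.allclose(a.density, b.density, atol=5e-5)

    def test_dwell_marginal_matches_exponential_law(self):
        # no current spread: 1-D KDE over log-dwell; compare with the
        # push-forward of Exp(tau) onto the log axis
        rng = np.random.default_rng(4)
        tau = 0.05
        obs = pd.DataFrame({"dwell": rng.exponential(tau, 4000),
                            "current": np.full(4000, 2.0)})
        grid = FingerprintGrid()
        fp = build_fingerprint(obs, "x", grid)
        assert fp.degenerate  # current axis carries no spread
        logd, _ = grid.centers()
        marginal = fp.density.sum(axis=1)
        d = np.exp(logd)
        expected = (d / tau) * np.exp(-d / tau)      # pdf of log-dwell
        expected /= expected.sum()
        assert np.max(np.abs(marginal - expected)) < 0.2 * expected.max()

    def test_degenerate_observations_flagged(self):
        obs = pd.DataFrame({"dwell": [0.05] * 30, "current": [2.0] * 30})
        with pytest.warns(UserWarning, match="degenerate"):
            fp = build_fingerprint(obs, "x")
        assert fp.degenerate
        assert fp.density.max() == 1.0


class TestReferenceLibrary:
    def test_dwell_marginal_order_follows_coordination_times(self):
        # tau2 ordering C < A < U < G
        rng = np.random.default_rng(5)
        obs = {b: base_observations(b, 2000, rng) for b in "AUCG"}
        lib = build_reference_library(obs)
        logd, _ = lib.grid.centers()
        means = {b: float((lib.fingerprints[b].density.sum(axis=1)
                           * logd).sum()) for b in "AUCG"}
        assert means["C"] < means["A"] < means["U"] < means["G"]

    def test_identical_inputs_identical_fingerprints(self):
        rng = np.random.default_rng(6)
        shared = base_observations("A", 500, rng)
        obs = {b: shared for b in "AUCG"}
        lib = build_reference_library(obs)
        assert np.allclose(lib.fingerprints["A"].density,
                           lib.fingerprints["G"].density)

    def test_missing_base_rejected(self):
        rng = np.random.default_rng(7)
        obs = {b: base_observations(b, 100, rng) for b in "AUC"}
        with pytest.raises(ValueError, match="missing"):
            build_reference_library(obs)

    def test_observation_bookkeeping(self):
        rng = np.random.default_rng(8)
        obs = {b: base_observations(b, 321, rng) for b in "AUCG"}
        lib = build_reference_library(obs)
        assert all(lib.fingerprints[b].n_obs == 321 for b in "AUCG")


class TestClassification:
    def test_self_consistency_at_full_depth(self, reference_classifier):
        rng = np.random.default_rng(9)
        for base in "AUCG":
            obs = base_observations(base, 150, rng)
            call = reference_classifier.call_position(
                obs[["dwell", "current"]].to_numpy())
            assert call.call == base

    def test_tied_references_called_n(self):
        rng = np.random.default_rng(10)
        shared = base_observations("A", 800, rng)
        X = np.vstack([shared[["dwell", "current"]].to_numpy()] * 4)
        y = np.concatenate([[b] * 800 for b in "AUCG"])
        clf = FingerprintClassifier().fit(X, y)
        call = clf.call_position(
            base_observations("A", 50, rng)[["dwell", "current"]].to_numpy())
        assert call.call == "N"
        assert call.margin == pytest.approx(0.0, abs=1e-12)

    def test_margin_threshold_controls_no_calls(self):
        # an extreme margin requirement turns every call into N
        rng = np.random.default_rng(20)
        X = np.vstack([base_observations(b, 400, rng)[["dwell", "current"]]
                       .to_numpy() for b in "AUCG"])
        y = np.concatenate([[b] * 400 for b in "AUCG"])
        strict = FingerprintClassifier(margin_threshold=1e6).fit(X, y)
        lenient = FingerprintClassifier(margin_threshold=0.05).fit(X, y)
        obs = base_observations("G", 150, rng)[["dwell", "current"]].to_numpy()
        assert strict.call_position(obs).call == "N"
        assert lenient.call_position(obs).call == "G"

    def test_empty_observations_rejected(self, reference_classifier):
        with pytest.raises(ValueError, match="empty"):
            reference_classifier.call_position(np.empty((0, 2)))

    def test_accuracy_monotone_in_observation_depth(self,
                                                    reference_classifier):
        rng = np.random.default_rng(11)
        rates = []
        for n in (10, 50, 150):
            hits = 0
            for _ in range(50):
                base = "AUCG"[int(rng.integers(4))]
                obs = base_observations(base, n, rng)
                call = reference_classifier.call_position(
                    obs[["dwell", "current"]].to_numpy())
                hits += call.call == base
            rates.append(hits / 50)
        assert rates[0] <= rates[1] + 0.05
        assert rates[1] <= rates[2] + 0.05
        assert rates[2] >= 0.95

    def test_label_permutation_null_is_chance_level(self):
        # averaged over all 24 label permutations, accuracy equals the
        # mean fixed-point fraction of S4 = 25%
        rng = np.random.default_rng(12)
        ref = {b: base_observations(b, 800, rng) for b in "AUCG"}
        query = {b: base_observations(b, 150, rng) for b in "AUCG"}
        accs = []
        for perm in itertools.permutations("AUCG"):
            X = np.vstack([ref[b][["dwell", "current"]].to_numpy()
                           for b in "AUCG"])
            y = np.concatenate([[p] * 800 for p in perm])
            clf = FingerprintClassifier().fit(X, y)
            hits = sum(clf.call_position(
                query[b][["dwell", "current"]].to_numpy()).call == b
                for b in "AUCG")
            accs.append(hits / 4)
        assert np.mean(accs) == pytest.approx(0.25, abs=0.05)


class TestLogoAggregation:
    def test_unanimous_collections(self):
        truth = "CGAU"
        logo = aggregate_logo([list(truth)] * 10, truth)
        assert logo.accuracy == 1.0
        for i, b in enumerate(truth, start=1):
            assert logo.probs.loc[i, b] == 1.0

    def test_all_n_collections(self):
        logo = aggregate_logo([["N"] * 4] * 10, "CGAU")
        assert logo.accuracy == 0.0
        assert logo.consensus == "NNNN"

    def test_majority_vote_with_ties_to_n(self):
        colls = [["A", "G"], ["A", "C"], ["U", "C"], ["A", "G"]]
        logo = aggregate_logo(colls, "AC")
        assert logo.consensus[0] == "A"       # 3/4 votes
        assert logo.consensus[1] == "N"       # G and C tie 2-2
        assert logo.accuracy == 0.5

    def test_probability_denominator_is_collection_count(self):
        colls = [["A"], ["A"], ["G"], ["N"]]
        logo = aggregate_logo(colls)
        assert logo.probs.loc[1, "A"] == 0.5
        assert logo.probs.loc[1, "G"] == 0.25
        assert logo.probs.loc[1, "N"] == 0.25

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="different position"):
            aggregate_logo([["A", "U"], ["A"]])


class TestCollections:
    def test_split_by_read_order(self):
        reads = list(range(20))
        colls = split_collections(reads, 4, 5)
        assert colls[0] == [0, 1, 2, 3, 4]
        assert len(colls) == 4

    def test_insufficient_reads_rejected(self):
        with pytest.raises(ValueError, match="not enough"):
            split_collections(list(range(10)), 3, 5)

    def test_seeded_shuffle_reproducible(self):
        a = split_collections(list(range(30)), 3, 10,
                              rng=np.random.default_rng(1))
        b = split_collections(list(range(30)), 3, 10,
                              rng=np.random.default_rng(1))
        assert a == b
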