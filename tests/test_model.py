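"""Unit and property tests for the dual-retrieval pattern model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualrecall import (
    PARAM_NAMES,
    PATTERN_LABELS,
    DualRetrievalParams,
    pattern_probabilities,
    simulate_patterns,
)
from dualrecall.model import _probabilities_from_vector, _probabilities_gradient


def params(d, f, j1, j2, j3, r):
    return DualRetrievalParams.from_array([d, f, j1, j2, j3, r])


def enumerate_paths(p: DualRetrievalParams) -> np.ndarray:
    """Independent oracle: walk every latent path and accumulate products.

    Branches: direct access (forgetting after tests 1 and 2), gist
    reconstruction (independent familiarity output per test), neither.
    """
    d, f, j1, j2, j3, r = p.to_array()
    probs = np.zeros(8)

    # Direct-access branch: recalled while the state survives.
    for lost1 in (False, True):          # between tests 1 and 2
        w1 = f if lost1 else 1 - f
        if lost1:
            probs[4] += d * w1           # C E E
            continue
        for lost2 in (False, True):      # between tests 2 and 3
            w2 = f if lost2 else 1 - f
            probs[6 if lost2 else 7] += d * w1 * w2  # CCE / CCC

    # Gist branch: output on each test independently.
    for x1 in (0, 1):
        for x2 in (0, 1):
            for x3 in (0, 1):
                w = (
                    (j1 if x1 else 1 - j1)
                    * (j2 if x2 else 1 - j2)
                    * (j3 if x3 else 1 - j3)
                )
                probs[4 * x1 + 2 * x2 + x3] += (1 - d) * r * w

    probs[0] += (1 - d) * (1 - r)        # neither trace
    return probs


class TestPatternProbabilities:
    def test_certain_direct_access_yields_only_ccc(self):
        dist = pattern_probabilities(params(1, 0, 0.5, 0.5, 0.5, 0.3))
        assert dist["CCC"] == pytest.approx(1.0)
        assert dist.probabilities[:7] == pytest.approx(np.zeros(7))

    def test_no_trace_yields_only_eee(self):
        dist = pattern_probabilities(params(0, 0.2, 0.5, 0.5, 0.5, 0))
        assert dist["EEE"] == pytest.approx(1.0)

    def test_hand_derived_interior_case(self):
        # D=0.4, F=0.1, R=0.5, J1=J2=J3=0.5: branch expressions by hand.
        dist = pattern_probabilities(params(0.4, 0.1, 0.5, 0.5, 0.5, 0.5))
        expected = {
            "CCC": 0.3615, "CCE": 0.0735, "CEE": 0.0775, "EEE": 0.3375,
            "CEC": 0.0375, "ECC": 0.0375, "ECE": 0.0375, "EEC": 0.0375,
        }
        for label, value in expected.items():
            assert dist[label] == pytest.approx(value, abs=1e-12), label

    def test_invalid_parameter_names_offending_field(self):
        with pytest.raises(ValueError, match="forgetting"):
            DualRetrievalParams(
                direct_access=0.5, forgetting=1.5, reconstruction=0.5,
                familiarity_t1=0.5, familiarity_t2=0.5, familiarity_t3=0.5,
            )

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6))
    def test_matches_path_enumeration_oracle(self, values):
        p = DualRetrievalParams.from_array(values)
        got = pattern_probabilities(p).probabilities
        assert got == pytest.approx(enumerate_paths(p), abs=1e-12)

    def test_normalization_over_random_parameter_vectors(self):
        rng = np.random.default_rng(7)
        for theta in rng.uniform(0, 1, size=(2000, 6)):
            probs = _probabilities_from_vector(theta)
            assert abs(probs.sum() - 1.0) < 1e-10
            assert np.all(probs >= 0) and np.all(probs <= 1)

    @pytest.mark.parametrize("index", [0, 2, 3, 4, 5])  # D, J1, J2, J3, R
    def test_eee_probability_nonincreasing(self, index):
        rng = np.random.default_rng(11)
        for theta in rng.uniform(0.05, 0.95, size=(50, 6)):
            grid = np.linspace(0, 1, 21)
            values = []
            for g in grid:
                t = theta.copy()
                t[index if index != 5 else 5] = g
                values.append(_probabilities_from_vector(t)[0])
            assert np.all(np.diff(values) <= 1e-12)

    def test_gradient_matches_finite_differences(self):
        from scipy.optimize import approx_fprime

        rng = np.random.default_rng(3)
        for theta in rng.uniform(0.05, 0.95, size=(10, 6)):
            numeric = np.stack([
                approx_fprime(
                    theta, lambda t, i=i: _probabilities_from_vector(t)[i], 1e-7
                )
                for i in range(8)
            ])
            assert _probabilities_gradient(theta) == pytest.approx(
                numeric, abs=1e-5
            )


class TestSimulatePatterns:
    def test_certain_recall_all_ccc(self):
        counts = simulate_patterns(params(1, 0, 0.5, 0.5, 0.5, 0.5), 100, seed=1)
        assert counts["CCC"] == 100 and counts.n_items == 100

    def test_same_seed_reproduces_counts(self):
        p = params(0.4, 0.1, 0.5, 0.6, 0.7, 0.3)
        a = simulate_patterns(p, 500, seed=42)
        b = simulate_patterns(p, 500, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_frequencies_match_probabilities_within_binomial_error(self):
        p = params(0.35, 0.08, 0.45, 0.55, 0.7, 0.25)
        n = 1_000_000
        counts = simulate_patterns(p, n, seed=9)
        probs = pattern_probabilities(p).probabilities
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(counts.counts / n - probs) <= 4 * se + 1e-12)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            simulate_patterns(params(0.4, 0.1, 0.5, 0.5, 0.5, 0.5), 0, seed=0)


class TestSerialization:
    def test_parameter_record_round_trip(self):
        p = params(0.42, 0.05, 0.40, 0.52, 0.79, 0.19)
        text = p.to_record()
        assert text.splitlines()[0] == "D,F,J1,J2,J3,R"
        assert DualRetrievalParams.from_record(text) == p

    def test_array_order_is_table_layout(self):
        p = DualRetrievalParams(
            direct_access=0.1, forgetting=0.2, reconstruction=0.6,
            familiarity_t1=0.3, familiarity_t2=0.4, familiarity_t3=0.5,
        )
        assert list(p.to_array()) == [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert PARAM_NAMES == ("D", "F", "J1", "J2", "J3", "R")

    def test_pattern_count_record_round_trip(self):
        counts = simulate_patterns(params(0.4, 0.1, 0.5, 0.5, 0.5, 0.5), 200, seed=5)
        text = counts.to_record()
        assert text.splitlines()[0] == "EEE,EEC,ECE,ECC,CEE,CEC,CCE,CCC"
        assert np.array_equal(type(counts).from_record(text).counts, counts.counts)

    def test_pattern_labels_follow_canonical_bit_order(self):
        # index = 4*[t1=C] + 2*[t2=C] + [t3=C]
        assert PATTERN_LABELS[0] == "EEE"
        assert PATTERN_LABELS[7] == "CCC"
        assert PATTERN_LABELS[6] == "CCE"
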