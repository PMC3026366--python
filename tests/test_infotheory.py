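import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlgrn.errors import ValidationError
from tlgrn.infotheory import (
    conditional_mutual_information,
    entropy,
    joint_entropy2,
    joint_entropy3,
    lag_trim_pair,
    mutual_information,
    tlcmi,
    tlmi,
)

# ---------------------------------------------------------------------------
# independent oracle: entropies straight from symbol counts


def oracle_entropy(*seqs):
    counts = Counter(zip(*seqs))
    total = sum(counts.values())
    return -sum(c / total * math.log2(c / total) for c in counts.values())


def oracle_cmi(a, b, c):
    return (
        oracle_entropy(a, c)
        + oracle_entropy(b, c)
        - oracle_entropy(c)
        - oracle_entropy(a, b, c)
    )


binary_seq = st.lists(st.integers(0, 1), min_size=4, max_size=50)


class TestEntropy:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ([0, 0, 1, 1], 1.0),
            ([0, 0, 0, 0], 0.0),
            ([0, 1, 1, 1], -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))),
        ],
    )
    def test_values(self, seq, expected):
        assert entropy(seq) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            entropy([])

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            entropy([0, 1, 2])


class TestJointEntropy:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0, 1, 0, 1], [0, 1, 0, 1], 1.0),        # H(A,A) = H(A)
            ([0, 0, 1, 1], [0, 1, 0, 1], 2.0),        # independent uniform
            ([0, 0, 1, 1], [1, 1, 0, 0], 1.0),        # deterministic complement
        ],
    )
    def test_pairwise(self, a, b, expected):
        assert joint_entropy2(a, b) == pytest.approx(expected, abs=1e-12)

    def test_three_way_collapse(self):
        a = [0, 1, 1, 0]
        assert joint_entropy3(a, a, a) == pytest.approx(entropy(a), abs=1e-12)

    def test_three_way_full_support(self):
        # the 8 binary patterns, one each
        a = [0, 0, 0, 0, 1, 1, 1, 1]
        b = [0, 0, 1, 1, 0, 0, 1, 1]
        c = [0, 1, 0, 1, 0, 1, 0, 1]
        assert joint_entropy3(a, b, c) == pytest.approx(3.0, abs=1e-12)

    def test_constant_third_variable_degenerates(self):
        a, b = [0, 1, 1, 0], [1, 1, 0, 0]
        assert joint_entropy3(a, b, [0, 0, 0, 0]) == pytest.approx(
            joint_entropy2(a, b), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            joint_entropy2([0, 1], [0, 1, 0])


class TestMutualInformation:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0, 1, 0, 1], [0, 1, 0, 1], 1.0),
            ([0, 0, 1, 1], [0, 1, 0, 1], 0.0),
            ([0, 0, 1, 1], [1, 1, 0, 0], 1.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert mutual_information(a, b) == pytest.approx(expected, abs=1e-12)

    def test_cmi_vacuous_conditioning(self):
        a, b = [0, 1, 1, 0, 1], [1, 1, 0, 0, 1]
        assert conditional_mutual_information(a, b, [1] * 5) == pytest.approx(
            mutual_information(a, b), abs=1e-12
        )

    def test_cmi_conditioning_variable_equals_b(self):
        a, b = [0, 1, 1, 0, 1], [1, 1, 0, 0, 1]
        assert conditional_mutual_information(a, b, b) == pytest.approx(0.0, abs=1e-12)

    def test_cmi_against_brute_force_oracle(self):
        a = [0, 0, 1, 1, 0, 1]
        b = [0, 1, 0, 1, 1, 0]
        c = [0, 0, 0, 1, 1, 1]
        assert conditional_mutual_information(a, b, c) == pytest.approx(
            oracle_cmi(a, b, c), abs=1e-12
        )


class TestLagTrimming:
    def test_zero_lag_is_identity(self):
        a, b = [0, 1, 0, 1], [1, 1, 0, 0]
        ta, tb = lag_trim_pair(a, b, 0)
        assert ta.tolist() == a and tb.tolist() == b

    def test_trim_indices(self):
        ta, tb = lag_trim_pair([0, 1, 0, 1], [1, 1, 0, 0], 1, min_overlap=3)
        assert ta.tolist() == [0, 1, 0] and tb.tolist() == [1, 0, 0]

    def test_full_lag_rejected(self):
        with pytest.raises(ValidationError):
            lag_trim_pair([0, 1, 0, 1], [1, 1, 0, 0], 4)

    def test_overlap_below_minimum_rejected(self):
        with pytest.raises(ValidationError, match="min_overlap"):
            lag_trim_pair([0, 1, 0, 1, 1], [1, 1, 0, 0, 1], 2, min_overlap=4)

    def test_tlmi_zero_lag_reduces_to_mi(self):
        a, b = [0, 1, 0, 1, 1, 0], [1, 1, 0, 0, 1, 0]
        assert tlmi(a, b, 0) == mutual_information(a, b)

    def test_tlmi_recovers_shifted_copy(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, size=30)
        tau = 3
        b = np.concatenate([rng.integers(0, 2, size=tau), a[:-tau]])
        trimmed_a = a[:-tau]
        assert tlmi(a, b, tau) == pytest.approx(entropy(trimmed_a), abs=1e-12)

    def test_tlmi_asymmetric_in_general(self):
        rng = np.random.default_rng(11)
        found = False
        for _ in range(20):
            a = rng.integers(0, 2, size=20)
            b = rng.integers(0, 2, size=20)
            if abs(tlmi(a, b, 2) - tlmi(b, a, 2)) > 1e-6:
                found = True
                break
        assert found, "TLMI should differ between directions on random data"

    def test_tlcmi_zero_lag_reduces_to_cmi(self):
        a, b, c = [0, 1, 0, 1, 1], [1, 1, 0, 0, 1], [0, 0, 1, 1, 0]
        assert tlcmi(a, b, c, 0) == conditional_mutual_information(a, b, c)

    def test_tlcmi_constant_conditioner_is_tlmi(self):
        a, b = [0, 1, 0, 1, 1, 0, 1], [1, 1, 0, 0, 1, 0, 0]
        assert tlcmi(a, b, [1] * 7, 2) == pytest.approx(tlmi(a, b, 2), abs=1e-12)

    def test_tlcmi_against_pretrimmed_oracle(self):
        a = [0, 0, 1, 1, 0, 1, 1]
        b = [0, 1, 0, 1, 1, 0, 0]
        c = [0, 0, 0, 1, 1, 1, 0]
        tau = 1
        expected = oracle_cmi(a[:-tau], b[tau:], c[:-tau])
        assert tlcmi(a, b, c, tau) == pytest.approx(expected, abs=1e-12)


class TestIdentities:
    """Distribution-free identities on random sequences (seeded)."""

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_entropy_and_mi_bounds(self, data):
        n = data.draw(st.integers(4, 50))
        a = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        b = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        ha, hb, hab = entropy(a), entropy(b), joint_entropy2(a, b)
        mi = mutual_information(a, b)
        assert 0.0 <= ha <= 1.0
        assert hab <= ha + hb + 1e-9
        assert hab >= max(ha, hb) - 1e-9
        assert mi == pytest.approx(mutual_information(b, a), abs=1e-9)
        assert mi <= min(ha, hb) + 1e-9

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_lagged_metrics_equal_pretrimmed_plain_metrics(self, data):
        n = data.draw(st.integers(6, 50))
        tau = data.draw(st.integers(0, n - 4))
        a = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        b = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        c = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        end = n - tau
        ta = a[:end]
        tb = b[tau:]
        tc = c[:end]
        assert tlmi(a, b, tau) == pytest.approx(
            mutual_information(ta, tb), abs=1e-9
        )
        assert tlcmi(a, b, c, tau) == pytest.approx(
            conditional_mutual_information(ta, tb, tc), abs=1e-9
        )
        assert conditional_mutual_information(ta, tb, tc) >= 0.0
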