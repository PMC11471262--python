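import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifcfg.alphabet import SequenceError, encode, normalize
from motifcfg.energy import (
    SecondaryStructure,
    StructureError,
    count_structures,
    default_energy_params,
    energy_of_structure,
    enumerate_structures,
    structure_partition,
)

PARAMS = default_energy_params(W=9)


class TestAlphabet:
    def test_t_normalized_to_u(self):
        assert normalize("acgt") == "ACGU"

    def test_rejects_other_characters(self):
        with pytest.raises(SequenceError):
            normalize("ACGN")


class TestEnergyOfStructure:
    def test_empty_structure_is_zero(self):
        assert energy_of_structure("GGGAAACCC", [], PARAMS) == 0.0

    def test_two_stack_hairpin_decomposition(self):
        # pairs (0,8),(1,7) on GGGAAACCC: one GC:GC stack + hairpin(5)
        p = PARAMS
        e = energy_of_structure("GGGAAACCC", [(0, 8), (1, 7)], p)
        expected = float(p.stack[2, 2]) + p.hairpin(5)
        assert e == pytest.approx(expected, abs=1e-12)

    def test_additive_over_independent_substructures(self):
        seq = "GGGAAACCC" + "GGGAAACCC"
        params = default_energy_params(W=18)
        e1 = energy_of_structure(seq, [(0, 8), (1, 7)], params)
        e2 = energy_of_structure(seq, [(9, 17), (10, 16)], params)
        e12 = energy_of_structure(seq, [(0, 8), (1, 7), (9, 17), (10, 16)], params)
        assert e12 == pytest.approx(e1 + e2, abs=1e-10)

    @pytest.mark.parametrize(
        "seq,pairs",
        [
            ("GAAAC", [(0, 3)]),          # hairpin of size 2 < 3
            ("GAAAC", [(0, 2)]),          # even smaller
            ("GAAAA", [(0, 4)]),          # non-canonical G-A
            ("GGAAACCAAAC", [(0, 6), (1, 10)]),  # crossing
        ],
    )
    def test_invalid_structures_rejected(self, seq, pairs):
        with pytest.raises(StructureError):
            energy_of_structure(seq, pairs, default_energy_params(W=12))

    def test_span_limit_enforced(self):
        seq = "G" + "A" * 10 + "C"
        with pytest.raises(StructureError, match="span"):
            energy_of_structure(seq, [(0, 11)], default_energy_params(W=9))

    def test_multiloop_energy_terms(self):
        # (0,14) closing two hairpin branches
        seq = "GGAAACCGAAAC" + "AAC"
        params = default_energy_params(W=15)
        pairs = [(0, 14), (1, 6), (7, 11)]
        e = energy_of_structure(seq, pairs, params)
        expected = (
            params.ml_close + 2 * params.ml_branch + 2 * params.ml_unpaired
            + params.hairpin(4) + params.hairpin(3)
        )
        assert e == pytest.approx(expected, abs=1e-10)


class TestEnumeration:
    def test_tiny_counts(self):
        assert len(enumerate_structures(4)) == 1
        assert len(enumerate_structures(5)) == 2
        assert len(enumerate_structures(10, W=10)) == 65

    def test_matches_independent_recurrence(self):
        for n in (6, 8, 10, 12):
            for W in (6, 9, n):
                assert len(enumerate_structures(n, W=W)) == count_structures(n, W=W)

    def test_guard_against_explosion(self):
        with pytest.raises(ValueError):
            enumerate_structures(15)

    def test_all_enumerated_structures_valid(self):
        params = default_energy_params(W=9)
        seq = "GGCGAAACGCC"[:9]
        for s in enumerate_structures(9, seq=seq, W=9):
            s.validate(seq, params)


class TestPartition:
    def test_no_pair_possible_gives_one(self):
        logQ, post = structure_partition("AAAA", PARAMS)
        assert np.exp(logQ) == pytest.approx(1.0, rel=1e-12)
        assert np.all(post == 0)

    def test_matches_enumeration_on_random_sequences(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 10))
            seq = "".join(rng.choice(list("ACGU"), n))
            logQ, post = structure_partition(seq, PARAMS)
            total = sum(
                np.exp(-energy_of_structure(seq, s, PARAMS) / PARAMS.kT)
                for s in enumerate_structures(n, seq=seq, W=9)
            )
            assert np.exp(logQ) == pytest.approx(total, rel=1e-9)

    def test_zero_energy_partition_counts_structures(self):
        z = default_energy_params(W=10).zeroed()
        logQ, _ = structure_partition("A" * 10, z, canonical_only=False)
        assert np.exp(logQ) == pytest.approx(65.0, rel=1e-9)
        assert count_structures(10, 3, 10) == 65

    def test_posterior_matches_enumeration(self, rng):
        seq = "GGCGAAACGCC"
        params = default_energy_params(W=11)
        logQ, post = structure_partition(seq, params)
        n = len(seq)
        brute = np.zeros((n, n))
        Z = 0.0
        for s in enumerate_structures(n, seq=seq, W=11):
            w = np.exp(-energy_of_structure(seq, s, params) / params.kT)
            Z += w
            for i, j in s.pairs:
                brute[i, j] += w
        brute = (brute + brute.T) / Z
        assert np.allclose(post, brute, rtol=1e-9, atol=1e-12)

    def test_posterior_rows_bounded(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 40))
        params = default_energy_params(W=20)
        _, post = structure_partition(seq, params)
        assert np.all(post >= 0) and np.all(post <= 1 + 1e-12)
        assert np.all(post.sum(axis=1) <= 1 + 1e-9)
        assert np.allclose(post, post.T)


@settings(max_examples=60, deadline=None)
@given(st.integers(4, 9), st.integers(0, 10_000))
def test_partition_equals_enumeration_property(n, seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), n))
    logQ, _ = structure_partition(seq, PARAMS)
    total = sum(
        np.exp(-energy_of_structure(seq, s, PARAMS) / PARAMS.kT)
        for s in enumerate_structures(n, seq=seq, W=9)
    )
    assert np.exp(logQ) == pytest.approx(total, rel=1e-9)


def test_param_validation():
    with pytest.raises(ValueError):
        default_energy_params(W=4)  # W < min_hairpin + 2
    with pytest.raises(ValueError):
        default_energy_params(kT=-1.0)
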