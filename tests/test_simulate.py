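from collections import Counter

import numpy as np
import pytest

from motifcfg.energy import default_energy_params, enumerate_structures, structure_partition
from motifcfg.simulate import (
    DesignError,
    design_positive,
    enumerate_motif_structures,
    make_benchmark,
)

PARAMS = default_energy_params(W=20)


@pytest.fixture(scope="module")
def motifs():
    return enumerate_motif_structures()


@pytest.fixture(scope="module")
def small_bench(motifs):
    # a well-stacked stem-loop designs quickly
    return make_benchmark(motifs[41], n_pos=12, n_neg=12, L=60, seed=1,
                          params=PARAMS)


class TestEnumerateMotifs:
    def test_all_structures_valid_with_pairs(self, motifs):
        for m in motifs:
            assert len(m.structure.pairs) >= 1
            m.structure.validate("G" * 0 + "GGGGGAAAAA"[: m.length] * 0 +
                                 _canonicalize(m), PARAMS)

    def test_motif_len5_single_structure(self):
        out = enumerate_motif_structures(motif_len=5, gap_range=(1, 1))
        # length-5, min_hairpin 3: only the (...)-shaped single pair
        assert len(out) == 1
        assert out[0].structure.to_dotbracket(5) == "(...)"
        assert len(enumerate_structures(5)) - 1 == 1  # non-empty structures

    def test_deterministic_across_runs(self, motifs):
        again = enumerate_motif_structures()
        assert len(again) == len(motifs)
        for a, b in zip(motifs, again):
            assert a.structure.pairs == b.structure.pairs
            assert a.gap_len == b.gap_len and a.gap_pos == b.gap_pos
            np.testing.assert_array_equal(a.loop_profile, b.loop_profile)

    def test_gap_lengths_cover_range(self, motifs):
        lens = {m.gap_len for m in motifs}
        assert lens == set(range(1, 11))

    def test_matched_pattern_parses(self, motifs):
        for m in motifs[:10]:
            pat = m.to_pattern()
            assert pat.text.startswith("*") and pat.text.endswith("*")
            assert pat.n_pairs == len(m.structure.pairs)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            enumerate_motif_structures(motif_len=15)
        with pytest.raises(ValueError):
            enumerate_motif_structures(gap_range=(0, 3))


def _canonicalize(m):
    # build a sequence realizing the motif's pairs canonically (G-C)
    seq = ["A"] * m.length
    for i, j in m.structure.pairs:
        seq[i], seq[j] = "G", "C"
    return "".join(seq)


class TestDesignPositive:
    def test_planted_pairs_canonical_and_supported(self, motifs, rng):
        m = motifs[41]
        seq, start = design_positive(m, 60, rng, PARAMS)
        from motifcfg.alphabet import encode, pair_type

        x = encode(seq)
        _, post = structure_partition(seq, PARAMS)
        for i, j in m.planted_pairs(start):
            assert pair_type(int(x[i]), int(x[j])) >= 0
            assert post[i, j] >= 0.5

    def test_fixed_seed_reproducible(self, motifs):
        m = motifs[41]
        a = design_positive(m, 60, np.random.default_rng(5), PARAMS)
        b = design_positive(m, 60, np.random.default_rng(5), PARAMS)
        assert a == b

    def test_too_short_rejected(self, motifs, rng):
        with pytest.raises(ValueError):
            design_positive(motifs[41], motifs[41].span + 5, rng, PARAMS)

    def test_undesignable_motif_raises(self, motifs, rng):
        # an isolated single pair with a long gap rarely folds; a tiny
        # retry cap makes the failure deterministic
        weak = motifs[5]
        with pytest.raises(DesignError):
            for _ in range(5):
                design_positive(weak, 60, rng, PARAMS, max_tries=1)


class TestBenchmark:
    def test_sizes_and_ids(self, small_bench):
        assert len(small_bench.positives) == 12
        assert len(small_bench.negatives) == 12
        assert len(small_bench.decoys) == 12
        assert len(small_bench.truth) == 12

    def test_decoy_composition_matches_positive(self, small_bench):
        for (pid, p), (did, d) in zip(small_bench.positives, small_bench.decoys):
            assert Counter(p) == Counter(d)
            assert len(p) == len(d)

    def test_truth_labels_partition_sequence(self, small_bench):
        for t, (_, seq) in zip(small_bench.truth, small_bench.positives):
            assert len(t.labels) == len(seq)
            inner = t.labels[t.start:t.end]
            assert set(inner) <= set("SLG")
            assert set(t.labels[: t.start]) <= {"B"}
            assert set(t.labels[t.end:]) <= {"B"}

    def test_decoys_lose_structural_support(self, small_bench):
        kept = 0
        for t, (_, d) in zip(small_bench.truth, small_bench.decoys):
            _, post = structure_partition(d, PARAMS)
            if all(post[i, j] >= 0.5 for i, j in t.pairs):
                kept += 1
        assert kept <= max(1, int(0.1 * len(small_bench.decoys)))

    def test_pure_function_of_seed(self, motifs):
        a = make_benchmark(motifs[41], n_pos=3, n_neg=3, L=60, seed=7, params=PARAMS)
        b = make_benchmark(motifs[41], n_pos=3, n_neg=3, L=60, seed=7, params=PARAMS)
        assert a.positives == b.positives
        assert a.negatives == b.negatives
        assert a.decoys == b.decoys

    def test_positive_and_decoy_length_distributions_identical(self, small_bench):
        lp = sorted(len(s) for _, s in small_bench.positives)
        ld = sorted(len(s) for _, s in small_bench.decoys)
        assert lp == ld
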