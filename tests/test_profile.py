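import numpy as np
import pytest

from motifcfg.profile import (
    ProfileParse,
    build_profile_model,
    enumerate_profile_parses,
    profile_parse_score,
)


class TestBuild:
    def test_single_loop_shapes(self):
        m = build_profile_model("*.*")
        assert m.theta_loop.shape == (1, 4)
        assert m.theta_pair.shape == (0, 6)
        assert m.theta_bg.shape == (4,)

    def test_bulge_loop_shapes(self):
        m = build_profile_model("*(.(*))*")
        assert m.theta_loop.shape == (1, 4)
        assert m.theta_pair.shape == (2, 6)

    def test_zero_init_scores_parses_identically_up_to_omega(self):
        m = build_profile_model("*.*", omega=-0.5)
        parses = [p for p in enumerate_profile_parses(5, "*.*") if p.present]
        for p in parses:
            n_self = p.counts("ACGUA", m.pattern)[3]
            assert profile_parse_score(p, "ACGUA", m) == pytest.approx(-0.5 * n_self)

    def test_jitter_init_is_seeded(self):
        a = build_profile_model("*(.)*", init="jitter", seed=3)
        b = build_profile_model("*(.)*", init="jitter", seed=3)
        c = build_profile_model("*(.)*", init="jitter", seed=4)
        assert np.array_equal(a.theta_loop, b.theta_loop)
        assert not np.array_equal(a.theta_loop, c.theta_loop)

    def test_invalid_lam_rejected(self):
        with pytest.raises(ValueError):
            build_profile_model("*.*", lam=-0.5)


class TestScore:
    def test_single_emission_term(self):
        m = build_profile_model("*.*", omega=0.0)
        m.theta_loop[0, 0] = 0.7  # loop emits 'A' with score 0.7
        phi = ProfileParse(4, ((0, 0), (0, 1), (1, 4)))
        assert profile_parse_score(phi, "ACGU", m) == pytest.approx(0.7)

    def test_self_transitions_add_omega_each(self):
        m = build_profile_model("*.*", omega=-1.0)
        one = ProfileParse(4, ((0, 0), (0, 1), (1, 4)))
        three = ProfileParse(4, ((0, 0), (0, 3), (3, 4)))
        d = profile_parse_score(three, "AAAA", m) - profile_parse_score(one, "AAAA", m)
        assert d == pytest.approx(2 * -1.0)

    def test_linearity_in_theta(self, rng):
        m = build_profile_model("*(..)*", omega=-0.3)
        seq = "GGAAAUCC"[:8]
        parses = [p for p in enumerate_profile_parses(8, m.pattern) if p.present]
        phi = parses[len(parses) // 2]
        counts = phi.counts(seq, m.pattern)
        h = 1e-6
        for block, cnt in (("theta_loop", counts[0]), ("theta_pair", counts[1]),
                           ("theta_bg", counts[2])):
            arr = getattr(m, block)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                base = profile_parse_score(phi, seq, m)
                arr[idx] += h
                up = profile_parse_score(phi, seq, m)
                arr[idx] -= h
                slope = (up - base) / h
                assert slope == pytest.approx(cnt[idx], abs=1e-5)

    def test_inconsistent_parse_rejected(self):
        m = build_profile_model("*.*")
        bad = ProfileParse(4, ((0, 1), (2, 3), (3, 4)))  # gap at position 1
        with pytest.raises(ValueError):
            profile_parse_score(bad, "ACGU", m)


class TestEnumerate:
    def test_counts_for_minimal_pattern(self):
        parses = enumerate_profile_parses(4, "*.*")
        present = [p for p in parses if p.present]
        assert len(present) == 10
        assert sum(1 for p in parses if not p.present) == 1

    def test_motif_longer_than_sequence(self):
        parses = enumerate_profile_parses(3, "*(...)*")  # motif needs >= 5
        assert len(parses) == 1 and not parses[0].present

    def test_parses_satisfy_invariants(self):
        pat = "*(.(*))*"
        for p in enumerate_profile_parses(8, pat):
            if not p.present:
                continue
            from motifcfg.pattern import parse_pattern

            sp = parse_pattern(pat)
            p._check_consistent(sp)
            try:
                nl, npair, nbg, ns = p.counts("GGGACGUC", sp)
            except ValueError:
                continue  # parse forces a non-canonical pair on this sequence
            assert ns >= 0
            assert np.all(nl >= 0) and np.all(nbg >= 0)

    def test_helix_pairs_nested_and_contiguous(self):
        pat = "*((.))*"
        for p in enumerate_profile_parses(8, pat):
            if not p.present:
                continue
            hp = p.helix_pairs(__import__("motifcfg.pattern", fromlist=["parse_pattern"]).parse_pattern(pat))
            for (i1, j1), (i2, j2) in zip(hp, hp[1:]):
                if i2 == i1 + 1:
                    assert j2 == j1 - 1  # stacked within one helix

    def test_length_guard(self):
        with pytest.raises(ValueError):
            enumerate_profile_parses(13, "*.*")
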