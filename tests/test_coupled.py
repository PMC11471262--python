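"""The joint DP against exhaustive (structure, parse) enumeration."""

import numpy as np
import pytest

from motifcfg.bruteforce import coupled_brute_force
from motifcfg.coupled import (
    coupled_charts,
    coupled_logZ,
    coupled_logZ_minus,
    motif_probability,
)
from motifcfg.energy import default_energy_params
from motifcfg.profile import build_profile_model

PARAMS9 = default_energy_params(W=9)
SMALL_PATTERNS = ["*.*", "*..*", "*(...)*", "*(.*)*", "*(.(*))*", "*(*)*",
                  "*((.))*", "*.(..)*"]


def random_instance(rng, patterns=SMALL_PATTERNS, lam_choices=(0.0, 0.5, 1.0)):
    pat = patterns[int(rng.integers(len(patterns)))]
    L = int(rng.integers(5, 10))
    seq = "".join(rng.choice(list("ACGU"), L))
    m = build_profile_model(pat, omega=float(rng.normal(-1.0, 0.5)),
                            lam=float(rng.choice(lam_choices)))
    m.theta_loop = rng.uniform(-2, 2, m.theta_loop.shape)
    m.theta_pair = rng.uniform(-2, 2, m.theta_pair.shape)
    m.theta_bg = rng.uniform(-2, 2, 4)
    return seq, m


class TestToyExample:
    """L=4, pattern *.*, zero scores: 10 motif parses + 1 background parse
    over a single (empty) structure."""

    def setup_method(self):
        self.model = build_profile_model("*.*", omega=0.0, lam=0.0)

    def test_partition_values(self):
        assert np.exp(coupled_logZ("ACGU", self.model, PARAMS9)) == pytest.approx(11.0, rel=1e-12)
        assert np.exp(coupled_logZ_minus("ACGU", self.model, PARAMS9)) == pytest.approx(1.0, rel=1e-12)

    def test_motif_probability(self):
        assert motif_probability("ACGU", self.model, PARAMS9) == pytest.approx(10 / 11, rel=1e-12)


class TestOracleEquivalence:
    def test_logZ_and_posteriors_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            seq, m = random_instance(rng)
            ch = coupled_charts(seq, m, PARAMS9, want_counts=True)
            bf = coupled_brute_force(seq, m, PARAMS9)
            assert ch.logZ == pytest.approx(bf.logZ, rel=1e-9)
            assert ch.logZ_minus == pytest.approx(bf.logZ_minus, rel=1e-9)
            if np.isfinite(bf.logZ_plus):
                assert ch.logZ_plus == pytest.approx(bf.logZ_plus, rel=1e-9)
            assert ch.prob == pytest.approx(bf.prob, rel=1e-9, abs=1e-12)
            np.testing.assert_allclose(
                ch.position_posterior("loop"), bf.post_loop, rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(
                ch.position_posterior("pair"), bf.post_pair, rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(
                ch.pair_posterior(), bf.pair_posterior, rtol=1e-8, atol=1e-12)

    def test_expected_counts_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            seq, m = random_instance(rng)
            ch = coupled_charts(seq, m, PARAMS9, want_counts=True)
            bf = coupled_brute_force(seq, m, PARAMS9)
            for ens in ("Z+", "Z-", "Z"):
                got = ch.counts(ens)
                exp = bf.counts[ens]
                for g, e in zip(got[:3], exp[:3]):
                    np.testing.assert_allclose(g, e, rtol=1e-8, atol=1e-10)
                assert got[3] == pytest.approx(exp[3], rel=1e-8, abs=1e-10)
                assert got[4] == pytest.approx(exp[4], rel=1e-8, abs=1e-10)

    def test_unsatisfiable_motif_gives_background_partition(self):
        # A/C-only sequence cannot form any canonical pair
        m = build_profile_model("*(...)*", omega=0.0, lam=1.0)
        seq = "ACACACAC"
        ch = coupled_charts(seq, m, PARAMS9)
        assert ch.logZ_plus == -np.inf
        assert ch.prob == 0.0
        assert ch.logZ == pytest.approx(ch.logZ_minus, rel=1e-12)


class TestIdentities:
    def test_partition_decomposition_and_probability_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq, m = random_instance(rng)
            ch = coupled_charts(seq, m, PARAMS9)
            lhs = np.exp(ch.logZ)
            rhs = (0.0 if ch.logZ_plus == -np.inf else np.exp(ch.logZ_plus)) \
                + np.exp(ch.logZ_minus)
            assert lhs == pytest.approx(rhs, rel=1e-9)
            p1 = ch.prob
            p0 = np.exp(ch.logZ_minus - ch.logZ)
            assert p1 + p0 == pytest.approx(1.0, rel=1e-9)

    def test_logZ_minus_never_exceeds_logZ(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq, m = random_instance(rng)
            ch = coupled_charts(seq, m, PARAMS9)
            assert ch.logZ_minus <= ch.logZ + 1e-12

    def test_raising_motif_scores_leaves_Zminus_unchanged(self):
        rng = np.random.default_rng(9)
        seq, m = random_instance(rng, patterns=["*(...)*"])
        z0 = coupled_logZ_minus(seq, m, PARAMS9)
        m2 = m.copy()
        m2.theta_loop = m2.theta_loop + 1.7
        m2.theta_pair = m2.theta_pair + 0.9
        assert coupled_logZ_minus(seq, m2, PARAMS9) == pytest.approx(z0, rel=1e-12)

    def test_position_posterior_bounded_by_motif_probability(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            seq, m = random_instance(rng)
            ch = coupled_charts(seq, m, PARAMS9, want_counts=True)
            post = ch.position_posterior("motif")
            assert np.all(post <= ch.prob + 1e-9)
            assert np.all(post >= -1e-12)

    def test_counts_under_Z_are_mixture(self):
        rng = np.random.default_rng(17)
        seq, m = random_instance(rng)
        ch = coupled_charts(seq, m, PARAMS9, want_counts=True)
        w = ch.prob
        for k in range(3):
            mix = ch.counts("Z+")[k] * w + ch.counts("Z-")[k] * (1 - w)
            np.testing.assert_allclose(ch.counts("Z")[k], mix, rtol=1e-10, atol=1e-12)


class TestGradientConsistency:
    def test_dlogZ_dtheta_equals_expected_counts(self):
        rng = np.random.default_rng(21)
        h = 1e-5
        for _ in range(6):
            seq, m = random_instance(rng, lam_choices=(0.5, 1.0))
            ch = coupled_charts(seq, m, PARAMS9, want_counts=True)
            nl, npair, nbg, ns, eterm = ch.counts("Z")

            def logZ_of(mm):
                return coupled_charts(seq, mm, PARAMS9, want_counts=False).logZ

            k = int(rng.integers(4))
            m2, m3 = m.copy(), m.copy()
            m2.theta_bg[k] += h
            m3.theta_bg[k] -= h
            fd = (logZ_of(m2) - logZ_of(m3)) / (2 * h)
            assert fd == pytest.approx(nbg[k], rel=1e-4, abs=1e-6)

            m4, m5 = m.copy(), m.copy()
            m4.lam += h
            m5.lam -= h
            fd_lam = (logZ_of(m4) - logZ_of(m5)) / (2 * h)
            assert fd_lam == pytest.approx(eterm, rel=1e-4, abs=1e-6)


class TestScaleRobustness:
    def test_long_sequence_large_theta_no_overflow(self):
        rng = np.random.default_rng(0)
        m = build_profile_model("*.*", omega=-1.0, lam=1.0)
        m.theta_loop[:] = 10.0
        m.theta_bg[:] = -10.0
        seq = "".join(rng.choice(list("ACGU"), 500))
        ch = coupled_charts(seq, m, default_energy_params(W=50))
        assert np.isfinite(ch.logZ) and np.isfinite(ch.logZ_minus)
        assert 0.0 <= ch.prob <= 1.0

    def test_monotone_in_lambda_for_structured_motif(self):
        # a planted stable hairpin: coupling should not reduce P(y=1)
        seq = "AAAGGGCGAAAGCCCAAA"
        params = default_energy_params(W=18)
        probs = []
        for lam in (0.0, 0.5, 1.0, 2.0):
            m = build_profile_model("*(...)*", omega=-1.0, lam=lam)
            m.theta_pair[:] = 0.0
            probs.append(motif_probability(seq, m, params))
        assert all(b >= a - 1e-9 for a, b in zip(probs, probs[1:]))

    def test_runtime_scales_reasonably_with_W(self):
        import time

        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGU"), 120))
        m = build_profile_model("*(...)*", omega=-1.0, lam=1.0)
        coupled_charts(seq, m, default_energy_params(W=12))  # warm
        t0 = time.time()
        coupled_charts(seq, m, default_energy_params(W=12))
        t1 = time.time() - t0
        t0 = time.time()
        coupled_charts(seq, m, default_energy_params(W=24))
        t2 = time.time() - t0
        # doubling W should cost well under ~8x (O(W^2)-ish with overhead)
        assert t2 < max(8 * t1, t1 + 2.0)
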