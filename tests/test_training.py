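import numpy as np
import pytest

from motifcfg.energy import default_energy_params
from motifcfg.profile import build_profile_model
from motifcfg.training import (
    TrainConfig,
    dinucleotide_shuffle,
    enrichment_score,
    gradient,
    objective,
    select_motif,
    train,
)

PARAMS = default_energy_params(W=9)


def _random_model(rng, pattern="*(..)*", lam=1.0):
    m = build_profile_model(pattern, omega=-0.8, lam=lam)
    m.theta_loop = rng.uniform(-1, 1, m.theta_loop.shape)
    m.theta_pair = rng.uniform(-1, 1, m.theta_pair.shape)
    m.theta_bg = rng.uniform(-1, 1, 4)
    return m


def _random_seqs(rng, n, lo=6, hi=10):
    return ["".join(rng.choice(list("ACGU"), int(rng.integers(lo, hi))))
            for _ in range(n)]


class TestObjective:
    def test_empty_sets_give_minus_regularizer(self, rng):
        m = _random_model(rng)
        val = objective([], [], m, PARAMS, c_theta=0.1, c_lam=0.2)
        sq = (m.theta_loop**2).sum() + (m.theta_pair**2).sum() + (m.theta_bg**2).sum()
        assert val == pytest.approx(-(0.05 * sq + 0.1 * m.lam**2), rel=1e-10)

    def test_duplicating_sequences_doubles_data_term(self, rng):
        m = _random_model(rng)
        Xp = _random_seqs(rng, 2)
        Xn = _random_seqs(rng, 2)
        base = objective(Xp, Xn, m, PARAMS, c_theta=0, c_lam=0)
        double = objective(Xp * 2, Xn * 2, m, PARAMS, c_theta=0, c_lam=0)
        assert double == pytest.approx(2 * base, rel=1e-10)


class TestGradient:
    def test_regularizer_only_gradient(self, rng):
        m = _random_model(rng)
        g = gradient([], [], m, PARAMS, c_theta=0.3, c_lam=0.7)
        np.testing.assert_allclose(g["theta_loop"], -0.3 * m.theta_loop)
        np.testing.assert_allclose(g["theta_bg"], -0.3 * m.theta_bg)
        assert g["lam"] == pytest.approx(-0.7 * m.lam)

    def test_matches_central_finite_differences(self, rng):
        h = 1e-5
        for trial in range(4):
            m = _random_model(rng, pattern=["*(..)*", "*.(*)*"][trial % 2])
            # positives must admit a motif occurrence: plant a G..C stem
            # (with an A prefix so a loop symbol can precede the stem)
            Xp = ["AG" + s[:4] + "C" + s[4] for s in _random_seqs(rng, 2, 7, 9)]
            Xn = _random_seqs(rng, 2)
            g = gradient(Xp, Xn, m, PARAMS, c_theta=0.01, c_lam=0.01)

            def obj(mm):
                return objective(Xp, Xn, mm, PARAMS, c_theta=0.01, c_lam=0.01)

            # one random component per block + lambda
            for block in ("theta_loop", "theta_pair", "theta_bg"):
                arr = getattr(m, block)
                if arr.size == 0:
                    continue
                flat = int(rng.integers(arr.size))
                idx = np.unravel_index(flat, arr.shape)
                m2, m3 = m.copy(), m.copy()
                getattr(m2, block)[idx] += h
                getattr(m3, block)[idx] -= h
                fd = (obj(m2) - obj(m3)) / (2 * h)
                assert fd == pytest.approx(g[block][idx], rel=1e-4, abs=1e-6)
            m2, m3 = m.copy(), m.copy()
            m2.lam += h
            m3.lam -= h
            fd = (obj(m2) - obj(m3)) / (2 * h)
            assert fd == pytest.approx(g["lam"], rel=1e-4, abs=1e-6)


class TestDinucShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        seq = "".join(rng.choice(list("ACGU"), 60))
        out = dinucleotide_shuffle(seq, rng)
        assert len(out) == len(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        c1 = Counter(zip(seq, seq[1:]))
        c2 = Counter(zip(out, out[1:]))
        assert c1 == c2

    def test_actually_shuffles(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 200))
        outs = {dinucleotide_shuffle(seq, rng) for _ in range(5)}
        assert any(o != seq for o in outs)


class TestTrain:
    def test_same_seed_identical_trajectory(self, rng):
        Xp = ["GGGCGAAAGCCC" + "A" * 4] * 6
        Xn = _random_seqs(rng, 6, 14, 18)
        cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=0.05, seed=9,
                          patience=0)
        pat = "*(...)*"
        params = default_energy_params(W=16)
        f1 = train(build_profile_model(pat, "jitter", seed=9), Xp, Xn, cfg, params)
        f2 = train(build_profile_model(pat, "jitter", seed=9), Xp, Xn, cfg, params)
        np.testing.assert_array_equal(f1.model.theta_loop, f2.model.theta_loop)
        np.testing.assert_array_equal(f1.model.theta_pair, f2.model.theta_pair)
        assert f1.model.lam == f2.model.lam
        assert f1.objective_trace == f2.objective_trace

    def test_zero_learning_rate_keeps_parameters(self, rng):
        Xp = ["GGGCGAAAGCCCAAAA"] * 4
        Xn = _random_seqs(rng, 4, 14, 18)
        cfg = TrainConfig(epochs=1, batch_size=4, learning_rate=0.0, seed=1,
                          patience=0, sim_negative_ratio=0.0)
        m0 = build_profile_model("*(...)*", "jitter", seed=1)
        params = default_energy_params(W=16)
        fit = train(m0, Xp, Xn, cfg, params)
        np.testing.assert_array_equal(fit.model.theta_loop, m0.theta_loop)
        assert fit.model.lam == m0.lam

    def test_lambda_stays_nonnegative(self, rng):
        Xp = ["GGGCGAAAGCCCAAAA"] * 4
        Xn = _random_seqs(rng, 4, 14, 18)
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=0.5, seed=2,
                          patience=0)
        m0 = build_profile_model("*(...)*", "jitter", seed=2, lam=0.01)
        fit = train(m0, Xp, Xn, cfg, default_energy_params(W=16))
        assert fit.model.lam >= 0.0

    def test_requires_nonempty_sets(self):
        with pytest.raises(ValueError):
            train(build_profile_model("*.*"), [], ["ACGU"], TrainConfig())


class TestEnrichmentScore:
    def test_perfect_separation(self):
        class Fake:
            pass

        # direct AUROC contract via raw scores
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0

    def test_tie_convention_and_hand_count(self, rng):
        # all-equal scores -> 0.5 by the rank convention
        m = build_profile_model("*.*", omega=0.0, lam=0.0)  # every P identical
        # same length, no pairable bases: every sequence scores identically
        Xp = ["ACACA", "CCCAA"]
        Xn = ["AACCA", "AAAAA"]
        assert enrichment_score(m, Xp, Xn, PARAMS) == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        # pos {0.9, 0.4}, neg {0.6}: one concordant, one discordant
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score([1, 1, 0], [0.9, 0.4, 0.6]) == pytest.approx(0.5)

    def test_empty_sets_rejected(self):
        m = build_profile_model("*.*")
        with pytest.raises(ValueError):
            enrichment_score(m, [], ["ACGU"], PARAMS)


class TestSelect:
    def test_single_pattern_is_selected(self, rng):
        Xp = ["GGGCGAAAGCCC" + "".join(rng.choice(list("ACGU"), 4))
              for _ in range(8)]
        Xn = _random_seqs(rng, 8, 14, 18)
        cfg = TrainConfig(k_folds=2, epochs=1, batch_size=8, seed=3,
                          patience=0, sim_negative_ratio=0.0)
        ranked, best = select_motif(["*(...)*"], Xp, Xn, cfg,
                                    default_energy_params(W=16))
        assert best.pattern.text == "*(...)*"
        assert len(ranked) == 1
        assert len(ranked[0].fold_scores) == 2

    def test_ranking_sorted_nonincreasing(self, rng):
        Xp = ["GGGCGAAAGCCC" + "".join(rng.choice(list("ACGU"), 4))
              for _ in range(8)]
        Xn = _random_seqs(rng, 8, 14, 18)
        cfg = TrainConfig(k_folds=2, epochs=1, batch_size=8, seed=3,
                          patience=0, sim_negative_ratio=0.0)
        ranked, _ = select_motif(["*(...)*", "*.*"], Xp, Xn, cfg,
                                 default_energy_params(W=16))
        scores = [f.enrichment_score for f in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_no_patterns_rejected(self):
        with pytest.raises(ValueError):
            select_motif([], ["ACGU"], ["ACGU"], TrainConfig())
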