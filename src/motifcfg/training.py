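"""Discriminative (CRF) training of coupled motif models.

The objective is the difference in log-likelihood between positive and
negative sequence sets,

    L = sum_x+ log P(y=1|x+) + sum_x- log P(y=0|x-) - R(theta, lambda),

with an L2 regularizer ``R = c_theta/2 ||theta||^2 + c_lam/2 lambda^2``.
Its gradient is assembled from inside-outside expected counts: for a
positive sequence the counts under ``Z+`` minus those under ``Z``, for a
negative those under ``Z-`` minus those under ``Z``; the coupling-scale
derivative uses the expected ``-dG/kT`` in the same way.  Optimization
is adaptive-moment (Adam) stochastic gradient ascent with a projection
keeping ``lambda >= 0``; the self-transition weight ``omega`` is a fixed
constant and is not trained.

"Simulated negatives" — dinucleotide-shuffled copies of the positives,
regenerated every epoch — are mixed into the negative stream to keep the
model from exploiting background composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .alphabet import encode, decode
from .coupled import coupled_charts
from .energy import EnergyParams, default_energy_params
from .pattern import SearchPattern, parse_pattern
from .profile import ProfileModel, build_profile_model

__all__ = [
    "TrainConfig",
    "MotifFit",
    "objective",
    "gradient",
    "train",
    "enrichment_score",
    "select_motif",
    "dinucleotide_shuffle",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (all unstated by the method itself;
    defaults chosen once and recorded in every fit's metadata)."""

    k_folds: int = 5
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 0.02
    c_theta: float = 0.01
    c_lam: float = 0.001
    seed: int = 0
    sim_negative_ratio: float = 1.0
    patience: int = 5
    validation_fraction: float = 0.2

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid learning rate / batch size / epochs")


@dataclass
class MotifFit:
    """A trained motif model with its selection statistics."""

    model: ProfileModel
    enrichment_score: float
    fold_scores: list[float]
    objective_trace: list[float]
    config: dict
    metadata: dict = field(default_factory=dict)

    @property
    def pattern(self) -> SearchPattern:
        return self.model.pattern


def _as_codes(X) -> list[np.ndarray]:
    return [x if isinstance(x, np.ndarray) else encode(x) for x in X]


def _reg_value(model: ProfileModel, c_theta: float, c_lam: float) -> float:
    sq = (
        float(np.sum(model.theta_loop**2))
        + float(np.sum(model.theta_pair**2))
        + float(np.sum(model.theta_bg**2))
    )
    return 0.5 * c_theta * sq + 0.5 * c_lam * model.lam**2


def objective(
    Xpos: Sequence,
    Xneg: Sequence,
    model: ProfileModel,
    params: EnergyParams | None = None,
    c_theta: float = 0.01,
    c_lam: float = 0.001,
) -> float:
    """The CRF objective (natural-log units); higher is better."""
    params = params or default_energy_params()
    total = -_reg_value(model, c_theta, c_lam)
    for i, x in enumerate(_as_codes(Xpos)):
        ch = coupled_charts(x, model, params, want_counts=False)
        lp = np.log(ch.prob) if ch.prob > 0 else -np.inf
        if not np.isfinite(lp):
            raise FloatingPointError(
                f"positive sequence #{i}: motif probability is zero "
                "(the motif cannot occur in this sequence under the pattern)"
            )
        total += lp
    for x in _as_codes(Xneg):
        ch = coupled_charts(x, model, params, want_counts=False)
        total += ch.logZ_minus - ch.logZ
    return float(total)


def _zero_blocks(model: ProfileModel):
    return {
        "theta_loop": np.zeros_like(model.theta_loop),
        "theta_pair": np.zeros_like(model.theta_pair),
        "theta_bg": np.zeros_like(model.theta_bg),
        "lam": 0.0,
    }


def _seq_grad(x, y: int, model: ProfileModel, params: EnergyParams):
    """Per-sequence data gradient (no regularizer).

    For y=1: E+[N] - E[N]; for y=0: E-[N] - E[N]; plus the matching
    expected -dG/kT difference for lambda.
    """
    ch = coupled_charts(x, model, params, want_counts=True)
    tgt = "Z+" if y == 1 else "Z-"
    nl_t, np_t, nb_t, ns_t, e_t = ch.counts(tgt)
    nl_z, np_z, nb_z, ns_z, e_z = ch.counts("Z")
    g = {
        "theta_loop": nl_t - nl_z,
        "theta_pair": np_t - np_z,
        "theta_bg": nb_t - nb_z,
        "lam": e_t - e_z,
    }
    if y == 1:
        ll = np.log(ch.prob) if ch.prob > 0 else -np.inf
    else:
        ll = ch.logZ_minus - ch.logZ
    return g, float(ll)


def gradient(
    Xpos: Sequence,
    Xneg: Sequence,
    model: ProfileModel,
    params: EnergyParams | None = None,
    c_theta: float = 0.01,
    c_lam: float = 0.001,
):
    """Full-batch gradient of :func:`objective` with respect to
    ``(theta_loop, theta_pair, theta_bg, lam)``."""
    params = params or default_energy_params()
    g = _zero_blocks(model)
    for x in _as_codes(Xpos):
        gi, _ = _seq_grad(x, 1, model, params)
        for k in g:
            g[k] = g[k] + gi[k]
    for x in _as_codes(Xneg):
        gi, _ = _seq_grad(x, 0, model, params)
        for k in g:
            g[k] = g[k] + gi[k]
    g["theta_loop"] = g["theta_loop"] - c_theta * model.theta_loop
    g["theta_pair"] = g["theta_pair"] - c_theta * model.theta_pair
    g["theta_bg"] = g["theta_bg"] - c_theta * model.theta_bg
    g["lam"] = g["lam"] - c_lam * model.lam
    return g


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Euler-path method)."""
    x = list(seq)
    n = len(x)
    if n < 3:
        return seq
    # adjacency multigraph of the walk
    succ: dict[str, list[str]] = {}
    for a, b in zip(x[:-1], x[1:]):
        succ.setdefault(a, []).append(b)
    last = x[-1]
    # choose, for every vertex but the walk's end, a final edge forming a
    # tree toward the end vertex (Altschul-Erickson), then shuffle the rest
    for _ in range(200):
        final_edge: dict[str, str] = {}
        for v, outs in succ.items():
            if v != last:
                final_edge[v] = outs[int(rng.integers(len(outs)))]
        # check: following final edges from every vertex reaches `last`
        ok = True
        for v in succ:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in final_edge:
                    ok = False
                    break
                seen.add(u)
                u = final_edge[u]
            if not ok:
                break
        if ok:
            break
    else:
        return seq
    shuffled: dict[str, list[str]] = {}
    for v, outs in succ.items():
        rest = list(outs)
        if v in final_edge:
            rest.remove(final_edge[v])
        rng.shuffle(rest)
        if v in final_edge:
            rest.append(final_edge[v])
        shuffled[v] = rest
    out = [x[0]]
    idx = {v: 0 for v in shuffled}
    v = x[0]
    for _ in range(n - 1):
        nxt = shuffled[v][idx[v]]
        idx[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _pack(model: ProfileModel) -> np.ndarray:
    return np.concatenate(
        [model.theta_loop.ravel(), model.theta_pair.ravel(),
         model.theta_bg.ravel(), [model.lam]]
    )


def _unpack(vec: np.ndarray, model: ProfileModel) -> None:
    nl = model.theta_loop.size
    npr = model.theta_pair.size
    model.theta_loop = vec[:nl].reshape(model.theta_loop.shape).copy()
    model.theta_pair = vec[nl:nl + npr].reshape(model.theta_pair.shape).copy()
    model.theta_bg = vec[nl + npr:nl + npr + 4].copy()
    model.lam = max(0.0, float(vec[-1]))


def _grad_vec(g: dict) -> np.ndarray:
    return np.concatenate(
        [g["theta_loop"].ravel(), g["theta_pair"].ravel(),
         g["theta_bg"].ravel(), [g["lam"]]]
    )


def train(
    model: ProfileModel,
    Xpos: Sequence[str],
    Xneg: Sequence[str],
    cfg: TrainConfig | None = None,
    params: EnergyParams | None = None,
    Xpos_val: Sequence[str] | None = None,
    Xneg_val: Sequence[str] | None = None,
) -> MotifFit:
    """Stochastic gradient (Adam) training of one coupled motif model.

    Deterministic given ``cfg.seed``.  If validation sets are supplied,
    they drive early stopping (patience on the validation objective) and
    the reported enrichment score; otherwise the fit reports an
    enrichment score on the training data.
    """
    cfg = cfg or TrainConfig()
    params = params or default_energy_params()
    if len(Xpos) == 0 or len(Xneg) == 0:
        raise ValueError("training requires non-empty positive and negative sets")
    rng = np.random.default_rng(cfg.seed)
    model = model.copy()

    pos_str = [s if isinstance(s, str) else decode(s) for s in Xpos]
    pos = _as_codes(Xpos)
    neg = _as_codes(Xneg)
    n_total = len(pos) + len(neg)

    theta = _pack(model)
    mom = np.zeros_like(theta)
    vel = np.zeros_like(theta)
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    trace: list[float] = []
    best_val = -np.inf
    best_theta = theta.copy()
    bad_epochs = 0

    for epoch in range(cfg.epochs):
        n_sim = int(round(cfg.sim_negative_ratio * len(pos)))
        sim = []
        if n_sim > 0:
            picks = rng.choice(len(pos_str), size=n_sim, replace=n_sim > len(pos_str))
            sim = [encode(dinucleotide_shuffle(pos_str[k], rng)) for k in picks]
        data = [(x, 1) for x in pos] + [(x, 0) for x in neg + sim]
        order = rng.permutation(len(data))
        epoch_ll = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = [data[k] for k in order[start:start + cfg.batch_size]]
            g = _zero_blocks(model)
            for x, y in batch:
                gi, ll = _seq_grad(x, y, model, params)
                if not np.isfinite(ll):
                    raise FloatingPointError(
                        "objective diverged (non-finite log-likelihood); "
                        f"epoch {epoch}, lam={model.lam:.3f}"
                    )
                epoch_ll += ll
                for k in g:
                    g[k] = g[k] + gi[k]
            gv = _grad_vec(g) / len(batch)
            # regularizer, apportioned across batches
            reg = _grad_vec({
                "theta_loop": cfg.c_theta * model.theta_loop,
                "theta_pair": cfg.c_theta * model.theta_pair,
                "theta_bg": cfg.c_theta * model.theta_bg,
                "lam": cfg.c_lam * model.lam,
            }) / max(1, n_total)
            gv = gv - reg * len(batch)
            step += 1
            mom = b1 * mom + (1 - b1) * gv
            vel = b2 * vel + (1 - b2) * gv * gv
            mhat = mom / (1 - b1**step)
            vhat = vel / (1 - b2**step)
            theta = theta + cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            _unpack(theta, model)
            theta = _pack(model)  # reflects the lambda projection
        trace.append(epoch_ll - _reg_value(model, cfg.c_theta, cfg.c_lam))

        if Xpos_val is not None and Xneg_val is not None and cfg.patience > 0:
            vobj = objective(Xpos_val, Xneg_val, model, params,
                             cfg.c_theta, cfg.c_lam)
            if vobj > best_val:
                best_val = vobj
                best_theta = theta.copy()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break

    if Xpos_val is not None and Xneg_val is not None and cfg.patience > 0:
        _unpack(best_theta, model)

    ev_pos = Xpos_val if Xpos_val is not None else Xpos
    ev_neg = Xneg_val if Xneg_val is not None else Xneg
    es = enrichment_score(model, ev_pos, ev_neg, params)
    return MotifFit(
        model=model,
        enrichment_score=es,
        fold_scores=[es],
        objective_trace=trace,
        config=asdict(cfg),
        metadata={
            "pattern": model.pattern.text,
            "seed": cfg.seed,
            "n_pos": len(Xpos),
            "n_neg": len(Xneg),
            "optimizer": "adam",
            "simulated_negatives": "per-epoch dinucleotide shuffles of positives",
        },
    )


def recovered_profiles(
    model: ProfileModel, X, params: EnergyParams | None = None,
    refine: int = 1,
):
    """Emission distributions the fitted motif actually matches in data.

    Aggregates the posterior-expected emission counts under ``Z+`` over
    the sequences in ``X`` and normalizes per state.  Returns
    ``(loop_profiles, pair_profiles, star_counts)``: loop rows over
    ACGU, pair rows over the six pair types, and the mean emission count
    of each insertion slot (the logo's gap-length annotation).

    This is the motif-recovery readout: a discriminatively trained model
    stops sharpening its raw parameters once the classes separate, so
    the softmax of theta understates conservation, but the expected
    emissions at the aligned motif states reproduce what the motif
    matches.  ``refine`` additionally applies that many
    expectation-maximization realignment steps (re-estimating the
    emission parameters from the expected counts and recomputing the
    alignment, as alignment-based motif finders do) to concentrate the
    placement posterior before the final readout.
    """
    params = params or default_energy_params()
    work = model.copy()
    loop = pair = star = None
    for _ in range(max(1, refine + 1)):
        loop, pair, star, bg = _expected_emissions(work, X, params)
        work = work.copy()
        if loop.size:
            work.theta_loop = np.log(np.maximum(loop, 1e-6))
        if pair.size:
            work.theta_pair = np.log(np.maximum(pair, 1e-6))
        work.theta_bg = np.log(np.maximum(bg, 1e-6))
    return loop, pair, star


def _expected_emissions(model, X, params):
    pat = model.pattern
    loop = np.zeros((pat.n_loops, 4))
    pair = np.zeros((pat.n_pairs, 6))
    bg = np.zeros(4)
    star = np.zeros(len(pat.insertion_slots))
    n = 0
    for x in _as_codes(X):
        ch = coupled_charts(x, model, params, want_counts=True)
        if ch.logZ_plus == -np.inf:
            continue
        nl, npair, nbg, _, _ = ch.counts("Z+")
        loop += nl
        pair += npair
        bg += nbg
        star += ch.plus.n_star
        n += 1
    loop = loop / np.maximum(loop.sum(axis=1, keepdims=True), 1e-300)
    pair = pair / np.maximum(pair.sum(axis=1, keepdims=True), 1e-300)
    bg = bg / max(bg.sum(), 1e-300)
    star = star / max(1, n)
    return loop, pair, star, bg


def scores_for(model_or_fit, X, params: EnergyParams | None = None) -> np.ndarray:
    """Motif probabilities P(y=1|x) for a list of sequences."""
    model = model_or_fit.model if isinstance(model_or_fit, MotifFit) else model_or_fit
    params = params or default_energy_params()
    return np.array(
        [coupled_charts(x, model, params, want_counts=False).prob
         for x in _as_codes(X)]
    )


def enrichment_score(
    model_or_fit, Xpos_val, Xneg_val, params: EnergyParams | None = None
) -> float:
    """AUROC of P(y=1|x) separating held-out positives from negatives
    (ties credited 0.5, the rank-based convention)."""
    if len(Xpos_val) == 0 or len(Xneg_val) == 0:
        raise ValueError("enrichment score requires non-empty validation sets")
    sp = scores_for(model_or_fit, Xpos_val, params)
    sn = scores_for(model_or_fit, Xneg_val, params)
    y = np.concatenate([np.ones(len(sp)), np.zeros(len(sn))])
    s = np.concatenate([sp, sn])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def select_motif(
    patterns: Sequence[SearchPattern | str],
    Xpos: Sequence[str],
    Xneg: Sequence[str],
    cfg: TrainConfig | None = None,
    params: EnergyParams | None = None,
):
    """K-fold pattern ranking and final retraining (the full workflow).

    Every candidate pattern is trained on each of K folds and scored on
    the held-out portion; patterns are ranked by mean enrichment score
    (ties broken by fewer motif symbols, then pattern text).  The best
    pattern is retrained on the complete data.  Returns
    ``(ranked_fits, best_fit)``.
    """
    cfg = cfg or TrainConfig()
    params = params or default_energy_params()
    pats = [p if isinstance(p, SearchPattern) else parse_pattern(p) for p in patterns]
    if not pats:
        raise ValueError("no patterns supplied")
    Xpos = list(Xpos)
    Xneg = list(Xneg)
    kf = KFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
    pos_folds = list(kf.split(Xpos))
    neg_folds = list(kf.split(Xneg))

    results = []
    failures = []
    for pat in pats:
        fold_scores = []
        last_fit = None
        try:
            for k in range(cfg.k_folds):
                ptr, pva = pos_folds[k]
                ntr, nva = neg_folds[k]
                m0 = build_profile_model(pat, init="jitter",
                                         seed=cfg.seed + 7919 * k, lam=1.0)
                fit = train(
                    m0,
                    [Xpos[i] for i in ptr], [Xneg[i] for i in ntr],
                    cfg, params,
                    Xpos_val=[Xpos[i] for i in pva],
                    Xneg_val=[Xneg[i] for i in nva],
                )
                fold_scores.append(fit.enrichment_score)
                last_fit = fit
        except FloatingPointError as e:
            failures.append((pat.text, str(e)))
            continue
        mean_es = float(np.mean(fold_scores))
        results.append(
            MotifFit(
                model=last_fit.model,
                enrichment_score=mean_es,
                fold_scores=fold_scores,
                objective_trace=last_fit.objective_trace,
                config=asdict(cfg),
                metadata={**last_fit.metadata, "mean_fold_es": mean_es},
            )
        )
    if not results:
        raise RuntimeError(f"all patterns failed training: {failures}")

    results.sort(
        key=lambda f: (-f.enrichment_score, f.pattern.motif_length, f.pattern.text)
    )
    best_pat = results[0].pattern
    m0 = build_profile_model(best_pat, init="jitter", seed=cfg.seed, lam=1.0)
    best_fit = train(m0, Xpos, Xneg, cfg, params)
    best_fit.metadata["mean_fold_es"] = results[0].enrichment_score
    best_fit.fold_scores = results[0].fold_scores
    return results, best_fit
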