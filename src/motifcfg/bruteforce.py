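"""Brute-force coupled-grammar reference by exhaustive double enumeration.

Sums ``exp(-lam * dG(sigma)/kT + profile_score(phi))`` over every
compatible (structure, parse) pair, where compatibility means: positions
emitted by a loop symbol are unpaired in the structure, the helix pairs
forced by bracket symbols are exactly pairs of the structure, and
insertion-region positions are unconstrained.  Intended as a test oracle
for tiny sequences; completely independent of the dynamic-programming
engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import encode
from .energy import EnergyParams, energy_of_structure, enumerate_structures
from .profile import ProfileModel, ProfileParse, enumerate_profile_parses, profile_parse_score

__all__ = ["BruteForceResult", "coupled_brute_force"]


@dataclass
class BruteForceResult:
    logZ: float
    logZ_plus: float
    logZ_minus: float
    prob: float                      # P(y=1 | x)
    post_loop: np.ndarray            # per-position loop-state membership
    post_pair: np.ndarray            # per-position pair-state membership
    post_motif: np.ndarray           # any motif-state membership (incl. internal insertions)
    counts: dict                     # ensemble -> (n_loop, n_pair, n_bg, n_self, neg_dG_over_kT)
    pair_posterior: np.ndarray       # P(i pairs with j) under the full ensemble


def _compatible(pairs_set: dict, phi: ProfileParse, pattern) -> bool:
    for i, j in phi.helix_pairs(pattern):
        if pairs_set.get(i) != j:
            return False
    for q in phi.loop_positions(pattern):
        if q in pairs_set:
            return False
    return True


def coupled_brute_force(
    seq: str,
    model: ProfileModel,
    params: EnergyParams,
) -> BruteForceResult:
    x = encode(seq)
    L = len(x)
    pattern = model.pattern
    structures = enumerate_structures(L, params.min_hairpin, params.W, seq=x)
    parses = enumerate_profile_parses(L, pattern, max_len=12)

    struct_info = []
    for s in structures:
        dg = energy_of_structure(x, s, params)
        partner = {}
        for i, j in s.pairs:
            partner[i] = j
            partner[j] = i
        struct_info.append((s, partner, dg))

    loop_idx = set(pattern.loop_indices)
    star_idx = set(pattern.insertion_slots)
    internal_stars = star_idx - {0, len(pattern.text) - 1}

    Z = Zp = Zm = 0.0
    post_loop = np.zeros(L)
    post_pair = np.zeros(L)
    post_motif = np.zeros(L)
    pair_post = np.zeros((L, L))
    zeros = lambda: [
        np.zeros((pattern.n_loops, 4)),
        np.zeros((pattern.n_pairs, 6)),
        np.zeros(4),
        0.0,
        0.0,
    ]
    acc = {"Z": zeros(), "Z+": zeros(), "Z-": zeros()}

    from .alphabet import pair_type

    for phi in parses:
        if any(
            pair_type(int(x[i]), int(x[j])) < 0
            for i, j in phi.helix_pairs(pattern)
        ):
            continue  # no structure can realize a non-canonical helix pair
        sc = profile_parse_score(phi, x, model)
        nl, npair, nbg, nself = phi.counts(x, pattern)
        for s, partner, dg in struct_info:
            if phi.present and not _compatible(partner, phi, pattern):
                continue
            e_term = -model.lam * dg / params.kT
            w = float(np.exp(e_term + sc))
            Z += w
            keys = ["Z"]
            if phi.present:
                Zp += w
                keys.append("Z+")
            else:
                Zm += w
                keys.append("Z-")
            for key in keys:
                a = acc[key]
                a[0] += w * nl
                a[1] += w * npair
                a[2] += w * nbg
                a[3] += w * nself
                a[4] += w * (-dg / params.kT)
            for i, j in s.pairs:
                pair_post[i, j] += w
            if phi.present:
                for q in phi.loop_positions(pattern):
                    post_loop[q] += w
                    post_motif[q] += w
                for i, j in phi.helix_pairs(pattern):
                    post_pair[i] += w
                    post_pair[j] += w
                    post_motif[i] += w
                    post_motif[j] += w
                for p in internal_stars:
                    sa, sb = phi.intervals[p]
                    for q in range(sa, sb):
                        post_motif[q] += w

    counts = {}
    for key, total in (("Z", Z), ("Z+", Zp), ("Z-", Zm)):
        a = acc[key]
        if total > 0:
            counts[key] = tuple(v / total for v in a)
        else:
            counts[key] = tuple(v * 0.0 for v in a)
    pair_post = (pair_post + pair_post.T) / Z

    return BruteForceResult(
        logZ=float(np.log(Z)),
        logZ_plus=float(np.log(Zp)) if Zp > 0 else -np.inf,
        logZ_minus=float(np.log(Zm)),
        prob=Zp / Z,
        post_loop=post_loop / Z,
        post_pair=post_pair / Z,
        post_motif=post_motif / Z,
        counts=counts,
        pair_posterior=pair_post,
    )
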