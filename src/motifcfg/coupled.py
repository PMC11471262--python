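"""Coupled grammar: joint partition functions, posteriors, expected counts.

``Z+`` (motif occurs exactly once) is computed by a direct dynamic
program whose profile automaton must traverse every motif symbol; ``Z-``
(motif absent: the whole sequence emitted by the background profile over
the full structure ensemble) by the same engine with the trivial
single-star automaton.  ``Z = Z+ + Z-`` is assembled in log space, so
the motif probability ``P(y=1|x) = Z+/Z`` never suffers cancellation.

All charts are kept in linear space with per-position scaling; reported
quantities are exact ratios in which the scale cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import PAIR_TYPE_TABLE, encode
from .energy import EnergyParams, default_energy_params
from ._machine import Machine, machine_for
from ._kernel import run_coupled
from .profile import ProfileModel

__all__ = [
    "CoupledCharts",
    "coupled_charts",
    "coupled_logZ",
    "coupled_logZ_minus",
    "coupled_logZ_plus",
    "motif_probability",
    "expected_counts",
    "position_posterior",
]


@dataclass
class _RunOut:
    logZ: float                  # log partition of this machine's parse set
    n_loop: np.ndarray
    n_pair: np.ndarray
    n_bg: np.ndarray
    n_self: float
    energy: float                # E[-dG/kT]
    post_loop: np.ndarray
    post_pairm: np.ndarray
    post_ins: np.ndarray
    pairpost: np.ndarray
    n_star: np.ndarray           # expected emissions per insertion slot


def _run_machine(
    mach: Machine,
    x: np.ndarray,
    theta_loop: np.ndarray,
    theta_pair: np.ndarray,
    theta_bg: np.ndarray,
    omega: float,
    lam: float,
    params: EnergyParams,
    want_counts: bool,
    canonical_only: bool = True,
) -> _RunOut:
    L = len(x)
    S = mach.S
    nl = max(1, mach.n_loops)
    npr = max(1, mach.n_pairs)
    kT = params.kT

    ptm = PAIR_TYPE_TABLE[x[:, None], x[None, :]].astype(np.int64)
    if not canonical_only:
        ptm = np.zeros((L, L), dtype=np.int64)

    # Per-position log-scale: the largest single-base emission weight.
    # Pair emissions and energy bonuses can exceed this, so the kernel
    # call below is wrapped in an adaptive retry that shifts the scale
    # uniformly on under-/overflow.
    th_l = theta_loop if mach.n_loops else np.zeros((1, 4))
    per_base = theta_bg[x].astype(float)
    if mach.n_loops:
        per_base = np.maximum(per_base, th_l[:, x].max(axis=0))
    sigma = per_base.copy()

    ntr = mach.n_tr
    CTW_raw = np.zeros((ntr, L))
    for t in range(ntr):
        kind = mach.tr_kind[t]
        if kind == 0:
            w = np.exp(theta_bg[x])
        elif kind == 1:
            w = np.exp(theta_loop[mach.tr_aux[t], x])
        else:
            w = np.exp(theta_loop[mach.tr_aux[t], x] + omega)
        CTW_raw[t] = w

    PE = np.exp(theta_pair) if mach.n_pairs else np.zeros((1, 6))
    WB = np.exp(theta_bg)

    Dmax = int(min(params.W + 1, L))
    mh = int(params.min_hairpin)

    wHP = np.zeros(Dmax + 1)
    fHP = np.zeros(Dmax + 1)
    for n in range(mh, Dmax + 1):
        f = -params.hairpin(n) / kT
        fHP[n] = f
        wHP[n] = np.exp(lam * f)
    fSW = -np.asarray(params.stack, dtype=float) / kT
    wSW = np.exp(lam * fSW)
    f_bb = -params.bulge_base / kT
    f_ib = -params.internal_base / kT
    f_mc = -params.ml_close / kT
    f_mlb = -params.ml_branch / kT
    f_si = -params.interior_slope / kT
    f_sml = -params.ml_unpaired / kT
    w_bb, w_ib, w_mc = np.exp(lam * f_bb), np.exp(lam * f_ib), np.exp(lam * f_mc)
    w_mlb, w_si, w_sml = np.exp(lam * f_mlb), np.exp(lam * f_si), np.exp(lam * f_sml)
    om_t = float(np.exp(omega))

    xi = x.astype(np.int64)
    shift = 500.0 / max(1, L)
    for attempt in range(12):
        g_bg = np.zeros(4)
        g_loop = np.zeros((nl, 4))
        g_pair = np.zeros((npr, 6))
        g_omega = np.zeros(1)
        g_energy = np.zeros(1)
        post_loop = np.zeros(L)
        post_pairm = np.zeros(L)
        post_ins = np.zeros(L)
        pairpost = np.zeros((L, L))
        g_star = np.zeros(max(1, len(mach.star_positions)))
        sc = np.exp(-sigma)
        Zs = run_coupled(
            L, S, mach.end_gap, mach.C,
            mach.tr_src, mach.tr_dst, mach.tr_kind, mach.tr_aux,
            mach.tr_internal, CTW_raw * sc[None, :],
            mach.em_kind, mach.em_a, mach.em_b, mach.em_entry_gap,
            mach.em_exit_state, mach.em_int_entry, mach.em_int_target,
            mach.em_internal_l, mach.em_internal_r, mach.em_eg_slot,
            mach.em_ent_slot, mach.peg_states, mach.ent_states,
            xi, ptm, PE, WB, sc,
            wHP, fHP, wSW, fSW,
            w_bb, f_bb, w_ib, f_ib, w_mc, f_mc, w_mlb, f_mlb, w_si, f_si,
            w_sml, f_sml, om_t,
            Dmax, mh,
            want_counts,
            g_bg, g_loop, g_pair, g_omega, g_energy,
            post_loop, post_pairm, post_ins, pairpost, g_star,
        )
        if np.isfinite(Zs) and Zs > 0.0:
            break
        if not np.isfinite(Zs):
            sigma = sigma + shift       # overflow: shrink all weights
        elif attempt < 3:
            sigma = sigma - shift       # possible underflow: grow weights
        else:
            break                       # a genuine zero (motif cannot occur)

    if Zs <= 0.0:
        logZ = -np.inf
        z = 1.0  # avoid division; counts are all zero anyway
    else:
        logZ = float(np.log(Zs) + np.sum(sigma))
        z = Zs
    pp = pairpost / z
    return _RunOut(
        logZ=logZ,
        n_loop=(g_loop / z)[: mach.n_loops],
        n_pair=(g_pair / z)[: mach.n_pairs],
        n_bg=g_bg / z,
        n_self=float(g_omega[0] / z),
        energy=float(g_energy[0] / z),
        post_loop=post_loop / z,
        post_pairm=post_pairm / z,
        post_ins=post_ins / z,
        pairpost=pp + pp.T,
        n_star=g_star / z,
    )


@dataclass
class CoupledCharts:
    """Results of the coupled inside-outside computation for one sequence.

    Satisfies ``Z = Z+ + Z-`` by construction; expected counts under the
    full ensemble are the probability-weighted mixture of the counts
    under ``Z+`` and ``Z-``.
    """

    seq: str
    logZ: float
    logZ_plus: float
    logZ_minus: float
    prob: float
    plus: _RunOut
    minus: _RunOut

    def position_posterior(self, kind: str = "motif") -> np.ndarray:
        """Per-position posterior of motif membership under the full
        ensemble (``kind``: 'motif', 'loop', 'pair' or 'insertion')."""
        w = self.prob
        if kind == "loop":
            return self.plus.post_loop * w
        if kind == "pair":
            return self.plus.post_pairm * w
        if kind == "insertion":
            return self.plus.post_ins * w
        if kind == "motif":
            return (self.plus.post_loop + self.plus.post_pairm + self.plus.post_ins) * w
        raise ValueError(f"unknown posterior kind {kind!r}")

    def pair_posterior(self) -> np.ndarray:
        """Base-pair posterior matrix under the full ensemble."""
        return self.plus.pairpost * self.prob + self.minus.pairpost * (1 - self.prob)

    def counts(self, ensemble: str = "Z"):
        """Expected emission counts ``(n_loop, n_pair, n_bg, n_self, energy)``.

        ``energy`` is the expectation of ``-dG/kT`` (the derivative of
        the log partition with respect to the coupling scale).
        """
        if ensemble == "Z+":
            r = self.plus
            if self.logZ_plus == -np.inf:
                warnings.warn("Z+ is zero; expected counts under Z+ are zeros")
            return r.n_loop, r.n_pair, r.n_bg, r.n_self, r.energy
        if ensemble == "Z-":
            r = self.minus
            nl = np.zeros_like(self.plus.n_loop)
            npr = np.zeros_like(self.plus.n_pair)
            return nl, npr, r.n_bg, 0.0, r.energy
        if ensemble == "Z":
            w = self.prob
            nlp, npp, nbp, nsp, ep = self.counts("Z+")
            nlm, npm, nbm, nsm, em_ = self.counts("Z-")
            return (
                nlp * w + nlm * (1 - w),
                npp * w + npm * (1 - w),
                nbp * w + nbm * (1 - w),
                nsp * w + nsm * (1 - w),
                ep * w + em_ * (1 - w),
            )
        raise ValueError(f"unknown ensemble {ensemble!r}")


def coupled_charts(
    seq: str | np.ndarray,
    model: ProfileModel,
    params: EnergyParams | None = None,
    want_counts: bool = True,
) -> CoupledCharts:
    """Run the joint inside(-outside) DP for one sequence."""
    params = params or default_energy_params()
    x = seq if isinstance(seq, np.ndarray) else encode(seq)
    if len(x) == 0:
        raise ValueError("empty sequence")
    mach = machine_for(model.pattern.text)
    triv = machine_for("*")
    plus = _run_machine(
        mach, x, model.theta_loop, model.theta_pair, model.theta_bg,
        model.omega, model.lam, params, want_counts,
    )
    zero_l = np.zeros((1, 4))
    zero_p = np.zeros((1, 6))
    minus = _run_machine(
        triv, x, zero_l, zero_p, model.theta_bg,
        model.omega, model.lam, params, want_counts,
    )
    logZp, logZm = plus.logZ, minus.logZ
    logZ = float(np.logaddexp(logZp, logZm))
    # P(y=1) = 1 / (1 + exp(logZ- - logZ+)), stable in both tails
    if logZp == -np.inf:
        prob = 0.0
    else:
        prob = float(1.0 / (1.0 + np.exp(logZm - logZp)))
    return CoupledCharts(
        seq=seq if isinstance(seq, str) else "",
        logZ=logZ,
        logZ_plus=logZp,
        logZ_minus=logZm,
        prob=prob,
        plus=plus,
        minus=minus,
    )


def coupled_logZ(seq, model, params=None) -> float:
    """log of the full coupled partition function Z."""
    return coupled_charts(seq, model, params, want_counts=False).logZ


def coupled_logZ_minus(seq, model, params=None) -> float:
    """log Z- (motif-absent parses over the full structure ensemble)."""
    return coupled_charts(seq, model, params, want_counts=False).logZ_minus


def coupled_logZ_plus(seq, model, params=None) -> float:
    """log Z+ (motif-containing parses); ``-inf`` if the motif cannot match."""
    return coupled_charts(seq, model, params, want_counts=False).logZ_plus


def motif_probability(seq, model, params=None) -> float:
    """P(y=1 | x) = Z+ / Z, computed stably in log space."""
    return coupled_charts(seq, model, params, want_counts=False).prob


def expected_counts(seq, model, params=None, ensemble: str = "Z"):
    """Expected emission counts under ``Z``, ``Z+`` or ``Z-``."""
    return coupled_charts(seq, model, params, want_counts=True).counts(ensemble)


def position_posterior(seq, model, params=None, kind: str = "motif") -> np.ndarray:
    """Per-position motif-membership posterior under the full ensemble."""
    return coupled_charts(seq, model, params, want_counts=True).position_posterior(kind)


def _structure_partition_impl(seq, params: EnergyParams, canonical_only: bool):
    """Energy-only ensemble: log partition value and base-pair posteriors."""
    x = encode(seq) if isinstance(seq, str) else seq
    triv = machine_for("*")
    out = _run_machine(
        triv, x, np.zeros((1, 4)), np.zeros((1, 6)), np.zeros(4),
        0.0, 1.0, params, want_counts=True, canonical_only=canonical_only,
    )
    return out.logZ, out.pairpost
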