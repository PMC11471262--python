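"""Joint inside-outside dynamic programming over structure x profile parses.

The chart families, all in linear space with per-position scaling:

``R[n, i, e, q]``
    all-unpaired emission runs of length ``n`` starting at ``i`` from
    interior-entry state ``e`` (used for hairpin interiors).
``VAL[em, d, i]``
    pair items: base pair ``(i, i+d-1)`` emitted by emitter ``em``
    (a pattern bracket pair or a background star pair), including its
    closed interior with the loop-type energy.
``SB0/SBL/SBR/SBLR[d, i, p, q]``
    closed-pair interiors holding exactly one branch with no / left-only
    / right-only / two-sided unpaired runs (stack, bulge and internal
    loops; per-base slope weights are folded into run growth, the
    case-dependent base cost is applied at the closing pair).
``MB, MA1, MA2[d, i, p, q]``
    multiloop segments: one branch plus trailing unpaired; a leading-run
    extension of that; and two-or-more branches.
``AC[d, i, p, g]``
    MA values closed into each pair-entry gap (for branch appending).
``Fo[j, q]``
    the exterior prefix.

Interior charts are only ever read at a small set of entry states (the
emitters' interior entries, the pair-entry gaps, and the transition
targets through which left-growing runs re-enter them), so their ``p``
dimension ranges over that restricted universe.  Epsilon
closure is handled through source-predecessor lists.  Statements are
strictly ordered; the outside pass is the literal adjoint executed in
reverse, which also accumulates expected emission counts, the expected
``-dG/kT`` (the coupling-scale gradient), per-position motif-membership
masses and base-pair posteriors.
"""

import numpy as np
from numba import njit

__all__ = ["run_coupled"]


@njit(cache=False, fastmath=True, inline="always")
def _acc_tr(cc, t, pos, tr_kind, tr_aux, tr_internal, x,
            g_bg, g_loop, g_omega, post_loop, post_ins, g_star):
    k = tr_kind[t]
    if k == 0:
        g_bg[x[pos]] += cc
        g_star[tr_aux[t]] += cc
        if tr_internal[t] == 1:
            post_ins[pos] += cc
    elif k == 1:
        g_loop[tr_aux[t], x[pos]] += cc
        post_loop[pos] += cc
    else:
        g_loop[tr_aux[t], x[pos]] += cc
        g_omega[0] += cc
        post_loop[pos] += cc


@njit(cache=False, fastmath=True)
def run_coupled(
    L, S, end_gap, Cm,
    tr_src, tr_dst, tr_kind, tr_aux, tr_internal, CTW,
    em_kind, em_a, em_b, em_entry_gap, em_exit_state, em_int_entry,
    em_int_target, em_internal_l, em_internal_r, em_eg_slot, em_ent_slot,
    peg_states, ent_states,
    x, ptm, PE, WB, sc,
    wHP, fHP, wSW, fSW,
    w_bb, f_bb, w_ib, f_ib, w_mc, f_mc, w_mlb, f_mlb, w_si, f_si,
    w_sml, f_sml, om_t,
    Dmax, mh,
    do_outside,
    g_bg, g_loop, g_pair, g_omega, g_energy,
    post_loop, post_pairm, post_ins, pairpost, g_star,
):
    ntr = tr_src.shape[0]
    nem = em_kind.shape[0]
    nE = ent_states.shape[0]
    nPEG = peg_states.shape[0]
    minps = mh + 2          # minimal span j - i of a pair item
    Dm = Dmax

    # ---- closure predecessor lists over full states (for Fo)
    cl_off = np.zeros(S + 1, dtype=np.int64)
    for s in range(S):
        c = 0
        for p in range(S):
            if Cm[p, s] > 0.0:
                c += 1
        cl_off[s + 1] = cl_off[s] + c
    cl_idx = np.zeros(cl_off[S], dtype=np.int64)
    for s in range(S):
        k = cl_off[s]
        for p in range(S):
            if Cm[p, s] > 0.0:
                cl_idx[k] = p
                k += 1

    # ---- restricted p-universe for interior charts
    inP = np.zeros(S, dtype=np.int64)
    for em in range(nem):
        inP[em_int_entry[em]] = 1
    for g in range(nPEG):
        inP[peg_states[g]] = 1
    for t in range(ntr):
        inP[tr_dst[t]] = 1  # left-growth re-enters interiors at these states
    nP = 0
    P_inv = -np.ones(S, dtype=np.int64)
    for p in range(S):
        if inP[p] == 1:
            P_inv[p] = nP
            nP += 1
    ge_slot = np.zeros(nem, dtype=np.int64)
    for em in range(nem):
        ge_slot[em] = P_inv[em_int_entry[em]]
    pegP = np.zeros(nPEG, dtype=np.int64)
    for g in range(nPEG):
        pegP[g] = P_inv[peg_states[g]]
    # predecessor lists restricted to the p-universe (slot indices)
    c2_off = np.zeros(S + 1, dtype=np.int64)
    for s in range(S):
        c = 0
        for p in range(S):
            if Cm[p, s] > 0.0 and inP[p] == 1:
                c += 1
        c2_off[s + 1] = c2_off[s] + c
    c2_idx = np.zeros(c2_off[S], dtype=np.int64)
    for s in range(S):
        k = c2_off[s]
        for p in range(S):
            if Cm[p, s] > 0.0 and inP[p] == 1:
                c2_idx[k] = P_inv[p]
                k += 1

    # ---- emission-run chart
    nR = Dm - 1 if Dm >= 2 else 1
    R = np.zeros((nR, L + 1, nE, S))
    for i in range(L + 1):
        for e in range(nE):
            R[0, i, e, ent_states[e]] = 1.0
    for n in range(1, nR):
        for i in range(L - n + 1):
            pos = i + n - 1
            for t in range(ntr):
                s = tr_src[t]
                dt = tr_dst[t]
                w = CTW[t, pos]
                if w == 0.0:
                    continue
                for e in range(nE):
                    acc = 0.0
                    for pi in range(cl_off[s], cl_off[s + 1]):
                        acc += R[n - 1, i, e, cl_idx[pi]]
                    if acc != 0.0:
                        R[n, i, e, dt] += w * acc

    VAL = np.zeros((nem, Dm + 1, L))
    SB0 = np.zeros((Dm + 1, L, nP, S))
    SBL = np.zeros((Dm + 1, L, nP, S))
    SBR = np.zeros((Dm + 1, L, nP, S))
    SBLR = np.zeros((Dm + 1, L, nP, S))
    MB = np.zeros((Dm + 1, L, nP, S))
    MA1 = np.zeros((Dm + 1, L, nP, S))
    MA2 = np.zeros((Dm + 1, L, nP, S))
    AC = np.zeros((Dm + 1, L, nP, nPEG))

    for d in range(2, Dm + 1):
        # ---- STEP A: pair items of span d
        if d >= minps:
            for i in range(L - d + 1):
                j = i + d
                jj = j - 1
                pt_o = ptm[i, jj]
                if pt_o < 0:
                    continue
                i1 = i + 1
                nint = d - 2
                for em in range(nem):
                    if em_kind[em] == 1:
                        w_emit = PE[em_a[em], pt_o]
                    else:
                        w_emit = WB[x[i]] * WB[x[jj]]
                    w_base = w_emit * sc[i] * sc[jj]
                    if w_base == 0.0:
                        continue
                    ge = ge_slot[em]
                    gt = em_int_target[em]
                    eix = em_ent_slot[em]
                    acc = 0.0
                    # hairpin interior
                    if nint < nR:
                        hsum = 0.0
                        for qi in range(cl_off[gt], cl_off[gt + 1]):
                            hsum += R[nint, i1, eix, cl_idx[qi]]
                        acc += wHP[nint] * hsum
                    # helix extension (motif pairs only)
                    if em_kind[em] == 1 and d - 2 >= minps:
                        pt_i = ptm[i1, jj - 1]
                        if pt_i >= 0:
                            acc += om_t * wSW[pt_o, pt_i] * VAL[em, d - 2, i1]
                    if nint >= minps:
                        # stack on a bare branch
                        pt_x = ptm[i1, j - 2]
                        if pt_x >= 0:
                            ssum = 0.0
                            for qi in range(cl_off[gt], cl_off[gt + 1]):
                                ssum += SB0[nint, i1, ge, cl_idx[qi]]
                            acc += wSW[pt_o, pt_x] * ssum
                        bsum = 0.0
                        isum = 0.0
                        msum = 0.0
                        for qi in range(cl_off[gt], cl_off[gt + 1]):
                            q = cl_idx[qi]
                            bsum += SBL[nint, i1, ge, q] + SBR[nint, i1, ge, q]
                            isum += SBLR[nint, i1, ge, q]
                            msum += MA2[nint, i1, ge, q]
                        acc += w_bb * bsum + w_ib * isum + w_mc * msum
                    VAL[em, d, i] = w_base * acc

        # ---- STEP B: interior content items of span d
        if d >= minps and d <= Dm - 2:
            for i in range(L - d + 1):
                # SB0: bare branch
                for em in range(nem):
                    v = VAL[em, d, i]
                    if v == 0.0:
                        continue
                    eg = em_entry_gap[em]
                    ex = em_exit_state[em]
                    for pi in range(c2_off[eg], c2_off[eg + 1]):
                        SB0[d, i, c2_idx[pi], ex] += v
                # SBL: grow left run
                for t in range(ntr):
                    s = tr_src[t]
                    dtp = P_inv[tr_dst[t]]
                    w = CTW[t, i] * w_si
                    if w == 0.0:
                        continue
                    for q in range(S):
                        v = SB0[d - 1, i + 1, dtp, q] + SBL[d - 1, i + 1, dtp, q]
                        if v == 0.0:
                            continue
                        wv = w * v
                        for pi in range(c2_off[s], c2_off[s + 1]):
                            SBL[d, i, c2_idx[pi], q] += wv
                # SBR: grow right run
                for t in range(ntr):
                    s = tr_src[t]
                    dt = tr_dst[t]
                    w = CTW[t, i + d - 1] * w_si
                    if w == 0.0:
                        continue
                    for p in range(nP):
                        acc = 0.0
                        for qi in range(cl_off[s], cl_off[s + 1]):
                            q1 = cl_idx[qi]
                            acc += SB0[d - 1, i, p, q1] + SBR[d - 1, i, p, q1]
                        if acc != 0.0:
                            SBR[d, i, p, dt] += w * acc
                # SBLR: two-sided
                for t in range(ntr):
                    s = tr_src[t]
                    dt = tr_dst[t]
                    w = CTW[t, i + d - 1] * w_si
                    if w == 0.0:
                        continue
                    for p in range(nP):
                        acc = 0.0
                        for qi in range(cl_off[s], cl_off[s + 1]):
                            q1 = cl_idx[qi]
                            acc += SBL[d - 1, i, p, q1] + SBLR[d - 1, i, p, q1]
                        if acc != 0.0:
                            SBLR[d, i, p, dt] += w * acc
                # MB: branch (+ trailing multiloop-unpaired)
                for em in range(nem):
                    v = VAL[em, d, i] * w_mlb
                    if v == 0.0:
                        continue
                    eg = em_entry_gap[em]
                    ex = em_exit_state[em]
                    for pi in range(c2_off[eg], c2_off[eg + 1]):
                        MB[d, i, c2_idx[pi], ex] += v
                for t in range(ntr):
                    s = tr_src[t]
                    dt = tr_dst[t]
                    w = CTW[t, i + d - 1] * w_sml
                    if w == 0.0:
                        continue
                    for p in range(nP):
                        acc = 0.0
                        for qi in range(cl_off[s], cl_off[s + 1]):
                            acc += MB[d - 1, i, p, cl_idx[qi]]
                        if acc != 0.0:
                            MB[d, i, p, dt] += w * acc
                # MA2: append last branch
                if d >= 2 * minps:
                    for dk in range(minps, d - minps + 1):
                        k = i + dk
                        for p in range(nP):
                            for g in range(nPEG):
                                a = AC[dk, i, p, g]
                                if a == 0.0:
                                    continue
                                pg = pegP[g]
                                for q in range(S):
                                    v = MB[d - dk, k, pg, q]
                                    if v != 0.0:
                                        MA2[d, i, p, q] += a * v
                # MA1 = MB + leading run
                for p in range(nP):
                    for q in range(S):
                        MA1[d, i, p, q] = MB[d, i, p, q]
                for t in range(ntr):
                    s = tr_src[t]
                    dtp = P_inv[tr_dst[t]]
                    w = CTW[t, i] * w_sml
                    if w == 0.0:
                        continue
                    for q in range(S):
                        v = MA1[d - 1, i + 1, dtp, q]
                        if v == 0.0:
                            continue
                        wv = w * v
                        for pi in range(c2_off[s], c2_off[s + 1]):
                            MA1[d, i, c2_idx[pi], q] += wv
                # AC
                for p in range(nP):
                    for g in range(nPEG):
                        pst = peg_states[g]
                        a = 0.0
                        for qi in range(cl_off[pst], cl_off[pst + 1]):
                            q = cl_idx[qi]
                            a += MA1[d, i, p, q] + MA2[d, i, p, q]
                        AC[d, i, p, g] = a

    # ---- exterior
    Fo = np.zeros((L + 1, S))
    FoC = np.zeros((L + 1, nPEG))
    Fo[0, 0] = 1.0
    for g in range(nPEG):
        FoC[0, g] = Cm[0, peg_states[g]]
    for jpos in range(1, L + 1):
        for t in range(ntr):
            s = tr_src[t]
            dt = tr_dst[t]
            w = CTW[t, jpos - 1]
            if w == 0.0:
                continue
            acc = 0.0
            for pi in range(cl_off[s], cl_off[s + 1]):
                acc += Fo[jpos - 1, cl_idx[pi]]
            if acc != 0.0:
                Fo[jpos, dt] += w * acc
        dmaxh = Dm if Dm < jpos else jpos
        for d in range(minps, dmaxh + 1):
            i = jpos - d
            for em in range(nem):
                v = VAL[em, d, i]
                if v != 0.0:
                    Fo[jpos, em_exit_state[em]] += FoC[i, em_eg_slot[em]] * v
        for g in range(nPEG):
            pst = peg_states[g]
            a = 0.0
            for pi in range(cl_off[pst], cl_off[pst + 1]):
                a += Fo[jpos, cl_idx[pi]]
            FoC[jpos, g] = a

    Zs = 0.0
    for qi in range(cl_off[end_gap], cl_off[end_gap + 1]):
        Zs += Fo[L, cl_idx[qi]]

    if (not do_outside) or Zs <= 0.0:
        return Zs

    # =================== outside / adjoint pass ===================
    Fo_b = np.zeros((L + 1, S))
    FoC_b = np.zeros((L + 1, nPEG))
    VAL_b = np.zeros((nem, Dm + 1, L))
    SB0_b = np.zeros((Dm + 1, L, nP, S))
    SBL_b = np.zeros((Dm + 1, L, nP, S))
    SBR_b = np.zeros((Dm + 1, L, nP, S))
    SBLR_b = np.zeros((Dm + 1, L, nP, S))
    MB_b = np.zeros((Dm + 1, L, nP, S))
    MA1_b = np.zeros((Dm + 1, L, nP, S))
    MA2_b = np.zeros((Dm + 1, L, nP, S))
    AC_b = np.zeros((Dm + 1, L, nP, nPEG))
    R_b = np.zeros((nR, L + 1, nE, S))

    for qi in range(cl_off[end_gap], cl_off[end_gap + 1]):
        Fo_b[L, cl_idx[qi]] = 1.0

    # reverse exterior
    for jpos in range(L, 0, -1):
        for g in range(nPEG):
            b = FoC_b[jpos, g]
            if b == 0.0:
                continue
            pst = peg_states[g]
            for pi in range(cl_off[pst], cl_off[pst + 1]):
                Fo_b[jpos, cl_idx[pi]] += b
        dmaxh = Dm if Dm < jpos else jpos
        for d in range(minps, dmaxh + 1):
            i = jpos - d
            for em in range(nem):
                fb = Fo_b[jpos, em_exit_state[em]]
                if fb == 0.0:
                    continue
                v = VAL[em, d, i]
                sl = em_eg_slot[em]
                if v != 0.0:
                    FoC_b[i, sl] += fb * v
                fc = FoC[i, sl]
                if fc != 0.0:
                    VAL_b[em, d, i] += fb * fc
        for t in range(ntr):
            s = tr_src[t]
            dt = tr_dst[t]
            w = CTW[t, jpos - 1]
            if w == 0.0:
                continue
            fb = Fo_b[jpos, dt]
            if fb == 0.0:
                continue
            fbw = fb * w
            accv = 0.0
            for pi in range(cl_off[s], cl_off[s + 1]):
                p = cl_idx[pi]
                Fo_b[jpos - 1, p] += fbw
                accv += Fo[jpos - 1, p]
            if accv != 0.0:
                _acc_tr(fbw * accv, t, jpos - 1, tr_kind, tr_aux, tr_internal,
                        x, g_bg, g_loop, g_omega, post_loop, post_ins, g_star)

    # reverse span loop
    for d in range(Dm, 1, -1):
        if d >= minps and d <= Dm - 2:
            for i in range(L - d, -1, -1):
                # AC adjoint
                for p in range(nP):
                    for g in range(nPEG):
                        b = AC_b[d, i, p, g]
                        if b == 0.0:
                            continue
                        pst = peg_states[g]
                        for qi in range(cl_off[pst], cl_off[pst + 1]):
                            q = cl_idx[qi]
                            MA1_b[d, i, p, q] += b
                            MA2_b[d, i, p, q] += b
                # MA1 adjoint: leading run, then MB copy
                for t in range(ntr):
                    s = tr_src[t]
                    dtp = P_inv[tr_dst[t]]
                    w = CTW[t, i] * w_sml
                    if w == 0.0:
                        continue
                    for q in range(S):
                        bsum = 0.0
                        for pi in range(c2_off[s], c2_off[s + 1]):
                            bsum += MA1_b[d, i, c2_idx[pi], q]
                        if bsum == 0.0:
                            continue
                        v = MA1[d - 1, i + 1, dtp, q]
                        MA1_b[d - 1, i + 1, dtp, q] += bsum * w
                        if v != 0.0:
                            cc = bsum * w * v
                            _acc_tr(cc, t, i, tr_kind, tr_aux, tr_internal,
                                    x, g_bg, g_loop, g_omega, post_loop,
                                    post_ins, g_star)
                            g_energy[0] += cc * f_sml
                for p in range(nP):
                    for q in range(S):
                        b = MA1_b[d, i, p, q]
                        if b != 0.0:
                            MB_b[d, i, p, q] += b
                # MA2 adjoint
                if d >= 2 * minps:
                    for p in range(nP):
                        for q in range(S):
                            b = MA2_b[d, i, p, q]
                            if b == 0.0:
                                continue
                            for dk in range(minps, d - minps + 1):
                                k = i + dk
                                for g in range(nPEG):
                                    a = AC[dk, i, p, g]
                                    pg = pegP[g]
                                    v = MB[d - dk, k, pg, q]
                                    if v != 0.0:
                                        AC_b[dk, i, p, g] += b * v
                                    if a != 0.0:
                                        MB_b[d - dk, k, pg, q] += b * a
                # MB adjoint: right growth, then branch
                for t in range(ntr):
                    s = tr_src[t]
                    dt = tr_dst[t]
                    w = CTW[t, i + d - 1] * w_sml
                    if w == 0.0:
                        continue
                    for p in range(nP):
                        b = MB_b[d, i, p, dt]
                        if b == 0.0:
                            continue
                        bw = b * w
                        accv = 0.0
                        for qi in range(cl_off[s], cl_off[s + 1]):
                            q1 = cl_idx[qi]
                            accv += MB[d - 1, i, p, q1]
                            MB_b[d - 1, i, p, q1] += bw
                        if accv != 0.0:
                            cc = bw * accv
                            _acc_tr(cc, t, i + d - 1, tr_kind, tr_aux,
                                    tr_internal, x, g_bg, g_loop, g_omega,
                                    post_loop, post_ins, g_star)
                            g_energy[0] += cc * f_sml
                for em in range(nem):
                    eg = em_entry_gap[em]
                    ex = em_exit_state[em]
                    bsum = 0.0
                    for pi in range(c2_off[eg], c2_off[eg + 1]):
                        bsum += MB_b[d, i, c2_idx[pi], ex]
                    if bsum != 0.0:
                        VAL_b[em, d, i] += bsum * w_mlb
                        v = VAL[em, d, i]
                        if v != 0.0:
                            g_energy[0] += bsum * w_mlb * v * f_mlb
                # SBLR adjoint
                for t in range(ntr):
                    s = tr_src[t]
                    dt = tr_dst[t]
                    w = CTW[t, i + d - 1] * w_si
                    if w == 0.0:
                        continue
                    for p in range(nP):
                        b = SBLR_b[d, i, p, dt]
                        if b == 0.0:
                            continue
                        bw = b * w
                        accv = 0.0
                        for qi in range(cl_off[s], cl_off[s + 1]):
                            q1 = cl_idx[qi]
                            accv += SBL[d - 1, i, p, q1] + SBLR[d - 1, i, p, q1]
                            SBL_b[d - 1, i, p, q1] += bw
                            SBLR_b[d - 1, i, p, q1] += bw
                        if accv != 0.0:
                            cc = bw * accv
                            _acc_tr(cc, t, i + d - 1, tr_kind, tr_aux,
                                    tr_internal, x, g_bg, g_loop, g_omega,
                                    post_loop, post_ins, g_star)
                            g_energy[0] += cc * f_si
                # SBR adjoint
                for t in range(ntr):
                    s = tr_src[t]
                    dt = tr_dst[t]
                    w = CTW[t, i + d - 1] * w_si
                    if w == 0.0:
                        continue
                    for p in range(nP):
                        b = SBR_b[d, i, p, dt]
                        if b == 0.0:
                            continue
                        bw = b * w
                        accv = 0.0
                        for qi in range(cl_off[s], cl_off[s + 1]):
                            q1 = cl_idx[qi]
                            accv += SB0[d - 1, i, p, q1] + SBR[d - 1, i, p, q1]
                            SB0_b[d - 1, i, p, q1] += bw
                            SBR_b[d - 1, i, p, q1] += bw
                        if accv != 0.0:
                            cc = bw * accv
                            _acc_tr(cc, t, i + d - 1, tr_kind, tr_aux,
                                    tr_internal, x, g_bg, g_loop, g_omega,
                                    post_loop, post_ins, g_star)
                            g_energy[0] += cc * f_si
                # SBL adjoint
                for t in range(ntr):
                    s = tr_src[t]
                    dtp = P_inv[tr_dst[t]]
                    w = CTW[t, i] * w_si
                    if w == 0.0:
                        continue
                    for q in range(S):
                        bsum = 0.0
                        for pi in range(c2_off[s], c2_off[s + 1]):
                            bsum += SBL_b[d, i, c2_idx[pi], q]
                        if bsum == 0.0:
                            continue
                        v = SB0[d - 1, i + 1, dtp, q] + SBL[d - 1, i + 1, dtp, q]
                        bw = bsum * w
                        SB0_b[d - 1, i + 1, dtp, q] += bw
                        SBL_b[d - 1, i + 1, dtp, q] += bw
                        if v != 0.0:
                            cc = bw * v
                            _acc_tr(cc, t, i, tr_kind, tr_aux, tr_internal,
                                    x, g_bg, g_loop, g_omega, post_loop,
                                    post_ins, g_star)
                            g_energy[0] += cc * f_si
                # SB0 adjoint
                for em in range(nem):
                    eg = em_entry_gap[em]
                    ex = em_exit_state[em]
                    bsum = 0.0
                    for pi in range(c2_off[eg], c2_off[eg + 1]):
                        bsum += SB0_b[d, i, c2_idx[pi], ex]
                    if bsum != 0.0:
                        VAL_b[em, d, i] += bsum

        # STEP A adjoint
        if d >= minps:
            for i in range(L - d, -1, -1):
                j = i + d
                jj = j - 1
                pt_o = ptm[i, jj]
                if pt_o < 0:
                    continue
                i1 = i + 1
                nint = d - 2
                for em in range(nem):
                    vb = VAL_b[em, d, i]
                    if vb == 0.0:
                        continue
                    vv = VAL[em, d, i]
                    cc_t = vb * vv
                    if cc_t != 0.0:
                        pairpost[i, jj] += cc_t
                        if em_kind[em] == 1:
                            g_pair[em_a[em], pt_o] += cc_t
                            post_pairm[i] += cc_t
                            post_pairm[jj] += cc_t
                        else:
                            g_bg[x[i]] += cc_t
                            g_bg[x[jj]] += cc_t
                            g_star[em_a[em]] += cc_t
                            g_star[em_b[em]] += cc_t
                            if em_internal_l[em] == 1:
                                post_ins[i] += cc_t
                            if em_internal_r[em] == 1:
                                post_ins[jj] += cc_t
                    if em_kind[em] == 1:
                        w_emit = PE[em_a[em], pt_o]
                    else:
                        w_emit = WB[x[i]] * WB[x[jj]]
                    w_base = w_emit * sc[i] * sc[jj]
                    if w_base == 0.0:
                        continue
                    ge = ge_slot[em]
                    gt = em_int_target[em]
                    eix = em_ent_slot[em]
                    # hairpin
                    if nint < nR:
                        whp = vb * w_base * wHP[nint]
                        hsum = 0.0
                        for qi in range(cl_off[gt], cl_off[gt + 1]):
                            q = cl_idx[qi]
                            hsum += R[nint, i1, eix, q]
                            R_b[nint, i1, eix, q] += whp
                        if hsum != 0.0:
                            g_energy[0] += whp * hsum * fHP[nint]
                    # helix extension
                    if em_kind[em] == 1 and d - 2 >= minps:
                        pt_i = ptm[i1, jj - 1]
                        if pt_i >= 0:
                            term_w = w_base * om_t * wSW[pt_o, pt_i]
                            v = VAL[em, d - 2, i1]
                            VAL_b[em, d - 2, i1] += vb * term_w
                            if v != 0.0:
                                cc = vb * term_w * v
                                g_omega[0] += cc
                                g_energy[0] += cc * fSW[pt_o, pt_i]
                    if nint >= minps:
                        pt_x = ptm[i1, j - 2]
                        if pt_x >= 0:
                            wst = vb * w_base * wSW[pt_o, pt_x]
                            ssum = 0.0
                            for qi in range(cl_off[gt], cl_off[gt + 1]):
                                q = cl_idx[qi]
                                ssum += SB0[nint, i1, ge, q]
                                SB0_b[nint, i1, ge, q] += wst
                            if ssum != 0.0:
                                g_energy[0] += wst * ssum * fSW[pt_o, pt_x]
                        wbu = vb * w_base * w_bb
                        win = vb * w_base * w_ib
                        wml = vb * w_base * w_mc
                        bsum = 0.0
                        isum = 0.0
                        msum = 0.0
                        for qi in range(cl_off[gt], cl_off[gt + 1]):
                            q = cl_idx[qi]
                            bsum += SBL[nint, i1, ge, q] + SBR[nint, i1, ge, q]
                            isum += SBLR[nint, i1, ge, q]
                            msum += MA2[nint, i1, ge, q]
                            SBL_b[nint, i1, ge, q] += wbu
                            SBR_b[nint, i1, ge, q] += wbu
                            SBLR_b[nint, i1, ge, q] += win
                            MA2_b[nint, i1, ge, q] += wml
                        if bsum != 0.0:
                            g_energy[0] += wbu * bsum * f_bb
                        if isum != 0.0:
                            g_energy[0] += win * isum * f_ib
                        if msum != 0.0:
                            g_energy[0] += wml * msum * f_mc

    # reverse R recurrences
    for n in range(nR - 1, 0, -1):
        for i in range(L - n + 1):
            pos = i + n - 1
            for t in range(ntr):
                s = tr_src[t]
                dt = tr_dst[t]
                w = CTW[t, pos]
                if w == 0.0:
                    continue
                for e in range(nE):
                    b = R_b[n, i, e, dt]
                    if b == 0.0:
                        continue
                    bw = b * w
                    accv = 0.0
                    for pi in range(cl_off[s], cl_off[s + 1]):
                        p = cl_idx[pi]
                        accv += R[n - 1, i, e, p]
                        R_b[n - 1, i, e, p] += bw
                    if accv != 0.0:
                        _acc_tr(bw * accv, t, pos, tr_kind, tr_aux,
                                tr_internal, x, g_bg, g_loop, g_omega,
                                post_loop, post_ins, g_star)

    return Zs
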