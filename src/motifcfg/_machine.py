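"""Profile-automaton metadata driving the coupled dynamic programming.

The joint grammar threads a small pushdown automaton derived from the
search pattern through the secondary-structure grammar.  Linear progress
through the pattern is tracked by *boundary states*: one "gap" state per
position between pattern symbols (gap ``u`` = symbols before ``u``
completed) plus one "run" state per loop symbol (the loop has emitted at
least one base and may self-transition).  Epsilon moves close a finished
star or loop run; values are stored *pre-closure* and every transition
closes over its source, so each parse is counted exactly once.

Base pairs of the structure are emitted either by a pattern bracket pair
(a "motif pair" emitter, one per bracket pair) or with both ends drawn
from insertion/background profiles (a "background pair" emitter, one per
ordered pair of star symbols).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .pattern import SearchPattern, parse_pattern

# linear-transition kinds
TR_BG = 0      # emission from a star (background profile)
TR_LOOP = 1    # first emission of a loop symbol (enter its run state)
TR_SELF = 2    # repeated loop emission (self-transition, costs omega)

# emitter kinds
EM_PB = 0      # background pair (both ends from star symbols)
EM_PM = 1      # motif pair (pattern bracket pair)


@dataclass(frozen=True)
class Machine:
    text: str
    n_loops: int
    n_pairs: int
    S: int                    # number of boundary states
    end_gap: int              # accepting gap state (= len(text))
    C: np.ndarray             # (S, S) float64 0/1 epsilon-closure (reflexive)
    # linear transitions
    tr_src: np.ndarray
    tr_dst: np.ndarray
    tr_kind: np.ndarray
    tr_aux: np.ndarray        # star slot index (TR_BG) or loop index
    tr_internal: np.ndarray   # 1 if a star emission from an internal star
    # pair emitters
    em_kind: np.ndarray
    em_a: np.ndarray          # PB: left star index; PM: pair index
    em_b: np.ndarray          # PB: right star index; PM: -1
    em_entry_gap: np.ndarray  # gap state required before the pair
    em_exit_state: np.ndarray # state after the pair
    em_int_entry: np.ndarray  # state at the start of the interior
    em_int_target: np.ndarray # gap state the interior must close into
    em_internal_l: np.ndarray # 1 if left end is an internal-star emission (PB)
    em_internal_r: np.ndarray
    em_eg_slot: np.ndarray    # index into peg_states
    peg_states: np.ndarray    # distinct entry-gap states (PEG)
    ent_states: np.ndarray    # distinct interior-entry states (for R runs)
    em_ent_slot: np.ndarray   # index of em_int_entry within ent_states
    loop_pattern_pos: np.ndarray  # pattern position of each loop symbol
    star_positions: np.ndarray

    @property
    def n_tr(self) -> int:
        return len(self.tr_src)

    @property
    def n_em(self) -> int:
        return len(self.em_kind)


def _closure(eps: list[tuple[int, int]], S: int) -> np.ndarray:
    C = np.eye(S)
    adj = np.zeros((S, S))
    for a, b in eps:
        adj[a, b] = 1.0
    for _ in range(S):
        new = np.minimum(1.0, C + C @ adj)
        if np.array_equal(new, C):
            break
        C = new
    return C


def build_machine(pattern: SearchPattern | str) -> Machine:
    """Construct the automaton for a pattern (or raw text like ``"*"``)."""
    if isinstance(pattern, SearchPattern):
        text = pattern.text
        pair_indices = list(pattern.pair_indices)
        loop_positions = list(pattern.loop_indices)
        star_positions = list(pattern.insertion_slots)
    else:
        text = pattern
        stack, pair_indices, loop_positions, star_positions = [], [], [], []
        for p, ch in enumerate(text):
            if ch == "(":
                stack.append(p)
            elif ch == ")":
                pair_indices.append((stack.pop(), p))
            elif ch == ".":
                loop_positions.append(p)
            elif ch == "*":
                star_positions.append(p)
            else:
                raise ValueError(f"bad pattern char {ch!r}")
        pair_indices.sort()

    m = len(text)
    S = m + 1 + len(loop_positions)
    run_state = {p: m + 1 + k for k, p in enumerate(loop_positions)}

    eps = []
    for s in star_positions:
        eps.append((s, s + 1))
    for p in loop_positions:
        eps.append((run_state[p], p + 1))
    C = _closure(eps, S)

    tr_src, tr_dst, tr_kind, tr_aux, tr_int = [], [], [], [], []
    for si, s in enumerate(star_positions):
        tr_src.append(s); tr_dst.append(s); tr_kind.append(TR_BG)
        tr_aux.append(si); tr_int.append(1 if 0 < s < m - 1 else 0)
    for k, p in enumerate(loop_positions):
        tr_src.append(p); tr_dst.append(run_state[p])
        tr_kind.append(TR_LOOP); tr_aux.append(k); tr_int.append(0)
        tr_src.append(run_state[p]); tr_dst.append(run_state[p])
        tr_kind.append(TR_SELF); tr_aux.append(k); tr_int.append(0)

    em_kind, em_a, em_b = [], [], []
    em_entry, em_exit, em_ie, em_it = [], [], [], []
    em_il, em_ir = [], []
    for us_i, us in enumerate(star_positions):
        for ws_i in range(us_i, len(star_positions)):
            ws = star_positions[ws_i]
            em_kind.append(EM_PB); em_a.append(us_i); em_b.append(ws_i)
            em_entry.append(us); em_exit.append(ws)
            em_ie.append(us); em_it.append(ws)
            em_il.append(1 if 0 < us < m - 1 else 0)
            em_ir.append(1 if 0 < ws < m - 1 else 0)
    for t, (l, r) in enumerate(pair_indices):
        em_kind.append(EM_PM); em_a.append(t); em_b.append(-1)
        em_entry.append(l); em_exit.append(r + 1)
        em_ie.append(l + 1); em_it.append(r)
        em_il.append(0); em_ir.append(0)

    peg_states = sorted(set(em_entry))
    peg_index = {g: k for k, g in enumerate(peg_states)}
    ent_states = sorted(set(em_ie))
    ent_index = {g: k for k, g in enumerate(ent_states)}

    return Machine(
        text=text,
        n_loops=len(loop_positions),
        n_pairs=len(pair_indices),
        S=S,
        end_gap=m,
        C=C,
        tr_src=np.array(tr_src, dtype=np.int64),
        tr_dst=np.array(tr_dst, dtype=np.int64),
        tr_kind=np.array(tr_kind, dtype=np.int64),
        tr_aux=np.array(tr_aux, dtype=np.int64),
        tr_internal=np.array(tr_int, dtype=np.int64),
        em_kind=np.array(em_kind, dtype=np.int64),
        em_a=np.array(em_a, dtype=np.int64),
        em_b=np.array(em_b, dtype=np.int64),
        em_entry_gap=np.array(em_entry, dtype=np.int64),
        em_exit_state=np.array(em_exit, dtype=np.int64),
        em_int_entry=np.array(em_ie, dtype=np.int64),
        em_int_target=np.array(em_it, dtype=np.int64),
        em_internal_l=np.array(em_il, dtype=np.int64),
        em_internal_r=np.array(em_ir, dtype=np.int64),
        em_eg_slot=np.array([peg_index[g] for g in em_entry], dtype=np.int64),
        peg_states=np.array(peg_states, dtype=np.int64),
        ent_states=np.array(ent_states, dtype=np.int64),
        em_ent_slot=np.array([ent_index[g] for g in em_ie], dtype=np.int64),
        loop_pattern_pos=np.array(loop_positions, dtype=np.int64),
        star_positions=np.array(star_positions, dtype=np.int64),
    )


@functools.lru_cache(maxsize=256)
def machine_for(text: str) -> Machine:
    if text == "*":
        return build_machine("*")
    return build_machine(parse_pattern(text))
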