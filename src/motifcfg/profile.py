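"""Profile CFG built from a search pattern.

Each ``.`` symbol carries a base profile over ACGU, each matched bracket
pair a base-pair profile over the six canonical pair types, and all
insertion regions (``*``) share one background base profile.  Every state
may repeat its emission through self-transitions with a constant
log-weight ``omega``; there are no deletion states, so every motif symbol
emits at least once and length variation comes only from self-transitions.
A parse either places the motif exactly once or not at all.

A parse is represented by the intervals of sequence positions consumed by
each pattern symbol, in pattern text order: loop and bracket symbols take
non-empty intervals (the two blocks of a bracket pair are equally long and
pair outermost-to-outermost), insertion symbols may be empty.  The
motif-absent parse emits the whole sequence from the background profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .alphabet import encode, pair_type
from .pattern import SearchPattern, parse_pattern

__all__ = [
    "ProfileModel",
    "ProfileParse",
    "build_profile_model",
    "profile_parse_score",
    "enumerate_profile_parses",
]

_PARSE_ENUM_GUARD = 12


@dataclass
class ProfileModel:
    """Parameters of a profile CFG for one search pattern.

    ``theta_loop[k]`` is the log-score profile of the k-th ``.`` symbol
    (pattern order), ``theta_pair[k]`` of the k-th bracket pair (ordered
    by opening position), ``theta_bg`` the shared background/insertion
    profile, ``omega`` the constant self-transition log-weight and
    ``lam`` the non-negative coupling scale on the energy model.
    """

    pattern: SearchPattern
    theta_loop: np.ndarray
    theta_pair: np.ndarray
    theta_bg: np.ndarray
    omega: float = -1.0
    lam: float = 1.0

    def __post_init__(self):
        if isinstance(self.pattern, str):
            self.pattern = parse_pattern(self.pattern)
        self.theta_loop = np.asarray(self.theta_loop, dtype=float).reshape(
            self.pattern.n_loops, 4
        )
        self.theta_pair = np.asarray(self.theta_pair, dtype=float).reshape(
            self.pattern.n_pairs, 6
        )
        self.theta_bg = np.asarray(self.theta_bg, dtype=float).reshape(4)
        self.validate()

    def validate(self) -> None:
        for name, arr in (
            ("theta_loop", self.theta_loop),
            ("theta_pair", self.theta_pair),
            ("theta_bg", self.theta_bg),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if not np.isfinite(self.omega):
            raise ValueError("omega must be finite")
        if not (self.lam >= 0):
            raise ValueError("lam must be >= 0")

    def copy(self) -> "ProfileModel":
        return ProfileModel(
            pattern=self.pattern,
            theta_loop=self.theta_loop.copy(),
            theta_pair=self.theta_pair.copy(),
            theta_bg=self.theta_bg.copy(),
            omega=self.omega,
            lam=self.lam,
        )


def build_profile_model(
    pattern: SearchPattern | str,
    init: str = "zeros",
    seed: int | None = None,
    omega: float = -1.0,
    lam: float = 1.0,
    jitter: float = 0.01,
) -> ProfileModel:
    """Allocate a profile model for ``pattern``.

    ``init='zeros'`` gives flat profiles; ``init='jitter'`` adds small
    seed-controlled N(0, jitter^2) noise to break ties at the start of
    training.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    nl, np_ = pattern.n_loops, pattern.n_pairs
    if init == "zeros":
        tl = np.zeros((nl, 4))
        tp = np.zeros((np_, 6))
        tb = np.zeros(4)
    elif init == "jitter":
        rng = np.random.default_rng(seed)
        tl = rng.normal(0.0, jitter, (nl, 4))
        tp = rng.normal(0.0, jitter, (np_, 6))
        tb = rng.normal(0.0, jitter, 4)
    else:
        raise ValueError(f"unknown init scheme {init!r}")
    return ProfileModel(pattern, tl, tp, tb, omega=omega, lam=lam)


@dataclass(frozen=True)
class ProfileParse:
    """One parse: per-pattern-symbol intervals, or the motif-absent parse.

    ``intervals[p] = (start, end)`` (half-open) for pattern position p;
    ``None`` intervals only for the motif-absent parse, where the whole
    sequence is background.
    """

    length: int
    intervals: tuple[tuple[int, int], ...] | None  # None => motif absent

    @property
    def present(self) -> bool:
        return self.intervals is not None

    def counts(self, x: str | np.ndarray, pattern: SearchPattern):
        """Emission counts (N_loop[k,a], N_pair[k,b], N_bg[a], N_self)."""
        xx = x if isinstance(x, np.ndarray) else encode(x)
        if len(xx) != self.length:
            raise ValueError("sequence length does not match parse")
        n_loop = np.zeros((pattern.n_loops, 4))
        n_pair = np.zeros((pattern.n_pairs, 6))
        n_bg = np.zeros(4)
        n_self = 0
        if not self.present:
            for b in xx:
                n_bg[b] += 1
            return n_loop, n_pair, n_bg, n_self
        iv = self.intervals
        self._check_consistent(pattern)
        loop_of = {p: k for k, p in enumerate(pattern.loop_indices)}
        star_set = set(pattern.insertion_slots)
        for p, (s, e) in enumerate(iv):
            if p in loop_of:
                for q in range(s, e):
                    n_loop[loop_of[p], xx[q]] += 1
                n_self += (e - s) - 1
            elif p in star_set:
                for q in range(s, e):
                    n_bg[xx[q]] += 1
        for k, (l, r) in enumerate(pattern.pair_indices):
            a, b = iv[l]
            c, d = iv[r]
            depth = b - a
            n_self += depth - 1
            for t in range(depth):
                bt = pair_type(int(xx[a + t]), int(xx[d - 1 - t]))
                if bt < 0:
                    raise ValueError(
                        f"parse pairs non-canonical bases at {(a + t, d - 1 - t)}"
                    )
                n_pair[k, bt] += 1
        return n_loop, n_pair, n_bg, n_self

    def helix_pairs(self, pattern: SearchPattern) -> list[tuple[int, int]]:
        """The base pairs this parse forces, as sequence position pairs."""
        if not self.present:
            return []
        out = []
        for l, r in pattern.pair_indices:
            a, b = self.intervals[l]
            c, d = self.intervals[r]
            for t in range(b - a):
                out.append((a + t, d - 1 - t))
        return out

    def loop_positions(self, pattern: SearchPattern) -> list[int]:
        if not self.present:
            return []
        out = []
        for p in pattern.loop_indices:
            s, e = self.intervals[p]
            out.extend(range(s, e))
        return out

    def motif_span(self, pattern: SearchPattern) -> tuple[int, int] | None:
        """Sequence interval covered by the motif (non-flank symbols)."""
        if not self.present:
            return None
        s = self.intervals[1][0]
        e = self.intervals[len(pattern.text) - 2][1]
        return (s, e)

    def _check_consistent(self, pattern: SearchPattern) -> None:
        iv = self.intervals
        if len(iv) != len(pattern.text):
            raise ValueError("interval count != pattern length")
        pos = 0
        for p, (s, e) in enumerate(iv):
            if s != pos or e < s:
                raise ValueError(f"intervals not contiguous at symbol {p}")
            pos = e
            ch = pattern.text[p]
            if ch in "().":
                if e - s < 1:
                    raise ValueError(f"motif symbol {p} emits nothing")
        if pos != self.length:
            raise ValueError("intervals do not cover the sequence")
        for l, r in pattern.pair_indices:
            if iv[l][1] - iv[l][0] != iv[r][1] - iv[r][0]:
                raise ValueError(f"unequal helix blocks for pair ({l},{r})")


def profile_parse_score(
    phi: ProfileParse, x: str | np.ndarray, m: ProfileModel
) -> float:
    """Log-weight of a parse: sum of theta-weighted emission counts plus
    ``omega`` per self-transition."""
    n_loop, n_pair, n_bg, n_self = phi.counts(x, m.pattern)
    return float(
        np.sum(m.theta_loop * n_loop)
        + np.sum(m.theta_pair * n_pair)
        + np.sum(m.theta_bg * n_bg)
        + m.omega * n_self
    )


def enumerate_profile_parses(
    x: str | np.ndarray | int,
    pattern: SearchPattern | str,
    max_len: int = _PARSE_ENUM_GUARD,
    include_absent: bool = True,
) -> list[ProfileParse]:
    """Exhaustively enumerate parses (test oracle; guarded length).

    ``x`` may be a sequence or just its length.  Returns motif-present
    parses (all interval splits) plus, optionally, the single
    motif-absent parse.  Parses forcing non-canonical pairs are *not*
    filtered here; compatibility with a structure handles that.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    L = x if isinstance(x, int) else len(x)
    if L > max_len:
        raise ValueError(f"sequence length {L} exceeds enumeration guard {max_len}")

    text = pattern.text
    m = len(text)
    pair_partner = {l: r for l, r in pattern.pair_indices}
    pair_partner.update({r: l for l, r in pattern.pair_indices})

    parses: list[ProfileParse] = []
    if include_absent:
        parses.append(ProfileParse(L, None))

    lengths = [0] * m

    def rec(p: int, pos: int) -> None:
        if p == m:
            if pos == L:
                iv = []
                q = 0
                for ln in lengths:
                    iv.append((q, q + ln))
                    q += ln
                parses.append(ProfileParse(L, tuple(iv)))
            return
        ch = text[p]
        if ch == "*":
            for ln in range(0, L - pos + 1):
                lengths[p] = ln
                rec(p + 1, pos + ln)
        elif ch == ".":
            for ln in range(1, L - pos + 1):
                lengths[p] = ln
                rec(p + 1, pos + ln)
        elif ch == "(":
            for ln in range(1, (L - pos) // 2 + 1):
                lengths[p] = ln
                lengths[pair_partner[p]] = ln
                rec(p + 1, pos + ln)
        else:  # ')': length fixed by partner
            ln = lengths[pair_partner[p]]
            rec(p + 1, pos + ln)

    rec(0, 0)
    return parses
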