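"""Search patterns: the modified dot-bracket strings that define motif topology.

A search pattern is a string over ``. ( ) *``.  Dots are single-stranded
(loop) motif positions with their own base profile, matched brackets are
base-paired motif positions with a base-pair profile, and ``*`` marks a
structure-unspecified insertion region emitted by a shared background
profile.  Patterns must be balanced, pseudoknot-free and begin and end
with ``*`` so the motif can match at any position of a sequence.

Positions are 0-based throughout; intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

PATTERN_ALPHABET = frozenset(".()*")


class PatternError(ValueError):
    """Base class for search-pattern validation errors."""


class IllegalCharacterError(PatternError):
    def __init__(self, text: str, pos: int):
        self.pos = pos
        super().__init__(
            f"illegal character {text[pos]!r} at position {pos} "
            f"(allowed: '.', '(', ')', '*')"
        )


class UnbalancedBracketError(PatternError):
    def __init__(self, pos: int, kind: str):
        self.pos = pos
        super().__init__(f"{kind} bracket at position {pos} has no partner")


class MissingFlankError(PatternError):
    def __init__(self, which: str, pos: int):
        self.pos = pos
        super().__init__(
            f"pattern must {which} with '*' (offending position {pos})"
        )


class EmptyMotifError(PatternError):
    def __init__(self):
        super().__init__("pattern contains no motif symbols ('.', '(' or ')')")


@dataclass(frozen=True)
class SearchPattern:
    """A validated search pattern.

    Attributes
    ----------
    text:
        The pattern string.
    loop_indices:
        Positions of ``.`` symbols, in order.
    pair_indices:
        Matched ``(``/``)`` position pairs ``(l, r)`` with ``l < r``,
        ordered by opening position.
    insertion_slots:
        Positions of ``*`` symbols, in order.  The first and last pattern
        positions are always insertion slots.
    """

    text: str
    loop_indices: tuple[int, ...] = field(repr=False)
    pair_indices: tuple[tuple[int, int], ...] = field(repr=False)
    insertion_slots: tuple[int, ...] = field(repr=False)

    @property
    def motif_length(self) -> int:
        """Number of motif (non-``*``) symbols."""
        return len(self.loop_indices) + 2 * len(self.pair_indices)

    @property
    def n_loops(self) -> int:
        return len(self.loop_indices)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_indices)

    def __len__(self) -> int:
        return len(self.text)

    def __str__(self) -> str:
        return self.text

    def min_span(self) -> int:
        """Minimum number of sequence positions a motif match occupies."""
        return self.motif_length

    def serialize(self) -> str:
        return self.text


def parse_pattern(text: str) -> SearchPattern:
    """Parse and validate a search pattern string.

    Raises a :class:`PatternError` subclass naming the offending position
    for: illegal characters, unbalanced brackets, a missing leading or
    trailing ``*``, or a pattern with no motif symbols.
    """
    if not text:
        raise PatternError("empty pattern")
    for pos, ch in enumerate(text):
        if ch not in PATTERN_ALPHABET:
            raise IllegalCharacterError(text, pos)
    if text[0] != "*":
        raise MissingFlankError("begin", 0)
    if text[-1] != "*":
        raise MissingFlankError("end", len(text) - 1)

    loops: list[int] = []
    pairs: list[tuple[int, int]] = []
    stars: list[int] = []
    stack: list[int] = []
    for pos, ch in enumerate(text):
        if ch == ".":
            loops.append(pos)
        elif ch == "*":
            stars.append(pos)
        elif ch == "(":
            stack.append(pos)
        else:  # ')'
            if not stack:
                raise UnbalancedBracketError(pos, "closing")
            pairs.append((stack.pop(), pos))
    if stack:
        raise UnbalancedBracketError(stack[-1], "opening")
    if not loops and not pairs:
        raise EmptyMotifError()
    pairs.sort()
    return SearchPattern(
        text=text,
        loop_indices=tuple(loops),
        pair_indices=tuple(pairs),
        insertion_slots=tuple(stars),
    )


@dataclass(frozen=True)
class PatternEnumerationConfig:
    """Bounds for the systematic default pattern enumeration.

    The enumeration walks all well-formed pattern bodies character by
    character, organized by topology: dots come in bounded segments
    (state self-transitions already model arbitrary loop lengths, so the
    per-segment dot count is bounded, not the matched loop length),
    bracket pairs form stems with bounded count and nesting depth, and
    the number of insertion stars besides the two mandatory flanks is
    bounded.  Internal stars are only admitted in patterns containing at
    least one stem: an insertion region models a structure-unspecified
    spacer held in proximity by base pairing, and without any pair it
    would merely split the motif into unrelated pieces.  The shipped
    defaults cover loop, hairpin, bulge, internal-loop and multi-stem
    topologies and emit exactly 135 patterns; they were calibrated once
    and are frozen.
    """

    max_dot_segment: int = 1     # longest consecutive '.' run
    max_dot_segments: int = 2    # number of '.' runs
    max_depth: int = 2           # bracket nesting depth
    max_stems: int = 3           # number of bracket pairs
    max_internal_stars: int = 1  # '*' symbols besides the two flanks


def _bodies(cfg: PatternEnumerationConfig) -> Iterator[str]:
    """Yield all pattern bodies (the text between the flanking stars).

    Bodies are nonempty, balanced, respect the config bounds, contain no
    empty bracket ``()`` (its innermost helix could never satisfy the
    minimum hairpin size) and neither start nor end with ``*`` (that
    would duplicate a flanking star).
    """
    R, G = cfg.max_dot_segment, cfg.max_dot_segments
    D, P, M = cfg.max_depth, cfg.max_stems, cfg.max_internal_stars

    def gen(s: str, depth: int, pairs: int, dotrun: int, nseg: int,
            prev: str, nstar: int) -> Iterator[str]:
        if depth == 0 and s and s[0] != "*" and s[-1] != "*" \
                and (pairs > 0 or nseg > 0) and not (nstar > 0 and pairs == 0):
            yield s
        if dotrun < R and (dotrun > 0 or nseg < G):
            yield from gen(s + ".", depth, pairs, dotrun + 1,
                           nseg if dotrun > 0 else nseg + 1, ".", nstar)
        if depth < D and pairs < P:
            yield from gen(s + "(", depth + 1, pairs + 1, 0, nseg, "(", nstar)
        if depth > 0 and prev != "(":
            yield from gen(s + ")", depth - 1, pairs, 0, nseg, ")", nstar)
        if prev not in ("*", "") and nstar < M:
            yield from gen(s + "*", depth, pairs, 0, nseg, "*", nstar + 1)

    yield from gen("", 0, 0, 0, 0, "", 0)


def default_pattern_set(
    config: PatternEnumerationConfig | None = None,
) -> list[SearchPattern]:
    """Enumerate the default search-pattern set.

    Deterministic, duplicate-free and lexicographically sorted.  With the
    shipped default bounds the list has exactly 135 elements, every one of
    which re-parses under :func:`parse_pattern`.
    """
    cfg = config or PatternEnumerationConfig()
    texts = sorted({"*" + body + "*" for body in _bodies(cfg)})
    out = []
    for t in texts:
        try:
            out.append(parse_pattern(t))
        except PatternError:
            continue
    if not out:
        raise PatternError("enumeration bounds admit no valid pattern")
    return out


def read_pattern_file(path) -> list[SearchPattern]:
    """Read a plain-text pattern file: one pattern per line, ``#`` comments
    and blank lines ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                out.append(parse_pattern(text))
            except PatternError as e:
                raise PatternError(f"{path}:{lineno}: {e}") from e
    return out


def write_pattern_file(path, patterns: Iterable[SearchPattern]) -> None:
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(p.text + "\n")
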