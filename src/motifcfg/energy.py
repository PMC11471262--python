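"""Nearest-neighbor secondary-structure ensemble with a maximal pair span.

The structure model is the usual loop decomposition: stacking terms for
adjacent pairs, length-dependent hairpin/bulge/internal-loop penalties and
an affine multiloop cost.  Only the six canonical pair types are allowed,
pairs may not cross (no pseudoknots), a hairpin loop must contain at least
``min_hairpin`` unpaired bases, and the span ``j - i`` between the two
bases of a pair is limited to ``W``.  A structure's Boltzmann weight is
``exp(-dG / kT)``.

The shipped parameter file is a simplified set (16 Watson-Crick stack
terms plus one GU default, logarithmic hairpins, affine bulge/internal and
multiloop costs).  Parameters are swappable via a plain-text table.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .alphabet import PAIR_TYPES, encode, pair_type

__all__ = [
    "EnergyParams",
    "SecondaryStructure",
    "StructureError",
    "load_energy_params",
    "default_energy_params",
    "energy_of_structure",
    "enumerate_structures",
    "structure_partition",
    "count_structures",
]


class StructureError(ValueError):
    """Invalid secondary structure for a sequence/parameter combination."""


@dataclass(frozen=True)
class EnergyParams:
    """Free-energy terms (kcal/mol) and ensemble constraints.

    ``stack`` is a 6x6 array indexed by (outer pair type, inner pair
    type) in the order AU, CG, GC, GU, UA, UG.  ``W`` is the maximal
    span ``j - i`` between pair-forming bases; ``min_hairpin`` the
    minimum number of unpaired bases closed by a hairpin.  Bulge and
    internal loops are limited only by the span constraint.
    """

    stack: np.ndarray
    hairpin_base: float
    hairpin_log: float
    bulge_base: float
    internal_base: float
    interior_slope: float
    ml_close: float
    ml_branch: float
    ml_unpaired: float
    kT: float = 0.6163
    W: int = 50
    min_hairpin: int = 3

    def __post_init__(self):
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.W < self.min_hairpin + 2:
            raise ValueError("W must be >= min_hairpin + 2")
        if np.asarray(self.stack).shape != (6, 6):
            raise ValueError("stack table must be 6x6")

    def hairpin(self, n: int) -> float:
        """Penalty of a hairpin loop with ``n`` unpaired bases."""
        if n < self.min_hairpin:
            raise StructureError(f"hairpin loop of size {n} < {self.min_hairpin}")
        return self.hairpin_base + self.hairpin_log * np.log(n / self.min_hairpin)

    def bulge(self, n: int) -> float:
        return self.bulge_base + self.interior_slope * n

    def internal(self, n: int) -> float:
        return self.internal_base + self.interior_slope * n

    def with_span(self, W: int | None = None, **kw) -> "EnergyParams":
        """Copy with a different span limit or other overrides."""
        if W is not None:
            kw["W"] = W
        return replace(self, **kw)

    def zeroed(self) -> "EnergyParams":
        """Copy with every energy term set to 0 (uniform ensemble)."""
        return replace(
            self,
            stack=np.zeros((6, 6)),
            hairpin_base=0.0, hairpin_log=0.0,
            bulge_base=0.0, internal_base=0.0, interior_slope=0.0,
            ml_close=0.0, ml_branch=0.0, ml_unpaired=0.0,
        )


def load_energy_params(path, **overrides) -> EnergyParams:
    """Read an energy-parameter table (term <TAB> context <TAB> value)."""
    scalars: dict[str, float] = {}
    stack = np.zeros((6, 6))
    stack_seen = np.zeros((6, 6), dtype=bool)
    gu_default = None
    pt_index = {p: i for i, p in enumerate(PAIR_TYPES)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'term context value'")
            term, ctx, val = parts[0], parts[1], float(parts[2])
            if term == "stack":
                outer, inner = ctx.split(":")
                stack[pt_index[outer], pt_index[inner]] = val
                stack_seen[pt_index[outer], pt_index[inner]] = True
            elif term == "stack_gu_default":
                gu_default = val
            else:
                scalars[term] = val
    if gu_default is not None:
        for a, pa in enumerate(PAIR_TYPES):
            for b, pb in enumerate(PAIR_TYPES):
                if not stack_seen[a, b] and ("G" in pa and "U" in pa or "G" in pb and "U" in pb):
                    stack[a, b] = gu_default
    return EnergyParams(
        stack=stack,
        hairpin_base=scalars["hairpin_base"],
        hairpin_log=scalars["hairpin_log"],
        bulge_base=scalars["bulge_base"],
        internal_base=scalars["internal_base"],
        interior_slope=scalars["interior_slope"],
        ml_close=scalars["ml_close"],
        ml_branch=scalars["ml_branch"],
        ml_unpaired=scalars["ml_unpaired"],
        kT=scalars.get("kT", 0.6163),
        **overrides,
    )


@functools.lru_cache(maxsize=None)
def _default_params_cached() -> EnergyParams:
    with resources.as_file(
        resources.files("motifcfg").joinpath("data/energy_params.tsv")
    ) as p:
        return load_energy_params(p)


def default_energy_params(**overrides) -> EnergyParams:
    """The shipped simplified nearest-neighbor parameter set."""
    base = _default_params_cached()
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs ``(i, j)`` with ``i < j``."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(sorted(tuple(p) for p in self.pairs)))

    def __len__(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def validate(self, seq: str | np.ndarray, params: EnergyParams) -> None:
        """Raise :class:`StructureError` on any invalid pair."""
        x = seq if isinstance(seq, np.ndarray) else encode(seq)
        n = len(x)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair {(i, j)} out of range for length {n}")
            if i in seen or j in seen:
                raise StructureError(f"position reused by pair {(i, j)}")
            seen.update((i, j))
            if j - i > params.W:
                raise StructureError(f"pair {(i, j)} exceeds span W={params.W}")
            if pair_type(int(x[i]), int(x[j])) < 0:
                raise StructureError(f"non-canonical pair {(i, j)}")
        for i, j in self.pairs:
            for k, l in self.pairs:
                if i < k < j < l:
                    raise StructureError(f"crossing pairs {(i, j)} and {(k, l)}")
        # hairpin check: a pair with no nested pair must close >= min_hairpin
        for i, j in self.pairs:
            if not any(i < k and l < j for k, l in self.pairs if (k, l) != (i, j)):
                if j - i - 1 < params.min_hairpin:
                    raise StructureError(
                        f"hairpin closed by {(i, j)} has {j - i - 1} < "
                        f"{params.min_hairpin} unpaired bases"
                    )

    def to_dotbracket(self, length: int) -> str:
        s = ["."] * length
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _loops(pairs: Sequence[tuple[int, int]], n: int):
    """Decompose a structure into loops.

    Yields ``(closing_pair_or_None, children, n_unpaired)`` where
    ``children`` are the pairs directly accessible from the loop.
    """
    pairs = sorted(pairs)

    def children_of(lo: int, hi: int, cand):
        out = []
        k = 0
        cand = [p for p in cand if lo < p[0] and p[1] < hi]
        cand.sort()
        last_end = lo
        for p in cand:
            if p[0] > last_end:
                out.append(p)
                last_end = p[1]
        return out

    # exterior loop
    top = children_of(-1, n, pairs)
    unpaired_top = n - sum(j - i + 1 for i, j in top)
    yield None, top, unpaired_top
    stack = list(top)
    while stack:
        (i, j) = stack.pop()
        inner = children_of(i, j, [p for p in pairs if i < p[0] and p[1] < j])
        unp = (j - i - 1) - sum(b - a + 1 for a, b in inner)
        yield (i, j), inner, unp
        stack.extend(inner)


def energy_of_structure(
    seq: str | np.ndarray,
    structure: SecondaryStructure | Iterable[tuple[int, int]],
    params: EnergyParams | None = None,
) -> float:
    """Free energy (kcal/mol) of ``structure`` on ``seq`` by loop decomposition.

    The empty structure has energy 0; energies are additive over
    independent substructures.  Raises :class:`StructureError` for
    invalid structures.
    """
    params = params or default_energy_params()
    if not isinstance(structure, SecondaryStructure):
        structure = SecondaryStructure(tuple(structure))
    x = seq if isinstance(seq, np.ndarray) else encode(seq)
    structure.validate(x, params)
    n = len(x)
    total = 0.0
    for closing, children, unp in _loops(structure.pairs, n):
        if closing is None:
            continue  # exterior loop costs nothing
        i, j = closing
        if len(children) == 0:
            total += params.hairpin(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                pt_o = pair_type(int(x[i]), int(x[j]))
                pt_i = pair_type(int(x[k]), int(x[l]))
                total += float(params.stack[pt_o, pt_i])
            elif n1 == 0 or n2 == 0:
                total += params.bulge(n1 + n2)
            else:
                total += params.internal(n1 + n2)
        else:
            total += (
                params.ml_close
                + params.ml_branch * len(children)
                + params.ml_unpaired * unp
            )
    return float(total)


_ENUM_GUARD = 14


def enumerate_structures(
    n: int,
    min_hairpin: int = 3,
    W: int | None = None,
    seq: str | np.ndarray | None = None,
) -> list[SecondaryStructure]:
    """Exhaustively enumerate all valid pair sets for a length-``n`` sequence.

    A brute-force oracle for the dynamic programming routines; guarded to
    ``n <= 14``.  If ``seq`` is given, only canonical pairs are used;
    otherwise every position pair is considered pairable.
    """
    if n > _ENUM_GUARD:
        raise ValueError(f"n={n} too large for exhaustive enumeration (max {_ENUM_GUARD})")
    W = W if W is not None else n
    x = None if seq is None else (seq if isinstance(seq, np.ndarray) else encode(seq))

    def can_pair(i: int, j: int) -> bool:
        if j - i - 1 < min_hairpin or j - i > W:
            return False
        if x is None:
            return True
        return pair_type(int(x[i]), int(x[j])) >= 0

    @functools.lru_cache(maxsize=None)
    def structs(lo: int, hi: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pair sets on positions [lo, hi)
        if hi - lo < 2:
            return ((),)
        out = list(structs(lo, hi - 1))  # hi-1 unpaired
        for i in range(lo, hi - 1):      # hi-1 paired with i
            if can_pair(i, hi - 1):
                for inner in structs(i + 1, hi - 1):
                    for left in structs(lo, i):
                        out.append(left + ((i, hi - 1),) + inner)
        return tuple(out)

    result = [SecondaryStructure(p) for p in structs(0, n)]
    structs.cache_clear()
    return result


def count_structures(n: int, min_hairpin: int = 3, W: int | None = None) -> int:
    """Count valid pair sets by an independent recurrence (no enumeration).

    ``f(lo, hi) = f(lo, hi-1) + sum_i f(i+1, hi-1) * f(lo, i)`` over
    admissible pairs ``(i, hi-1)``.
    """
    W = W if W is not None else n

    @functools.lru_cache(maxsize=None)
    def f(lo: int, hi: int) -> int:
        if hi - lo < 2:
            return 1
        total = f(lo, hi - 1)
        for i in range(lo, hi - 1):
            if min_hairpin <= hi - 1 - i - 1 and hi - 1 - i <= W:
                total += f(i + 1, hi - 1) * f(lo, i)
        return total

    out = f(0, n)
    f.cache_clear()
    return out


def structure_partition(
    seq: str,
    params: EnergyParams | None = None,
    canonical_only: bool = True,
):
    """Partition value and base-pair posterior matrix of the ensemble.

    Returns ``(logQ, posterior)`` where ``posterior[i, j]`` is the
    probability that ``i`` pairs with ``j`` (symmetric; row sums are at
    most 1).  With ``canonical_only=False`` every position pair is
    treated as pairable (useful only as a counting/diagnostic mode, e.g.
    with zeroed energies the partition value equals the number of valid
    structures).
    """
    from .coupled import _structure_partition_impl

    params = params or default_energy_params()
    return _structure_partition_impl(seq, params, canonical_only)
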