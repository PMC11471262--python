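"""Synthetic benchmarks with planted sequence-structure motifs.

A planted motif is a local secondary structure of ~10 positions with an
internal structure-unspecified gap of 1-10 nt, a per-position sequence
profile (conservation level ``c``: the dominant base or pair type has
probability ``c``) and a deterministic identity given its index.
Positives embed one motif instance at a random position in uniform
background; a candidate is accepted only when the energy model assigns
every planted pair a posterior of at least ``accept_posterior`` and
every planted loop position stays predominantly unpaired (rejection
sampling), so positives really fold into the planted structure.  Negatives are uniform i.i.d. sequences.  Decoys relocate
each positive's motif bases to random positions, destroying both the
structure and the motif's contiguity while preserving base composition
exactly — a model that merely reads composition cannot separate
positives from decoys.

Everything is a pure function of (motif, sizes, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import BASES, PAIR_TYPES
from .energy import (
    EnergyParams,
    SecondaryStructure,
    default_energy_params,
    enumerate_structures,
    structure_partition,
)
from .pattern import SearchPattern, parse_pattern

__all__ = [
    "PlantedMotif",
    "BenchmarkSet",
    "SequenceTruth",
    "enumerate_motif_structures",
    "planted_motif",
    "design_positive",
    "make_benchmark",
]

# default benchmark study conditions
DEFAULT_MOTIF_LEN = 10
DEFAULT_GAP_RANGE = (1, 10)
DEFAULT_N_POS = 200
DEFAULT_N_NEG = 200
DEFAULT_L = 100
DEFAULT_CONSERVATION = 0.9
DEFAULT_W = 20          # covers the largest planted pair span (<= 19)
ACCEPT_POSTERIOR = 0.5


@dataclass(frozen=True)
class PlantedMotif:
    """A gapped local structure with per-position emission profiles.

    ``structure`` lives on motif coordinates ``0..length-1`` (gap
    excluded); the gap of ``gap_len`` unconstrained nucleotides is
    inserted before motif coordinate ``gap_pos``.
    """

    index: int
    length: int
    structure: SecondaryStructure
    gap_pos: int
    gap_len: int
    loop_profile: np.ndarray   # (length, 4); rows for paired positions unused
    pair_profile: np.ndarray   # (n_pairs, 6)
    conservation: float

    @property
    def span(self) -> int:
        """Sequence positions occupied by one motif instance."""
        return self.length + self.gap_len

    def paired_positions(self) -> set[int]:
        out = set()
        for i, j in self.structure.pairs:
            out.update((i, j))
        return out

    def seq_offset(self, motif_coord: int) -> int:
        """Motif coordinate -> offset within the embedded instance."""
        return motif_coord + (self.gap_len if motif_coord >= self.gap_pos else 0)

    def planted_pairs(self, start: int) -> list[tuple[int, int]]:
        """Planted pairs in sequence coordinates for an instance at ``start``."""
        return [
            (start + self.seq_offset(i), start + self.seq_offset(j))
            for i, j in self.structure.pairs
        ]

    def to_pattern(self) -> SearchPattern:
        """The search pattern matched to this motif's topology."""
        db = list(self.structure.to_dotbracket(self.length))
        db.insert(self.gap_pos, "*")
        return parse_pattern("*" + "".join(db) + "*")

    def labels(self) -> str:
        """Per-position labels of one instance: S(tem), L(oop), G(ap)."""
        paired = self.paired_positions()
        lab = []
        for i in range(self.length):
            if i == self.gap_pos:
                lab.extend("G" * self.gap_len)
            lab.append("S" if i in paired else "L")
        if self.gap_pos == self.length:
            lab.extend("G" * self.gap_len)
        return "".join(lab)


def _default_gap_position(s: SecondaryStructure, length: int) -> int:
    """Put the gap inside the first hairpin loop (so it is enclosed by
    pairing, the configuration insertion regions are meant to model)."""
    hairpins = []
    for i, j in s.pairs:
        if not any(i < k and l < j for k, l in s.pairs if (k, l) != (i, j)):
            hairpins.append((i, j))
    if hairpins:
        i, j = min(hairpins)
        return (i + 1 + j) // 2
    return length // 2


def enumerate_motif_structures(
    motif_len: int = DEFAULT_MOTIF_LEN,
    gap_range: tuple[int, int] = DEFAULT_GAP_RANGE,
    min_hairpin: int = 3,
    conservation: float = DEFAULT_CONSERVATION,
) -> list[PlantedMotif]:
    """Deterministically enumerate planted-motif skeletons.

    All secondary structures of ``motif_len`` positions with at least
    one base pair, each given a gap whose length cycles through
    ``gap_range`` and whose position sits in the first hairpin loop.
    Profiles are drawn once per motif from a seed equal to its index.
    """
    if motif_len > 14:
        raise ValueError("motif_len > 14 would enumerate too many structures")
    if not (1 <= gap_range[0] <= gap_range[1]):
        raise ValueError("invalid gap_range")
    structs = [
        s for s in enumerate_structures(motif_len, min_hairpin)
        if len(s.pairs) >= 1
    ]
    glo, ghi = gap_range
    nspan = ghi - glo + 1
    out = []
    for k, s in enumerate(structs):
        gap_len = glo + (k % nspan)
        gap_pos = _default_gap_position(s, motif_len)
        out.append(
            _with_profiles(k, motif_len, s, gap_pos, gap_len, conservation)
        )
    return out


def _with_profiles(
    index: int,
    length: int,
    s: SecondaryStructure,
    gap_pos: int,
    gap_len: int,
    conservation: float,
) -> PlantedMotif:
    rng = np.random.default_rng(982_451_653 + index)
    c = conservation
    loop_profile = np.full((length, 4), (1 - c) / 3)
    for i in range(length):
        loop_profile[i, rng.integers(4)] = c
    # dominant pair types favor stable Watson-Crick stems (CG/GC)
    stable = [PAIR_TYPES.index("CG"), PAIR_TYPES.index("GC")]
    pair_profile = np.full((len(s.pairs), 6), (1 - c) / 5)
    for k in range(len(s.pairs)):
        pair_profile[k, stable[int(rng.integers(2))]] = c
    return PlantedMotif(
        index=index, length=length, structure=s,
        gap_pos=gap_pos, gap_len=gap_len,
        loop_profile=loop_profile, pair_profile=pair_profile,
        conservation=c,
    )


def planted_motif(
    structure_index: int,
    gap_len: int | None = None,
    motif_len: int = DEFAULT_MOTIF_LEN,
    min_hairpin: int = 3,
    conservation: float = DEFAULT_CONSERVATION,
) -> PlantedMotif:
    """A planted motif from skeleton ``structure_index`` with a chosen
    insertion-gap length (profiles are re-drawn deterministically per
    (skeleton, gap) combination, so variants are distinct motifs)."""
    structs = [
        s for s in enumerate_structures(motif_len, min_hairpin)
        if len(s.pairs) >= 1
    ]
    s = structs[structure_index]
    base = enumerate_motif_structures(motif_len, min_hairpin=min_hairpin,
                                      conservation=conservation)[structure_index]
    if gap_len is None:
        return base
    return _with_profiles(
        structure_index * 1000 + gap_len, motif_len, s,
        base.gap_pos, gap_len, conservation,
    )


@dataclass(frozen=True)
class SequenceTruth:
    """Ground-truth annotation of one positive sequence."""

    seq_id: str
    start: int                      # motif instance start (incl. gap region)
    end: int                        # half-open end
    labels: str                     # per-position S/L/G/B over the sequence
    pairs: tuple[tuple[int, int], ...]  # planted pairs, sequence coordinates


@dataclass
class BenchmarkSet:
    motif: PlantedMotif
    positives: list[tuple[str, str]]    # (id, sequence)
    negatives: list[tuple[str, str]]
    decoys: list[tuple[str, str]]
    truth: list[SequenceTruth]
    seed: int


class DesignError(RuntimeError):
    pass


def design_positive(
    motif: PlantedMotif,
    L: int,
    rng: np.random.Generator,
    params: EnergyParams | None = None,
    max_tries: int = 200,
    accept_posterior: float = ACCEPT_POSTERIOR,
):
    """Design one motif-bearing sequence with ground truth.

    Returns ``(sequence, start)``; raises :class:`DesignError` when the
    rejection-sampling cap is exhausted (suggesting weaker constraints).
    """
    params = params or default_energy_params(W=DEFAULT_W)
    span = motif.span
    if L < span + 10:
        raise ValueError(f"L={L} too short for motif span {span} + 10")
    pt_left = [p[0] for p in PAIR_TYPES]
    pt_right = [p[1] for p in PAIR_TYPES]
    paired = {}
    for k, (i, j) in enumerate(motif.structure.pairs):
        paired[i] = (k, 0)
        paired[j] = (k, 1)
    for _ in range(max_tries):
        inst = [""] * motif.length
        for k, (i, j) in enumerate(motif.structure.pairs):
            b = int(rng.choice(6, p=motif.pair_profile[k]))
            inst[i] = pt_left[b]
            inst[j] = pt_right[b]
        for i in range(motif.length):
            if i not in paired:
                inst[i] = BASES[int(rng.choice(4, p=motif.loop_profile[i]))]
        gap = "".join(rng.choice(list(BASES), motif.gap_len))
        core = "".join(inst[: motif.gap_pos]) + gap + "".join(inst[motif.gap_pos:])
        start = int(rng.integers(0, L - span + 1))
        left = "".join(rng.choice(list(BASES), start))
        right = "".join(rng.choice(list(BASES), L - span - start))
        seq = left + core + right
        pairs = motif.planted_pairs(start)
        _, post = structure_partition(seq, params)
        if all(post[i, j] >= accept_posterior for i, j in pairs):
            # the instance must fold into the *expected* structure:
            # planted loop positions must also be predominantly unpaired
            loops_ok = True
            paired = motif.paired_positions()
            for c in range(motif.length):
                if c not in paired:
                    p = start + motif.seq_offset(c)
                    if post[p, :].sum() > 1.0 - accept_posterior:
                        loops_ok = False
                        break
            if loops_ok:
                return seq, start
    raise DesignError(
        f"could not design a sequence folding into motif {motif.index} "
        f"within {max_tries} tries; consider weaker constraints"
    )


def make_benchmark(
    motif: PlantedMotif,
    n_pos: int = DEFAULT_N_POS,
    n_neg: int = DEFAULT_N_NEG,
    L: int = DEFAULT_L,
    seed: int = 0,
    params: EnergyParams | None = None,
) -> BenchmarkSet:
    """Generate positives, negatives, decoys and the truth table."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("set sizes must be >= 1")
    params = params or default_energy_params(W=DEFAULT_W)
    rng = np.random.default_rng(seed)
    positives = []
    truth = []
    inst_labels = motif.labels()
    for k in range(n_pos):
        seq, start = design_positive(motif, L, rng, params)
        sid = f"pos_{k}"
        positives.append((sid, seq))
        labels = "B" * start + inst_labels + "B" * (L - start - motif.span)
        truth.append(
            SequenceTruth(
                seq_id=sid,
                start=start,
                end=start + motif.span,
                labels=labels,
                pairs=tuple(motif.planted_pairs(start)),
            )
        )
    negatives = [
        (f"neg_{k}", "".join(rng.choice(list(BASES), L))) for k in range(n_neg)
    ]
    decoys = []
    for k, (sid, seq) in enumerate(positives):
        t = truth[k]
        motif_positions = [
            p for p in range(t.start, t.end)
            if t.labels[p] in "SL"
        ]
        decoys.append((f"decoy_{k}", _relocate(seq, motif_positions, rng)))
    return BenchmarkSet(
        motif=motif,
        positives=positives,
        negatives=negatives,
        decoys=decoys,
        truth=truth,
        seed=seed,
    )


def _relocate(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    """Remove the bases at ``positions`` and re-insert each at a random
    position: composition is preserved exactly, contiguity and structure
    are destroyed."""
    removed = [seq[p] for p in positions]
    keep = [c for p, c in enumerate(seq) if p not in set(positions)]
    for c in removed:
        keep.insert(int(rng.integers(0, len(keep) + 1)), c)
    return "".join(keep)
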