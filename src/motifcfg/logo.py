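"""Sequence-structure logos and graph diagrams for trained motif models.

The extended logo shows one column per pattern symbol, in pattern order:
loop columns are base stacks peaking at log2(4) bits, bracket columns are
base-pair stacks peaking at log2(6) bits (each pair profile is drawn at
both bracket positions; at the partner position the letters carry a
``partner`` flag and are rendered gray), and insertion columns show the
shared background profile with the expected gap length annotated.  The
search pattern string is printed beneath the columns.  Probabilities come
from exponentiating and column-normalizing the log-scaled profile
parameters.  Columns whose information content exceeds 1.5 bits are
labeled with the smallest covering IUPAC code.

Rendering is deterministic: the same model always yields byte-identical
SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import BASES, PAIR_TYPES
from .profile import ProfileModel

__all__ = [
    "LogoColumn",
    "information_content",
    "iupac_label",
    "model_to_logo",
    "render",
    "graph_diagram",
]

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("GU"): "K",
    frozenset("AC"): "M", frozenset("CG"): "S", frozenset("AU"): "W",
    frozenset("CGU"): "B", frozenset("AGU"): "D", frozenset("ACU"): "H",
    frozenset("ACG"): "V", frozenset("ACGU"): "N",
}


@dataclass(frozen=True)
class LogoColumn:
    kind: str                      # 'loop' | 'pair' | 'insertion'
    symbol: str                    # the pattern character
    probabilities: np.ndarray      # over 4 bases or 6 pair types
    information: float             # bits
    partner: bool = False          # True at the ')' position of a pair
    pair_index: int = -1
    mean_gap_length: float | None = None
    iupac: str | None = None


def information_content(probs, alphabet_size: int | None = None) -> float:
    """Shannon information in bits: log2(n) - H(p).

    ``probs`` must be normalized (sum 1 within 1e-6); the alphabet size
    must be 4 (bases) or 6 (pair types).
    """
    p = np.asarray(probs, dtype=float)
    n = alphabet_size if alphabet_size is not None else p.size
    if n not in (4, 6) or p.size != n:
        raise ValueError("alphabet size must be 4 or 6 and match probs")
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("probabilities must be normalized and non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return float(np.log2(n) + plogp.sum())


def iupac_label(probs, ic_threshold: float = 1.5) -> str | None:
    """IUPAC code of a conserved base column, or None below threshold.

    Above the information threshold, the smallest IUPAC set covering all
    bases with probability at least a quarter of the maximum.
    """
    p = np.asarray(probs, dtype=float)
    if information_content(p, 4) <= ic_threshold:
        return None
    keep = frozenset(BASES[k] for k in range(4) if p[k] >= 0.25 * p.max())
    return IUPAC[keep]


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def model_to_logo(
    model: ProfileModel,
    mean_gap_lengths: dict[int, float] | None = None,
) -> list[LogoColumn]:
    """One logo column per pattern symbol, in pattern order.

    ``mean_gap_lengths`` maps insertion-slot pattern positions to
    expected emission counts (e.g. from expected counts on a data set);
    flanking slots are conventionally not annotated.
    """
    pat = model.pattern
    loop_of = {p: k for k, p in enumerate(pat.loop_indices)}
    pair_of: dict[int, tuple[int, bool]] = {}
    for k, (l, r) in enumerate(pat.pair_indices):
        pair_of[l] = (k, False)
        pair_of[r] = (k, True)
    bg = _softmax(model.theta_bg)
    cols: list[LogoColumn] = []
    m = len(pat.text)
    for p, ch in enumerate(pat.text):
        if ch == ".":
            probs = _softmax(model.theta_loop[loop_of[p]])
            cols.append(LogoColumn(
                kind="loop", symbol=ch, probabilities=probs,
                information=information_content(probs, 4),
                iupac=iupac_label(probs),
            ))
        elif ch in "()":
            k, is_partner = pair_of[p]
            probs = _softmax(model.theta_pair[k])
            cols.append(LogoColumn(
                kind="pair", symbol=ch, probabilities=probs,
                information=information_content(probs, 6),
                partner=is_partner, pair_index=k,
            ))
        else:
            gap = None
            if mean_gap_lengths is not None and 0 < p < m - 1:
                gap = float(mean_gap_lengths.get(p, 0.0))
            cols.append(LogoColumn(
                kind="insertion", symbol="*", probabilities=bg,
                information=information_content(bg, 4),
                mean_gap_length=gap,
            ))
    return cols


# ------------------------------------------------------------- rendering

_BASE_COLORS = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "U": "#d62839"}
_COL_W = 28.0
_STACK_H = 80.0
_PAD = 12.0


def render(logo: list[LogoColumn], fmt: str = "svg") -> str:
    """Render a logo to SVG or a plain-text table (deterministic)."""
    if fmt == "svg":
        return _render_svg(logo)
    if fmt == "text":
        return _render_text(logo)
    raise ValueError(f"unknown format {fmt!r} (use 'svg' or 'text')")


def _render_text(logo: list[LogoColumn]) -> str:
    lines = ["# col\tkind\tsymbol\tinfo_bits\ttop\tgap_len\tiupac"]
    for k, col in enumerate(logo):
        names = PAIR_TYPES if col.kind == "pair" else tuple(BASES)
        top = names[int(np.argmax(col.probabilities))]
        gap = "" if col.mean_gap_length is None else f"{col.mean_gap_length:.2f}"
        lines.append(
            f"{k}\t{col.kind}\t{col.symbol}\t{col.information:.4f}\t{top}"
            f"\t{gap}\t{col.iupac or ''}"
        )
    return "\n".join(lines) + "\n"


def _svg_header(width: float, height: float) -> list[str]:
    return [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
    ]


def _render_svg(logo: list[LogoColumn]) -> str:
    width = 2 * _PAD + _COL_W * len(logo)
    height = _STACK_H + 46.0
    out = _svg_header(width, height)
    max_bits = np.log2(6)
    for k, col in enumerate(logo):
        x0 = _PAD + k * _COL_W
        names = PAIR_TYPES if col.kind == "pair" else tuple(BASES)
        total_h = _STACK_H * col.information / max_bits
        order = np.argsort(col.probabilities)  # small at top, big at base
        y = _STACK_H + 2.0
        for idx in order:
            h = float(col.probabilities[idx]) * total_h
            if h < 0.25:
                continue
            name = names[int(idx)]
            color = "#8a8a8a" if (col.kind == "pair" and col.partner) else \
                _BASE_COLORS.get(name[0], "#555555") if col.kind != "insertion" \
                else "#9a9a9a"
            fs = h if col.kind != "pair" else h * 0.9
            y -= h
            out.append(
                f'<text x="{x0 + _COL_W / 2:.1f}" y="{y + h - 1:.1f}" '
                f'font-family="monospace" text-anchor="middle" '
                f'font-size="{max(fs, 1.0):.2f}" '
                f'textLength="{_COL_W - 6:.1f}" lengthAdjust="spacingAndGlyphs" '
                f'fill="{color}">{name}</text>'
            )
        # pattern row
        out.append(
            f'<text x="{x0 + _COL_W / 2:.1f}" y="{_STACK_H + 18:.1f}" '
            f'font-family="monospace" text-anchor="middle" font-size="14" '
            f'fill="#000000">{_esc(col.symbol)}</text>'
        )
        if col.mean_gap_length is not None:
            out.append(
                f'<text x="{x0 + _COL_W / 2:.1f}" y="{_STACK_H + 32:.1f}" '
                f'font-family="monospace" text-anchor="middle" font-size="9" '
                f'fill="#444444">~{col.mean_gap_length:.1f}nt</text>'
            )
        if col.iupac:
            out.append(
                f'<text x="{x0 + _COL_W / 2:.1f}" y="{_STACK_H + 44:.1f}" '
                f'font-family="monospace" text-anchor="middle" font-size="11" '
                f'fill="#7a0000">{col.iupac}</text>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _esc(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def graph_diagram(model: ProfileModel) -> str:
    """Arc-style backbone diagram of the pattern: black backbone, gray
    hydrogen-bond arcs between bracket partners, dotted insertion
    segments, IUPAC codes above conserved (>1.5 bit) loop columns."""
    pat = model.pattern
    m = len(pat.text)
    step = 26.0
    width = 2 * _PAD + step * m
    base_y = 90.0
    out = _svg_header(width, base_y + 40.0)
    xs = [_PAD + step * (k + 0.5) for k in range(m)]
    for k in range(m - 1):
        dash = ' stroke-dasharray="3,3"' if (
            pat.text[k] == "*" or pat.text[k + 1] == "*"
        ) else ""
        out.append(
            f'<line x1="{xs[k]:.1f}" y1="{base_y:.1f}" x2="{xs[k + 1]:.1f}" '
            f'y2="{base_y:.1f}" stroke="#000000" stroke-width="1.6"{dash}/>'
        )
    for l, r in pat.pair_indices:
        rad = (xs[r] - xs[l]) / 2
        out.append(
            f'<path d="M {xs[l]:.1f} {base_y - 4:.1f} A {rad:.1f} '
            f'{rad * 0.8:.1f} 0 0 1 {xs[r]:.1f} {base_y - 4:.1f}" '
            f'fill="none" stroke="#9a9a9a" stroke-width="1.4"/>'
        )
    loop_of = {p: k for k, p in enumerate(pat.loop_indices)}
    for p, ch in enumerate(pat.text):
        label = ch
        if ch == ".":
            probs = np.exp(model.theta_loop[loop_of[p]])
            probs /= probs.sum()
            code = iupac_label(probs)
            if code:
                out.append(
                    f'<text x="{xs[p]:.1f}" y="{base_y - 12:.1f}" '
                    f'font-family="monospace" text-anchor="middle" '
                    f'font-size="12" fill="#7a0000">{code}</text>'
                )
        out.append(
            f'<text x="{xs[p]:.1f}" y="{base_y + 18:.1f}" '
            f'font-family="monospace" text-anchor="middle" font-size="13" '
            f'fill="#000000">{_esc(label)}</text>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"
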