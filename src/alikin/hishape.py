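"""Position-aware structure abstraction: helices and helix-index shapes.

A helix is a maximal run of directly stacked base pairs; any interruption
(bulge, internal loop, multiloop) starts a new helix. A helix is located
by the central position (i+j)/2 of its innermost pair, a half-integer on
1-based coordinates, and labelled by the loop it closes on its inner side:
hairpin helices carry no marker, multiloop-, bulge- and internal-loop-
closing helices are marked ``m``, ``b`` and ``i``.

The hishape (helix index shape) of a structure is the ordered list of the
helix indices retained at an abstraction level:

* ``a``  — all helices;
* ``m``  — hairpin and multiloop-closing helices;
* ``h+`` — hairpin helices plus multiloop-closing helices whose multiloop
  directly contains at least two branches (for canonical structures this
  coincides with ``m``; the ``hplus_as_m`` flag makes the identification
  explicit);
* ``h``  — hairpin helices only.

The open chain maps to the distinguished empty hishape, rendered ``[_]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

from .alignment_io import CoordinateMap, SecondaryStructure

__all__ = [
    "Helix",
    "HelixIndex",
    "Hishape",
    "LEVELS",
    "ProjectionError",
    "abstract",
    "decompose_helices",
    "helix_index",
    "project_hishape",
]

LEVELS = ("h", "h+", "m", "a")

LoopType = Literal["hairpin", "bulge", "internal", "multiloop"]

#: CLI numbering of abstraction levels, most abstract last.
LEVEL_BY_NUMBER = {1: "a", 2: "m", 3: "h+", 4: "h"}


class ProjectionError(ValueError):
    """A helix index could not be projected onto a row (gap at an endpoint)."""


@dataclass(frozen=True)
class Helix:
    """A maximal run of directly stacked pairs, outer (p,q) to innermost (i,j)."""

    outer: tuple[int, int]
    inner: tuple[int, int]
    length: int
    closing_loop_type: LoopType
    #: number of branches directly inside the loop the helix closes
    branches: int = 0


@dataclass(frozen=True)
class HelixIndex:
    """Central position (i+j)/2 of a helix's innermost pair, with loop marker."""

    value: Fraction
    marker: Literal["", "m", "b", "i"]

    def render(self) -> str:
        v = self.value
        text = str(int(v)) if v.denominator == 1 else f"{float(v):.1f}"
        return text + self.marker


@dataclass(frozen=True)
class Hishape:
    """An ordered list of helix indices at one abstraction level."""

    indices: tuple[HelixIndex, ...]
    level: str

    def render(self) -> str:
        if not self.indices:
            return "[_]"
        return "[" + ",".join(ix.render() for ix in self.indices) + "]"

    def __str__(self) -> str:
        return self.render()


def decompose_helices(s: SecondaryStructure) -> list[Helix]:
    """Split a structure into maximal directly-stacked helices, 5'→3'.

    Every pair belongs to exactly one helix; the sum of helix lengths
    equals the number of pairs. Each helix is labelled by the type of the
    loop on its inner side (hairpin / bulge / internal / multiloop).
    """
    pairs = s.sorted_pairs()
    # children of each pair in the nesting forest
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    helices: list[Helix] = []

    def walk(pair: tuple[int, int]) -> None:
        outer = pair
        cur = pair
        length = 1
        while True:
            kids = children[cur]
            if len(kids) == 1 and kids[0] == (cur[0] + 1, cur[1] - 1):
                cur = kids[0]
                length += 1
                continue
            break
        kids = children[cur]
        if not kids:
            loop: LoopType = "hairpin"
        elif len(kids) == 1:
            k, l = kids[0]
            loop = "bulge" if (k == cur[0] + 1 or l == cur[1] - 1) else "internal"
        else:
            loop = "multiloop"
        helices.append(
            Helix(outer=outer, inner=cur, length=length,
                  closing_loop_type=loop, branches=len(kids))
        )
        for kid in kids:
            walk(kid)

    for top in children[None]:
        walk(top)
    helices.sort(key=lambda h: h.outer[0])
    return helices


_MARKER = {"hairpin": "", "multiloop": "m", "bulge": "b", "internal": "i"}


def helix_index(h: Helix) -> HelixIndex:
    """Helix index (i+j)/2 over the innermost pair, marked by closing loop type."""
    i, j = h.inner
    return HelixIndex(value=Fraction(i + j, 2), marker=_MARKER[h.closing_loop_type])


def abstract(
    s: SecondaryStructure, level: str, hplus_as_m: bool = False
) -> Hishape:
    """Map a structure to its hishape at the given abstraction level.

    A total function: every valid structure has exactly one hishape per
    level; the open chain maps to the empty hishape at every level.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown abstraction level {level!r}; choose from {LEVELS}")
    kept: list[HelixIndex] = []
    for h in decompose_helices(s):
        t = h.closing_loop_type
        if t == "hairpin":
            kept.append(helix_index(h))
        elif level == "a":
            kept.append(helix_index(h))
        elif t == "multiloop" and level == "m":
            kept.append(helix_index(h))
        elif t == "multiloop" and level == "h+" and (hplus_as_m or h.branches >= 2):
            kept.append(helix_index(h))
    return Hishape(indices=tuple(kept), level=level)


def project_hishape(
    hs: Hishape, s: SecondaryStructure, cmap: CoordinateMap
) -> Hishape:
    """Re-express a hishape of *s* in one row's ungapped coordinates.

    Alignment gaps shift helix indices between consensus and individual
    sequences; each retained index is recomputed as (pos(i)+pos(j))/2 from
    the row's coordinate map. A retained helix whose innermost pair
    touches a gap column raises :class:`ProjectionError`.
    """
    helices = decompose_helices(s)
    by_index = {helix_index(h): h for h in helices}
    out: list[HelixIndex] = []
    for ix in hs.indices:
        h = by_index.get(ix)
        if h is None:
            raise ProjectionError(f"hishape index {ix.render()} not found in structure")
        i, j = h.inner
        pi, pj = cmap.pos(i), cmap.pos(j)
        if pi is None or pj is None:
            raise ProjectionError(
                f"helix at ({i},{j}) has a gap at an innermost endpoint in row {cmap.row}"
            )
        out.append(HelixIndex(value=Fraction(pi + pj, 2), marker=ix.marker))
    return Hishape(indices=tuple(out), level=hs.level)
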