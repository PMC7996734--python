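"""Consensus folding-space enumeration and k-best hishape classes.

The folding space of an alignment is the set of canonical consensus
structures over its columns: non-crossing, hairpin loops with at least
three unpaired positions, no lonely pairs (every helix at least two pairs
long), and every base pair supported by at least a threshold fraction of
rows (0.5 by default). Structures are scored with the consensus pseudo
free energy and partitioned into hishape classes; each class is reported
through its minimum-pseudo-energy member, the hishrep.

At the problem sizes this package targets (a few tens of columns) the
constrained space is enumerated exhaustively; the classified k-best list
is exact by construction, and an independently coded brute-force oracle
in :mod:`alikin.synthetic` cross-checks it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .alignment_io import Alignment, SecondaryStructure
from .energy import (
    ConsensusEnergyEvaluator,
    CovarianceParams,
    EnergyBackend,
    NearestNeighborBackend,
    PseudoEnergy,
    pair_fraction,
)
from .hishape import Hishape, abstract, decompose_helices

__all__ = [
    "FoldingSpaceConfig",
    "HishapeClass",
    "allowed_pairs",
    "apply_x_filter",
    "enumerate_structures",
    "external_components",
    "kbest_hishapes",
]

#: Safety cap on the number of enumerated structures.
DEFAULT_GUARD = 5_000_000


@dataclass(frozen=True)
class FoldingSpaceConfig:
    """Parameters of the consensus folding-space search."""

    k: int = 10
    level: str = "h"
    bp_threshold: float = 0.5
    x_filter: float | None = None
    energy_band: float | None = None
    min_helix_length: int = 2
    min_hairpin_unpaired: int = 3
    backend: EnergyBackend = field(default_factory=NearestNeighborBackend)
    params: CovarianceParams = field(default_factory=CovarianceParams)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.bp_threshold <= 1.0:
            raise ValueError("bp_threshold must be in [0,1]")
        if self.min_helix_length < 2:
            raise ValueError("canonical grammar requires min_helix_length >= 2")


@dataclass(frozen=True)
class HishapeClass:
    """A hishape class with its minimum-pseudo-energy representative."""

    hishape: Hishape
    hishrep: SecondaryStructure
    energy: PseudoEnergy
    rank: int = 0


def allowed_pairs(aln: Alignment, cfg: FoldingSpaceConfig) -> list[tuple[int, int]]:
    """Column pairs passing the base-pairing filter and the hairpin span."""
    out = []
    min_span = cfg.min_hairpin_unpaired + 1
    for i in range(1, aln.L + 1):
        for j in range(i + min_span, aln.L + 1):
            if pair_fraction(aln, i, j) >= cfg.bp_threshold:
                out.append((i, j))
    return out


def _canonical(pairs: frozenset[tuple[int, int]], length: int, cfg: FoldingSpaceConfig) -> bool:
    if not pairs:
        return True
    s = SecondaryStructure(length=length, pairs=pairs)
    return all(h.length >= cfg.min_helix_length for h in decompose_helices(s))


def _enumerate_pair_sets(
    lo: int,
    hi: int,
    by_open: dict[int, list[int]],
    counter: list[int],
    guard: int,
) -> Iterator[frozenset[tuple[int, int]]]:
    """All non-crossing subsets of the allowed pairs within [lo, hi], each once."""
    if lo > hi:
        yield frozenset()
        return
    # column lo unpaired
    for rest in _enumerate_pair_sets(lo + 1, hi, by_open, counter, guard):
        yield rest
    # column lo paired with j
    for j in by_open.get(lo, ()):
        if j > hi:
            continue
        for inner in _enumerate_pair_sets(lo + 1, j - 1, by_open, counter, guard):
            for rest in _enumerate_pair_sets(j + 1, hi, by_open, counter, guard):
                counter[0] += 1
                if counter[0] > guard:
                    raise RuntimeError(
                        f"folding-space enumeration exceeded guard of {guard} structures"
                    )
                yield frozenset({(lo, j)}) | inner | rest


def enumerate_structures(
    aln: Alignment, cfg: FoldingSpaceConfig, guard: int = DEFAULT_GUARD
) -> Iterator[tuple[SecondaryStructure, PseudoEnergy]]:
    """Stream every canonical consensus structure with its pseudo energy.

    Yields each structure exactly once (the interval recursion is
    non-ambiguous); at minimum the open chain is yielded. When
    ``cfg.energy_band`` is set, structures more than the band above the
    minimum are withheld, which requires buffering the space internally.
    """
    evaluator = ConsensusEnergyEvaluator(aln, cfg.backend, cfg.params)
    by_open: dict[int, list[int]] = {}
    for i, j in allowed_pairs(aln, cfg):
        by_open.setdefault(i, []).append(j)
    counter = [0]

    def raw() -> Iterator[tuple[SecondaryStructure, PseudoEnergy]]:
        for pairs in _enumerate_pair_sets(1, aln.L, by_open, counter, guard):
            if not _canonical(pairs, aln.L, cfg):
                continue
            s = SecondaryStructure(length=aln.L, pairs=pairs)
            yield s, evaluator.evaluate(s)

    if cfg.energy_band is None:
        yield from raw()
        return
    buffered = list(raw())
    emin = min(e.total for _, e in buffered)
    for s, e in buffered:
        if e.total <= emin + cfg.energy_band:
            yield s, e


def external_components(s: SecondaryStructure) -> list[SecondaryStructure]:
    """Maximal substructures whose outermost helix sits in the external loop."""
    tops = []
    pairs = s.sorted_pairs()
    end = 0
    for i, j in pairs:
        if i > end:
            tops.append((i, j))
            end = j
    comps = []
    for i, j in tops:
        sub = frozenset(p for p in s.pairs if i <= p[0] and p[1] <= j)
        comps.append(SecondaryStructure(length=s.length, pairs=sub))
    return comps


def apply_x_filter(
    stream,
    e: float,
    evaluator: ConsensusEnergyEvaluator,
):
    """Drop structures with an external-loop component above *e* kcal/mol.

    A component is a maximal substructure rooted in the external loop; a
    component with pseudo free energy strictly greater than *e* marks the
    whole structure as unlikely and removes it. The open chain has no
    components and is always retained. With ``e = 0`` exactly the
    positive-pseudo-energy components are filtered.
    """
    for s, pe in stream:
        ok = True
        for comp in external_components(s):
            if evaluator.total(comp) > e:
                ok = False
                break
        if ok:
            yield s, pe


def kbest_hishapes(
    aln: Alignment, cfg: FoldingSpaceConfig, guard: int = DEFAULT_GUARD
) -> list[HishapeClass]:
    """The k lowest-pseudo-energy hishape classes of the consensus folding space.

    Classifies every structure of the constrained space at ``cfg.level``,
    keeps the minimum-energy representative per class and returns the k
    best classes ordered by class energy. Ties between classes break on
    the rendered hishape text, ties within a class on the representative's
    dot-bracket string, so repeated runs are byte-identical.
    """
    evaluator = ConsensusEnergyEvaluator(aln, cfg.backend, cfg.params)
    stream = enumerate_structures(aln, cfg, guard=guard)
    if cfg.x_filter is not None:
        stream = apply_x_filter(stream, cfg.x_filter, evaluator)
    best: dict[str, tuple[float, str, SecondaryStructure, PseudoEnergy, Hishape]] = {}
    for s, pe in stream:
        hs = abstract(s, cfg.level)
        key = hs.render()
        entry = (pe.total, s.dotbracket(), s, pe, hs)
        if key not in best or entry[:2] < best[key][:2]:
            best[key] = entry
    ranked = sorted(best.items(), key=lambda kv: (kv[1][0], kv[0]))
    out = []
    for rank, (key, (tot, db, s, pe, hs)) in enumerate(ranked[: cfg.k], start=1):
        out.append(HishapeClass(hishape=hs, hishrep=s, energy=pe, rank=rank))
    return out
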