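"""Refolding pathways and barrier estimation between consensus structures.

Moves add or remove a single base pair, restricted to pairs unique to the
start or target structure, so every applied move reduces the base-pair
distance by one and a path between structures at distance d has exactly
d+1 states. The barrier (saddle) of a path is the maximum pseudo free
energy along it.

The search is a width-limited breadth-first heuristic: a frontier of at
most ``width`` partial paths is advanced one move per round; the frontier
is ranked by lowest saddle-so-far (then current energy, then dot-bracket
text) — ranking by the quantity being minimised is the key heuristic
choice. Wider frontiers can only improve (never worsen) the barrier.

Indirect pathways route through intermediate hishreps: the barrier of
a→m→b is the maximum of the two legs, and the best of the direct and all
single-intermediate routes is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment_io import Alignment, SecondaryStructure
from .energy import ConsensusEnergyEvaluator, CovarianceParams, EnergyBackend

__all__ = [
    "Move",
    "Path",
    "direct_path",
    "indirect_barrier",
    "move_set",
]


@dataclass(frozen=True)
class Move:
    """Addition or removal of a single base pair."""

    kind: str  # "add" | "remove"
    pair: tuple[int, int]


@dataclass(frozen=True)
class Path:
    """A refolding path: states one base-pair move apart, with energies."""

    states: tuple[SecondaryStructure, ...]
    energies: tuple[float, ...]
    moves: tuple[Move, ...]

    @property
    def barrier(self) -> float:
        return max(self.energies)

    def __post_init__(self) -> None:
        assert len(self.states) == len(self.energies) == len(self.moves) + 1


def _compatible(pair: tuple[int, int], pairs: frozenset[tuple[int, int]]) -> bool:
    i, j = pair
    for k, l in pairs:
        if i in (k, l) or j in (k, l):
            return False
        if k < i <= l < j or i < k <= j < l:
            return False
    return True


def move_set(current: SecondaryStructure, target: SecondaryStructure) -> list[Move]:
    """Applicable single-pair moves toward *target*.

    Removable: pairs of *current* absent from *target*. Addable: pairs of
    *target* absent from *current* that are compatible with it
    (endpoints unpaired, non-crossing). Every move strictly decreases the
    base-pair distance to the target by one.
    """
    if current.length != target.length:
        raise ValueError("structures live on different coordinate systems")
    moves = [Move("remove", p) for p in sorted(current.pairs - target.pairs)]
    for p in sorted(target.pairs - current.pairs):
        if _compatible(p, current.pairs):
            moves.append(Move("add", p))
    return moves


def _apply(s: SecondaryStructure, mv: Move) -> SecondaryStructure:
    if mv.kind == "remove":
        return SecondaryStructure(length=s.length, pairs=s.pairs - {mv.pair})
    return SecondaryStructure(length=s.length, pairs=s.pairs | {mv.pair})


@dataclass
class _Partial:
    saddle: float
    energy: float
    db: str
    state: SecondaryStructure
    states: tuple[SecondaryStructure, ...]
    energies: tuple[float, ...]
    moves: tuple[Move, ...]

    def rank_key(self):
        return (self.saddle, self.energy, self.db)


def direct_path(
    aln: Alignment,
    a: SecondaryStructure,
    b: SecondaryStructure,
    width: int = 16,
    backend: EnergyBackend | None = None,
    params: CovarianceParams = CovarianceParams(),
    evaluator: ConsensusEnergyEvaluator | None = None,
) -> Path:
    """Width-limited BFS refolding path from *a* to *b* over the alignment.

    Intermediate states are scored with the same consensus pseudo free
    energy as the folding space. Returns the completed path with the
    lowest barrier found; the barrier is non-increasing in ``width``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if evaluator is None:
        if backend is None:
            raise ValueError("provide an energy backend or evaluator")
        evaluator = ConsensusEnergyEvaluator(aln, backend, params)
    e_a = evaluator.total(a)
    start = _Partial(
        saddle=e_a, energy=e_a, db=a.dotbracket(), state=a,
        states=(a,), energies=(e_a,), moves=(),
    )
    distance = len(a.pairs ^ b.pairs)
    frontier = [start]
    for _ in range(distance):
        successors: list[_Partial] = []
        for part in frontier:
            for mv in move_set(part.state, b):
                nxt = _apply(part.state, mv)
                e = evaluator.total(nxt)
                successors.append(
                    _Partial(
                        saddle=max(part.saddle, e),
                        energy=e,
                        db=nxt.dotbracket(),
                        state=nxt,
                        states=part.states + (nxt,),
                        energies=part.energies + (e,),
                        moves=part.moves + (mv,),
                    )
                )
        successors.sort(key=_Partial.rank_key)
        seen: set[str] = set()
        frontier = []
        for part in successors:
            if part.db in seen:
                continue
            seen.add(part.db)
            frontier.append(part)
            if len(frontier) >= width:
                break
        if not frontier:
            raise RuntimeError("refolding search stalled (no applicable moves)")
    best = min(frontier, key=_Partial.rank_key)
    assert best.state.pairs == b.pairs
    return Path(states=best.states, energies=best.energies, moves=best.moves)


def _concat(first: Path, second: Path) -> Path:
    assert first.states[-1].pairs == second.states[0].pairs
    return Path(
        states=first.states + second.states[1:],
        energies=first.energies + second.energies[1:],
        moves=first.moves + second.moves,
    )


def indirect_barrier(
    aln: Alignment,
    a: SecondaryStructure,
    b: SecondaryStructure,
    intermediates: Iterable[SecondaryStructure] = (),
    width: int = 16,
    backend: EnergyBackend | None = None,
    params: CovarianceParams = CovarianceParams(),
    evaluator: ConsensusEnergyEvaluator | None = None,
) -> Path:
    """Best of the direct route and all single-intermediate routes a→m→b.

    The barrier of an indirect route is the maximum over its two legs, so
    the result is never worse than the direct path.
    """
    if evaluator is None:
        if backend is None:
            raise ValueError("provide an energy backend or evaluator")
        evaluator = ConsensusEnergyEvaluator(aln, backend, params)
    best = direct_path(aln, a, b, width=width, evaluator=evaluator)
    for m in intermediates:
        if m.pairs in (a.pairs, b.pairs):
            continue
        leg1 = direct_path(aln, a, m, width=width, evaluator=evaluator)
        leg2 = direct_path(aln, m, b, width=width, evaluator=evaluator)
        cand = _concat(leg1, leg2)
        if (cand.barrier, len(cand.states)) < (best.barrier, len(best.states)):
            best = cand
    return best
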