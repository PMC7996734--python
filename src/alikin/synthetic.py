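"""Synthetic alignments with planted covariation, and brute-force oracles.

The generator emulates the statistical signal the covariance score
rewards: homologous rows share a conserved ("planted") secondary
structure whose base pairs undergo joint compensatory exchanges, while
unpaired positions mutate independently and gaps enter per row. It does
not model phylogeny (no tree, no correlated row ancestry) or realistic
indel processes — rows are independent perturbations of one reference.

The oracles recompute, by strategies independent of the production code
paths, the quantities the main algorithms produce: exhaustive
classification of the folding space, and exact minimax saddle energies
over the complete direct move graph.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .alignment_io import Alignment, SecondaryStructure
from .energy import BP, ConsensusEnergyEvaluator, CovarianceParams, EnergyBackend
from .folding_space import FoldingSpaceConfig, HishapeClass, allowed_pairs
from .hishape import abstract, decompose_helices

__all__ = [
    "SyntheticSpec",
    "brute_force_hishapes",
    "generate_alignment",
    "minimax_barrier_oracle",
]

_BP_LIST = sorted(BP)
_BASES = "ACGU"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic alignment around a planted structure.

    ``comp_rate`` is the probability that a planted pair is jointly
    replaced in a row by another valid base-pair type (the covariation
    signal); ``mut_rate`` the per-position substitution rate at unpaired
    positions; ``gap_rate`` the per-position gap probability under the
    chosen policy (``terminal``: contiguous runs of unpaired terminal
    positions become gaps, keeping planted pairs intact; ``interior``:
    any unpaired position may become a gap).
    """

    reference: str
    structure: SecondaryStructure
    n_rows: int = 8
    comp_rate: float = 0.7
    mut_rate: float = 0.1
    gap_rate: float = 0.0
    seed: int = 0
    gap_policy: str = "terminal"

    def __post_init__(self) -> None:
        for name in ("comp_rate", "mut_rate", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if len(self.reference) != self.structure.length:
            raise ValueError("reference length must match planted structure")
        if self.gap_policy not in ("terminal", "interior"):
            raise ValueError(f"unknown gap policy {self.gap_policy!r}")


def generate_alignment(spec: SyntheticSpec) -> tuple[Alignment, dict]:
    """Generate a seeded alignment and a truth record of the planted signal.

    Rows derive independently from the reference: each planted pair is,
    with probability ``comp_rate``, replaced by a uniformly chosen
    different member of the valid-pair set (both bases jointly); unpaired
    positions substitute independently at ``mut_rate``; gaps are applied
    per row per the gap policy. The truth record lists the planted pair
    columns and the planted level-h hishape.
    """
    rng = np.random.default_rng(spec.seed)
    ref = list(spec.reference.upper().replace("T", "U"))
    pairs = spec.structure.sorted_pairs()
    paired_pos = {p for ij in pairs for p in ij}
    unpaired = [p for p in range(1, len(ref) + 1) if p not in paired_pos]
    rows = []
    for _ in range(spec.n_rows):
        row = ref[:]
        for i, j in pairs:
            if rng.random() < spec.comp_rate:
                current = (row[i - 1], row[j - 1])
                choices = [bp for bp in _BP_LIST if bp != current]
                a, b = choices[rng.integers(len(choices))]
                row[i - 1], row[j - 1] = a, b
        for p in unpaired:
            if rng.random() < spec.mut_rate:
                alt = [c for c in _BASES if c != row[p - 1]]
                row[p - 1] = alt[rng.integers(3)]
        if spec.gap_rate > 0:
            if spec.gap_policy == "terminal":
                for p in range(1, len(ref) + 1):
                    if p in paired_pos or rng.random() >= spec.gap_rate:
                        break
                    row[p - 1] = "-"
                for p in range(len(ref), 0, -1):
                    if p in paired_pos or rng.random() >= spec.gap_rate:
                        break
                    row[p - 1] = "-"
            else:
                for p in unpaired:
                    if rng.random() < spec.gap_rate:
                        row[p - 1] = "-"
        rows.append("".join(row))
    aln = Alignment.from_rows(rows)
    truth = {
        "pairs": pairs,
        "hishape_h": abstract(spec.structure, "h").render(),
        "structure": spec.structure.dotbracket(),
    }
    return aln, truth


# ---------------------------------------------------------------------------
# oracles


def brute_force_hishapes(
    aln: Alignment, cfg: FoldingSpaceConfig, guard: int = 10_000_000
) -> list[HishapeClass]:
    """Exhaustive oracle for the k-best hishape classes.

    Enumerates every constraint-satisfying structure by backtracking over
    the sorted candidate-pair list (an enumeration strategy independent of
    the production interval recursion), classifies at ``cfg.level``, keeps
    the per-class minimum and orders classes exactly as
    :func:`alikin.folding_space.kbest_hishapes` does.
    """
    evaluator = ConsensusEnergyEvaluator(aln, cfg.backend, cfg.params)
    cand = allowed_pairs(aln, cfg)
    count = 0

    def backtrack(idx: int, chosen: list[tuple[int, int]]):
        nonlocal count
        count += 1
        if count > guard:
            raise RuntimeError(f"oracle enumeration exceeded guard of {guard}")
        yield frozenset(chosen)
        for nxt in range(idx, len(cand)):
            p = cand[nxt]
            if _fits(p, chosen):
                chosen.append(p)
                yield from backtrack(nxt + 1, chosen)
                chosen.pop()

    def _fits(p: tuple[int, int], chosen: list[tuple[int, int]]) -> bool:
        i, j = p
        for k, l in chosen:
            if i in (k, l) or j in (k, l):
                return False
            if k < i <= l < j or i < k <= j < l:
                return False
        return True

    best: dict[str, tuple[float, str, SecondaryStructure, object]] = {}
    for pairs in backtrack(0, []):
        s = SecondaryStructure(length=aln.L, pairs=pairs)
        if pairs and any(
            h.length < cfg.min_helix_length for h in decompose_helices(s)
        ):
            continue
        pe = evaluator.evaluate(s)
        hs = abstract(s, cfg.level)
        key = hs.render()
        entry = (pe.total, s.dotbracket(), s, pe, hs)
        if key not in best or entry[:2] < best[key][:2]:
            best[key] = entry
    ranked = sorted(best.items(), key=lambda kv: (kv[1][0], kv[0]))
    return [
        HishapeClass(hishape=hs, hishrep=s, energy=pe, rank=r)
        for r, (key, (tot, db, s, pe, hs)) in enumerate(ranked[: cfg.k], start=1)
    ]


def minimax_barrier_oracle(
    aln: Alignment,
    a: SecondaryStructure,
    b: SecondaryStructure,
    backend: EnergyBackend,
    params: CovarianceParams = CovarianceParams(),
    guard: int = 1_000_000,
) -> float:
    """Exact minimax saddle energy between *a* and *b* on the direct move graph.

    States are all valid structures whose pairs come from the union of the
    endpoint pair sets; edges add or remove one such pair. Best-first
    search (Dijkstra on the max-energy-along-path objective) returns the
    lowest achievable barrier; by construction it lower-bounds any
    width-limited heuristic estimate.
    """
    evaluator = ConsensusEnergyEvaluator(aln, backend, params)
    universe = sorted(a.pairs ^ b.pairs)  # shared pairs never move
    if len(universe) > 20:
        raise RuntimeError("direct move graph too large for the oracle")

    def valid(pairs: frozenset[tuple[int, int]]) -> bool:
        try:
            SecondaryStructure(length=a.length, pairs=pairs)
        except Exception:
            return False
        return True

    def energy(pairs: frozenset[tuple[int, int]]) -> float:
        return evaluator.total(SecondaryStructure(length=a.length, pairs=pairs))

    start, goal = a.pairs, b.pairs
    e0 = energy(start)
    best_saddle = {start: e0}
    heap = [(e0, sorted(start))]
    visited: set[frozenset] = set()
    popped = 0
    while heap:
        saddle, state_list = heapq.heappop(heap)
        state = frozenset(tuple(p) for p in state_list)
        if state in visited:
            continue
        visited.add(state)
        popped += 1
        if popped > guard:
            raise RuntimeError(f"oracle state expansion exceeded guard of {guard}")
        if state == goal:
            return saddle
        for p in universe:
            if p in state:
                nxt = state - {p}
            else:
                nxt = state | {p}
                if not valid(nxt):
                    continue
            cand = max(saddle, energy(nxt))
            if cand < best_saddle.get(nxt, np.inf):
                best_saddle[nxt] = cand
                heapq.heappush(heap, (cand, sorted(nxt)))
    raise RuntimeError("target unreachable in direct move graph")
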