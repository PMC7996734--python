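"""Free-energy and pseudo-free-energy evaluation.

Two layers live here.

* Single-sequence nearest-neighbour energies: a structure is decomposed
  into its unique set of loops (hairpin, stack, bulge, internal, multi,
  external) and an :class:`EnergyBackend` prices each loop. Two backends
  are provided: :class:`ToyBackend`, whose constant per-loop costs make
  every test energy hand-computable, and :class:`NearestNeighborBackend`,
  a Turner-style table loaded from a bundled parameter file.

* Alignment-level pseudo free energy: the mean of the per-row energies of
  a consensus structure plus a weighted covariance term,

      dG# = dG_mean + lambda * sum_{(i,j) in pairs} C_ij,
      C_ij = V_ij - phi * Q_ij,

  where V rewards compensatory base-pair exchanges between rows and Q
  penalises rows that cannot form the pair. With the default lambda = -1
  covariation lowers the pseudo free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

from .alignment_io import Alignment, SecondaryStructure, coordinate_map

__all__ = [
    "BP",
    "CovarianceParams",
    "EnergyBackend",
    "InvalidLoopError",
    "NearestNeighborBackend",
    "PseudoEnergy",
    "ToyBackend",
    "ConsensusEnergyEvaluator",
    "consensus_pseudo_energy",
    "conservation_score_V",
    "covariance_C",
    "gap_penalty_Q",
    "get_backend",
    "pair_fraction",
    "project_structure_to_row",
    "sequence_energy",
]

#: Valid base pairs (Watson-Crick + wobble).
BP = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})


class InvalidLoopError(ValueError):
    """A loop was queried with bases that cannot form the required pair."""


class EnergyBackend:
    """Loop-resolved nearest-neighbour energy function.

    Subclasses price each loop context in kcal/mol. Backends are
    deterministic and return finite values for all valid loops; querying a
    stack on an invalid pair raises :class:`InvalidLoopError`.
    """

    name: str = "abstract"

    def hairpin(self, seq: str, i: int, j: int) -> float:
        raise NotImplementedError

    def stack(self, seq: str, i: int, j: int) -> float:
        """Stack of pair (i,j) on the directly nested pair (i+1, j-1)."""
        raise NotImplementedError

    def bulge(self, seq: str, i: int, j: int, k: int, l: int) -> float:
        raise NotImplementedError

    def internal(self, seq: str, i: int, j: int, k: int, l: int) -> float:
        raise NotImplementedError

    def multiloop(self, seq: str, i: int, j: int, branches: int, unpaired: int) -> float:
        raise NotImplementedError

    def external(self, seq: str, branches: int, unpaired: int) -> float:
        raise NotImplementedError

    def _require_pair(self, seq: str, i: int, j: int) -> None:
        if (seq[i - 1], seq[j - 1]) not in BP:
            raise InvalidLoopError(
                f"({seq[i-1]},{seq[j-1]}) at ({i},{j}) is not a valid base pair"
            )


@dataclass(frozen=True)
class ToyBackend(EnergyBackend):
    """Constant-cost backend: every energy in tests is hand-computable.

    stack −2.0, hairpin closure +3.0, bulge/internal +2.0, multiloop
    closure +4.0, external loop 0.0 (kcal/mol).
    """

    STACK = -2.0
    HAIRPIN = 3.0
    BULGE_INTERNAL = 2.0
    MULTILOOP = 4.0

    name: str = "toy"

    def hairpin(self, seq, i, j):
        return self.HAIRPIN

    def stack(self, seq, i, j):
        self._require_pair(seq, i, j)
        self._require_pair(seq, i + 1, j - 1)
        return self.STACK

    def bulge(self, seq, i, j, k, l):
        return self.BULGE_INTERNAL

    def internal(self, seq, i, j, k, l):
        return self.BULGE_INTERNAL

    def multiloop(self, seq, i, j, branches, unpaired):
        return self.MULTILOOP

    def external(self, seq, branches, unpaired):
        return 0.0


class NearestNeighborBackend(EnergyBackend):
    """Turner-style nearest-neighbour model from the bundled parameter table.

    Stacking energies are pair/pair resolved; hairpin, bulge and internal
    loops are priced by size with Jacobson-Stockmayer extrapolation beyond
    the tabulated range; multiloops are affine in branches and unpaired
    nucleotides. Dangling ends and coaxial stacking are not modelled, which
    keeps the loop decomposition unambiguous. Hairpins smaller than the
    tabulated minimum (possible only in row-projected structures) are
    clamped to the size-3 value.
    """

    name = "turner"

    def __init__(self, path: str | None = None) -> None:
        self._stack: dict[tuple[str, str], float] = {}
        self._hairpin: dict[int, float] = {}
        self._bulge: dict[int, float] = {}
        self._internal: dict[int, float] = {}
        self._ml: dict[str, float] = {}
        self._extrap = 1.079
        if path is None:
            text = (resources.files("alikin") / "data" / "nn_params.txt").read_text()
        else:
            text = open(path).read()
        self._parse(text)

    def _parse(self, text: str) -> None:
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            kind = tok[0]
            if kind == "stack":
                self._stack[(tok[1], tok[2])] = float(tok[3])
            elif kind == "hairpin":
                self._hairpin[int(tok[1])] = float(tok[2])
            elif kind == "bulge":
                self._bulge[int(tok[1])] = float(tok[2])
            elif kind == "internal":
                self._internal[int(tok[1])] = float(tok[2])
            elif kind == "multiloop":
                self._ml[tok[1]] = float(tok[2])
            elif kind == "extrapolation":
                self._extrap = float(tok[1])
            else:
                raise ValueError(f"unknown parameter record {kind!r}")

    def _sized(self, table: dict[int, float], size: int) -> float:
        if size <= min(table):
            return table[min(table)]
        if size in table:
            return table[size]
        mx = max(table)
        return table[mx] + self._extrap * math.log(size / mx)

    def hairpin(self, seq, i, j):
        return self._sized(self._hairpin, j - i - 1)

    def stack(self, seq, i, j):
        self._require_pair(seq, i, j)
        self._require_pair(seq, i + 1, j - 1)
        outer = seq[i - 1] + seq[j - 1]
        inner = seq[i] + seq[j - 2]
        return self._stack[(outer, inner)]

    def bulge(self, seq, i, j, k, l):
        size = (k - i - 1) + (j - l - 1)
        return self._sized(self._bulge, size)

    def internal(self, seq, i, j, k, l):
        size = (k - i - 1) + (j - l - 1)
        return self._sized(self._internal, size)

    def multiloop(self, seq, i, j, branches, unpaired):
        return (
            self._ml["closing"]
            + self._ml["branch"] * branches
            + self._ml["unpaired"] * unpaired
        )

    def external(self, seq, branches, unpaired):
        return 0.0


_BACKENDS = {"toy": ToyBackend, "turner": NearestNeighborBackend}


def get_backend(name: str) -> EnergyBackend:
    """Instantiate a named backend (``toy`` or ``turner``)."""
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown energy backend {name!r}") from None


# ---------------------------------------------------------------------------
# loop decomposition


def _loops(pairs: Iterable[tuple[int, int]], length: int):
    """Yield loop records for the unique loop decomposition of a pair set.

    Records are tuples ``(kind, data)`` with kind in
    {hairpin, stack, bulge, internal, multiloop, external}.
    """
    pairs = sorted(pairs)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    for parent, kids in children.items():
        if parent is None:
            unpaired = length - sum(j - i + 1 for i, j in kids)
            yield ("external", (len(kids), unpaired))
            continue
        i, j = parent
        if not kids:
            yield ("hairpin", (i, j))
        elif len(kids) == 1:
            k, l = kids[0]
            if k == i + 1 and l == j - 1:
                yield ("stack", (i, j))
            elif k == i + 1 or l == j - 1:
                yield ("bulge", (i, j, k, l))
            else:
                yield ("internal", (i, j, k, l))
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            yield ("multiloop", (i, j, len(kids), unpaired))


def sequence_energy(
    seq: str, s: SecondaryStructure, backend: EnergyBackend
) -> float:
    """Nearest-neighbour free energy of structure *s* on the ungapped *seq*.

    The energy is the sum of loop energies over the unique loop
    decomposition of the structure; the open chain scores the external-loop
    contribution only (0.0 for both bundled backends).
    """
    if len(seq) != s.length:
        raise ValueError(f"sequence length {len(seq)} != structure length {s.length}")
    total = 0.0
    for kind, data in _loops(s.pairs, s.length):
        if kind == "external":
            total += backend.external(seq, *data)
        elif kind == "hairpin":
            total += backend.hairpin(seq, *data)
        elif kind == "stack":
            total += backend.stack(seq, *data)
        elif kind == "bulge":
            total += backend.bulge(seq, *data)
        elif kind == "internal":
            total += backend.internal(seq, *data)
        else:
            total += backend.multiloop(seq, *data)
    return total


# ---------------------------------------------------------------------------
# covariance scoring


@dataclass(frozen=True)
class CovarianceParams:
    """Weights of the covariance contribution.

    ``lam`` converts covariance score units into kcal/mol; the default −1.0
    makes covariation a bonus. ``phi`` scales the inconsistency penalty Q.
    ``normalization`` selects the prefactor of V: ``per_M`` divides the
    row-pair sum by M, ``per_pairs`` by the number of row pairs M(M−1)/2.
    """

    lam: float = -1.0
    phi: float = 1.0
    normalization: Literal["per_M", "per_pairs"] = "per_M"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.normalization not in ("per_M", "per_pairs"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _check_cols(aln: Alignment, i: int, j: int) -> None:
    if not (1 <= i < j <= aln.L):
        raise IndexError(f"columns ({i},{j}) out of range 1..{aln.L} with i<j")


def conservation_score_V(
    aln: Alignment, i: int, j: int, normalization: str = "per_M"
) -> float:
    """Conservation/covariation score V of the column pair (i, j).

    Sums, over all row pairs (k, l) whose bases at (i, j) both form valid
    base pairs, the Hamming distance between the two rows' pairs,
    h(s_ik, s_il) + h(s_jk, s_jl); compensatory exchanges therefore score
    2, consistent single mutations 1, identity 0. Normalized by 1/M
    (``per_M``) or by the number of row pairs (``per_pairs``).
    """
    _check_cols(aln, i, j)
    M = aln.M
    total = 0
    for k in range(M):
        a_i, a_j = aln.rows[k][i - 1], aln.rows[k][j - 1]
        if (a_i, a_j) not in BP:
            continue
        for l in range(k + 1, M):
            b_i, b_j = aln.rows[l][i - 1], aln.rows[l][j - 1]
            if (b_i, b_j) not in BP:
                continue
            total += (a_i != b_i) + (a_j != b_j)
    if normalization == "per_pairs":
        npairs = M * (M - 1) // 2
        return total / npairs if npairs else 0.0
    return total / M


def gap_penalty_Q(aln: Alignment, i: int, j: int) -> float:
    """Fraction of rows that can neither pair (i, j) nor are gapped at both columns."""
    _check_cols(aln, i, j)
    bad = 0
    for row in aln.rows:
        a, b = row[i - 1], row[j - 1]
        if a == b == "-" or (a, b) in BP:
            continue
        bad += 1
    return bad / aln.M


def covariance_C(
    aln: Alignment, i: int, j: int, params: CovarianceParams = CovarianceParams()
) -> float:
    """Covariance score C = V − phi * Q for the column pair (i, j)."""
    return conservation_score_V(aln, i, j, params.normalization) - params.phi * gap_penalty_Q(
        aln, i, j
    )


def pair_fraction(aln: Alignment, i: int, j: int) -> float:
    """Fraction of rows forming a valid base pair at columns (i, j).

    Rows with a gap in either column never count as valid; the consensus
    folding space admits a column pair when this fraction reaches the
    base-pairing threshold (0.5 by default).
    """
    _check_cols(aln, i, j)
    ok = sum(1 for row in aln.rows if (row[i - 1], row[j - 1]) in BP)
    return ok / aln.M


# ---------------------------------------------------------------------------
# consensus pseudo free energy


@dataclass(frozen=True)
class PseudoEnergy:
    """Alignment-level pseudo free energy and its two components."""

    mean_energy: float
    covariance_term: float

    @property
    def total(self) -> float:
        return self.mean_energy + self.covariance_term


def project_structure_to_row(
    aln: Alignment, s: SecondaryStructure, row: int
) -> SecondaryStructure:
    """Project a consensus structure onto one row's ungapped coordinates.

    Pairs touching a gap in the row, and pairs whose bases are invalid for
    the row, are dropped (the inconsistency is already penalised through
    Q); remaining pairs are re-indexed via the row's coordinate map. The
    result may contain lonely pairs or short hairpins and is evaluated
    as-is by the energy backend.
    """
    cmap = coordinate_map(aln, row)
    seq_row = aln.rows[row - 1]
    kept = []
    for i, j in s.pairs:
        a, b = seq_row[i - 1], seq_row[j - 1]
        if a == "-" or b == "-" or (a, b) not in BP:
            continue
        kept.append((cmap.pos(i), cmap.pos(j)))
    return SecondaryStructure.make(len(aln.ungapped(row)), kept, min_hairpin=0)


class ConsensusEnergyEvaluator:
    """Cached pseudo-free-energy evaluator for one alignment.

    Precomputes ungapped rows, coordinate maps, per-row base columns and
    covariance scores so that the folding-space enumeration and the
    pathway search can score many structures on the same alignment
    cheaply. Produces exactly the same numbers as
    :func:`consensus_pseudo_energy`.
    """

    def __init__(
        self,
        aln: Alignment,
        backend: EnergyBackend,
        params: CovarianceParams = CovarianceParams(),
    ) -> None:
        self.aln = aln
        self.backend = backend
        self.params = params
        self._rows_ungapped = [aln.ungapped(r) for r in range(1, aln.M + 1)]
        self._cmaps = [coordinate_map(aln, r) for r in range(1, aln.M + 1)]
        self._C_cache: dict[tuple[int, int], float] = {}

    def covariance(self, i: int, j: int) -> float:
        key = (i, j)
        if key not in self._C_cache:
            self._C_cache[key] = covariance_C(self.aln, i, j, self.params)
        return self._C_cache[key]

    def evaluate(self, s: SecondaryStructure) -> PseudoEnergy:
        if s.length != self.aln.L:
            raise ValueError(
                f"structure length {s.length} != alignment width {self.aln.L}"
            )
        pairs_sorted = sorted(s.pairs)  # fixed order: float sums independent of set history
        mean = 0.0
        for r, (seq, cmap) in enumerate(zip(self._rows_ungapped, self._cmaps), start=1):
            row_str = self.aln.rows[r - 1]
            kept = []
            for i, j in pairs_sorted:
                a, b = row_str[i - 1], row_str[j - 1]
                if a == "-" or b == "-" or (a, b) not in BP:
                    continue
                kept.append((cmap.pos(i), cmap.pos(j)))
            proj = SecondaryStructure.make(len(seq), kept, min_hairpin=0)
            mean += sequence_energy(seq, proj, self.backend)
        mean /= self.aln.M
        cov = self.params.lam * sum(self.covariance(i, j) for i, j in pairs_sorted)
        return PseudoEnergy(mean_energy=mean, covariance_term=cov)

    def total(self, s: SecondaryStructure) -> float:
        return self.evaluate(s).total


def consensus_pseudo_energy(
    aln: Alignment,
    s: SecondaryStructure,
    backend: EnergyBackend,
    params: CovarianceParams = CovarianceParams(),
) -> PseudoEnergy:
    """Pseudo free energy of a consensus structure over alignment columns.

    ``mean_energy`` averages the per-row nearest-neighbour energies of the
    row-projected structure; ``covariance_term`` is lambda times the sum of
    C over the structure's column pairs; ``total`` is their exact sum.
    """
    return ConsensusEnergyEvaluator(aln, backend, params).evaluate(s)
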