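"""Arrhenius rate matrices over hishape classes and master-equation kinetics.

States are hishape classes represented by their hishreps; the rate from
state a to state b is

    R[a][b] = A * exp(-(B_ab - E_a) / (R_gas * T)),

with B_ab the (symmetrised) barrier between the representatives and E_a
the pseudo free energy of a. Barriers are symmetrised to the best value
found in either direction, which makes the chain satisfy detailed balance
with respect to the Boltzmann distribution of the state energies. The
master equation dp/dt = p R is integrated either by symmetrised
eigendecomposition (exact for detailed-balance chains, stable over many
decades of time) or by the matrix exponential as a fallback.

The default simulation protocol starts all population in the open
chain and follows the flow into the low-energy hishapes on a logarithmic
time grid; times are in units of the Arrhenius prefactor A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GAS_CONSTANT_KCAL",
    "RateMatrix",
    "Trajectory",
    "build_rate_matrix",
    "default_times",
    "equilibrium",
    "group_populations",
    "simulate",
]

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT_KCAL = 0.0019872


class BarrierError(ValueError):
    """A barrier is missing or below an endpoint energy."""


@dataclass
class RateMatrix:
    """Arrhenius transition rates between coarse-grained states."""

    names: tuple[str, ...]
    energies: np.ndarray
    R: np.ndarray
    temperature: float
    prefactor: float

    @property
    def n(self) -> int:
        return len(self.names)


@dataclass
class Trajectory:
    """Time-resolved state populations; rows sum to one."""

    times: np.ndarray
    populations: np.ndarray  # shape (len(times), n_states)
    names: tuple[str, ...]
    p0: np.ndarray


def build_rate_matrix(
    names,
    energies,
    barriers: dict[tuple[int, int], float | None],
    temperature: float = 310.15,
    prefactor: float = 1.0,
) -> RateMatrix:
    """Assemble the Arrhenius rate matrix from state energies and barriers.

    ``barriers`` maps unordered index pairs (either orientation) to the
    saddle pseudo energy, or to ``None`` for a pair explicitly found
    disconnected (rate 0, reported via a warning). A pair absent from the
    map altogether is an error — no silent zero rates. Barriers are
    symmetrised to the lower value when both orientations are present and
    must not lie below either endpoint energy (tolerance 1e-9).
    """
    energies = np.asarray(energies, dtype=float)
    n = len(names)
    if energies.shape != (n,):
        raise ValueError("energies must match names")
    rt = GAS_CONSTANT_KCAL * temperature
    B = np.full((n, n), np.nan)
    disconnected = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            vals = [barriers[k] for k in ((a, b), (b, a)) if k in barriers]
            if not vals:
                raise BarrierError(f"no barrier provided for state pair ({a},{b})")
            finite = [v for v in vals if v is not None]
            if not finite:
                disconnected[a, b] = disconnected[b, a] = True
                continue
            bb = min(finite)
            floor = max(energies[a], energies[b])
            if bb < floor - 1e-9:
                raise BarrierError(
                    f"barrier {bb} for pair ({a},{b}) lies below endpoint energy {floor}"
                )
            B[a, b] = B[b, a] = max(bb, floor)
    if disconnected.any():
        warnings.warn(
            f"{int(disconnected.sum()) // 2} state pair(s) disconnected (rate 0)",
            stacklevel=2,
        )
    R = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b or disconnected[a, b]:
                continue
            R[a, b] = prefactor * np.exp(-(B[a, b] - energies[a]) / rt)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    return RateMatrix(
        names=tuple(names), energies=energies, R=R,
        temperature=temperature, prefactor=prefactor,
    )


def default_times(t_start: float = 1e-2, t_end: float = 1e10, n: int = 60) -> np.ndarray:
    """Logarithmically spaced output times (arbitrary units of 1/A)."""
    return np.logspace(np.log10(t_start), np.log10(t_end), n)


def _boltzmann(energies: np.ndarray, temperature: float) -> np.ndarray:
    w = np.exp(-(energies - energies.min()) / (GAS_CONSTANT_KCAL * temperature))
    return w / w.sum()


def simulate(rm: RateMatrix, p0, times) -> Trajectory:
    """Integrate the master equation: p(t) = p0 · exp(R t).

    When the chain satisfies detailed balance with respect to the
    Boltzmann distribution of the state energies (the generic case for
    Arrhenius rates with symmetric barriers), the propagator is computed
    through the symmetrised eigendecomposition, which stays accurate over
    arbitrarily many decades of time; otherwise scipy's matrix exponential
    is used per time point.
    """
    p0 = np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if p0.shape != (rm.n,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0, atol=1e-9):
        raise ValueError("p0 must be a probability distribution over the states")
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("times must be increasing and non-negative")
    if not np.all(np.isfinite(rm.R)):
        raise ValueError("rate matrix contains non-finite entries")

    R = rm.R
    pi = _boltzmann(rm.energies, rm.temperature)
    db_residual = np.max(np.abs(pi[:, None] * R - (pi[:, None] * R).T))
    scale = max(np.max(np.abs(R)), 1.0)
    pops = np.empty((len(times), rm.n))
    if db_residual <= 1e-10 * scale:
        sq = np.sqrt(pi)
        S = (sq[:, None] * R) / sq[None, :]
        S = 0.5 * (S + S.T)
        lam, U = np.linalg.eigh(S)
        # the top eigenvalue is exactly 0 for a conservative generator; remove
        # the O(eps) numerical offset, which exp(lam*t) would amplify at large t
        lam = lam - lam.max()
        # p(t) = p0 diag(1/sq) U e^{lam t} U^T diag(sq)
        left = (p0 / sq) @ U
        for ti, t in enumerate(times):
            pops[ti] = ((left * np.exp(lam * t)) @ U.T) * sq
    else:  # pragma: no cover - non-detailed-balance input
        for ti, t in enumerate(times):
            pops[ti] = p0 @ scipy.linalg.expm(R * t)
    return Trajectory(times=times, populations=pops, names=rm.names, p0=p0)


def equilibrium(rm: RateMatrix) -> np.ndarray:
    """Stationary distribution: normalized null vector of R^T.

    For a reducible rate matrix the stationary distribution is not unique;
    a warning is emitted and each connected component is internally at its
    own stationary distribution, components weighted equally.
    """
    R = rm.R
    adj = (np.abs(R) > 0).astype(int)
    np.fill_diagonal(adj, 0)
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp == 1:
        return _stationary(R)
    warnings.warn(
        f"rate matrix is reducible ({ncomp} components); "
        "per-component stationary distributions, equally weighted",
        stacklevel=2,
    )
    out = np.zeros(rm.n)
    for c in range(ncomp):
        idx = np.where(labels == c)[0]
        out[idx] = _stationary(R[np.ix_(idx, idx)]) / ncomp
    return out


def _stationary(R: np.ndarray) -> np.ndarray:
    """Solve pi R = 0, sum(pi) = 1 by replacing one balance equation."""
    n = R.shape[0]
    if n == 1:
        return np.ones(1)
    A = R.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def group_populations(traj: Trajectory, groups: dict[str, list[str]]) -> Trajectory:
    """Sum member populations per group; ungrouped states pass through.

    ``groups`` maps a group name to the state names it contains; a state
    assigned to two groups is an error. Total population is conserved.
    """
    assigned: dict[str, str] = {}
    for gname, members in groups.items():
        for m in members:
            if m in assigned:
                raise ValueError(f"state {m!r} assigned to groups {assigned[m]!r} and {gname!r}")
            if m not in traj.names:
                raise KeyError(f"unknown state {m!r}")
            assigned[m] = gname
    out_names: list[str] = []
    columns: list[np.ndarray] = []
    done_groups: set[str] = set()
    for idx, name in enumerate(traj.names):
        if name in assigned:
            g = assigned[name]
            if g in done_groups:
                continue
            done_groups.add(g)
            member_idx = [i for i, n in enumerate(traj.names) if assigned.get(n) == g]
            out_names.append(g)
            columns.append(traj.populations[:, member_idx].sum(axis=1))
        else:
            out_names.append(name)
            columns.append(traj.populations[:, idx])
    pops = np.stack(columns, axis=1)
    p0 = np.array([
        traj.p0[[i for i, n in enumerate(traj.names) if assigned.get(n) == name]].sum()
        if name in groups else traj.p0[traj.names.index(name)]
        for name in out_names
    ])
    return Trajectory(times=traj.times, populations=pops, names=tuple(out_names), p0=p0)
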