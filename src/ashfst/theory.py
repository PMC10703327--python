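"""Coancestry dynamics under an arbitrary migration matrix.

The metapopulation model: ``r`` populations of effective sizes ``N_i``
exchange alleles according to a backward migration matrix ``M`` whose
entry ``m[i, i']`` is the fraction of alleles in population ``i`` that
resided in population ``i'`` one generation earlier.  Mean coancestries
(identity-by-descent probabilities for pairs of alleles drawn from
distinct individuals) evolve by a one-generation recursion combining
drift (``1/(2N_i)``), migration mixing and mutation (a ``(1 - mu)**2``
decay of identity).  Iterating the recursion from a zero matrix gives
coancestries relative to the founding generation; re-expressing them
relative to the mean between-population coancestry gives the expected
matrix of population-specific (diagonal) and population-pair
(off-diagonal) F_ST values.

Builders for the classical structures (continent-island, finite island,
one-dimensional stepping stone, dendritic river) return ready-made
:class:`MigrationModel` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MigrationModel",
    "CoancestryState",
    "FstMatrix",
    "step_coancestry",
    "iterate_coancestry",
    "iterate_to_equilibrium",
    "fst_from_theta",
    "overall_fst_from_theta",
    "pairwise_fst_from_theta",
    "make_continent_island",
    "make_finite_island",
    "make_stepping_stone_1d",
    "make_river",
    "continent_island_equilibrium",
]

_ROW_TOL = 1e-12

#: Effective size used to represent an effectively infinite continent.
CONTINENT_SIZE = 1e9


class ValidationError(ValueError):
    """A model or matrix violates its declared invariants."""


@dataclass(frozen=True)
class MigrationModel:
    """Demographic parameterization of the coancestry recursion.

    Parameters
    ----------
    N : array of float, shape (r,)
        Effective population sizes (diploid individuals).  A continent
        is represented by a very large finite size (1e9 by default in
        :func:`make_continent_island`).
    M : array of float, shape (r, r)
        Backward migration matrix; ``M[i, j]`` is the fraction of
        alleles of population ``i`` that were in population ``j`` one
        generation before.  Rows must sum to one.
    mu : float
        Mutation rate per generation, in [0, 1).  Any mutation destroys
        identity, hence the ``(1 - mu)**2`` factor in the recursion.
    """

    N: np.ndarray
    M: np.ndarray
    mu: float = 0.0

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "M", M)
        if N.ndim != 1 or N.size == 0:
            raise ValidationError("N must be a non-empty 1-D vector of sizes")
        if np.any(N <= 0):
            raise ValidationError("all effective sizes must be positive")
        if M.shape != (N.size, N.size):
            raise ValidationError(
                f"migration matrix shape {M.shape} does not match r={N.size}"
            )
        if np.any(M < 0):
            raise ValidationError("migration matrix entries must be non-negative")
        rowsums = M.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValidationError(
                f"row {bad} of the migration matrix sums to {rowsums[bad]!r}, not 1"
            )
        if not (0.0 <= self.mu < 1.0):
            raise ValidationError("mutation rate must lie in [0, 1)")

    @property
    def r(self) -> int:
        """Number of populations."""
        return int(self.N.size)


@dataclass(frozen=True)
class CoancestryState:
    """Symmetric r x r matrix of mean coancestries at generation ``t``.

    ``theta[i, i]`` is the mean IBD probability for two alleles drawn
    from distinct individuals of population ``i``; ``theta[i, j]`` for
    one individual in each of ``i`` and ``j``.  Values are relative to
    the reference generation ``t = 0``.
    """

    theta: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValidationError("theta must be a square matrix")
        if not np.allclose(theta, theta.T, atol=1e-9):
            raise ValidationError("theta must be symmetric")
        if np.any(theta < -1e-12) or np.any(theta > 1 + 1e-12):
            raise ValidationError("coancestries must lie in [0, 1]")
        if self.t < 0:
            raise ValidationError("generation counter must be non-negative")

    @property
    def r(self) -> int:
        return int(self.theta.shape[0])

    @classmethod
    def zero(cls, r: int) -> "CoancestryState":
        """The founding-generation state: no coancestry anywhere."""
        return cls(theta=np.zeros((r, r)), t=0)


@dataclass(frozen=True)
class FstMatrix:
    """Matrix of relative coancestries.

    The diagonal holds population-specific F_ST values and the
    off-diagonal holds population-pair values, all expressed relative
    to the reference point recorded in ``reference``:

    - ``"mean-between"`` — the mean between-population coancestry
      (off-diagonal elements then average to zero by construction);
    - ``"minimum-between"`` — the minimum between-population value
      (all elements then non-negative, minimum off-diagonal zero);
    - ``"external-constant"`` — an arbitrary constant ``c < 1``,
      stored in ``constant``.
    """

    values: np.ndarray
    reference: str = "mean-between"
    origin: str = "expected-from-theory"
    constant: float | None = None
    argmin_pair: tuple[int, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("F_ST values must form a square matrix")
        if self.reference not in ("mean-between", "minimum-between", "external-constant"):
            raise ValidationError(f"unknown reference tag {self.reference!r}")
        if self.origin not in ("expected-from-theory", "estimated-from-data"):
            raise ValidationError(f"unknown origin tag {self.origin!r}")

    @property
    def r(self) -> int:
        return int(self.values.shape[0])

    def offdiag(self) -> np.ndarray:
        """The r(r-1) off-diagonal elements, flattened."""
        mask = ~np.eye(self.r, dtype=bool)
        return self.values[mask]


def _phi_matrix(theta: np.ndarray, N: np.ndarray) -> np.ndarray:
    # diagonal: phi_i = 1/(2N_i) + (1 - 1/(2N_i)) * theta_i ; off-diagonal: theta_ii'
    phi = theta.copy()
    d = 1.0 / (2.0 * N)
    np.fill_diagonal(phi, d + (1.0 - d) * np.diag(theta))
    return phi


def step_coancestry(state: CoancestryState, model: MigrationModel) -> CoancestryState:
    """Advance the coancestry matrix by one generation.

    Computes ``(1 - mu)**2 * M @ Phi @ M.T`` where ``Phi`` equals the
    coancestry matrix with its diagonal replaced by
    ``1/(2N_i) + (1 - 1/(2N_i)) * theta_i`` (drift within populations).
    """
    if state.r != model.r:
        raise ValidationError(
            f"state has {state.r} populations but model has {model.r}"
        )
    phi = _phi_matrix(state.theta, model.N)
    nxt = (1.0 - model.mu) ** 2 * (model.M @ phi @ model.M.T)
    nxt = 0.5 * (nxt + nxt.T)  # kill float asymmetry
    return CoancestryState(theta=nxt, t=state.t + 1)


def iterate_coancestry(
    model: MigrationModel,
    generations: int,
    initial: CoancestryState | None = None,
    keep_trajectory: bool = True,
) -> list[CoancestryState]:
    """Iterate the recursion; return the trajectory (length generations+1).

    Starts from an all-zero coancestry matrix unless ``initial`` is
    given, so returned coancestries are relative to generation 0.  With
    ``keep_trajectory=False`` only the first and final states are
    returned (a two-element list), saving memory for long runs.
    """
    if generations < 0:
        raise ValidationError("generations must be non-negative")
    state = initial if initial is not None else CoancestryState.zero(model.r)
    out = [state]
    for _ in range(generations):
        state = step_coancestry(state, model)
        if keep_trajectory:
            out.append(state)
    if not keep_trajectory:
        out.append(state)
    return out


def iterate_to_equilibrium(
    model: MigrationModel,
    tol: float = 1e-12,
    max_iter: int = 10**6,
    initial: CoancestryState | None = None,
) -> CoancestryState:
    """Iterate until the elementwise change drops below ``tol``.

    Raises if equilibrium is not reached within ``max_iter`` steps
    (small mutation rates make convergence slow for large populations).
    """
    state = initial if initial is not None else CoancestryState.zero(model.r)
    for _ in range(max_iter):
        nxt = step_coancestry(state, model)
        if np.max(np.abs(nxt.theta - state.theta)) < tol:
            return nxt
        state = nxt
    raise RuntimeError(f"no equilibrium within {max_iter} iterations (tol={tol})")


def _theta_b(theta: np.ndarray) -> float:
    r = theta.shape[0]
    mask = ~np.eye(r, dtype=bool)
    return float(theta[mask].mean())


def fst_from_theta(state: CoancestryState) -> FstMatrix:
    """Expected F_ST matrix relative to the mean between-population coancestry.

    ``F = (Theta - J * theta_B) / (1 - theta_B)`` with ``theta_B`` the
    unweighted mean of the off-diagonal coancestries.
    """
    if state.r < 2:
        raise ValidationError("F_ST requires at least two populations")
    tb = _theta_b(state.theta)
    if abs(1.0 - tb) < 1e-12:
        raise ValidationError("singular reference: mean between-population coancestry is 1")
    values = (state.theta - tb) / (1.0 - tb)
    return FstMatrix(values=values, reference="mean-between", origin="expected-from-theory")


def overall_fst_from_theta(state: CoancestryState) -> float:
    """Overall expected F_ST: ``(theta_S - theta_B) / (1 - theta_B)``.

    Equals the mean of the diagonal of :func:`fst_from_theta`.
    """
    return float(np.diag(fst_from_theta(state).values).mean())


def pairwise_fst_from_theta(state: CoancestryState) -> np.ndarray:
    """Two-population F_ST for every pair, using only that pair.

    Entry ``(i, i')`` equals
    ``[(theta_i + theta_i')/2 - theta_ii'] / (1 - theta_ii')``; the
    diagonal is zero.  These values are invariant to the global
    reference point.
    """
    th = state.theta
    diag = np.diag(th)
    denom = 1.0 - th
    off_mask = ~np.eye(state.r, dtype=bool)
    if np.any(np.abs(denom[off_mask]) < 1e-12):
        raise ValidationError("singular pair: between-population coancestry is 1")
    num = 0.5 * (diag[:, None] + diag[None, :]) - th
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / denom
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Classical model builders


def _as_sizes(N: Sequence[float] | np.ndarray) -> np.ndarray:
    N = np.asarray(N, dtype=float)
    if N.ndim != 1:
        raise ValidationError("sizes must be a 1-D vector")
    return N


def _check_diag(M: np.ndarray) -> None:
    if np.any(np.diag(M) < -_ROW_TOL):
        raise ValidationError("off-diagonal migration rates exceed 1 in some row")


def make_continent_island(
    N_islands: Sequence[float],
    m: float | Sequence[float],
    N_continent: float = CONTINENT_SIZE,
    mu: float = 0.0,
) -> MigrationModel:
    """Continent-island model: population 0 is the continent.

    The continent receives no immigrants (its row of M is the identity
    row); island ``i`` receives a fraction ``m_i`` of its alleles from
    the continent and none from other islands.
    """
    N_isl = _as_sizes(N_islands)
    k = N_isl.size
    m_vec = np.broadcast_to(np.asarray(m, dtype=float), (k,))
    if np.any((m_vec < 0) | (m_vec > 1)):
        raise ValidationError("immigration rates must lie in [0, 1]")
    r = k + 1
    M = np.zeros((r, r))
    M[0, 0] = 1.0
    for i in range(k):
        M[i + 1, 0] = m_vec[i]
        M[i + 1, i + 1] = 1.0 - m_vec[i]
    N = np.concatenate([[float(N_continent)], N_isl])
    return MigrationModel(N=N, M=M, mu=mu)


def make_finite_island(N: Sequence[float], m: float, mu: float = 0.0) -> MigrationModel:
    """Finite island model: total immigration ``m`` split equally among
    the ``r - 1`` other islands; diagonal ``1 - m``."""
    N = _as_sizes(N)
    r = N.size
    if r < 2:
        raise ValidationError("finite island model needs at least two islands")
    if not (0.0 <= m <= 1.0):
        raise ValidationError("migration rate must lie in [0, 1]")
    M = np.full((r, r), m / (r - 1))
    np.fill_diagonal(M, 1.0 - m)
    _check_diag(M)
    return MigrationModel(N=N, M=M, mu=mu)


def make_stepping_stone_1d(N: Sequence[float], m: float, mu: float = 0.0) -> MigrationModel:
    """One-dimensional stepping stone: rate ``m/2`` to each of the left
    and right neighbours; end populations receive only from their single
    neighbour at ``m/2`` (so their diagonal is ``1 - m/2``)."""
    N = _as_sizes(N)
    r = N.size
    if r < 2:
        raise ValidationError("stepping stone needs at least two populations")
    if not (0.0 <= m <= 1.0):
        raise ValidationError("migration rate must lie in [0, 1]")
    M = np.zeros((r, r))
    for i in range(r):
        if i > 0:
            M[i, i - 1] = m / 2.0
        if i < r - 1:
            M[i, i + 1] = m / 2.0
        M[i, i] = 1.0 - M[i].sum()
    _check_diag(M)
    return MigrationModel(N=N, M=M, mu=mu)


def make_river(
    edges: Iterable[tuple[int, int]],
    N: Sequence[float],
    m_down: float,
    m_up: float,
    mu: float = 0.0,
) -> MigrationModel:
    """Dendritic river system with asymmetric up/downstream migration.

    ``edges`` lists ``(upstream, downstream)`` station pairs using
    1-based station labels.  Rates are backward (immigration) fractions:
    each station draws ``m_down`` of its alleles from each of its
    upstream neighbours and ``m_up`` from each of its downstream
    neighbours; the diagonal absorbs the remainder.  Junction stations
    may have several upstream neighbours.
    """
    N = _as_sizes(N)
    r = N.size
    edge_list = [(int(u), int(d)) for u, d in edges]
    for u, d in edge_list:
        if not (1 <= u <= r and 1 <= d <= r) or u == d:
            raise ValidationError(f"invalid edge ({u}, {d}) for {r} stations")
    if not (0.0 <= m_down <= 1.0 and 0.0 <= m_up <= 1.0):
        raise ValidationError("migration rates must lie in [0, 1]")
    # connectivity check on the undirected station graph
    adj: dict[int, set[int]] = {i: set() for i in range(1, r + 1)}
    for u, d in edge_list:
        adj[u].add(d)
        adj[d].add(u)
    seen = {1}
    stack = [1]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != r:
        raise ValidationError("river graph is disconnected")
    M = np.zeros((r, r))
    for u, d in edge_list:
        M[d - 1, u - 1] += m_down  # downstream station receives from upstream
        M[u - 1, d - 1] += m_up
    for i in range(r):
        M[i, i] = 1.0 - M[i].sum()
    _check_diag(M)
    return MigrationModel(N=N, M=M, mu=mu)


def continent_island_equilibrium(
    N: float, m: float, mu: float = 0.0, approximate: bool = False
) -> float:
    """Equilibrium within-island coancestry in the continent-island model.

    Exact closed form
    ``(1-m)^2 (1-mu)^2 / (2N - (2N-1)(1-m)^2 (1-mu)^2)``;
    with ``approximate=True`` returns ``1 / (1 + 4N(m + mu))``.
    """
    if N <= 0:
        raise ValidationError("N must be positive")
    if approximate:
        return 1.0 / (1.0 + 4.0 * N * (m + mu))
    a = (1.0 - m) ** 2 * (1.0 - mu) ** 2
    denom = 2.0 * N - (2.0 * N - 1.0) * a
    if denom <= 0:
        raise ValidationError("equilibrium denominator is not positive")
    return a / denom
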