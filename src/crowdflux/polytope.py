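"""Reduction of the steady-state flux space to a full-dimensional polytope.

Mass balance ``S f = 0`` confines the flux vector to the null space of the
stoichiometric matrix.  Rather than sampling in the ambient space, the
equalities are solved analytically: ``S`` is brought to Reduced Row Echelon
Form (over exact rationals, so the pivot/free split is unique given the
reaction ordering), pivot fluxes become affine functions of the free
("independent") ones, and every inequality — flux bounds, crowding rows,
shared coupling rows — is rewritten over the independent coordinates.  The
result is a full-dimensional convex polytope ``{x : A x <= b}`` of dimension
``D = n_reactions - rank(S)``.

The module also finds a strictly interior starting point (Chebyshev-center
linear program, with an iterative Motzkin-style relaxation as fallback) and
computes a *rounding ellipsoid* whose metric makes the polytope roughly
isotropic, which is what keeps Hit-and-Run mixing polynomial on strongly
elongated flux spaces (axis ratios of order 1e4 occur in practice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from crowdflux.network import CoupledNetwork, CrowdingSpec, MetabolicNetwork, crowding_rows

__all__ = [
    "FluxPolytope",
    "RoundingEllipsoid",
    "InfeasiblePolytopeError",
    "EmptyInteriorError",
    "UnboundedChordError",
    "rref_reduce",
    "find_interior_point",
    "round_polytope",
    "chord",
]


class InfeasiblePolytopeError(ValueError):
    """The inequality system admits no point at all."""


class EmptyInteriorError(ValueError):
    """The polytope is nonempty but has no strict interior (degenerate)."""


class UnboundedChordError(ValueError):
    """A sampling line escapes to infinity: the polytope is unbounded."""


@dataclass
class FluxPolytope:
    """Affine parameterization of the steady-state flux set.

    ``full = transform @ x + offset`` maps independent coordinates ``x`` to
    the full flux vector; ``A x <= b`` collects every inequality.
    """

    reaction_ids: list[str]
    independent_ids: list[str]
    transform: np.ndarray  # (n_reactions, D)
    offset: np.ndarray  # (n_reactions,)
    A: np.ndarray  # (n_ineq, D)
    b: np.ndarray  # (n_ineq,)

    @property
    def dimension(self) -> int:
        return self.transform.shape[1]

    def to_full(self, x: np.ndarray) -> np.ndarray:
        """Map independent coordinates (vector or matrix of rows) to fluxes."""
        x = np.asarray(x, dtype=float)
        return x @ self.transform.T + self.offset

    def contains(self, x: np.ndarray, tol: float = 1e-9) -> bool:
        return bool(np.all(self.A @ x <= self.b + tol))

    def slacks(self, x: np.ndarray) -> np.ndarray:
        return self.b - self.A @ x

    def reduce_objective(self, w: np.ndarray) -> np.ndarray:
        """Rewrite a linear functional over full fluxes in independent coords."""
        return np.asarray(w, dtype=float) @ self.transform

    def lp_optimum(self, w: np.ndarray, sense: str = "max") -> tuple[float, np.ndarray]:
        """Optimize ``w . f`` over the polytope (returns value, full fluxes)."""
        g = self.reduce_objective(w)
        c = -g if sense == "max" else g
        res = linprog(c, A_ub=self.A, b_ub=self.b, bounds=(None, None),
                      method="highs")
        if res.status != 0:
            raise InfeasiblePolytopeError(f"LP failed: {res.message}")
        val = float(g @ res.x + np.asarray(w) @ self.offset)
        return val, self.to_full(res.x)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "reaction_ids": self.reaction_ids,
            "independent_ids": self.independent_ids,
            "transform": self.transform.tolist(),
            "offset": self.offset.tolist(),
            "A": self.A.tolist(),
            "b": self.b.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "FluxPolytope":
        d = json.loads(Path(path).read_text())
        return cls(
            d["reaction_ids"], d["independent_ids"],
            np.array(d["transform"]), np.array(d["offset"]),
            np.array(d["A"]), np.array(d["b"]),
        )


@dataclass
class RoundingEllipsoid:
    """Metric under which the polytope is approximately round.

    ``shape`` is SPD; sampling directions are ``L z`` with ``L`` its Cholesky
    factor and ``z`` standard normal, so long axes are explored more often.
    """

    center: np.ndarray
    shape: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        # symmetrize before factoring; tiny asymmetries arise from averaging
        self.shape = 0.5 * (self.shape + self.shape.T)
        self.cholesky = np.linalg.cholesky(self.shape)

    @property
    def axis_ratio(self) -> float:
        """Ratio of the longest to the shortest ellipsoid axis."""
        w = np.linalg.eigvalsh(self.shape)
        return float(np.sqrt(w[-1] / w[0]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"center": self.center.tolist(), "shape": self.shape.tolist()}
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoundingEllipsoid":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["center"]), np.array(d["shape"]))


# ---------------------------------------------------------------------------
# RREF reduction

_MAX_EXACT_ENTRIES = 200_000  # beyond this, fall back to floating point


def _rref_fraction(M: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Gauss-Jordan elimination over exact rationals; returns (RREF, pivots)."""
    rows = len(M)
    cols = len(M[0]) if rows else 0
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        pivot = next((i for i in range(r, rows) if M[i][c] != 0), None)
        if pivot is None:
            continue
        M[r], M[pivot] = M[pivot], M[r]
        inv = M[r][c]
        M[r] = [v / inv for v in M[r]]
        for i in range(rows):
            if i != r and M[i][c] != 0:
                factor = M[i][c]
                M[i] = [vi - factor * vr for vi, vr in zip(M[i], M[r])]
        pivots.append(c)
        r += 1
        if r == rows:
            break
    return M, pivots


def _rref_float(S: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, list[int]]:
    M = S.astype(float).copy()
    rows, cols = M.shape
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        if r >= rows:
            break
        pivot = r + int(np.argmax(np.abs(M[r:, c])))
        if abs(M[pivot, c]) < tol:
            continue
        M[[r, pivot]] = M[[pivot, r]]
        M[r] /= M[r, c]
        for i in range(rows):
            if i != r:
                M[i] -= M[i, c] * M[r]
        pivots.append(c)
        r += 1
    return M, pivots


def rref_reduce(
    net: MetabolicNetwork | CoupledNetwork,
    crowding: CrowdingSpec | None = None,
    extra_rows: tuple[np.ndarray, np.ndarray] | None = None,
    exact: bool | None = None,
) -> FluxPolytope:
    """Parameterize ``S f = 0`` by independent fluxes and build inequalities.

    Pivot (dependent) fluxes are eliminated through the unique RREF of ``S``;
    flux bounds, crowding rows, the shared rows of a coupled network, and any
    ``extra_rows`` (A, b) are all rewritten over the independent coordinates.
    """
    S = net.stoichiometric_matrix()
    n = net.n_reactions
    if exact is None:
        exact = S.size <= _MAX_EXACT_ENTRIES
    if exact:
        M = [[Fraction(v).limit_denominator(10**9) for v in row] for row in S]
        R, pivots = _rref_fraction(M)
        R = np.array([[float(v) for v in row] for row in R])
    else:
        R, pivots = _rref_float(S)
    free = [j for j in range(n) if j not in pivots]
    D = len(free)
    T = np.zeros((n, D))
    for k, j in enumerate(free):
        T[j, k] = 1.0
    for row_idx, pc in enumerate(pivots):
        # f_pivot = -sum_j R[row, free_j] * x_j
        T[pc, :] = -R[row_idx, free]
    offset = np.zeros(n)

    ids = net.reaction_ids
    lb, ub = net.bounds()
    A_rows, b_rows = [], []
    for i in range(n):
        if np.isfinite(ub[i]):
            A_rows.append(T[i])
            b_rows.append(ub[i])
        if np.isfinite(lb[i]):
            A_rows.append(-T[i])
            b_rows.append(-lb[i])
    if crowding is not None:
        Ac, bc = crowding_rows(net, crowding)
        for row, rhs in zip(Ac, bc):
            A_rows.append(row @ T)
            b_rows.append(rhs)
    if isinstance(net, CoupledNetwork):
        for row, rhs in zip(net.shared_rows, net.shared_rhs):
            A_rows.append(row @ T)
            b_rows.append(rhs)
    if extra_rows is not None:
        for row, rhs in zip(*extra_rows):
            A_rows.append(np.asarray(row) @ T)
            b_rows.append(rhs)
    A = np.array(A_rows) if A_rows else np.zeros((0, D))
    b = np.array(b_rows)
    # prune identically-zero rows (fully determined fluxes); an infeasible
    # zero row means the equality system contradicts a bound
    keep = []
    for i in range(A.shape[0]):
        if np.max(np.abs(A[i])) < 1e-12:
            if b[i] < -1e-9:
                raise InfeasiblePolytopeError(
                    "equality system forces a flux outside its bounds"
                )
            continue
        keep.append(i)
    return FluxPolytope(
        reaction_ids=list(ids),
        independent_ids=[ids[j] for j in free],
        transform=T,
        offset=offset,
        A=A[keep],
        b=b[keep],
    )


# ---------------------------------------------------------------------------
# Interior point

def _motzkin_relaxation(
    poly: FluxPolytope, max_iter: int = 20_000, lam: float = 1.5
) -> np.ndarray | None:
    """Iteratively project onto the most-violated half-space (with margin)."""
    A, b = poly.A, poly.b
    norms = np.linalg.norm(A, axis=1)
    margin = 1e-9 * np.maximum(1.0, np.abs(b))
    x = np.zeros(poly.dimension)
    for _ in range(max_iter):
        viol = A @ x - (b - margin)
        i = int(np.argmax(viol / norms))
        if viol[i] <= 0:
            return x
        x -= lam * viol[i] / norms[i] ** 2 * A[i]
    return None


def find_interior_point(
    poly: FluxPolytope, eps: float = 1e-9
) -> np.ndarray:
    """Strictly interior point by Chebyshev center, Motzkin fallback.

    Raises :class:`InfeasiblePolytopeError` if no point exists at all and
    :class:`EmptyInteriorError` if the polytope is degenerate (its largest
    inscribed sphere has radius <= ``eps``).
    """
    A, b = poly.A, poly.b
    D = poly.dimension
    norms = np.linalg.norm(A, axis=1)
    c = np.zeros(D + 1)
    c[-1] = -1.0  # maximize the inscribed radius r
    A_cheb = np.hstack([A, norms[:, None]])
    res = linprog(c, A_ub=A_cheb, b_ub=b,
                  bounds=[(None, None)] * D + [(0, None)], method="highs")
    if res.status == 2:
        raise InfeasiblePolytopeError("polytope is empty (infeasible rows)")
    if res.status != 0:
        x = _motzkin_relaxation(poly)
        if x is None:
            raise InfeasiblePolytopeError(
                f"interior-point search failed: {res.message}"
            )
        return x
    x, r = res.x[:-1], res.x[-1]
    if r <= eps:
        raise EmptyInteriorError(
            f"polytope has empty interior (Chebyshev radius {r:.2e} <= {eps:.0e})"
        )
    return x


# ---------------------------------------------------------------------------
# Chord

def chord(
    poly: FluxPolytope, point: np.ndarray, direction: np.ndarray
) -> tuple[float, float]:
    """Parametric interval of ``point + t * direction`` inside the polytope."""
    a_d = poly.A @ direction
    slack = poly.slacks(point)
    t_max = np.inf
    t_min = -np.inf
    pos = a_d > 1e-14
    neg = a_d < -1e-14
    if pos.any():
        t_max = float(np.min(slack[pos] / a_d[pos]))
    if neg.any():
        t_min = float(np.max(slack[neg] / a_d[neg]))
    if not np.isfinite(t_min) or not np.isfinite(t_max):
        raise UnboundedChordError(
            "polytope unbounded along the sampled direction; add finite "
            "bounds (or a cap) to every flux"
        )
    return t_min, t_max


# ---------------------------------------------------------------------------
# Rounding

def _uniform_walk(
    poly: FluxPolytope,
    L: np.ndarray,
    x0: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    record_every: int = 1,
) -> np.ndarray:
    """Plain uniform Hit-and-Run used internally for covariance rounding."""
    D = poly.dimension
    x = x0.copy()
    out = []
    for step in range(n_steps):
        d = L @ rng.standard_normal(D)
        d /= np.linalg.norm(d)
        t_min, t_max = chord(poly, x, d)
        x = x + (t_min + (t_max - t_min) * rng.random()) * d
        if (step + 1) % record_every == 0:
            out.append(x.copy())
    return np.array(out)


def round_polytope(
    poly: FluxPolytope,
    method: str = "covariance",
    seed: int | np.random.Generator = 0,
    n_rounds: int = 3,
    samples_per_round: int = 2000,
    center: np.ndarray | None = None,
) -> RoundingEllipsoid:
    """Estimate an ellipsoidal metric approximating the polytope's shape.

    The default iterates covariance rounding: sample uniformly under the
    current metric, re-estimate the sample covariance, use it as the next
    metric.  Anisotropic bodies (axis ratios of order 1e4) become O(1)-round
    in the transformed coordinates after a few rounds.
    """
    if method != "covariance":
        raise ValueError(f"unknown rounding method {method!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = find_interior_point(poly) if center is None else np.asarray(center, float)
    D = poly.dimension
    L = np.eye(D)
    cov = np.eye(D)
    for _ in range(n_rounds):
        xs = _uniform_walk(poly, L, x, samples_per_round, rng)
        cov = np.cov(xs.T) if D > 1 else np.array([[np.var(xs[:, 0])]])
        cov += 1e-12 * np.trace(cov) / D * np.eye(D)  # guard degeneracy
        L = np.linalg.cholesky(cov)
        x = xs.mean(axis=0)
    return RoundingEllipsoid(center=x, shape=cov)
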