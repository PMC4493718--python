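"""Coarse-grained crowding-constrained model of one and two coupled cells.

The model reduces central carbon catabolism to three lumped fluxes per cell:

* ``f_glyc`` — glycolysis, converting one glucose into ``pyr_per_glc``
  pyruvates and ``y_glyc`` ATP (defaults 2 and 2);
* ``f_ox`` — mitochondrial oxidation of pyruvate, yielding ``y_ox`` ATP per
  pyruvate (default 18, so full oxidation of one glucose yields 38 ATP);
* ``f_LDH`` — lactate dehydrogenase, draining pyruvate to lactate
  (``f_LDH > 0``) or, in a lactate-importing cell, regenerating pyruvate
  from imported lactate (``f_LDH < 0``).

Steady state ties the fluxes together through the pyruvate balance
``f_ox + f_LDH = pyr_per_glc * f_glyc``.  Finite cellular volume available
for ATP-producing enzymes imposes the *crowding constraint*

    a_glyc * f_glyc + a_ox * f_ox + a_LDH * |f_LDH| <= phi_ATP,

with empirical volume-per-flux coefficients ``a_LDH < a_glyc << a_ox``.
Because oxidation is by far the most volume-hungry route, a cell maximizing
ATP output switches from pure oxidation to lactate overflow (the Warburg
effect) once its glucose supply exceeds the crowding-onset threshold
``u_G = phi_ATP / (pyr_per_glc * a_ox + a_glyc)``.

The two-cell variant couples a lactate *donor* (secretion only) with an
*acceptor* (may import lactate through reverse LDH) sharing a common glucose
supply ``U_G`` while each must sustain a minimum ATP flux ``f_atp_min``.
All piecewise closed forms are re-derived here from those constraints; an
independent linear-programming oracle (:func:`lp_oracle`) checks them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MinimalModelParams",
    "CellFluxes",
    "Thresholds",
    "Regime",
    "TwoCellSolution",
    "StarvationError",
    "thresholds",
    "single_cell_optimum",
    "two_cell_solution",
    "lp_oracle",
]


class StarvationError(ValueError):
    """Raised when the glucose supply cannot sustain the minimum ATP flux."""


class Regime(str, Enum):
    """Operating regime of the donor/acceptor pair as glucose supply grows."""

    STARVED = "starved"
    GLUCOSE_SHARED = "glucose-shared"
    LACTATE_SUBSIDIZED = "lactate-subsidized"
    FULL_SEQUESTRATION = "full-sequestration"


@dataclass(frozen=True)
class MinimalModelParams:
    """Constants of the coarse-grained model.

    Volume-per-ATP-flux coefficients ``a_*`` are in min/mM, ``phi_ATP`` is the
    dimensionless volume fraction available for ATP production, and
    ``f_atp_min`` (mM/min) is the survival ATP flux each cell must sustain.
    The default ``f_atp_min`` equals ``38 * u_G``, i.e. one crowding-onset
    glucose flux converted at maximum yield — the convention used for the
    large-scale network as well ("1 u_G" of minimum ATP demand).
    """

    a_glyc: float = 3e-3
    a_LDH: float = 4.6e-4
    a_ox: float = 2e-1
    phi_ATP: float = 0.4
    f_atp_min: float | None = None
    y_glyc: int = 2
    y_ox: int = 18
    pyr_per_glc: int = 2

    def __post_init__(self) -> None:
        for name in ("a_glyc", "a_LDH", "a_ox"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.phi_ATP <= 1:
            raise ValueError("phi_ATP must lie in (0, 1]")
        if not self.a_LDH < self.a_ox:
            raise ValueError("a_LDH < a_ox required (LDH cheaper than OXPHOS)")
        if min(self.y_glyc, self.y_ox, self.pyr_per_glc) <= 0:
            raise ValueError("yields must be positive")
        if self.f_atp_min is None:
            # default: survival demand equals maximum-yield conversion of u_G
            u_g = self.phi_ATP / (self.pyr_per_glc * self.a_ox + self.a_glyc)
            object.__setattr__(self, "f_atp_min", self.max_yield * u_g)
        elif self.f_atp_min <= 0:
            raise ValueError("f_atp_min must be positive")

    @property
    def max_yield(self) -> float:
        """ATP per glucose when every pyruvate is oxidized (38 by default)."""
        return self.y_glyc + self.pyr_per_glc * self.y_ox


@dataclass(frozen=True)
class CellFluxes:
    """Steady-state lumped fluxes of one cell (mM/min).

    ``f_ox`` and ``f_LDH`` are in pyruvate units; ``f_LDH < 0`` means lactate
    intake.  ``capped`` flags a glucose supply truncated to the single-cell
    crowding capacity ``v_G``.
    """

    f_glyc: float
    f_ox: float
    f_LDH: float
    U_G_in: float
    f_ATP: float
    capped: bool = False

    def crowding_load(self, p: MinimalModelParams) -> float:
        return (
            p.a_glyc * self.f_glyc + p.a_ox * self.f_ox + p.a_LDH * abs(self.f_LDH)
        )


@dataclass(frozen=True)
class Thresholds:
    """Characteristic glucose supplies (mM/min) of the model.

    * ``u_G``  — crowding onset: above it a single ATP-maximizing cell ferments.
    * ``v_G``  — full fermentation: the largest glucose flux one cell can process.
    * ``u_G0`` — minimum per-cell glucose supply avoiding starvation.
    * ``u_G1 = u_G + u_G0`` — onset of the lactate-subsidized regime.
    * ``u_G2`` — full glucose sequestration by the donor.
    """

    u_G: float
    v_G: float
    u_G0: float
    u_G1: float
    u_G2: float


@dataclass(frozen=True)
class TwoCellSolution:
    """Donor optimum plus the acceptor's feasible flux range at that optimum."""

    donor: CellFluxes
    acceptor_min: CellFluxes
    acceptor_max: CellFluxes
    delta_U_G: float
    regime: Regime
    U_G: float


def thresholds(params: MinimalModelParams) -> Thresholds:
    """Compute the five characteristic glucose supplies.

    ``u_G2`` follows from intersecting the acceptor-subsidy line
    ``f_LDH_don = (max_yield / y_ox) * dU`` with the donor overflow line
    evaluated at donor supply ``U_G - u_G0 + dU``, solved at ``dU = u_G0``.
    """
    p = params
    n = p.pyr_per_glc
    u_g = p.phi_ATP / (n * p.a_ox + p.a_glyc)
    v_g = p.phi_ATP / (n * p.a_LDH + p.a_glyc)
    u_g0 = p.f_atp_min / p.max_yield
    u_g1 = u_g + u_g0
    # slopes of the two f_LDH_don(dU) relations (see docs/methods.md)
    k = p.max_yield / p.y_ox
    c = (n * p.a_ox + p.a_glyc) / (p.a_ox - p.a_LDH)
    if k <= c:
        raise ValueError(
            "degenerate parameters: lactate subsidy cannot close (k <= c)"
        )
    u_g2 = u_g1 + u_g0 * (k - c) / c
    return Thresholds(u_G=u_g, v_G=v_g, u_G0=u_g0, u_G1=u_g1, u_G2=u_g2)


def single_cell_optimum(params: MinimalModelParams, U_G: float) -> CellFluxes:
    """ATP-maximizing fluxes of one isolated cell supplied with glucose ``U_G``.

    Below the crowding onset ``u_G`` all glucose is oxidized and
    ``f_ATP = max_yield * U_G``.  Between ``u_G`` and ``v_G`` the crowding
    constraint saturates and the glucose excess is diverted to LDH.  Above
    ``v_G`` the intake is capped at ``v_G`` (flagged), the excess glucose
    remaining unconsumed.
    """
    if U_G < 0:
        raise ValueError("glucose supply must be non-negative")
    p = params
    th = thresholds(p)
    capped = U_G > th.v_G
    u = min(U_G, th.v_G)
    n = p.pyr_per_glc
    if u <= th.u_G:
        f_glyc, f_ox = u, n * u
        f_ldh = 0.0
    else:
        f_glyc = u
        f_ox = (p.phi_ATP - (p.a_glyc + n * p.a_LDH) * u) / (p.a_ox - p.a_LDH)
        f_ldh = n * u - f_ox
    f_atp = p.y_glyc * f_glyc + p.y_ox * f_ox
    return CellFluxes(
        f_glyc=f_glyc, f_ox=f_ox, f_LDH=f_ldh, U_G_in=f_glyc, f_ATP=f_atp,
        capped=capped,
    )


def _donor_overflow_ldh(p: MinimalModelParams, th: Thresholds, u_don: float) -> float:
    """Lactate output of an ATP-maximizing donor with supply ``u_don > u_G``."""
    n = p.pyr_per_glc
    return (n * p.a_ox + p.a_glyc) * (u_don - th.u_G) / (p.a_ox - p.a_LDH)


def _acceptor_pinned(
    p: MinimalModelParams, g: float, lactate_in: float
) -> CellFluxes:
    """Acceptor fluxes when it runs at exactly ``f_atp_min``.

    ``g`` is its glucose intake, ``lactate_in >= 0`` the imported lactate
    (all of which is oxidized).
    """
    n = p.pyr_per_glc
    f_ox = n * g + lactate_in
    f_ldh = -lactate_in
    f_atp = p.y_glyc * g + p.y_ox * f_ox
    return CellFluxes(f_glyc=g, f_ox=f_ox, f_LDH=f_ldh, U_G_in=g, f_ATP=f_atp)


def _acceptor_max_vertex(
    p: MinimalModelParams, glc_avail: float, lac_avail: float
) -> CellFluxes:
    """ATP-maximizing acceptor given glucose and lactate caps.

    Exact vertex enumeration of the 3-variable LP over oxidized glucose,
    fermented glucose and oxidized imported lactate, subject to the glucose
    cap, the lactate cap and the acceptor's own crowding constraint.
    """
    n = p.pyr_per_glc
    vol = np.array(  # crowding volume per unit of each activity
        [p.a_glyc + n * p.a_ox, p.a_glyc + n * p.a_LDH, p.a_ox + p.a_LDH]
    )
    atp = np.array([p.max_yield, p.y_glyc, float(p.y_ox)])
    # constraints: x >= 0; x0 + x1 <= G; x2 <= L; vol . x <= phi
    A = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0], vol])
    b = np.array([glc_avail, lac_avail, p.phi_ATP])
    best, best_x = -np.inf, np.zeros(3)
    rows = [A[i] for i in range(3)] + [np.eye(3)[i] for i in range(3)]
    rhs = list(b) + [0.0, 0.0, 0.0]
    m = len(rows)
    for i in range(m):
        for j in range(i + 1, m):
            for l in range(j + 1, m):
                M = np.array([rows[i], rows[j], rows[l]])
                r = np.array([rhs[i], rhs[j], rhs[l]])
                if abs(np.linalg.det(M)) < 1e-14:
                    continue
                x = np.linalg.solve(M, r)
                if np.all(x >= -1e-12) and np.all(A @ x <= b + 1e-12):
                    val = float(atp @ x)
                    if val > best:
                        best, best_x = val, x
    g_ox, g_fer, lac = best_x
    f_glyc = g_ox + g_fer
    f_ox = n * g_ox + lac
    f_ldh = n * g_fer - lac
    return CellFluxes(
        f_glyc=f_glyc, f_ox=f_ox, f_LDH=f_ldh, U_G_in=f_glyc,
        f_ATP=p.y_glyc * f_glyc + p.y_ox * f_ox,
    )


def two_cell_solution(params: MinimalModelParams, U_G: float) -> TwoCellSolution:
    """Closed-form donor/acceptor solution at total glucose supply ``U_G``.

    The donor maximizes its ATP output subject to both cells sustaining
    ``f_atp_min``.  Four regimes arise as ``U_G`` grows:

    1. ``U_G < 2 u_G0`` — starvation (error);
    2. ``2 u_G0 <= U_G <= u_G1`` — glucose-shared: the acceptor keeps the
       glucose ``u_G0`` it needs, the donor oxidizes the rest;
    3. ``u_G1 < U_G <= u_G2`` — lactate-subsidized: the donor overflows
       lactate; each unit re-routed glucose ``dU`` must be repaid with
       ``(max_yield / y_ox) dU`` lactate to keep the acceptor alive;
    4. ``U_G > u_G2`` — full sequestration: the acceptor lives on lactate
       alone and its fluxes span a feasible range.
    """
    p = params
    th = thresholds(p)
    if U_G < 2 * th.u_G0 - 1e-12:
        raise StarvationError(
            f"U_G={U_G} cannot sustain two cells (needs >= {2 * th.u_G0})"
        )
    n = p.pyr_per_glc
    if U_G <= th.u_G1:
        donor = single_cell_optimum(p, U_G - th.u_G0)
        acc = _acceptor_pinned(p, th.u_G0, 0.0)
        return TwoCellSolution(donor, acc, acc, 0.0, Regime.GLUCOSE_SHARED, U_G)
    if U_G <= th.u_G2:
        k = p.max_yield / p.y_ox
        c = (n * p.a_ox + p.a_glyc) / (p.a_ox - p.a_LDH)
        d_u = c * (U_G - th.u_G1) / (k - c)
        donor = single_cell_optimum(p, U_G - th.u_G0 + d_u)
        lac = donor.f_LDH
        acc = _acceptor_pinned(p, th.u_G0 - d_u, lac)
        if acc.crowding_load(p) > p.phi_ATP + 1e-9:
            raise RuntimeError(
                "acceptor crowding constraint unexpectedly binding in the "
                "lactate-subsidized regime"
            )
        return TwoCellSolution(
            donor, acc, acc, d_u, Regime.LACTATE_SUBSIDIZED, U_G
        )
    # full sequestration: donor takes everything it can process
    donor = single_cell_optimum(p, U_G)
    glc_left = max(0.0, U_G - donor.U_G_in)
    lac_out = donor.f_LDH
    # acceptor minimum: survive on lactate alone (cheapest in glucose terms)
    lac_min = p.f_atp_min / p.y_ox
    acc_min = _acceptor_pinned(p, 0.0, lac_min)
    if acc_min.crowding_load(p) > p.phi_ATP + 1e-9:
        raise RuntimeError(
            "acceptor cannot sustain f_atp_min on lactate alone: its crowding "
            "constraint binds, violating the full-sequestration assumption "
            "(lower f_atp_min)"
        )
    if lac_out < lac_min - 1e-9:
        raise StarvationError(
            "donor lactate output insufficient for acceptor survival"
        )
    if glc_left <= 1e-12:
        lac_cap = min(lac_out, p.phi_ATP / (p.a_ox + p.a_LDH))
        acc_max = _acceptor_pinned(p, 0.0, lac_cap)
    else:
        acc_max = _acceptor_max_vertex(p, glc_left, lac_out)
    return TwoCellSolution(
        donor, acc_min, acc_max, th.u_G0, Regime.FULL_SEQUESTRATION, U_G
    )


# ---------------------------------------------------------------------------
# Independent LP oracle


def _lp_matrices(p: MinimalModelParams, U_G: float):
    """Shared constraint matrices of the six-flux donor/acceptor LP.

    Variable order: (g_d, ox_d, ldh_d, g_a, ox_a, ldh_a); ``ldh_a`` is split
    into + and − parts internally, giving 7 LP variables, so the acceptor's
    crowding |f_LDH| term stays linear.
    """
    n = p.pyr_per_glc
    # vars: g_d, ox_d, ldh_d, g_a, ox_a, ldh_a_pos, ldh_a_neg  (all >= 0)
    A_eq = np.array(
        [
            [n, -1.0, -1.0, 0, 0, 0, 0],  # donor pyruvate balance
            [0, 0, 0, n, -1.0, -1.0, 1.0],  # acceptor pyruvate balance
        ]
    )
    b_eq = np.zeros(2)
    atp_d = np.array([p.y_glyc, p.y_ox, 0, 0, 0, 0, 0], dtype=float)
    atp_a = np.array([0, 0, 0, p.y_glyc, p.y_ox, 0, 0], dtype=float)
    A_ub = np.array(
        [
            [1.0, 0, 0, 1.0, 0, 0, 0],  # shared glucose
            [p.a_glyc, p.a_ox, p.a_LDH, 0, 0, 0, 0],  # donor crowding
            [0, 0, 0, p.a_glyc, p.a_ox, p.a_LDH, p.a_LDH],  # acceptor crowding
            [0, 0, -1.0, 0, 0, -1.0, 1.0],  # joint lactate >= 0
            list(-atp_d),  # donor survival
            list(-atp_a),  # acceptor survival
        ]
    )
    b_ub = np.array(
        [U_G, p.phi_ATP, p.phi_ATP, 0.0, -p.f_atp_min, -p.f_atp_min]
    )
    return A_eq, b_eq, A_ub, b_ub, atp_d, atp_a


def _unpack(p: MinimalModelParams, x: np.ndarray) -> tuple[CellFluxes, CellFluxes]:
    g_d, ox_d, ldh_d, g_a, ox_a, lp_, lm_ = x
    don = CellFluxes(
        f_glyc=g_d, f_ox=ox_d, f_LDH=ldh_d, U_G_in=g_d,
        f_ATP=p.y_glyc * g_d + p.y_ox * ox_d,
    )
    acc = CellFluxes(
        f_glyc=g_a, f_ox=ox_a, f_LDH=lp_ - lm_, U_G_in=g_a,
        f_ATP=p.y_glyc * g_a + p.y_ox * ox_a,
    )
    return don, acc


def lp_oracle(params: MinimalModelParams, U_G: float) -> TwoCellSolution:
    """Solve the donor/acceptor system as an explicit linear program.

    Stage 1 maximizes donor ATP.  Stage 1b breaks the optimal-face degeneracy
    by minimizing the donor's LDH flux at fixed optimal ATP: below crowding
    saturation the donor could ferment extra glucose whose lactate the
    acceptor recycles — a futile shuttle that changes no ATP output — and the
    minimal-lactate representative is the purely oxidative donor.  Stage 2
    pins the donor and minimizes / maximizes acceptor ATP to recover the
    acceptor's feasible range.  Independent of the closed forms throughout.
    """
    p = params
    A_eq, b_eq, A_ub, b_ub, atp_d, atp_a = _lp_matrices(p, U_G)
    res = linprog(-atp_d, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if res.status != 0:
        raise StarvationError(f"two-cell LP infeasible at U_G={U_G}")
    donor_atp = -res.fun
    # stage 1b: minimal donor lactate at fixed optimal donor ATP
    ldh_d = np.zeros(7)
    ldh_d[2] = 1.0
    A_eq1 = np.vstack([A_eq, atp_d])
    b_eq1 = np.append(b_eq, donor_atp)
    res1 = linprog(ldh_d, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq1, b_eq=b_eq1,
                   bounds=(0, None), method="highs")
    if res1.status != 0:
        b_eq1[-1] = donor_atp * (1 - 1e-9)
        res1 = linprog(ldh_d, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq1, b_eq=b_eq1,
                       bounds=(0, None), method="highs")
    if res1.status != 0:
        raise RuntimeError(f"donor tie-break LP failed at U_G={U_G}")
    donor, _ = _unpack(p, res1.x)
    # stage 2: acceptor range at (numerically) fixed donor optimum
    A_eq2 = np.vstack([A_eq, atp_d, ldh_d])
    b_eq2 = np.concatenate([b_eq, [donor_atp, donor.f_LDH]])
    sols = []
    for sign in (+1.0, -1.0):
        r2 = linprog(sign * atp_a, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2,
                     b_eq=b_eq2, bounds=(0, None), method="highs")
        if r2.status != 0:  # fall back: tiny relaxation of the pinned optimum
            b_eq2[-1] = donor_atp * (1 - 1e-9)
            r2 = linprog(sign * atp_a, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2,
                         b_eq=b_eq2, bounds=(0, None), method="highs")
        if r2.status != 0:
            raise RuntimeError(f"acceptor-range LP failed at U_G={U_G}")
        sols.append(_unpack(p, r2.x)[1])
    acc_min, acc_max = sols
    th = thresholds(p)
    if U_G <= th.u_G1 + 1e-12:
        regime = Regime.GLUCOSE_SHARED
    elif U_G <= th.u_G2 + 1e-12:
        regime = Regime.LACTATE_SUBSIDIZED
    else:
        regime = Regime.FULL_SEQUESTRATION
    if regime is Regime.FULL_SEQUESTRATION:
        d_u = th.u_G0  # the acceptor's entire baseline share is re-routed
    else:
        # glucose re-routed beyond the donor's glucose-shared allotment
        d_u = max(0.0, min(th.u_G0, donor.U_G_in - (U_G - th.u_G0)))
    return TwoCellSolution(donor, acc_min, acc_max, d_u, regime, U_G)
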