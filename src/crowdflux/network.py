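"""Stoichiometric network representation, I/O, coupling and crowding rows.

A :class:`MetabolicNetwork` holds the stoichiometric matrix ``S`` (species x
reactions), per-reaction flux bounds and reversibility flags, plus a *role
map* naming the reactions that play the model's special parts (glucose
uptake, LDH, PDH/oxidation, hexokinase/glycolysis, glutaminase, ATP demand).

Two file formats are supported: SBML (read through python-libsbml) and a
plain tabular dialect, one reaction per line::

    id <TAB> reversible(0/1) <TAB> lb <TAB> ub <TAB> stoichiometry

where the stoichiometry is written as ``2 A + B --> C`` (irreversible) or
``A <=> B`` (reversible).  Exchange reactions may have an empty side.  Sign
convention: uptake reactions carry positive flux when importing, secretion
reactions positive flux when exporting.

Two replicas of a network can be coupled into a donor/acceptor pair sharing
one glucose supply with a joint non-negative lactate balance (no external
lactate source); the donor's lactate exchange is clamped to secretion only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "CrowdingSpec",
    "CoupledNetwork",
    "NetworkParseError",
    "read_network",
    "read_tabular",
    "write_tabular",
    "read_sbml",
    "minimal_as_network",
    "default_crowding_spec",
    "couple_cells",
    "crowding_rows",
    "validate_flux",
]

#: default cap standing in for "unbounded" (in units of the glucose scale)
BIG = 1.0e4


class NetworkParseError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite -> signed coefficient
    lb: float
    ub: float
    reversible: bool

    def __post_init__(self) -> None:
        for met, coeff in self.stoichiometry.items():
            if not np.isfinite(coeff) or coeff == 0:
                raise NetworkParseError(
                    f"reaction {self.id}: bad coefficient {coeff} for {met}"
                )
        if self.lb > self.ub:
            raise NetworkParseError(
                f"reaction {self.id}: lower bound {self.lb} > upper {self.ub}"
            )
        if not self.reversible and self.lb < 0:
            raise NetworkParseError(
                f"reaction {self.id}: irreversible but lb={self.lb} < 0"
            )


@dataclass
class MetabolicNetwork:
    """A stoichiometric network with bounds and named flux roles."""

    reactions: list[Reaction]
    named_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkParseError(f"duplicate reaction identifiers: {dup}")
        for role, rid in self.named_roles.items():
            if rid not in ids:
                raise NetworkParseError(
                    f"role {role!r} names unknown reaction {rid!r}"
                )

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for met in r.stoichiometry:
                seen.setdefault(met)
        return list(seen)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reversible(self) -> int:
        return sum(r.reversible for r in self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        """S with shape (n_species, n_reactions); S f = 0 at steady state."""
        species_index = {m: i for i, m in enumerate(self.species)}
        S = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[species_index[met], j] = coeff
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([r.lb for r in self.reactions]),
            np.array([r.ub for r in self.reactions]),
        )

    def index_of(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"no reaction {rid!r}") from None

    def role_index(self, role: str) -> int:
        if role not in self.named_roles:
            raise KeyError(f"role {role!r} not mapped")
        return self.index_of(self.named_roles[role])

    def exchange_ids(self) -> list[str]:
        """Reactions with a one-sided stoichiometry (uptake/secretion)."""
        out = []
        for r in self.reactions:
            signs = {np.sign(c) for c in r.stoichiometry.values()}
            if len(signs) == 1:
                out.append(r.id)
        return out

    def with_bound(self, rid: str, lb=None, ub=None) -> "MetabolicNetwork":
        """Copy of the network with one reaction's bounds replaced."""
        reactions = []
        for r in self.reactions:
            if r.id == rid:
                r = replace(
                    r,
                    lb=r.lb if lb is None else lb,
                    ub=r.ub if ub is None else ub,
                )
            reactions.append(r)
        return MetabolicNetwork(reactions, dict(self.named_roles))


@dataclass(frozen=True)
class CrowdingSpec:
    """Crowding constraint a . f <= phi over the role fluxes.

    ``coefficients`` maps roles (hexokinase, PDH or oxidation, LDH,
    glutaminase) to volume-per-flux coefficients; roles listed in
    ``absolute_value_roles`` enter as |f| (two inequality rows).
    """

    coefficients: dict[str, float]
    phi: float
    absolute_value_roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        for role, a in self.coefficients.items():
            if a < 0:
                raise ValueError(f"negative crowding coefficient for {role}")


@dataclass
class CoupledNetwork:
    """Donor/acceptor replicas sharing glucose and a joint lactate balance.

    ``shared_rows`` / ``shared_rhs`` encode extra inequalities A f <= b over
    the concatenated (donor + acceptor) flux vector.
    """

    donor: MetabolicNetwork
    acceptor: MetabolicNetwork
    shared_rows: np.ndarray
    shared_rhs: np.ndarray
    U_G_total: float

    @property
    def reactions(self) -> list[Reaction]:
        return self.donor.reactions + self.acceptor.reactions

    @property
    def reaction_ids(self) -> list[str]:
        return self.donor.reaction_ids + self.acceptor.reaction_ids

    @property
    def n_reactions(self) -> int:
        return self.donor.n_reactions + self.acceptor.n_reactions

    def stoichiometric_matrix(self) -> np.ndarray:
        Sd = self.donor.stoichiometric_matrix()
        Sa = self.acceptor.stoichiometric_matrix()
        top = np.hstack([Sd, np.zeros((Sd.shape[0], Sa.shape[1]))])
        bot = np.hstack([np.zeros((Sa.shape[0], Sd.shape[1])), Sa])
        return np.vstack([top, bot])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lbd, ubd = self.donor.bounds()
        lba, uba = self.acceptor.bounds()
        return np.concatenate([lbd, lba]), np.concatenate([ubd, uba])

    def cell_slice(self, which: str) -> slice:
        n = self.donor.n_reactions
        if which == "donor":
            return slice(0, n)
        if which == "acceptor":
            return slice(n, n + self.acceptor.n_reactions)
        raise ValueError(which)


# ---------------------------------------------------------------------------
# Tabular dialect

_ARROWS = ("<=>", "-->")


def _parse_side(text: str, rid: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise NetworkParseError(f"reaction {rid}: empty term")
        m = re.fullmatch(r"(?:([0-9.eE+-]+)\s+)?(\S+)", term)
        if not m:
            raise NetworkParseError(f"reaction {rid}: cannot parse {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coeff
    return out


def _parse_equation(eq: str, rid: str) -> tuple[dict[str, float], bool]:
    for arrow in _ARROWS:
        if arrow in eq:
            lhs, rhs = eq.split(arrow)
            stoich: dict[str, float] = {}
            for met, c in _parse_side(lhs, rid).items():
                stoich[met] = stoich.get(met, 0.0) - c
            for met, c in _parse_side(rhs, rid).items():
                stoich[met] = stoich.get(met, 0.0) + c
            stoich = {m: c for m, c in stoich.items() if c != 0}
            if not stoich:
                raise NetworkParseError(f"reaction {rid}: empty stoichiometry")
            return stoich, arrow == "<=>"
    raise NetworkParseError(f"reaction {rid}: no reaction arrow found")


def _format_side(terms: list[tuple[str, float]]) -> str:
    parts = []
    for met, c in terms:
        parts.append(met if c == 1 else f"{c:g} {met}")
    return " + ".join(parts)


def write_tabular(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the tabular dialect (plus a JSON role-map sidecar if roles set)."""
    path = Path(path)
    lines = ["# id\treversible\tlb\tub\tequation"]
    for r in net.reactions:
        lhs = [(m, -c) for m, c in r.stoichiometry.items() if c < 0]
        rhs = [(m, c) for m, c in r.stoichiometry.items() if c > 0]
        arrow = "<=>" if r.reversible else "-->"
        eq = f"{_format_side(lhs)} {arrow} {_format_side(rhs)}".strip()
        lines.append(
            f"{r.id}\t{int(r.reversible)}\t{r.lb!r}\t{r.ub!r}\t{eq}"
        )
    path.write_text("\n".join(lines) + "\n")
    if net.named_roles:
        path.with_suffix(path.suffix + ".roles.json").write_text(
            json.dumps(net.named_roles, indent=1)
        )


def read_tabular(path: str | Path) -> MetabolicNetwork:
    path = Path(path)
    reactions = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise NetworkParseError(f"{path}:{ln}: expected 5 tab fields")
        rid, rev, lb, ub, eq = parts
        stoich, arrow_rev = _parse_equation(eq, rid)
        reversible = bool(int(rev))
        if reversible != arrow_rev:
            raise NetworkParseError(
                f"{path}:{ln}: reversible flag and arrow disagree for {rid}"
            )
        reactions.append(
            Reaction(rid, stoich, float(lb), float(ub), reversible)
        )
    roles_path = path.with_suffix(path.suffix + ".roles.json")
    roles = json.loads(roles_path.read_text()) if roles_path.exists() else {}
    return MetabolicNetwork(reactions, roles)


# ---------------------------------------------------------------------------
# SBML

def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML Level 2/3 model.

    Bounds are taken from fbc flux bounds when present, otherwise from
    kinetic-law parameters named ``LOWER_BOUND`` / ``UPPER_BOUND``; missing
    bounds default to [0, BIG] (irreversible) or [-BIG, BIG] (reversible).
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise NetworkParseError(
            f"libsbml: {doc.getError(0).getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkParseError("SBML file contains no model")
    fbc = model.getPlugin("fbc")
    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    boundary = {
        model.getSpecies(i).getId()
        for i in range(model.getNumSpecies())
        if model.getSpecies(i).getBoundaryCondition()
    }
    reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            sr = rxn.getReactant(j)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = (
                stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
            )
        for j in range(rxn.getNumProducts()):
            sr = rxn.getProduct(j)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = (
                stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}
        reversible = rxn.getReversible()
        lb, ub = (-BIG if reversible else 0.0), BIG
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.getLowerFluxBound():
            lb = params.get(rfbc.getLowerFluxBound(), lb)
            ub = params.get(rfbc.getUpperFluxBound(), ub)
        elif rxn.isSetKineticLaw():
            kl = rxn.getKineticLaw()
            for k in range(kl.getNumParameters()):
                kp = kl.getParameter(k)
                if kp.getId() == "LOWER_BOUND":
                    lb = kp.getValue()
                elif kp.getId() == "UPPER_BOUND":
                    ub = kp.getValue()
        lb, ub = max(lb, -BIG), min(ub, BIG)
        if not stoich:
            continue  # pure boundary exchange with no internal species
        reactions.append(
            Reaction(rxn.getId(), stoich, lb, ub, reversible or lb < 0)
        )
    return MetabolicNetwork(reactions)


def read_network(path: str | Path) -> MetabolicNetwork:
    """Read SBML (.xml/.sbml) or the tabular dialect (anything else)."""
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        return read_sbml(path)
    return read_tabular(path)


# ---------------------------------------------------------------------------
# Minimal-model fixture network

def minimal_as_network(
    params=None,
    *,
    U_G: float = BIG,
    atp_min: float = 0.0,
    reversible_ldh: bool = False,
) -> MetabolicNetwork:
    """The coarse-grained cell as a 4-species / 6-reaction network.

    Reactions: glucose uptake, lumped glycolysis (glc -> 2 pyr + 2 atp),
    lumped oxidation (pyr -> 18 atp), LDH (pyr -> lac, reversible on
    request), lactate exchange, ATP demand.  ``U_G`` caps glucose uptake and
    ``atp_min`` sets the survival lower bound on the ATP demand.
    """
    from crowdflux.minimal_model import MinimalModelParams

    p = params or MinimalModelParams()
    n, yg, yo = p.pyr_per_glc, p.y_glyc, p.y_ox
    ldh_lb = -BIG if reversible_ldh else 0.0
    lac_lb = -BIG if reversible_ldh else 0.0
    reactions = [
        Reaction("GLC_in", {"glc": 1.0}, 0.0, U_G, False),
        Reaction(
            "GLYC", {"glc": -1.0, "pyr": float(n), "atp": float(yg)},
            0.0, BIG, False,
        ),
        Reaction("OX", {"pyr": -1.0, "atp": float(yo)}, 0.0, BIG, False),
        Reaction("LDH", {"pyr": -1.0, "lac": 1.0}, ldh_lb, BIG, reversible_ldh),
        Reaction("LAC_out", {"lac": -1.0}, lac_lb, BIG, reversible_ldh),
        Reaction("ATP_demand", {"atp": -1.0}, atp_min, BIG, False),
    ]
    roles = {
        "glucose_uptake": "GLC_in",
        "hexokinase": "GLYC",
        "PDH": "OX",
        "LDH": "LDH",
        "lactate_exchange": "LAC_out",
        "atp_demand": "ATP_demand",
    }
    return MetabolicNetwork(reactions, roles)


def default_crowding_spec(params=None) -> CrowdingSpec:
    """Crowding spec with the coarse-grained coefficients mapped onto roles.

    ``a_GLUN`` defaults to ``a_PDH`` (both are mitochondrial volume-occupying
    fluxes); LDH is an absolute-value role so lactate-importing cells are
    charged for reverse flux too.
    """
    from crowdflux.minimal_model import MinimalModelParams

    p = params or MinimalModelParams()
    return CrowdingSpec(
        coefficients={
            "hexokinase": p.a_glyc,
            "PDH": p.a_ox,
            "LDH": p.a_LDH,
            "glutaminase": p.a_ox,
        },
        phi=p.phi_ATP,
        absolute_value_roles=("LDH",),
    )


# ---------------------------------------------------------------------------
# Coupling

def _suffix_network(net: MetabolicNetwork, suffix: str) -> MetabolicNetwork:
    reactions = [
        Reaction(
            r.id + suffix,
            {m + suffix: c for m, c in r.stoichiometry.items()},
            r.lb, r.ub, r.reversible,
        )
        for r in net.reactions
    ]
    roles = {k: v + suffix for k, v in net.named_roles.items()}
    return MetabolicNetwork(reactions, roles)


def couple_cells(
    net: MetabolicNetwork, U_G_total: float, *, symmetric: bool = False
) -> CoupledNetwork:
    """Build a donor/acceptor pair from two replicas of ``net``.

    The donor's lactate exchange (and LDH) is clamped to secretion only
    unless ``symmetric``; the acceptor's is made reversible.  Shared rows:
    the two glucose uptakes are bounded by ``U_G_total`` and the joint
    lactate secretion is non-negative (no external lactate source).
    """
    for role in ("glucose_uptake", "lactate_exchange"):
        if role not in net.named_roles:
            raise KeyError(f"couple_cells requires the {role!r} role")
    donor = _suffix_network(net, "_don")
    acceptor = _suffix_network(net, "_acc")

    def _set_lactate(cell: MetabolicNetwork, reversible: bool, roles):
        for role in roles:
            if role not in cell.named_roles:
                continue
            rid = cell.named_roles[role]
            r = cell.reactions[cell.index_of(rid)]
            lb = -BIG if reversible else max(0.0, r.lb)
            cell.reactions[cell.index_of(rid)] = replace(
                r, lb=lb, reversible=reversible
            )

    # an importing cell needs both a reversible exchange and a reversible LDH;
    # the donor's internal reactions are left untouched (secretion-only exchange)
    _set_lactate(donor, symmetric, ("lactate_exchange", "LDH") if symmetric
                 else ("lactate_exchange",))
    _set_lactate(acceptor, True, ("lactate_exchange", "LDH"))
    # donor glucose must not exceed the shared pool on its own either
    n_tot = donor.n_reactions + acceptor.n_reactions
    glc = np.zeros(n_tot)
    glc[donor.role_index("glucose_uptake")] = 1.0
    glc[donor.n_reactions + acceptor.role_index("glucose_uptake")] = 1.0
    lac = np.zeros(n_tot)
    lac[donor.role_index("lactate_exchange")] = -1.0
    lac[donor.n_reactions + acceptor.role_index("lactate_exchange")] = -1.0
    shared_rows = np.vstack([glc, lac])  # glc_d+glc_a <= U_G; -(lac_d+lac_a) <= 0
    shared_rhs = np.array([U_G_total, 0.0])
    # cap each uptake by the pool as an explicit bound too
    for cell in (donor, acceptor):
        rid = cell.named_roles["glucose_uptake"]
        idx = cell.index_of(rid)
        r = cell.reactions[idx]
        cell.reactions[idx] = replace(r, ub=min(r.ub, U_G_total))
    return CoupledNetwork(donor, acceptor, shared_rows, shared_rhs, U_G_total)


# ---------------------------------------------------------------------------
# Crowding rows

def crowding_rows(
    net: MetabolicNetwork | CoupledNetwork, spec: CrowdingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Linear rows (A, b) with A f <= b encoding the crowding constraint.

    Roles flagged as absolute-value produce two rows (one per sign of the
    role flux); their conjunction equals the |f| form exactly.  For a coupled
    network each cell gets its own constraint.
    """
    if isinstance(net, CoupledNetwork):
        Ad, bd = crowding_rows(net.donor, spec)
        Aa, ba = crowding_rows(net.acceptor, spec)
        n_d, n_a = net.donor.n_reactions, net.acceptor.n_reactions
        rows = [np.concatenate([row, np.zeros(n_a)]) for row in Ad]
        rows += [np.concatenate([np.zeros(n_d), row]) for row in Aa]
        return np.array(rows), np.concatenate([bd, ba])
    base = np.zeros(net.n_reactions)
    abs_indices = []
    for role, a in spec.coefficients.items():
        if role not in net.named_roles:
            continue
        idx = net.role_index(role)
        # |f| handling only matters when the flux can actually go negative
        if role in spec.absolute_value_roles and net.reactions[idx].lb < 0:
            abs_indices.append((idx, a))
        else:
            base[idx] += a
    rows, rhs = [], []
    n_abs = len(abs_indices)
    for signs in range(2 ** n_abs):
        row = base.copy()
        for k, (idx, a) in enumerate(abs_indices):
            row[idx] += a if (signs >> k) & 1 == 0 else -a
        rows.append(row)
        rhs.append(spec.phi)
    return np.array(rows), np.array(rhs)


# ---------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class FluxReport:
    """Diagnostic report from :func:`validate_flux`."""

    max_balance_residual: float
    bound_violations: list[tuple[str, float]]
    crowding_slack: float | None
    shared_slack: float | None
    tol: float

    @property
    def ok(self) -> bool:
        worst = self.max_balance_residual
        if self.bound_violations:
            worst = max(worst, max(v for _, v in self.bound_violations))
        for slack in (self.crowding_slack, self.shared_slack):
            if slack is not None:
                worst = max(worst, -min(slack, 0.0))
        return worst <= self.tol


def validate_flux(
    net: MetabolicNetwork | CoupledNetwork,
    f: np.ndarray,
    tol: float = 1e-8,
    crowding: CrowdingSpec | None = None,
) -> FluxReport:
    """Check mass balance, bounds, crowding and shared rows for one vector."""
    f = np.asarray(f, dtype=float)
    if f.shape != (net.n_reactions,):
        raise ValueError(
            f"flux vector has shape {f.shape}, expected ({net.n_reactions},)"
        )
    S = net.stoichiometric_matrix()
    residual = float(np.max(np.abs(S @ f))) if S.size else 0.0
    lb, ub = net.bounds()
    ids = net.reaction_ids
    violations = []
    for i, (lo, hi) in enumerate(zip(lb, ub)):
        excess = max(lo - f[i], f[i] - hi)
        if excess > tol:
            violations.append((ids[i], float(excess)))
    crowding_slack = None
    if crowding is not None:
        A, b = crowding_rows(net, crowding)
        crowding_slack = float(np.min(b - A @ f))
    shared_slack = None
    if isinstance(net, CoupledNetwork):
        shared_slack = float(np.min(net.shared_rhs - net.shared_rows @ f))
    return FluxReport(residual, violations, crowding_slack, shared_slack, tol)
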