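"""Derived quantities: ATP production, pathway fractions, scans, correlations.

Conventions:

* "ATP production" of a cell is the flux through its ATP-demand reaction; at
  steady state production equals consumption, so this avoids double counting
  over the many ATP-generating reactions of a large network.
* Pathway fractions are normalized by the *pyruvate equivalent* — the sum of
  imported lactate and ``pyr_per_glc`` times the glucose intake — so the
  fermentative and oxidative fractions add to one wherever defined.
* Standard errors of chain averages use batch means (the samples of a Markov
  chain are correlated even after thinning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crowdflux.network import (
    CoupledNetwork,
    CrowdingSpec,
    MetabolicNetwork,
    couple_cells,
)
from crowdflux.polytope import (
    EmptyInteriorError,
    InfeasiblePolytopeError,
    FluxPolytope,
    round_polytope,
    rref_reduce,
    find_interior_point,
)
from crowdflux.sampler import SampleSet, SamplerConfig, hit_and_run

__all__ = [
    "ScanResult",
    "CorrelationMatrix",
    "atp_flux",
    "atp_objective",
    "pathway_fractions",
    "glucose_scan",
    "beta_scan",
    "pearson_matrix",
    "batch_means_sem",
]


def atp_objective(net: MetabolicNetwork | CoupledNetwork, cell: str = "donor") -> np.ndarray:
    """Indicator vector of the ATP-demand flux (the donor's, if coupled)."""
    w = np.zeros(net.n_reactions)
    if isinstance(net, CoupledNetwork):
        half = net.donor if cell == "donor" else net.acceptor
        off = 0 if cell == "donor" else net.donor.n_reactions
        w[off + half.role_index("atp_demand")] = 1.0
    else:
        w[net.role_index("atp_demand")] = 1.0
    return w


def atp_flux(f: np.ndarray, net: MetabolicNetwork | CoupledNetwork, cell: str = "donor") -> float:
    """ATP production of one cell: its ATP-demand reaction's flux."""
    return float(atp_objective(net, cell) @ np.asarray(f, dtype=float))


def pathway_fractions(
    f: np.ndarray,
    net: MetabolicNetwork,
    pyr_per_glc: float = 2.0,
    atp_weighted: bool = False,
    y_glyc: float = 2.0,
    y_ox: float = 18.0,
) -> tuple[float | None, float | None]:
    """(fermentative, oxidative) fractions of the pyruvate equivalent.

    The pyruvate equivalent is ``pyr_per_glc * glucose_in + lactate_in``.
    With ``atp_weighted`` the split is instead by ATP contribution
    (``y_glyc`` per glucose-derived pair via glycolysis, ``y_ox`` per
    oxidized pyruvate).  Returns ``(None, None)`` when the pyruvate
    equivalent vanishes.
    """
    f = np.asarray(f, dtype=float)
    glc = f[net.role_index("glucose_uptake")]
    ldh = f[net.role_index("LDH")]
    pdh = f[net.role_index("PDH")]
    lac_in = max(0.0, -ldh)
    if atp_weighted:
        glyc_part = y_glyc * glc
        ox_part = y_ox * pdh
        total = glyc_part + ox_part
    else:
        glyc_part = max(0.0, ldh)  # pyruvate drained to fermentation
        ox_part = pdh
        total = pyr_per_glc * glc + lac_in
    if total <= 1e-12:
        return None, None
    return glyc_part / total, ox_part / total


def batch_means_sem(series: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of the mean of a correlated series via batch means."""
    x = np.asarray(series, dtype=float)
    n = x.size
    n_batches = min(n_batches, n)
    usable = (n // n_batches) * n_batches
    if usable < 2 * n_batches:
        return float(x.std(ddof=1) / np.sqrt(max(n - 1, 1)))
    means = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


@dataclass
class ScanResult:
    """Per-grid-point chain statistics of selected fluxes."""

    grid: np.ndarray
    grid_name: str
    stats: pd.DataFrame  # one row per grid point
    infeasible: list[float] = field(default_factory=list)

    def column(self, name: str) -> np.ndarray:
        return self.stats[name].to_numpy()


def _sample_network(
    net: MetabolicNetwork | CoupledNetwork,
    crowding: CrowdingSpec | None,
    config: SamplerConfig,
    rounding_seed: int,
) -> SampleSet:
    poly = rref_reduce(net, crowding=crowding)
    center = find_interior_point(poly)
    ell = round_polytope(poly, seed=rounding_seed, center=center)
    return hit_and_run(poly, config, start=ell.center, rounding=ell)


def _flux_stats(
    ss: SampleSet, net: MetabolicNetwork | CoupledNetwork
) -> dict[str, float]:
    out: dict[str, float] = {}

    def add(prefix: str, cell: MetabolicNetwork):
        for role in ("glucose_uptake", "LDH", "PDH", "atp_demand"):
            if role not in cell.named_roles:
                continue
            col = ss.column(cell.named_roles[role])
            out[f"{prefix}{role}_mean"] = float(col.mean())
            out[f"{prefix}{role}_sem"] = batch_means_sem(col)

    if isinstance(net, CoupledNetwork):
        add("donor_", net.donor)
        add("acceptor_", net.acceptor)
    else:
        add("", net)
    return out


def glucose_scan(
    net: MetabolicNetwork,
    glucose_grid: np.ndarray,
    config: SamplerConfig,
    crowding: CrowdingSpec | None = None,
    coupled: bool = False,
    symmetric: bool = False,
    atp_min: float = 0.0,
) -> ScanResult:
    """Sample the network across a grid of glucose supplies.

    For each grid value the glucose cap is set (couple into a donor/acceptor
    pair when ``coupled``), the polytope is rebuilt, rounded and sampled,
    and means/standard errors of the role fluxes are recorded.  Infeasible
    grid points (below survival) are flagged and skipped.

    Because the network is rebuilt per grid point, a fixed objective vector
    would be ill-defined; passing any non-``None`` ``config.objective``
    requests the Boltzmann bias on the (donor) ATP-demand flux instead.
    """
    rows = []
    infeasible = []
    glc_id = net.named_roles["glucose_uptake"]
    for i, u_g in enumerate(np.asarray(glucose_grid, dtype=float)):
        if coupled:
            target = couple_cells(net, u_g, symmetric=symmetric)
        else:
            target = net.with_bound(glc_id, ub=u_g)
        cfg = SamplerConfig(
            n_samples=config.n_samples, burn_in=config.burn_in,
            thinning=config.thinning, beta=config.beta,
            objective=(None if config.objective is None
                       else atp_objective(target)),
            seed=config.seed + i,
        )
        try:
            ss = _sample_network(target, crowding, cfg, rounding_seed=cfg.seed)
        except (InfeasiblePolytopeError, EmptyInteriorError):
            infeasible.append(float(u_g))
            continue
        row = {"U_G": float(u_g), **_flux_stats(ss, target)}
        rows.append(row)
    stats = pd.DataFrame(rows)
    return ScanResult(np.asarray(glucose_grid, float), "U_G", stats, infeasible)


def beta_scan(
    net: MetabolicNetwork | CoupledNetwork,
    beta_grid: np.ndarray,
    config: SamplerConfig,
    crowding: CrowdingSpec | None = None,
    lp_fraction_target: float = 0.98,
) -> ScanResult:
    """Mean ATP production versus the bias strength beta.

    Also reports (in ``stats.attrs``) the LP maximum of the objective and the
    smallest grid beta whose mean reaches ``lp_fraction_target`` of it.
    """
    poly = rref_reduce(net, crowding=crowding)
    center = find_interior_point(poly)
    ell = round_polytope(poly, seed=config.seed, center=center)
    objective = (atp_objective(net) if config.objective is None
                 else np.asarray(config.objective, float))
    lp_max, _ = poly.lp_optimum(objective)
    rows = []
    for i, beta in enumerate(np.asarray(beta_grid, dtype=float)):
        cfg = SamplerConfig(
            n_samples=config.n_samples, burn_in=config.burn_in,
            thinning=config.thinning, beta=float(beta), objective=objective,
            seed=config.seed + i,
        )
        ss = hit_and_run(poly, cfg, start=ell.center, rounding=ell)
        vals = ss.samples @ objective
        rows.append({
            "beta": float(beta),
            "atp_mean": float(vals.mean()),
            "atp_sem": batch_means_sem(vals),
            "lp_fraction": float(vals.mean() / lp_max) if lp_max else np.nan,
        })
    stats = pd.DataFrame(rows)
    stats.attrs["lp_max"] = lp_max
    reached = stats[stats["lp_fraction"] >= lp_fraction_target]
    stats.attrs["beta_at_target"] = (
        float(reached["beta"].iloc[0]) if len(reached) else None
    )
    return ScanResult(np.asarray(beta_grid, float), "beta", stats, [])


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over a flux selection."""

    flux_ids: list[str]
    r: np.ndarray
    zero_variance: list[str] = field(default_factory=list)

    def block(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = [self.flux_ids.index(i) for i in rows]
        ci = [self.flux_ids.index(i) for i in cols]
        return self.r[np.ix_(ri, ci)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.flux_ids, columns=self.flux_ids)


def pearson_matrix(
    samples: SampleSet, flux_ids: list[str] | None = None
) -> CorrelationMatrix:
    """Sample Pearson correlation matrix over the selected fluxes.

    Zero-variance (pinned) fluxes get zero rows/columns — correlating a
    constant is undefined and pinned fluxes carry no information — with unit
    diagonal retained; they are listed in ``zero_variance``.
    """
    ids = flux_ids or list(samples.reaction_ids)
    if samples.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = np.column_stack([samples.column(i) for i in ids])
    sd = X.std(axis=0)
    scale = np.mean(np.abs(X), axis=0) + 1e-300
    pinned = sd / scale < 1e-10
    r = np.zeros((len(ids), len(ids)))
    live = ~pinned
    if live.sum() >= 2:
        r_live = np.corrcoef(X[:, live].T)
        r[np.ix_(live, live)] = np.clip(r_live, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        flux_ids=list(ids), r=r,
        zero_variance=[i for i, p in zip(ids, pinned) if p],
    )
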