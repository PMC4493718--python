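"""Bundled fixtures, experiment configuration and summary reports.

Every fixture is generated deterministically from code — nothing is shipped
as data.  The minimal-cell fixtures mirror the coarse-grained model's
stoichiometry (glucose -> 2 pyruvate + 2 ATP; pyruvate -> 18 ATP; pyruvate
<-> lactate), so the sampler can be validated against its closed forms; the
geometric fixtures (triangle, anisotropic box) have analytic moments used by
the sampler and rounding tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from crowdflux.minimal_model import MinimalModelParams, thresholds
from crowdflux.network import (
    CoupledNetwork,
    MetabolicNetwork,
    couple_cells,
    default_crowding_spec,
    minimal_as_network,
    write_tabular,
)
from crowdflux.polytope import FluxPolytope

__all__ = [
    "FIXTURE_NAMES",
    "ExperimentConfig",
    "make_fixture",
    "two_cell_test_params",
    "run_report",
]

FIXTURE_NAMES = (
    "minimal-single",
    "minimal-two-cell",
    "triangle-toy",
    "anisotropic-box",
)


def two_cell_test_params() -> MinimalModelParams:
    """Reference parameters for donor/acceptor experiments.

    The survival demand is half the single-cell maximum at crowding onset
    (``f_atp_min = 19 u_G``, i.e. ``u_G0 = u_G / 2``): at the printed
    coefficients this is the regime in which all four glucose-supply regimes
    of the two-cell model exist (at ``f_atp_min = 38 u_G`` the acceptor's
    own crowding constraint forbids survival on lactate alone).
    """
    base = MinimalModelParams()
    u_g = thresholds(base).u_G
    return MinimalModelParams(f_atp_min=19.0 * u_g)


@dataclass
class ExperimentConfig:
    """Validated description of one reproducible experiment."""

    network: str = "minimal-single"  # fixture name or file path
    coupled: bool = False
    symmetric: bool = False
    U_G: float = 1.0
    beta: float = 0.0
    n_samples: int = 2000
    seed: int = 1234
    atp_min: float = 0.0
    glucose_grid: list[float] = field(default_factory=list)
    beta_grid: list[float] = field(default_factory=list)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.network not in FIXTURE_NAMES and not Path(self.network).exists():
            raise ValueError(
                f"network {self.network!r} is neither a fixture name "
                f"({', '.join(FIXTURE_NAMES)}) nor an existing file"
            )
        if self.n_samples < 1 or self.beta < 0 or self.seed < 0:
            raise ValueError("invalid sampler settings")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**json.loads(Path(path).read_text()))


def _box_polytope(widths: list[float]) -> FluxPolytope:
    D = len(widths)
    ids = [f"x{i}" for i in range(D)]
    A = np.vstack([np.eye(D), -np.eye(D)])
    b = np.concatenate([np.asarray(widths, float), np.zeros(D)])
    return FluxPolytope(ids, ids, np.eye(D), np.zeros(D), A, b)


def make_fixture(
    name: str,
    out_dir: str | Path | None = None,
    U_G: float = 10.0,
    atp_min: float = 0.0,
):
    """Build a named fixture; optionally write its files to ``out_dir``.

    Returns a :class:`MetabolicNetwork`, :class:`CoupledNetwork` or
    :class:`FluxPolytope` depending on the fixture.
    """
    if name == "minimal-single":
        obj = minimal_as_network(MinimalModelParams(), U_G=U_G, atp_min=atp_min)
    elif name == "minimal-two-cell":
        params = two_cell_test_params()
        base = minimal_as_network(params, U_G=U_G, atp_min=params.f_atp_min)
        obj = couple_cells(base, U_G)
    elif name == "triangle-toy":
        # x, y >= 0, x + y <= 1: marginals are Beta(1, 2)
        ids = ["x", "y"]
        A = np.array([[1.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        b = np.array([1.0, 0.0, 0.0])
        obj = FluxPolytope(ids, ids, np.eye(2), np.zeros(2), A, b)
    elif name == "anisotropic-box":
        obj = _box_polytope([1.0, 1.0e4])
    else:
        raise ValueError(f"unknown fixture {name!r}; know {FIXTURE_NAMES}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if isinstance(obj, MetabolicNetwork):
            write_tabular(obj, out_dir / f"{name}.tsv")
        elif isinstance(obj, CoupledNetwork):
            write_tabular(obj.donor, out_dir / f"{name}-donor.tsv")
            write_tabular(obj.acceptor, out_dir / f"{name}-acceptor.tsv")
            np.savetxt(out_dir / f"{name}-shared-rows.csv",
                       np.column_stack([obj.shared_rows, obj.shared_rhs]),
                       delimiter=",")
        else:
            obj.to_json(out_dir / f"{name}.json")
    return obj


def run_report(results_dir: str | Path) -> dict:
    """Summarize scan outputs found in a results directory.

    Reads the ``glucose_scan.csv`` / ``beta_scan.csv`` files written by the
    examples (pandas CSVs of :class:`~crowdflux.analysis.ScanResult` stats)
    and reports yields, threshold estimates and the beta ladder.  Raises
    ``FileNotFoundError`` listing the expected files when none is present.
    """
    import pandas as pd

    results_dir = Path(results_dir)
    expected = ["glucose_scan.csv", "beta_scan.csv"]
    found = [f for f in expected if (results_dir / f).exists()]
    if not found:
        raise FileNotFoundError(
            f"no scan outputs in {results_dir}; expected any of {expected}"
        )
    report: dict = {"directory": str(results_dir)}
    params = MinimalModelParams()
    th = thresholds(params)
    if "glucose_scan.csv" in found:
        df = pd.read_csv(results_dir / "glucose_scan.csv")
        atp_col = next(
            (c for c in ("atp_demand_mean", "donor_atp_demand_mean")
             if c in df), None,
        )
        if atp_col:
            yields = df[atp_col] / df["U_G"]
            report["yield_low_glucose"] = float(yields.iloc[0])
            report["yield_high_glucose"] = float(yields.iloc[-1])
            # crowding onset: largest grid point whose yield is still >90%
            # of the maximum observed yield
            near_max = df["U_G"][yields >= 0.9 * yields.max()]
            report["estimated_crowding_onset"] = float(near_max.max())
            # u_G depends only on the crowding coefficients, not on the
            # survival demand, so it is a valid reference for any scan
            report["reference_u_G"] = th.u_G
    if "beta_scan.csv" in found:
        df = pd.read_csv(results_dir / "beta_scan.csv")
        report["beta_ladder"] = df[["beta", "lp_fraction"]].to_dict("records")
        reached = df[df["lp_fraction"] >= 0.98]
        report["beta_at_98pct"] = (
            float(reached["beta"].iloc[0]) if len(reached) else None
        )
    return report
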