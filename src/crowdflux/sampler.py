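"""Hit-and-Run sampling of flux polytopes with a Boltzmann objective bias.

The chain samples the reduced polytope ``{x : A x <= b}`` under the measure

    P(f) ∝ exp(beta * L(f)),

where ``L`` is a linear functional of the full flux vector (e.g. the ATP
demand flux) and ``beta >= 0`` interpolates between uniform exploration of
every feasible flux state (beta = 0) and maximization of ``L`` (beta → ∞).
Each step draws an isotropic direction *under the rounding-ellipsoid metric*
(a normalized standard-normal vector — the Marsaglia-Bray construction —
pushed through the ellipsoid's Cholesky factor), intersects the line with
the polytope, and picks the new point along the chord from the exact
one-dimensional restriction of ``P``: uniform at beta = 0, a truncated
exponential otherwise, drawn by inverse CDF in log-domain form so that even
``beta * slope * chord_length ~ 1e3`` cannot overflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from crowdflux.polytope import FluxPolytope, RoundingEllipsoid, chord, find_interior_point

__all__ = [
    "SamplerConfig",
    "SampleSet",
    "hit_and_run",
    "chord_sample",
    "autocorrelation_time",
]


@dataclass
class SamplerConfig:
    """Knobs of one sampling run.

    ``objective`` is a vector over *full* fluxes defining ``L(f)``; ``None``
    means uniform sampling regardless of beta.  ``burn_in`` and ``thinning``
    default to 10 D^2 and D respectively — conservative choices given only
    order-of-magnitude mixing guidance for rounded polytopes.
    """

    n_samples: int = 1000
    burn_in: int | None = None
    thinning: int | None = None
    beta: float = 0.0
    objective: np.ndarray | None = None
    seed: int = 1234
    retry_cap: int = 100

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class SampleSet:
    """Sampled flux vectors plus the metadata needed to reproduce them."""

    samples: np.ndarray  # (n_samples, n_reactions) full flux vectors
    independent_samples: np.ndarray  # (n_samples, D)
    reaction_ids: list[str]
    config: SamplerConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def mean(self, rid: str) -> float:
        return float(self.column(rid).mean())

    def write_csv(self, path: str | Path) -> None:
        """CSV of flux vectors plus a JSON sidecar with config/diagnostics."""
        path = Path(path)
        header = ",".join(self.reaction_ids)
        np.savetxt(path, self.samples, delimiter=",", header=header, comments="")
        cfg = {
            "n_samples": self.config.n_samples,
            "burn_in": self.config.burn_in,
            "thinning": self.config.thinning,
            "beta": self.config.beta,
            "seed": self.config.seed,
            "objective": (None if self.config.objective is None
                          else np.asarray(self.config.objective).tolist()),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(cfg))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSet":
        path = Path(path)
        with open(path) as fh:
            ids = fh.readline().strip().split(",")
        samples = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        meta = side.pop("meta", {})
        obj = side.pop("objective", None)
        cfg = SamplerConfig(
            **{k: v for k, v in side.items() if k in
               ("n_samples", "burn_in", "thinning", "beta", "seed")},
            objective=None if obj is None else np.array(obj),
        )
        return cls(samples, np.zeros((samples.shape[0], 0)), ids, cfg, meta)


def chord_sample(
    t_min: float,
    t_max: float,
    beta: float,
    slope: float,
    rng: np.random.Generator,
) -> float:
    """Draw t from the density ∝ exp(beta * slope * t) on [t_min, t_max].

    Exact inverse-CDF draw, formulated in log domain: with
    ``w = beta * slope * (t_max - t_min)`` the standardized quantile is
    ``log(1 + u (e^w - 1)) / w``, computed as ``1 + log(u + (1-u) e^-w)/w``
    for w > 0 (never exponentiating a positive number), and via
    ``log1p(u expm1(w))/w`` for w < 0 (where ``expm1`` saturates at -1).
    """
    if t_min > t_max:
        raise ValueError("empty chord")
    width = t_max - t_min
    w = beta * slope * width
    u = rng.random()
    if abs(w) < 1e-12:
        frac = u
    elif w > 0:
        frac = 1.0 + np.log(u + (1.0 - u) * np.exp(-w)) / w
    else:
        frac = np.log1p(u * np.expm1(w)) / w
    return t_min + width * float(np.clip(frac, 0.0, 1.0))


def hit_and_run(
    poly: FluxPolytope,
    config: SamplerConfig,
    start: np.ndarray | None = None,
    rounding: RoundingEllipsoid | None = None,
) -> SampleSet:
    """Run the (possibly Boltzmann-biased) Hit-and-Run chain.

    Fully reproducible given ``config.seed``; the objective's directional
    slope along each chord is exact (the functional is pushed through the
    affine map, no finite differences).
    """
    D = poly.dimension
    rng = np.random.default_rng(config.seed)
    burn_in = 10 * D * D if config.burn_in is None else config.burn_in
    thinning = max(1, D if config.thinning is None else config.thinning)
    L = np.eye(D) if rounding is None else rounding.cholesky
    x = np.asarray(find_interior_point(poly) if start is None else start,
                   dtype=float).copy()
    if not poly.contains(x, tol=1e-7):
        raise ValueError("start point is not inside the polytope")
    g = (None if config.objective is None
         else poly.reduce_objective(config.objective))
    total = burn_in + config.n_samples * thinning
    out = np.empty((config.n_samples, D))
    kept = 0
    degenerate_retries = 0
    for step in range(total):
        for attempt in range(config.retry_cap + 1):
            d = L @ rng.standard_normal(D)
            d /= np.linalg.norm(d)
            t_min, t_max = chord(poly, x, d)
            if t_max - t_min > 1e-13:
                break
            degenerate_retries += 1
        else:
            raise RuntimeError(
                f"no usable chord after {config.retry_cap} retries "
                "(interior point too close to the boundary)"
            )
        slope = 0.0 if g is None else float(g @ d)
        t = chord_sample(t_min, t_max, config.beta, slope, rng)
        x = x + t * d
        if step >= burn_in and (step - burn_in) % thinning == thinning - 1:
            out[kept] = x
            kept += 1
    assert kept == config.n_samples
    full = poly.to_full(out)
    meta = {
        "burn_in": burn_in,
        "thinning": thinning,
        "degenerate_retries": degenerate_retries,
        "dimension": D,
    }
    return SampleSet(full, out, list(poly.reaction_ids), config, meta)


def autocorrelation_time(series: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time by self-consistent windowing.

    ``tau = 1 + 2 sum_k rho_k`` summed over the window ``k < c * tau``
    (Sokal's criterion).  White noise gives tau ≈ 1; an AR(1) chain with
    coefficient phi gives (1 + phi) / (1 - phi).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("series too short for a meaningful estimate (< 100)")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return 1.0
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[:n] / n
    rho = acov / var
    tau = 1.0
    for k in range(1, n):
        tau += 2.0 * rho[k]
        if k >= c * tau:
            break
    return float(max(tau, 1e-12))
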