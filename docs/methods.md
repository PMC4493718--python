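# Methods

`crowdflux` models how a finite intracellular volume budget for ATP-producing
enzymes (macromolecular crowding) shapes the energetic strategy of one cell,
and how it couples two cells — a lactate *donor* and a lactate *acceptor* —
sharing a glucose supply. It has two layers: an exactly solvable
coarse-grained model, and a constraint-based sampling pipeline for arbitrary
stoichiometric networks.

## The coarse-grained model

Each cell carries three lumped fluxes (mM/min): glycolysis `f_glyc` (one
glucose → `pyr_per_glc` pyruvate + `y_glyc` ATP; defaults 2 and 2),
oxidation `f_ox` (one pyruvate → `y_ox` ATP; default 18), and LDH `f_LDH`
(pyruvate ↔ lactate; negative flux = lactate import). Steady state imposes
the pyruvate balance

    f_ox + f_LDH = pyr_per_glc · f_glyc,

ATP accounting `f_ATP = y_glyc f_glyc + y_ox f_ox`, and the crowding
constraint

    a_glyc f_glyc + a_ox f_ox + a_LDH |f_LDH| ≤ Φ_ATP,

with volume-per-flux coefficients `a_glyc = 3·10⁻³`, `a_LDH = 4.6·10⁻⁴`,
`a_ox = 0.2` min/mM and budget `Φ_ATP = 0.4` (empirical estimates for human
cells; oxidation is ~70× more volume-hungry per unit flux than glycolysis).

**Single cell.** An ATP-maximizing cell oxidizes everything
(`f_ATP = 38 U_G`) while its supply stays below the crowding onset
`u_G = Φ/(2 a_ox + a_glyc) ≈ 0.993`. Above `u_G` the constraint saturates:
`f_ox = (Φ − (a_glyc + 2 a_LDH) U_G)/(a_ox − a_LDH)` and the glucose excess
overflows to lactate — aerobic glycolysis. At
`v_G = Φ/(2 a_LDH + a_glyc) ≈ 102` the cell is fully fermentative (yield 2);
larger supplies are capped at `v_G` and flagged.

**Two cells.** Both cells must sustain a survival flux `f_atp_min`, defining
the per-cell minimum supply `u_G0 = f_atp_min/38`. Four regimes arise as the
shared supply `U_G` grows:

1. **starved** (`U_G < 2 u_G0`): infeasible, raised as an error;
2. **glucose-shared** (`≤ u_G1 = u_G + u_G0`): the acceptor keeps `u_G0`,
   the donor oxidizes the rest;
3. **lactate-subsidized** (`u_G1 < U_G ≤ u_G2`): the donor overflows; each
   re-routed glucose `ΔU_G` must be repaid with `k ΔU_G` lactate
   (`k = 38/18`) to keep the acceptor alive. Intersecting this with the
   donor's overflow line `f_LDH = c (U_don − u_G)`,
   `c = (2 a_ox + a_glyc)/(a_ox − a_LDH)`, gives
   `ΔU_G = c (U_G − u_G1)/(k − c)` and
   `u_G2 = u_G1 + u_G0 (k − c)/c`;
4. **full sequestration** (`U_G > u_G2`): the acceptor's glucose share is
   zero and its fluxes span a feasible range (lactate intake between
   `f_atp_min/18` and the smaller of the donor's output and its own
   crowding cap `Φ/(a_ox + a_LDH)`; leftover glucose past the donor's `v_G`
   cap re-opens glucose to the acceptor, handled by exact vertex
   enumeration of the 3-variable acceptor program).

The piecewise solution requires `k > c` (at the defaults `k ≈ 2.11 >
c ≈ 2.02`); parameter sets violating this are rejected as degenerate.

**Survival demand.** The package default is `f_atp_min = 38 u_G` (one
crowding-onset supply converted at maximum yield), matching the convention
used for large networks. At that demand, however, the acceptor *cannot*
survive on lactate alone — the lactate-only ATP ceiling is
`18 Φ/(a_ox + a_LDH) ≈ 35.9 < 37.7` — so the subsidized/full-sequestration
closed forms do not exist and `two_cell_solution` raises rather than return
an infeasible state. Two-cell fixtures and examples therefore use
`f_atp_min = 19 u_G` (`u_G0 = u_G/2`), chosen once as the regime in which
all four regimes exist; see `two_cell_test_params()`.

**LP oracle and the futile-shuttle degeneracy.** `lp_oracle` solves the
six-flux donor/acceptor program with an off-the-shelf LP solver, entirely
independently of the closed forms. The donor-ATP optimum is degenerate on a
face: because `2 + 2·18 = 38`, the donor may ferment extra glucose (gaining
`2 dg`) while the acceptor swaps `38 dg` of glucose-ATP for `36 dg` of
lactate-ATP — exactly ATP-neutral. The oracle breaks the tie
lexicographically (minimal donor LDH at fixed optimal ATP), which selects
the natural no-futile-shuttle representative the closed forms describe; the
closed form and oracle then agree to ~1e-14 across all regimes. The same
degeneracy is a *physical* feature of the sampled network model: at large β
the Boltzmann measure averages over the whole face, so sampled donor LDH in
the subsidized window is face-averaged (it lies inside `[k ΔU_G, k u_G0]`)
while face-invariant quantities — donor ATP, acceptor ATP — match the
closed form tightly. Hit-and-Run additionally mixes slowly *along* such a
face; conclusions drawn from high-β samples should rest on face-invariant
observables.

## The network pipeline

**Representation and I/O.** `MetabolicNetwork` stores reactions with signed
stoichiometry maps, bounds, reversibility and a role map naming the special
fluxes (glucose uptake, hexokinase, PDH, LDH, glutaminase, lactate exchange,
ATP demand). SBML Level 2/3 is read through libsbml (fbc bounds or
kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters); a one-line-per-reaction
tab-separated dialect (`id, reversible, lb, ub, equation`) covers plain-text
exchange with a JSON role-map sidecar. Sign convention: uptakes are positive
when importing, secretions positive when exporting. "Unbounded" bounds are
capped at `1e4` (in glucose-supply units) so the sampled polytope is always
bounded.

**Crowding rows.** The general constraint
`a_glyc f_HEX + a_PDH f_PDH + a_LDH |f_LDH| + a_GLUN f_GLUN ≤ Φ` is encoded
as one row when LDH is secretion-only and as the exact two-row conjunction
`±a_LDH f_LDH` when LDH is reversible. `a_GLUN` is not independently
estimated; it defaults to `a_PDH` (both mitochondrial volume-occupying
fluxes) and is configurable.

**Coupling.** `couple_cells` replicates a network into suffixed donor and
acceptor copies. The only asymmetry is lactate: the donor's exchange is
clamped to secretion, the acceptor's exchange and LDH are made reversible
(a `symmetric` flag removes the asymmetry). Two shared inequality rows are
added: total glucose uptake ≤ `U_G`, and joint lactate secretion ≥ 0 (no
external lactate source).

**Reduction.** `rref_reduce` brings the stoichiometric matrix to reduced
row echelon form over exact rationals (floating point with pivot tolerance
1e-9 beyond 200k entries), splitting fluxes into pivot (dependent) and free
(independent) sets — the split is unique given the reaction ordering. All
inequalities are rewritten over the `D = N − rank(S)` independent
coordinates; the reconstructed full vectors satisfy `S f = 0` to ≤1e-10.

**Interior point and rounding.** A strictly interior start is the Chebyshev
center (an LP), with an iterative most-violated-constraint relaxation as
fallback; an empty interior (Chebyshev radius ≤ 1e-9) and outright
infeasibility raise distinct errors. The rounding ellipsoid is estimated by
iterative covariance rounding (3 rounds × 2000 uniform steps by default):
sample under the current metric, re-estimate the covariance, re-transform.
Flux polytopes are strongly anisotropic (axis ratios ~1e4 on realistic
networks); under the learned metric the transformed body is O(1)-round and
the chain's autocorrelation time drops by orders of magnitude.

**Sampling.** Hit-and-Run draws a direction as a normalized standard-normal
vector pushed through the ellipsoid's Cholesky factor, computes the exact
chord through all inequalities, and picks the next point from the chord
restriction of `P(f) ∝ exp(β L(f))` by inverse CDF. The one-dimensional
draw is computed in log-domain form (`1 + log(u + (1−u)e^{−w})/w` for
`w = β·slope·width > 0`), stable for arbitrarily large `|w|`. Defaults:
burn-in `10 D²`, thinning `D` — conservative, since only order-of-magnitude
mixing guidance exists; both configurable. Chains are bit-reproducible given
the seed. Degenerate chords are retried up to 100 times (thin facets occur
at regime boundaries).

**Analysis.** ATP production is the flux through the ATP-demand reaction
(steady-state production = consumption; avoids double counting). Pathway
fractions are normalized by the pyruvate equivalent (`2·glucose + imported
lactate`), with an ATP-weighted variant (2 per glucose glycolytic, 18 per
pyruvate oxidative). Scans rebuild, re-round and re-sample the polytope per
grid point (seeded per point); standard errors use batch means (20 batches)
because chain samples remain correlated after thinning. Pearson matrices
are exact sample correlations; pinned (zero-variance) fluxes get zero
rows/columns with unit diagonal, and are listed in `zero_variance`.

## What the fixtures do and do not establish

The bundled fixtures mirror the coarse-grained stoichiometry exactly
(glucose → 2 pyruvate + 2 ATP; pyruvate → 18 ATP; pyruvate ↔ lactate), so
sampler output can be validated against closed forms: LP maxima, the β → ∞
limit, shuttle signs and thresholds. They do *not* emulate the
combinatorial richness of a genome-scale network: with only two degrees of
freedom per cell, nutrient-scarcity alone already couples every flux pair,
so the donor–acceptor correlation block is near its ceiling throughout the
scarce regimes and only its *decay* at glucose excess (`U_G ≥ 2 v_G`) is
informative. The low-glucose *dilution* of mean |r| reported for large
networks (most flux pairs uncorrelated below the overflow threshold)
requires a high-dimensional network such as the deposited 67-metabolite /
75-reaction human core catabolic model, which this package reads from SBML
when supplied but does not bundle.

## Numerical choices

- Mass-balance residual tolerance 1e-8 in `validate_flux`; crowding slack
  reported signed.
- Closed-form vs oracle agreement asserted at 1e-6 relative (achieved:
  ~1e-14).
- LP solves use HiGHS throughout.
- Zero-variance Pearson convention `r := 0` (flagged), since pinned fluxes
  carry no linear information.
- Chebyshev-radius interior threshold `ε = 1e-9`; rounding covariance
  regularized by `1e-12 · tr(C)/D · I`.

## Known limitations

- No dynamics: steady states only; at most two coupled cells.
- The acceptor's feasible range is reported at the *tie-broken* donor
  optimum; other points of the degenerate optimal face are equally optimal
  for the donor (see above).
- Loop-free networks are assumed (the fixture networks are loop-free by
  construction); no infeasible-loop removal is performed.
- Biomass-style objectives are supported as arbitrary linear functionals
  over named reactions; no curated biomass coefficient vector ships with
  the package.
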