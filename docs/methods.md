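# Methods

## Scope and model structure

`tritrace` simulates the seasonal uptake of four trace metals (Cu, Pb, Cd,
Ni) by a wheat plant resolved into four compartments — root, stem, leaf,
grain — coupled to a logistic growth model. The state of the system is the
metal concentration C_i (mg/kg fresh mass) of each compartment; soil and
atmospheric pools are treated as constant boundary conditions over one
season (no depletion feedback, no multi-season carryover).

### Growth

Each compartment follows the closed-form logistic trajectory
M_i(t) = M_max/(1 + ((M_max − M_0)/M_0) e^(−G (t − t_e))) with parameters
(M_0, M_max, G) per part and an emergence day t_e (0 for the vegetative
parts, 50 d for grain). The logistic clock starts at emergence; mass is
identically zero before it. Germination lag is not modelled separately —
the initial masses are already near-zero — but t_e is configurable per part.
The default root growth coefficient (G = 0.0075 d⁻¹) is an order of
magnitude below the shoot coefficients, which places the root's logistic
inflection far beyond a single season: root mass is still well below its
asymptote at harvest. The value is exposed in the config rather than
corrected, and the long-horizon fixed-point checks integrate to 1500 d so
every compartment actually reaches its plateau.

Sap fluxes are not printed in any source we can ship, so the package uses
the simplest scheme consistent with the observed orderings: xylem flux
proportional to compartment mass, Q_up = q·M(t) with a per-part coefficient
q (L kg⁻¹ d⁻¹), and phloem flux a fixed fraction φ < 1 of it. This
guarantees Q_down ≤ Q_up at all times and reproduces the qualitative flux
hierarchy (root largest upward, grain smallest). The proportionality has a
convenient consequence: every inter-part hop rate Q_j/(K_iw M_j) = q_j/K_iw
is constant in time, so the only time dependence left in the balance
equation is the 1/M_i(t) dilution factor.

### Transfer network

Metal moves along a fixed directed network: soil → root → stem → {leaf,
grain} upward, and leaf → stem → root downward (phloem re-export);
atmosphere deposits directly on leaf and grain. Elementary rates:

* inter-part hop i→j: Q_j/(K_iw M_j), with the receiving part's flux
  (xylem for upward edges, phloem for downward) and the source part's
  water partition coefficient;
* soil→root: (Q + A_R f_c D_R)/(M_S K_SW) — advective (transpiration) plus
  diffusive entry, exactly additive;
* atmosphere→surface: A P (1 − f_P) + A v_dep f_P — metabolic permeation of
  the gas-phase fraction plus particulate deposition of the adsorbed
  fraction (units m³/d; multiplied by C_A when used as a source).

Serial pathways are composed multiplicatively: the first stage keeps its
native units and each later stage enters as the dimensionless efficiency
r·τ, with τ a reference time defaulting to 1 d. The underlying literature
lists pathway chains without an explicit composition operator; the
multiplicative rule is the package's choice — it preserves serial-pathway
semantics, is monotone in every stage, and reduces to the identity for
one-stage chains. τ is exposed in the config. The per-part loss rate k_i is
the sum of the part's outgoing elementary rates; grain has no outgoing edge,
so k_grain = 0 and grain concentration has no fixed point under a constant
source (it keeps accumulating, slowly, as 1/M saturates).

### Accumulation balance

dC_i/dt = [r_S−i (C_S + C_t) W_i + r_A−i C_A]/M_i(t) − k_i C_i, integrated
verbatim. Two structural caveats are worth making explicit rather than
papering over:

* the loss term k_i C_i has **no matched gain** in the receiving
  compartment — inter-compartment mass is not conserved by construction;
  metal reaching a part always arrives through its composed source chain;
* the soil source term is not dimensionally closed against mg kg⁻¹ d⁻¹
  without absorbing a conversion into the composed rate. The package
  implements the formula as stated, declares units on every config
  parameter, and refuses mixed-unit input rather than rescaling silently.

Integration is fixed-step RK4 (default dt = 0.5 d, horizon 160 d), with
coefficients sampled on a half-step grid and Euler retained for
cross-checks. Coefficients jump at grain emergence; because the emergence
day lies on the grid, the integrator uses left-limit coefficients for the
stage that ends a step there and re-initialises a newly emerged compartment
to zero concentration. This keeps the dt-halving convergence of every
trajectory below 1e-4 relative despite the discontinuity. On numerical
failure the step is halved and retried twice before raising. The equation
is linear in (C_S, C_t, C_A); trajectories are homogeneous of degree one in
the sources, which the test suite exploits heavily.

The Monte Carlo and per-site prediction paths reuse one precomputed
coefficient schedule and integrate all replicates as a vectorised state —
arithmetic identical to a per-draw loop (asserted by a test against
individual `simulate` calls).

## Default parameters

Growth parameters (M_0, M_max, G per part) are field-typical values for
winter wheat. Everything else in the default configuration — geometry,
partition coefficients, fluxes, atmospheric parameters — is a documented
**placeholder**: the literature sources behind such parameter inventories do
not print usable values, and the original survey data are not public. The
placeholder set was calibrated once, by hand, to reproduce the robust
qualitative orderings reported for field wheat (root ≫ leaf > stem; root >
grain; soil-water partition ranking Cd most mobile, Pb least) and is not
fitted to any measurement. Consequently the package's simulated
concentrations are structurally meaningful (orderings, linearity, dynamics)
but their absolute magnitudes are not comparable to any survey table.
Every parameter carries a unit and a provenance tag (`this study` /
literature / `placeholder`); the loader validates units against the schema
and warns whenever a placeholder is actually exercised.

## Verification statistics

RMS, V_DR, CV and F_DR are computed per (metal, part) group over sites,
averaged over parts within each metal, then averaged equally over metals.
The standard deviation inside CV is the sample SD (n−1) by default, with the
population variant behind a flag. C_wheat in BCF_sw is the **sum** of the
four part concentrations: the mean-of-parts reading fails to reproduce the
published factor table, while sum-of-parts reproduces all eight values at
two-decimal rounding — that arithmetic check ships as a test.

## Monte Carlo verification

Only the soil concentration is randomised, mirroring the observation that
soil totals vary strongly between sites while atmospheric levels do not.
Logs of the soil totals are fitted with a normal law; the fit is gated by a
one-sample K-S test at p > 0.05 against the fitted parameters (no Lilliefors
correction for estimated parameters — deliberately, matching the simple
gate; the omission makes the gate conservative toward acceptance and is
noted here). Draws are exp(x); each site's soluble and exchangeable pools
scale proportionally with the drawn total, preserving the configured
fraction ratios. With the atmospheric source switched off the model output
is an exact lognormal with the input log-SD; with it on, compartments with a
non-negligible air share follow a *shifted* lognormal (constant offset), so
lognormality checks target the soil-dominated root compartment or a
zero-atmosphere configuration. Ensemble densities use a Gaussian KDE with
Silverman bandwidth; measured histograms use Freedman–Diaconis bins; the
overlap coefficient is the common area of the two densities.

## Spatial stage

The empirical semivariogram bins squared differences into equal-width lags
up to half the maximum pairwise distance (extended to the full distance for
degenerate layouts where that rule would discard every pair). Model fitting
is weighted least squares in two stages — pair counts first, then Cressie's
n/γ² weights about the first-stage curve — with parameters bounded to the
data scale (range ≤ twice the largest lag), which keeps the flat
pure-nugget case identifiable. Spherical, exponential and gaussian shapes
use the practical-range convention. Ordinary kriging solves the standard
(n+1) system with a Lagrange multiplier; weights sum to one by construction
and the surface is exact at sample sites when the nugget is zero. Duplicate
coordinates are rejected with the offending site pairs rather than jittered.
Site-level validation extracts predictions at measured sites (leave-nothing-
out by default, leave-one-out available) and classifies |pred − meas|/meas
into half-open bands [0, 0.25), [0.25, 0.5), [0.5, ∞). Coordinates are
assumed planar metric; inputs that look like lon/lat degrees trigger a
warning.

## Synthetic surveys

The generator emulates the *shape* of a watershed survey — by default 52
sites, 32 with mature wheat — not any real landscape. Site coordinates are
uniform over a 5 × 5 km extent; per-metal log-concentrations follow a
Gaussian process with exponential covariance (range 1 km by default),
exponentiated to a lognormal field whose medians sit near published regional
soil means; soluble/exchangeable pools are fixed fractions (0.2% / 1%) of
the total at a configurable 1 L/kg soil-solution ratio. Tissue
"measurements" are the model's own predictions times mean-one multiplicative
lognormal noise at CV 0.3 (a typical field-replicate spread). Because the
measurements are model-derived, passing the downstream agreement and
overlay tests demonstrates the *pipeline's* correctness and calibration
machinery — not predictive skill against real field data, which would
require the unpublished survey measurements.

## Problem sizes and numerical defaults

Default simulations run 160 d at dt = 0.5 (321 grid points); long-horizon
fixed-point checks use 1500 d; Monte Carlo ensembles use 10,000 replicates;
synthetic surveys 52 sites; kriging grids 50 × 50. These sizes keep a full
pipeline run in seconds on one core while leaving Monte Carlo standard
errors and variogram fits well inside the tolerances the tests assert.
Variogram range recovery from a single 200-site realisation is inherently
noisy (roughly ±30%); the tests pin fixed seeds and the spread is documented
here rather than hidden.

## Known limitations

* No phytotoxic feedback of metal burden on growth; no temperature, water
  or phenology response.
* No speciation/chelation chemistry; K_SW carries all soil-chemistry
  dependence and is a scalar per metal.
* Soil pools constant over the season; no irrigation or deposition inputs.
* The atmosphere pathway for root and stem passes through leaf re-export
  without depleting the leaf's own uptake (no conservation, see above).
* Placeholder parameter magnitudes — structural results only.
* No anisotropy or co-kriging; geographic coordinates must be pre-projected.
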