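# Methods

## The model

`surfcol` is an individual-based model of early bacterial surface
colonization under periodic desiccation stress.  The habitat is a square
surface of side 1 mm (periodic boundaries) topped by a well-mixed bulk
fluid.  Each bacterium is either **planktonic** (foraging in the fluid)
or **sessile** (attached to the surface).  Time advances in steps of
`dt` = 0.05 h over `n_days` = 5 diel cycles; each 24 h cycle opens with
`H` = 12 wet hours followed by 12 dry hours.  The hydration state is

    W(t) = 1  if mod(t, 24) <= H   (wet),  else 0  (dry).

Setting `stress_mode="constant"` makes the surface permanently dry,
which is the control regime for separating the effect of periodicity
from that of mean stress.

### Growth and division

Cell biomass follows Monod kinetics on a single shared nutrient pool
c(t) (g·m⁻³):

    m(t + dt) = (1 − f)·m(t)·exp(μ_max · c/(c + K_s) · dt) + f·m(t)

with μ_max = 0.4 h⁻¹ and K_s = 0.3 g·m⁻³.  Sessile cells divert a
fraction f = 0.5 of biomass to EPS, which does not compound — their
effective growth rate is roughly half the planktonic rate.  That is the
growth half of the planktonic–biofilm tradeoff.  A cell divides when its
mass reaches its personal division threshold, drawn once at birth as
M_div·(1 + U(−0.1, 0.1)) around the mean division mass M_div = 2·10⁻¹²
g; the jitter desynchronizes division waves.  Both halves of a division
receive mass m/2, fresh thresholds and the parent's lineage label
(lineages are indexed by founder).  A sessile daughter is placed one
cell diameter away in a uniform random direction and then shoved into
the packing; a planktonic daughter is co-located with its parent (both
are remixed by motion in the next step anyway).

Each division consumes C_div = 3·10⁻¹³ g of nutrient, debited from the
shared pool; the pool relaxes toward an infinite source of
concentration N_c at permeation rate k_perm = 0.1 h⁻¹:

    c(t + dt) = max(0, c + k_perm·(N_c − c)·dt − n_divisions·C_div / V_water)

with V_water = 0.1 mm³.  Nutrient is a single scalar: no spatial
gradients.  Runs start with c = N_c (equilibrium with the source) and
N0 = 100 planktonic founders at uniform random positions.  N_c defaults
to 30 g·m⁻³; it is the main environmental fertility axis and is scanned
in the phase-plane experiments.

### Stress and death

The local density Q of a cell is the number of sessile cells within the
sensing radius R = 10 μm (minimum-image metric).  The hourly death
probability has three regimes:

    Q <  Q_L : (1 − W)·S_L + S_B     unprotected — desiccation when dry
    Q >= Q_H : S_H + S_B             overcrowded — regardless of hydration
    else     : S_B                   protected

with defaults S_L = 0.4, S_H = 0.3, S_B = 0.025 h⁻¹, Q_L = 40,
Q_H = 75.  Collective protection is the biofilm half of the tradeoff:
only cells inside sufficiently dense aggregates survive dry periods at
the background rate.  Planktonic cells always use Q = 0 — they are
solitary foragers in the bulk and enjoy no aggregate protection (the
alternative, letting cells that hover above an aggregate inherit its
protection, is a documented sensitivity question; it is off here).

### Lifestyle transitions

Sessile cells detach at the constant rate D = 0.01 h⁻¹.  Planktonic
cells attach according to their strategy:

* **RA (random attachment)** — constant probability A_RA per hour,
  independent of the surroundings.
* **PA (preferential attachment)** — a step-like Hill response to the
  local sessile density at the cell's position:

      A(Q) = (A_PA − a_ra) / ((Q_PA / Q)^n + 1) + a_ra

  rising from the RA baseline a_ra to the ceiling A_PA = 0.5 per time
  step as Q crosses the threshold Q_PA.  The Hill exponent n (default
  10) sets the steepness; n ≥ ~8 makes the response effectively a step.
  Q = 0 returns the baseline exactly (the limit of the expression).

Note the unit convention: A_PA is specified per *time step* while A_RA
and all death/detachment rates are per *hour*.  Hourly probabilities are
converted to the scheduler with the compounding rule

    p_step = 1 − (1 − p_hourly)^dt,

never p·dt, so survival multiplies correctly over any window.  The same
arithmetic underlies the constant-stress equivalence transform

    S' = 1 − (1 − S)^(H_dry / T),

which maps a periodic dry-period death rate S to the constant rate S'
with identical unprotected survival per cycle (e.g. S = 0.45 over 12 h
↦ S' ≈ 0.26 over 24 h).

### Space and mechanics

Sessile cells are hard discs of diameter 1 μm in a single layer.
Overlaps created by attachment or division are resolved by *shoving*:
pairs closer than the diameter are pushed apart symmetrically along
their center line, iterated until no pair overlaps by more than 1% of
the diameter.  The relaxation is a deterministic worklist Gauss–Seidel
scheme on a uniform bin grid, seeded at newly placed cells, so a shove
cascade spreads exactly as far as the mechanics require; coincident
cells separate along a fixed golden-angle direction so the mechanics
consume no randomness.  Aggregates are the connected components of the
contact graph at contact distance 1.2 μm.

Planktonic motion defaults to `well_mixed`: positions are redrawn
uniformly every step.  At the nominal swimming speed (V ≈ 50 μm·s⁻¹) a
cell covers V·dt = 9 mm per step — nine domain lengths — so persistent
ballistic motion is indistinguishable from remixing.  A `bounded_walk`
mode (one random step of length ≤ V·dt, wrapped) is retained for
sensitivity analyses.  This choice matters: under well-mixed foraging
the total attachment flux to qualifying sites scales with their summed
capture area, which favors strategies that certify many sites (see
*Limitations*).

### Scheduler

Each step applies, in fixed order: (1) hydration state; (2) planktonic
motion; (3) local-density evaluation against the sessile surface as it
stood at the start of the step; (4) transitions — attachment draws for
planktonic cells (with the density from 3), detachment draws for cells
sessile at step start, then shoving; (5) growth and division; (6) death
draws using per-step probabilities (sessile cells use the step's
densities; daughters born in 5 are scored against the same start-of-step
surface); (7) nutrient update with the step's division count.  The
order is a modelling commitment, not a physical statement; at
dt = 0.05 h the per-step probabilities are small enough that
re-orderings change nothing detectable.

Determinism: a run is a pure function of (parameters, seed).  All
randomness flows from one `numpy` PCG64 generator in a fixed draw
order; replicate r of an experiment uses seed base_seed + r.  The
death draw is taken for every cell and the local density is then
evaluated only for cells whose draw could possibly kill them — an exact
shortcut, not an approximation.

## What the experiments measure

*Population yield* — live cells at the end of the last dry period — is
the fitness measure.  `scan_strategy` maximizes mean yield over a
one-parameter strategy grid (ties break toward the smaller value);
`phase_plane` compares the best RA against the best PA per
(N_c, S_L) cell and classifies zones: `extinct`, `equal` (ratio within
10% of 1), `PA-favored`/`RA-favored`, and `PA-only` when every RA rate
goes extinct in at least 80% of replicates while PA persists — the
niche-extension signature.  Common random numbers (same seed block per
grid point) tighten paired comparisons.

## Problem sizes

Full study conditions are five diel cycles, N0 = 100, 1 mm² domain;
single runs take seconds to ~10 s depending on final population size
(10³–10⁴ cells).  The bundled test suite and the acceptance script use
these full conditions for single-condition quantities (vacant-site
attachment fractions, zone-a extinction, threshold scans at 5
replicates) and reduced designs for the expensive grids: 2×2
environmental grids with two-point strategy grids and 2 replicates for
the region-mean comparisons, and 10 replicates for extinction
fractions.  Standard errors are reported everywhere; trend claims are
tested as trends, not per-point equalities.

## Known limitations

* **Well-mixed foraging.**  Because every planktonic cell samples a
  fresh uniform position each step, attachment flux to aggregates is
  proportional to their total capture area rather than
  encounter-limited.  Low attachment thresholds therefore certify many
  sites and the yield optimum sits at low Q_PA under the default steep
  response (n = 10); with gentler response steepness (n ≤ 4) the
  optimum moves into the interior of the threshold range
  (Q_PA ≈ 4–16) but high-threshold strategies then retain enough
  residual attraction to build protected aggregates.  Encounter-limited
  (diffusive) foraging would change this allocation and is out of
  scope.
* **High random-attachment rates.**  With A_RA far above the
  detachment rate the population is sessile-dominated, grows at the
  EPS-discounted rate and is unprotected in dry periods; such
  populations collapse within the first cycles, so statistics
  conditioned on their long-term persistence (e.g. attachment-site
  occupancy late in a run) are dominated by the early colonization
  window.
* Nutrient is well-mixed: no local depletion under dense aggregates, so
  aggregate size is capped by overcrowding death alone.
* Single-layer mechanics: no 3D growth; shoving resolves overlaps but
  aggregates have no cohesion and never translocate as units.
* The synthetic environment is the model itself — there is no external
  data; passing tests demonstrate internal consistency and reproduction
  of the model's documented phenomenology, not agreement with any
  particular organism.
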