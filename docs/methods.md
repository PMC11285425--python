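# Methods

## Model summary and assumptions

The model couples two periodic 1-D lattices of N columns. The lower layer is
a chain of well-mixed surface habitats where a bacterial host grows
logistically and a lytic phage preys on it by mass action; the upper layer is
a purely physical atmosphere that advects at a constant speed and decays, with
no replication or predation aloft. The layers exchange biomass vertically in
an intermittent, stochastic fashion parameterized by (p, j0, τ): every window
of length τ each (column, species) pair independently becomes active with
probability p, and an active pair exchanges biomass down the vertical density
gradient at rate j0 for the duration of the window (j_up = j0·n_s,
j_down = j0·n_a, net j_n = j_up − j_down). Populations are effectively
integer: any density strictly below ρ_ext = 1/V (one individual per grid box)
is set to zero, in both layers, at window ends.

Assumptions inherited from this construction: lytic infection only (no
lysogeny); well-mixed boxes (no intra-habitat structure); constant wind and
per-species-identical (p, j0); exchange uncorrelated across species and
windows; a single limiting resource folded into the logistic term. Species-
specific emission parameters are accepted by the data structures but the
defaults keep them equal.

### Deterministic skeleton

With continuous loss r = p·j0 (the τ→0 limit of intermittent pure loss) the
local system

    dn_s/dt = g n_s (1 − n_s/K) − η n_s m_s − r n_s
    dm_s/dt = (β−1) η n_s m_s − δ_s m_s − r m_s

has the coexistence fixed point n_s* = (δ_s+r)/((β−1)η),
m_s* = (g(1−n_s*/K)−r)/η, feasible while r < g and n_s* < K(1−r/g); for
r ≥ g even a phage-free habitat is drained (the "deterministically unstable"
region, with boundary p·j0 = g). At the fixed point the Jacobian reduces to
[[−g n_s*/K, −η n_s*], [(β−1)η m_s*, 0]]; in the oscillatory regime the
eigenvalues are −g n_s*/(2K) ± iω, giving the perturbation-relaxation time

    τ_per = 2K/(g n_s*) = 2K(β−1)η/(g(δ_s+r)) ∝ 1/δ_s  (closed system: r = 0).

These closed forms are cross-checked in the tests against independent
numerical root-finding and eigen-decomposition.

### The critical trajectory

With an extinction floor ρ_ext > 0, the safe set around the fixed point is
bounded by a deterministic separatrix: initial states outside it transiently
dip below ρ_ext before the spiral can relax. The safe set at fixed n_s is an
*interval* of phage densities around m_s* — a very small arriving dose blooms
and crashes the host exactly like a very large one, because the transient
amplitude is set by the distance from the fixed point in either direction.
`critical_trajectory` therefore locates the upper boundary by bisection from
a safe seed found near m_s*, and reports 0 where no safe dose ≥ ρ_ext exists.
At n_s = K no arrival is safe for the default parameters: the host trough of
the ensuing bloom is ~8·10⁻³ individuals per box, four orders of magnitude
below the floor. This doom-at-capacity property is parameter-dependent — it
requires a deep fixed point, roughly n_s*/K ≲ 0.05 at K/ρ_ext = 10⁵ — and
that requirement pins the default δ_s given (β, η, K).

## Parameters

Canonical values live in `aerophage.constants` and nowhere else.

Full scale (SI): g = 1.2e-5 s⁻¹ (host generation ≈ 1 day), K = 1e5 per box
(V = 1, ρ_ext = 1), β = 50, η = 2e-12 box volumes s⁻¹, δ_s = 4e-7 s⁻¹
(surface half-life ≈ 20 days), v = 1 m s⁻¹, Δx = 10 m, τ = 600 s, N = 1000;
experiment-specific transport values as printed in the figure fixtures
(e.g. the connected mosaic: p = 1e-4, j0 = 6e-3 s⁻¹, L = 0.5; competition:
(p, j0) = (1e-4, 3.2e-3 s⁻¹), L = 0.1; horizons of 150/350 years with
50-year burn-in).

Desk scale: the unit of time is one host generation (g = 1) and τ = 1. The
set preserves the dimensionless groups that govern the dynamics:

| group                                   | desk | full |
|-----------------------------------------|------|------|
| β                                       | 50   | 50   |
| K/ρ_ext                                 | 1e5  | 1e5  |
| n_s*/K = δ_s/((β−1)ηK)                  | 0.04 | 0.041|
| kick size j0·τ                          | 3    | 3.6  |
| mean loss p·j0/g                        | 0.03 | 0.05 |
| events per relaxation time p·τ_per/τ    | 0.5  | 0.68 |
| plume transit L·N·Δx/(v·τ) (windows)    | 10   | 8.3  |

The desk activation probability per window (p = 0.01) is necessarily larger
than the full-scale one (1e-4) because a desk window spans a much larger
fraction of τ_per; the per-relaxation-time event rate, which is what the
dynamics feel, matches. Desk lattices use N = 200 columns and horizons of a
few thousand generations — sizes chosen so every experiment runs in seconds
to ~1 minute in pure numpy.

## Numerics

* **Window stepping.** Operator split per window: draw the activity mask;
  jointly integrate each column's surface equations with the same-column
  atmospheric exchange (fixed-step RK4, default 40 substeps per window;
  an adaptive per-window DOP853 mode is available and used where 1e-6
  agreement with reference integrations is asserted); advect and decay the
  atmosphere; apply the threshold; log events. Vertical exchange is a linear
  invariant of the within-window system, so Runge–Kutta conserves two-layer
  column mass exactly; advection is an exact periodic shift and decay an
  exact exponential factor.
* **Sub-window advection.** The atmosphere shifts one column per leg,
  v·τ/Δx legs per window, with exchange integrated within each leg. A single
  end-of-window shift of k columns would let a plume interact only with every
  k-th column (the residue classes of gcd(k, N)); the interleaved form lets a
  plume exchange with each column it passes, which is the finer discretization
  of the continuous transport equations.
* **Threshold convention.** "Drops below" is strict: a density exactly at
  ρ_ext survives. The threshold applies in both layers at window ends (the
  connectivity calibration assumes atmospheric densities below ρ_ext are
  lost).
* **Continuous-rate flux closure.** Exchange follows the instantaneous
  gradient throughout an active window rather than freezing the window-start
  densities; this makes the p = 1 limit reduce exactly to the continuous-loss
  equations and keeps densities non-negative.
* **Negative-density guard.** Surface and atmospheric fields are clipped at
  zero after each substep; legitimate trajectories approach zero only
  exponentially, so clipping acts on solver round-off.
* **ODE tolerances.** Deterministic analyses (fixed points, critical
  trajectories, reference integrations) use adaptive solvers at rtol 1e-8 /
  atol 1e-12 by default, tightened in tests where the assertion demands it.
  Critical-region classification integrates 20·τ_per with terminal
  zero-crossing events at the floor; the bisection tolerance is 1e-6 relative.
* **RNG.** One Philox stream per run, seeded from the master seed; the
  activity mask is drawn in a single (species × columns) call per window, and
  the p = 0/1 degenerate cases still consume a draw so parameter sweeps stay
  stream-aligned. Runs are bit-reproducible per (config, seed); experiment
  drivers spawn child seeds in a fixed order, so sweeps are reproducible and
  embarrassingly parallel.

## Initialization

Surface hosts start at U(0, K], each phage strain at U(0, 2·m_s*], the
atmosphere empty ("random" init). Ensemble extinction studies start at the
loss-shifted fixed point ("fixed_point") so extinction times measure the
escape from the steady state rather than the initial transient. Two-strain
competition runs use a "mosaic" init — each column carries exactly one of the
strains — because seeding the near-immortal strong competitor
(δ_s → 0) into *every* column crashes every host column in the first
oscillation and extinguishes the whole lattice before any spatial dynamics
can act; the mosaic represents an assembled community in which the strains
meet through migration.

## Event bookkeeping

Habitat classes are derived from surface presence after thresholding:
C (host and ≥1 phage), F (host only), E (no host; a phage-only column is
classed E because the phage is merely decaying there). Label changes are
logged per window with same-window deposition flags. A same-window E→C
change — possible only through simultaneous, independent host and phage
deposition — is decomposed into E→F then F→C records, so a direct E→C
transition never appears in any event log.

The migration-outcome statistic counts windows with active net-downward
phage flux into a column labelled F whose phage population is present at the
window end (at least one individual arrived); the outcome is "extinction" if
the column reaches E within 20·τ_per of the event, the window in which the
post-migration deterministic transient resolves. Sub-threshold arrivals are
excluded from the denominator by default (`established_only=False` includes
them); with the default fixtures the statistic moves by well under one
percentage point between the two conventions.

## What the desk fixtures do and do not show

The desk experiments reproduce the qualitative phenomenology — the three
single-column (p, j0) regimes; exponential single-habitat extinction times
with a p-dependent rate along an equivalent deterministic line; a stationary
three-state mosaic at intermediate connectivity whose extinct fraction rises
(falls) for a stronger (weaker) phage; local competitive exclusion alongside
regional two-strain coexistence with a non-monotone weak-strain occupancy and
an interior optimum bounded by the deterministic feasibility limit — and one
quantitative statistic, the fraction of phage migrations into F habitats
ending in extinction (≈0.94 at desk scale, n ≈ 600 events per run). They are
*not* calibrated to any real organism: rates are generic magnitudes, the wind
is constant, deposition is purely local, and the desk lattice is 5× shorter
and its horizon ~100× shorter than the full-scale configuration, so absolute
rates (extinction rates per window, plume counts) should only be compared
after undoing the time rescaling. Features of real aerobiology that the model
deliberately omits: environmental filtering during transport (species- or
condition-dependent survival aloft), correlated emission of predator and
prey, vertical structure in the atmosphere, and metabolic activity aloft.

## Known limitations

* The operator splitting detects threshold crossings only at window ends; a
  surface density can dip below ρ_ext transiently within a window and
  recover. At the default substep counts this affects only trajectories that
  were within one kick of the floor anyway.
* The migration-outcome attribution window (20·τ_per) can overlap later,
  unrelated kicks in a busy mosaic; the statistic is therefore an upper bound
  on strictly-causal attribution. Shortening the window to 5·τ_per moves the
  desk statistic by under two percentage points.
* The Kendall-based stationarity flag block-averages the fraction series to
  12 points; with decorrelation times of order 10³ windows it remains a
  heuristic, and the burn-in-doubling check (means move < 2σ) is the
  operative steady-state criterion in the tests.
* Upwind advection is provided for non-integer v·τ/Δx but introduces
  numerical diffusion that lengthens effective connectivity; the default
  fixtures keep v·τ/Δx integer and use the exact shift.
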