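# Model and methods

`haptosim` simulates mesenchymal haptotaxis by coupling a stochastic lattice
of nascent adhesion sites to a deterministic phase-field model of cell shape,
peripheral signaling, and actin protrusion. This note records the model, the
numerical scheme, the places where the design was genuinely open and what was
chosen, and the limits of what the tests demonstrate.

## Stochastic adhesion lattice

Potential adhesion sites sit on an `Nx x Ny` grid with pitch `ell` (0.1 cell
radii). Each site is occupied (`n = 1`) or not. The expected occupancy is an
exponential gradient in y with constant relative steepness,

    chi_n(y) = n0 * exp(g * (y - y0)),

so the fractional change per cell radius is `g`. Integrating `chi_n` over the
lattice gives the expected occupied count `Nn` (closed form for the pristine
exponential; midpoint quadrature of the per-site array once ECM removal has
acted). Configurations in which `chi_n` reaches 1 anywhere are rejected:
occupancy is a probability-like weight and the studied regimes keep it well
below 1.

At each 2-second step every site draws a ranking score `s = -ln(u)/chi_n`,
an exponential race key: taking the lowest scores is weighted sampling
without replacement with weights `chi_n` (the Efraimidis–Spirakis scheme).
Exactly `round((dt/tau) Nn)` occupied sites are relegated uniformly at
random (`tau = 30` steps, so the per-step hazard is 1/30 and site lifetimes
are geometric with mean 60 s), and the same number of previously unoccupied
sites — fewer, if removal has lowered `Nn` — are promoted by lowest updated
score. Rounding is round-half-to-even throughout for platform stability.

ECM removal multiplies `chi_n` by `exp(-krem0 * phi * dt)` under the cell
footprint (the exact integral of the removal rate over a step during which
the footprint is frozen); `krem0` is 0.03 (low) or 0.1 (high), with onset
time `tstart` defaulting to 0.

Randomness is organized in *supersets*: one master seed expands through a
documented two-stream scheme (score draws; relegation shuffles) so that a
superset id reproduces `n(x, y, t)` bit for bit, and model variants that
share a superset consume identical adhesion histories until removal first
changes the expected count. Schedules can be packed to HDF5 (bit-packed
booleans) and replayed.

### Recovering the gradient from occupancy

Because promotion is weighted sampling without replacement, the stationary
per-site occupancy is `lam*chi/(1 + lam*chi)` for a global constant `lam`
(relegation is uniform at hazard 1/30; promotion of an unoccupied site is
proportional to `chi` to first order, giving logit-linear flow balance).
Hence the **log-odds** of time-averaged row occupancy is exactly linear in y
with slope `g`, while a plain log fit is biased low by the saturation factor
`1 - lam*chi` (about 7% relative at `n0 = 5%`, `g = 10%/radius` — several
standard errors at the precision a 1500-step average reaches).
`fit_gradient` therefore defaults to the logit link and exposes the naive
log link for comparison.

### Lifetime estimation

The mean site lifetime is estimated from occupancy episodes that both start
and end within the run. Episodes starting near the end of the run are
right-censored: counting only those that happen to finish shortens the mean
by about `tau^2/T` steps, which exceeds three standard errors at typical run
lengths. `completed_lifetimes` therefore excludes episodes starting within a
margin (20 lifetimes by default) of the end, leaving censoring probability
`e^-20`.

## Phase-field model

The cell is the `phi ~ 1` region of a phase field on a square mesh (pitch
0.05, matching the interface-width parameter `eps = 0.05`):

    dphi/dt = Gamma_phi (eps lap phi - G(phi)/eps) - alpha p . grad phi
    G(phi)  = phi (1 - phi) (delta - sigma|p| - phi)
    delta   = 1/2 + mu * iint (phi - phi0) dA

The well `G` has stable roots at 0 and 1 and a mobile middle root
`delta - sigma|p|`; the cell phase invades wherever that root is below 1/2
(bistable front speed `~ 1 - 2 delta_eff`). Local protrusion (`sigma|p|`)
therefore drives outgrowth, and the area feedback must *raise* `delta` when
the cell is oversized to be restoring — the sign written above. With
`mu = 1` the feedback balances interface curvature with a standing area
deficit of about `sqrt(2) eps / R` (1.1% of the disc area at `eps = 0.05`,
2.3% at the desk-scale `eps = 0.1`); area is controlled about that settled
value, not pinned to `phi0` exactly.

The activator `a` (a proxy for Rac/PI3K-axis signaling) obeys

    da/dt = Da div(phi grad a)
            + [k0 phi + (kaf n + chemo) a (eps|grad phi|) / (1 + beta_a a)] b
            - (kar + kar2/(1 + (100 phi)^2)) a
            - alpha p . grad(phi a)

with the well-mixed precursor `b` set by mass conservation,
`b = iint(phi0 b0 - phi a) dA / iint phi dA`. Two readings of the generation
term were genuinely open and were resolved as follows.

* **Peripheral localizer.** The autocatalytic term is weighted by the
  dimensionless interface indicator `eps |grad phi|` (order one across the
  transition region), not the bare gradient. With the bare gradient, whose
  maximum is `1/(4 sqrt2 eps) ~ 3.5`, the autocatalytic gain
  `kaf |grad phi| ~ 350/s` dwarfs the decay `kar = 3/s` at any precursor
  level above ~1%: every adhesion touching the interface ignites, the
  precursor pool collapses, `|p|` reaches order one and cells migrate
  ballistically (persistence ~ 1 even with no gradient) with constant
  solver step-halving. None of that matches the reported behavior (halving
  only in the first few steps, persistence well below 1, radius-scale
  tracks over hours); the localized form reproduces it.
* **Basal term.** Basal generation is gated by the cell phase (`k0 phi b`):
  the stated initialization `a = (k0/(kar b0)) phi` is exactly the interior
  fixed point of that form, and an ungated basal term would hold the
  exterior activator at `k0 b/13`, visible everywhere in empty space.

`k0` itself is not printed anywhere; the default 0.1 keeps the basal level
(`a ~ 0.033` inside) small against peripheral elevations.

The protrusion force field obeys

    dp/dt = Dp lap p - kpf (a n / (1 + beta a)) grad phi
            - (kpr + kpr2/(1 + (100 phi)^2)) p

generating outward force (antiparallel to `grad phi`) only where adhesions
provide mechanical clutch, and the chemotactic modification replaces
`kaf n -> kaf n + ka_C exp(g_C (x - x0))` for an orthogonal gradient (the
antiparallel orientation mirrors the exponent's sign in y).

## Numerical scheme

Each 1-second PDE step runs the 4-stage loop: field solves; removal decay of
`chi_n`; a stochastic adhesion step every 2 s with re-rasterization onto the
mesh (each 0.1-pitch site covers a 2x2 block of 0.05-pitch voxels); and
window recentering once the centroid drifts more than 0.5 from the window
center, by a lattice-pitch-aligned whole-voxel translation (the reference
field `phi0` rides with the window; only its integral enters the model).
Centroids are recorded in absolute domain coordinates.

Per field solve (backward Euler, first order in time):

* Diffusion is implicit (finite volume, arithmetic-mean face coefficients,
  zero-flux edges). Advection is implicit first-order upwind — explicit
  advection violates the CFL bound by an order of magnitude at `dt = 1` —
  and the activator advection upwinds the advected product `phi a` directly
  (operator `T . diag(phi)`), which avoids the spurious voxel-scale source
  that either split form produces.
* The double well is linearized about the old field with the
  positive-slope (decaying) part implicit; the global area feedback
  `delta(phi_new)` is a rank-one coupling folded in exactly via the
  Sherman–Morrison identity (two Krylov solves).
* The activator's autocatalytic coefficient (linear in `a` at lagged
  saturation) joins the implicit operator; the saturation factor and the
  precursor are relaxed by sweeps within the step so the mass-conservation
  brake acts inside the step. Hotspot ignition is locally supercritical
  until saturation, so the activator subsystem is sub-cycled adaptively
  (doubling its substep count on sweep failure) before the whole coupled
  step is halved.
* Linear systems are solved with preconditioned CG (symmetric operators) or
  BiCGSTAB (upwind operators) to tolerance 1e-10 with a 10-iteration cap;
  the preconditioner is a cached incomplete LU, refreshed when stale. A
  solve that fails the cap triggers one refresh-and-retry, then the step is
  redone as two half-steps (recursively, down to dt/64), which in practice
  only happens during the first few steps of strong-input runs.

Numerical guards, all rarely binding and logged: the committed activator is
floored at 0 and capped at 500 (about 10x the saturated hotspot scale; the
advective term `-alpha p.grad(phi a)` is a pure transport with no intrinsic
amplitude bound and can amplify isolated near-empty voxels at a quasi-
stalled front); gradient magnitudes entering the generation terms are
clipped at 1.25x the analytic interface maximum `1/(4 sqrt2 eps)`; the
precursor uses `phi` clipped to [0, 1] (overshoots carry no mass) and clamps
at 0 with a warning if a violent protrusion episode transiently overdraws
the budget, which shuts generation off until the excess decays.

Determinism: a run is a pure function of (simulation configuration, model
parameters, lattice configuration, superset id); tracks replay bit for bit.

## Migration metrics

Centroids are sampled at a microscopy-like interval (default 60 s; the
final position is always recorded). From step vectors `c_i`:
`Dx = sum c_ix`, `Dy = sum c_iy`, `D = |(Dx, Dy)|`, `T = sum |c_i|`,
haptotactic index `HI = Dy/T`, chemotactic index `CI = Dx/T`, persistence
`D/T`, and the Cartesian displacement angle `theta = atan2(Dy, Dx)`, with
`HI = (D/T) sin theta` and `CI = (D/T) cos theta` holding identically.
Both the Cartesian angle and the angle measured from the +y gradient axis
are exported, since both conventions circulate. Degenerate zero-travel
tracks return zero indices with a warning. Wind roses accumulate step
magnitudes into angular bins (Cartesian by default, so the gradient axis
sits at +90 degrees; a gradient-referenced variant is available); bin masses
partition the travel distance. Replicate summaries use the t-based 95%
confidence interval.

## Study harness and problem sizes

The condition grids reproduce the published design: 3 adhesion densities
(2.5, 5, 7.5%) x 4 steepnesses (0, 2, 5, 10%) with 6 supersets x 3 starting
positions (18 replicates); removal variants at 0.03 and 0.1; and the
54-condition dual-gradient grids (3 haptotactic x 3 chemotactic steepnesses
x 3 densities x 2 removal levels) with 12 supersets and the start pinned at
(10, 8). Sweeps are resumable, record replay-sufficient manifests, and share
packed adhesion schedules across variants within a superset.

Full scale (8x8 window at 0.05 voxels, 20,000 one-second steps, 216 runs
for the base grid) is of order days on one CPU and is planned but not run
by the test suite. The trend checks instead use a desk-scale configuration
chosen once: a 6x6 window at half resolution (voxel 0.1 with `eps = 0.1`,
under which the `eps |grad phi|` localizer is invariant) inside a 16x16
domain, 1200-step runs, 8 supersets per condition. At that scale the two
qualitative predictions are strong effects: mean HI at (7.5%, 10%) is about
0.5 against about 0 at no gradient, and high removal raises mean persistence
from about 0.3 to above 0.9 (tested by one-sided signed-rank over paired
supersets).

## What the synthetic inputs do and do not show

The stochastic lattice *is* the study's input generator — there is no
external data. The generator reproduces the prescribed occupancy statistics
exactly (counts, lifetimes, gradient) but contains no spatial correlation
between sites, no adhesion maturation, and no mechanical coupling; the
phase-field cell has no membrane tension or explicit actin flow. Passing
tests demonstrate the stated model behaves as described, not that real
fibroblasts do; the quantitative indices at desk scale differ from
full-scale values (shorter tracks inflate persistence estimates, coarser
meshes soften hotspots), which is why the trend tests compare conditions
rather than asserting absolute index values.

## Known limitations

* First-order time accuracy; the upwind advection adds numerical diffusion.
* `eps = voxel` resolves the interface over only a few cells (as in the
  configuration the model is defined at); gradient-magnitude clipping
  covers the resulting discrete overshoots.
* The activator cap and the precursor clamp regularize rare violent
  episodes rather than resolving them; runs report how often each engaged.
* The ungated exterior (`phi < 0.1`) is not exactly field-free: peripheral
  quantities peak in the transition region and `p` spreads outward with its
  free decay length `sqrt(Dp/(kpr + kpr2)) ~ 0.48` radius, so suppression
  is quantified by distance beyond the interface, not by the `phi = 0.1`
  isoline.
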