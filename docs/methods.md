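# Methods

## The system being modeled

Many communities — bacteria with microcins, plants with phytotoxins,
competing cell populations — wage *allelopathic* warfare: each species
secretes chemicals that raise the mortality (or depress the replication) of
specific target species, while all species also compete for common
resources. `allelloscape` implements two spatially explicit formulations of
this interaction and the analysis tools needed to ask when biochemical
warfare supports, rather than destroys, biodiversity on a landscape.

Both models consume the same object: a binary interaction network where
`poison[a, t] = 1` means species *a* poisons species *t*. Cyclic networks
(`build_cycle(n, d)`: each species beats the next *d* modulo *n*) give the
classic rock–paper–scissors game at `(3, 1)` and a
rock–paper–scissors–lizard–Spock-style game at `(5, 2)`; arbitrary
networks can be supplied as plain-text 0/1 matrices.

## Continuous model

Species densities `N_i(x, y, t)` and toxin concentrations `B_i(x, y, t)`
evolve on a 2-D landscape under

    dN_i/dt = d_i ∇²N_i + r_i N_i (1 − Σ_j ν_ij N_j) − Σ_{j→i} μ Φ_ij(B_j) N_i
    dB_i/dt = D_i ∇²B_i + β_i N_i − δ_i B_i − Σ_{j→i} γ N_j B_i

where `j→i` ranges over the poisoners of *i*. The Holling type-I
functional response is `Φ_ij = B_j` (kind 1: mortality from the free local
toxin) or `Φ_ij = γ N_i B_j` (kind 2: mortality from the uptaken amount).
All quantities are dimensionless; the carrying capacity is scaled to 1
(`ν_ii = 1`).

Parameter defaults are the reference experiment of the three-species
cyclic game: `r = 0.3`, off-diagonal `ν = 0.5`, `μ = 0.4`, `β = 0.5`,
`δ = 0.1`, `γ = 0.1`, `d = D = 0.005`, response kind 2. Two deliberate
literal-isms are kept and exposed rather than silently "fixed":

* **Kind-2 response is quadratic in the victim density.** The mortality
  term `μ Φ_ij N_i` with `Φ_ij = γ N_i B_j` carries `N_i²`. It is
  implemented exactly as stated; no attempt is made to decide whether one
  density factor was intended.
* **Toxin-uptake sink orientation.** As stated, toxin `B_i` is consumed by
  the species that poison *i* (`uptake_mask="printed"`). The
  mass-consistent alternative — `B_i` is taken up by the species that *i*
  poisons, matching the kind-2 response — is available via
  `uptake_mask="transposed"`.

### Numerics

Explicit forward Euler with the standard 5-point Laplacian. Boundary
conditions: zero-Dirichlet (default, fields vanish at the domain edge),
periodic, or zero-flux Neumann. The diffusive stability bound
`dt ≤ dx²/(4·max(d, D))` is enforced with a 0.9 safety factor
(auto-reduction in `integrate`, warning in `step`); a second warning fires
when `dt` is large against a crude per-capita reaction-rate bound.
Negative values are never clamped: with an admissible `dt` the update is
provably nonnegativity-preserving (the suite checks 10³ random states),
and a negative value therefore indicates a bug or an inadmissible step
rather than something to hide. Non-finite values abort integration with
the failure time.

Default grid 128×128 at `dx = 1` (96×96 in the shipped end-to-end checks;
the qualitative outcomes are grid-robust at these sizes), default
`dt = 0.05`.

### Initial conditions

Two generators emulate the study's initial layouts:

* **Isolated circular patches** — species *i* at density 0.25 inside its
  own disc (radius `L/10`), discs evenly spaced on a ring of radius `L/4`
  about the domain center, everything else empty and toxin-free. Centers
  and radius are not fixed by the original description; the ring layout is
  the package's choice and is configurable.
* **Random patchwork** — the landscape tiled by `a×a` squares
  (`a = L/20` by default), each occupied by one uniformly chosen species
  at a density uniform in [0.01, 1]; trailing partial tiles at the far
  edges follow the same rule.

These are idealizations: real landscapes have irregular patch geometry,
environmental gradients, and pre-established toxin fields. Passing tests
on these initial conditions demonstrates properties of the model dynamics,
not predictions for any particular field system.

## Hybrid lattice model

Discrete individuals live on a periodic `L×L` lattice, at most one per
site (spatial exclusion); individuals never move. Continuous toxin fields
couple them: each MCS (Monte Carlo step), every individual draws one
action — replication attempt or death attempt with probability ½ each —
evaluated against saturating functions of the squared local toxin load
from its poisoners, `S = Σ_{l→k} B_l²`:

    prep_k = p0_k · C_k / (C_k + S)        (replication)
    pdel_k = q0_k · S / (A_k + S)          (death)

A successful replication sends the offspring to a uniformly random empty
von Neumann neighbor; contested sites go to the proposer with the largest
local `prep` (ties uniform at random). After the sweep, each toxin field
is relaxed by `relax_iters = 400` explicit-Euler iterations of

    dB_k/dt = D_k ∇²B_k + β_k · 1[occupied by k] − γ_k B_k

continuing from its previous profile (a quasi-stationary solution; the
relaxed field at static sources matches a dense linear solve of the
steady state to better than 1e-6 in the suite). Defaults are the
five-species reference experiment: `p0 = q0 = 0.5`, `A = C = 0.5`,
`β = 0.7`, `γ = 0.2`, `D = 0.001`.

Ambiguities resolved as package choices, each behind a switch:

* **Action semantics.** "Replicate or die with equal probability" and
  "die with probability pdel or replicate with probability prep" are
  honored together: choose the action type with probability ½, then
  succeed with the corresponding probability (`action_semantics="choose"`).
  Independent death-then-birth trials are available as `"independent"`.
* **Sweep order.** All proposals and death draws are evaluated against the
  same pre-sweep occupancy ("simultaneously selected"); deaths are applied
  first, then colonizations. A failed replication attempt (no empty
  neighbor) consumes the agent's action.
* **Isolated agents never die.** `pdel = 0` at zero toxin load as stated;
  a toxin-independent floor is available via `baseline_death` (default 0).
* **Sub-solver step.** The iteration count (400) is fixed by the
  procedure, the step size is not; `relax_dt = 0.2/(4·max(D) + max(γ))`
  sits well inside the explicit stability bound. Dead individuals stop
  emitting immediately; fields persist across MCS.

## Observables and classification

* Spatial means (density per node, or lattice occupancy fraction
  `count/L²`) and their time series.
* Ternary coordinates (fractional densities of a 3-species state) for
  orbit plots; scale-invariant and normalized to sum 1.
* Dominant-species label maps (argmax density per node, floor `1e-3`,
  ties to the lowest index for determinism).
* Survivor counting: on the lattice a species survives iff it has ≥ 1
  individual (no arbitrary threshold); in the continuous model a spatial
  mean threshold `eps = 1e-3` is unavoidable and documented as an artifact
  choice.
* Homogeneity classification: a state is homogeneous iff every survivor's
  spatial coefficient of variation (std/mean over nodes) is below 0.05 —
  machine-level ripples are far below, visible stripes/spirals measure
  CV ≳ 0.3. Under zero-Dirichlet boundaries the edge depletion layer
  alone contributes CV ≈ 0.1 even for a bulk-uniform state, so for such
  states the CV is evaluated on the interior, excluding a margin of
  `max(2, min(nx, ny)//16)` nodes per side (several boundary-layer widths
  `√(D/r)` at the diffusivities of interest); `margin=0` restores the
  all-nodes rule.
* Species–toxin correlation: plain Pearson correlation between a species'
  occupancy indicator and its own toxin field over all sites.
* Characteristic toxin length: the diffusion–decay balance gives
  `ℓ = √(D/γ)`; the literal ratio `D/γ` is available via a flag for
  comparison with looser scaling statements.

## Parameter-plane scans

`scan_plane` sweeps one of the planes μ×D, ν×D, r×D, setting the scanned
traits uniformly across species (ν applied off-diagonal only, the D axis
tying species and toxin diffusivities `d = D`), integrating each cell from
the patched initial condition and classifying the final state. Cells whose
integration blows up are flagged and skipped, not fatal. Desk-scale
defaults are a 64×64 grid, `t_end = 600`, 8×8 cells; the CLI `--full` flag
switches to 128×128 and `t = 3000`. Axis ranges default to
D ∈ [0, 0.1], μ ∈ [0, 0.2], ν ∈ [0, 1], r ∈ [0, 0.6], bracketing all
reference values. The robust, testable structure of the plane is the
diffusivity rule: low D supports inhomogeneous self-organized coexistence,
large D homogenizes the survivors — the shipped checks compare the
inhomogeneous-cell fraction of a low-D column (D = 0.005) against a 50×
larger D column.

## Problem sizes in the shipped checks

The end-to-end suite and `scripts/acceptance.py` use 96×96 / `t = 600`
for the three-species continuous run, `L = 60` / 500 MCS / 5 seeds for the
five-species lattice run, a 16×16 lattice for the dense-oracle
equivalence, and a 2×3-cell scan at 64×64. These sizes are the package's
validation conditions; all qualitative claims they check (coexistence,
pattern class, diffusivity dependence) were chosen for robustness at and
above these sizes.

## Known limitations

* Explicit Euler only; no implicit or adaptive stepping, no 1-D/3-D
  domains, no spatially heterogeneous parameters.
* Pattern classification is a CV threshold: it separates homogeneous from
  inhomogeneous states but does not recognize spiral vs concentric vs
  striped morphology.
* The lattice model has no agent motility and von Neumann neighborhoods
  only.
* Pairwise interactions only; no higher-order (multi-species) suppression
  terms, and interaction strengths are binary (a network edge carries the
  global μ, γ).
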