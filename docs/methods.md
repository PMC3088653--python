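# Methods

## The model

`protrusim` integrates a coarse-grained model of the cell edge: a
one-dimensional membrane contour coupled to a conserved surface density of
curved membrane-protein complexes (BAR/IMD-domain proteins bound to
actin-nucleating and adhesion machinery).  Two geometries are supported: a
periodic Monge segment `h(x)` ("flat"), representing a piece of the cell
margin pinned to the substrate, and a closed counterclockwise polyline
("round"), representing the outline of a whole spread cell.  The protein
field `phi` is a fractional area coverage, `0 <= phi <= 1`.

The free energy is of Helfrich type with protein coupling:

```
F = w ∮ ds [  κ/2 (H − H̄ φ)²                 curvature mismatch
            + λ(L) − α φ                      tension minus adhesion gain
            + γ/2 h²                          substrate pinning (flat only)
            + T n_s (φ ln φ + (1−φ) ln(1−φ))  saturated mixing entropy
            − J n_s/2 φ²                      direct binding (bulk)
            + J n_s b²/2 (∂φ/∂s)² ]           direct binding (surface)
```

`w` is the thickness of the membrane strip represented by the contour
(`dA = w ds`).  The curvature sign convention is fixed once: a
counterclockwise circle of radius `R` has `H = −1/R`, and the flat
linearized curvature is `H = ∂²h/∂x²`, so outward protrusions have `H < 0`
and match the convex protein curvature `H̄ < 0`.

The membrane moves along its local normal with velocity `v = f_total/ξ`.
Conservative forces are obtained by varying `F` with respect to normal
displacement at fixed `phi`; in the continuum limit

```
f_curv = −κ[(∂²_s + H²)(H − H̄φ)] + κ/2 H (H − H̄φ)²
f_ten  = (λ(L) − α φ) H
f_spr  = −γ h                                  (flat)
f_agg  = −J n_s b²/2 · H (∂φ/∂s)²
```

Two active/constraint forces are added: the actin polymerization pressure
`f_act = A φ` along the outward normal (in the flat geometry the
instantaneous mean of `A φ` is subtracted so the segment does not drift),
and in the round geometry a global pressure `f_area = −K (A − A₀)/A₀`
restoring the projected area toward `A₀ = π R₀²`.

The membrane's area reservoir is finite, which is modeled as a hardening
tension `λ(L) = λ [1 + ((L − L₀)/(λ_nl L₀))²]`; `λ_nl` is the contour
strain at which the hardening sets in and `λ_nl = 0` switches it off.  The
tension force uses the energy primitive `G(L)` with `G′ = λ(L)`, so the
hardening is variationally consistent.

The protein current along the contour has four parts,

```
J_curv = Λ φ κ H̄ ∂H/∂s        drift toward matching curvature
J_disp = −Λ φ κ H̄² ∂φ/∂s      bending-resistance dispersion
J_agg  = Λ φ J n_s (∂φ/∂s + b² ∂(∂²φ/∂s²)/∂s)   binding (up-gradient)
J_diff = −D ∂φ/∂s              thermal diffusion
```

and `phi` obeys the covariant conservation law on the moving contour: the
local line element stretches and dilutes the density, so total protein
number is an exact invariant.

Two simplifications follow the conventions of this model class: the flat
geometry keeps the curvature force to linear order only, and the metric
("contour-expansion") forces of the scalar entropy and bulk-binding terms
are neglected — those terms contribute to the energy and to the currents
but exert no shape force.  The mobilities `ξ, Λ, D` are constants
(adhesion-dependent friction and crowding-dependent mobility are known not
to change the linear stability and are out of scope).

## Linear stability

Linearizing about the uniform state and Fourier transforming gives a 2×2
matrix per wavevector whose eigenvalue branches `ω∓(q)` are assembled from
the same coefficients the simulator integrates (`protrusim.stability`).
Both branches are real for this sign structure; one is negative at every
`q > 0`.  Increasing either driver destabilizes a band `[q₁, q₂]`: type II
when bounded away from the smallest resolved wavevector `2π/L`, type I
when it reaches it.  On the circle the modes are integers `m`, the
curvature perturbation of mode m is `(1/R² − m²/R²)ρ`, so `m = 1` (rigid
translation) is exactly neutral — a structural zero of the matrix, used as
a self-test.  The uniform equilibrium circle solves the radial force
balance with the coverage tied to the circumference; the solver keeps only
mechanically stable roots (net force decreasing in `R`).

A caveat tested explicitly: the fully variational round forces carry the
curvature-frustration energy density `κ/2 (H − H̄φ)²` as an extra effective
tension, which survives the large-radius limit as `κ/2 H̄² φ₀²`.  The
linearized flat model deliberately drops it, so the round dispersion
approaches the flat one only after shifting the flat tension by that
amount; round critical drivers are correspondingly about an order of
magnitude above the flat ones.

## Numerics

* Explicit Euler (the reference scheme for this model) with
  `dt = C·min(ξ Δs⁴/κ, Δs²/D, Δs²/(Λ κ H̄²))`, `C = 0.1`, safely inside
  the von Neumann limit `ξ Δs⁴/(8κ)` of the bending operator.
* Forces are exact discrete gradients of the discretized energy terms
  (machine-precision agreement with central-difference variation at any
  resolution); the curvature of the closed contour is the signed
  circumscribed-circle (Menger) formula, second-order accurate.
* Transport is finite-volume: each node carries the conserved mass
  `φ ds`, updated by the difference of edge currents; the covariant
  dilution is realized by re-dividing the conserved mass by the updated
  line element.  Total protein number is conserved to round-off over
  arbitrary runs, including contour resampling.
* The advective curvature flux evaluates its mobility upwind, so a
  depleted node cannot be driven below zero coverage; if a step would
  still leave `[0, 1]` the step is halved (repeatedly, with a floor)
  rather than clipping mass.
* The round contour is re-discretized to uniform arclength (periodic cubic
  spline) whenever the node-spacing ratio exceeds 1.5 (checked at most
  every 200 steps), with piecewise-linear, globally rescaled density
  transfer (exact mass conservation).  Self-intersection is a hard error:
  topology changes are out of scope.
* The inner loops are numba-compiled; a reference numpy implementation of
  a single step is kept and agreement between the two is pinned in the
  tests at 1e-10 relative.
* Steady state is declared when the relative change of the maximum
  amplitude over a trailing window (5% of elapsed time) falls below a
  tolerance and the protrusion count is unchanged; long coalescence runs
  additionally require the count to have reached its target (one) so the
  slow multi-peak plateaus between mergers are not mistaken for the end
  state.

## Parameters

Printed reference values: `φ̄ = 0.1`, `n_s = 10 µm⁻²`, `κ = 100 k_BT`,
`H̄ = −10 µm⁻¹`, `R₀ = 3 µm`, `λ_nl ∈ {0, 0.1, 1}`.  The remaining
constants are package defaults chosen once so that the model exhibits its
characteristic regime structure (passive state stable in both geometries,
type-II onset, micron-scale fastest wavelength, coalescence over hundreds
of seconds, complete coarsening to a single protrusion at strong driving):

| symbol | default | units | role |
|---|---|---|---|
| ξ | 100 | k_BT·s/µm⁴ | membrane friction |
| D | 0.2 | µm²/s | protein thermal diffusion |
| Λ | 3·10⁻³ | µm⁴/(k_BT·s) | protein mobility |
| λ | 1 | k_BT/µm² | bare tension |
| γ | 0.1 | k_BT/µm⁴ | pinning spring (flat) |
| J | 1 | k_BT | direct binding energy |
| b | 0.1 | µm | binding interaction range |
| K | 100 | k_BT/µm³ | area bulk modulus (round) |
| w | 1 | µm | strip thickness |

Flat study conditions: domain `L = 24 µm` at `N = 128` nodes (≥ 20 nodes
per fastest wavelength; `N = 256` is the generic default of the
constructors), initial coverage noise of maximal amplitude `0.01 φ̄`
(shape unperturbed), drivers quoted as multiples of the computed critical
values (`α_c ≈ 25.7`, `A_c ≈ 27.4` k_BT-units at these defaults).  Round
runs use `λ_nl = 0.02`: with the bare tension `λ = 1` the printed strain
scales would let strongly actin-driven contours elongate into
self-intersecting fingers, so the hardening strain scale is matched to the
package's tension scale.

Two deliberate trade-offs of these defaults, found while mapping the
model's behavior and worth knowing:

* The pinning spring both localizes features and arrests late-stage
  coarsening (a confining potential suppresses ripening).  At `γ ≳ 0.3`
  multi-tent states freeze permanently; at `γ = 0.1` the cascade completes
  to a single protrusion.  The flip side is that the flat actin-driven
  steady state relaxes to a smooth broad bump rather than the flat-topped
  plateau-with-dip shape that a stiffer spring produces, because the
  plateau height scales as `A(φ_p − φ̄)/γ`.
* The trough coverage between saturated tents scales as
  `exp(Λ κ H̄ ΔH / D)`: too small a `D` empties the troughs entirely and
  freezes mass exchange between protrusions.

## What the generator does and does not emulate

Initial conditions are synthetic: a uniform membrane with seeded uniform
i.i.d. coverage noise (mean-corrected, so the mean coverage is exact) or a
localized Gaussian coverage bump of fixed total mass.  This captures the
protocol of a quiescent edge developing protrusions from molecular noise.
It does not emulate spatially correlated noise, ongoing stochastic
fluctuations during the run (the dynamics are deterministic), protein
turnover (total number is strictly conserved), myosin contractility,
stress fibers, microtubules, three-dimensional protein reorientation, or
force-dependent polymerization rates.  Passing tests therefore validate
the deterministic curvature-feedback mechanism under idealized conditions,
not the full stochastic biology of a cell edge.

## Degenerate inputs and tie-breaks

`phi` exactly 0 or 1 evaluates the entropy with clamped logarithms (and a
warning).  Counting protrusions uses local maxima of the amplitude above
the mean shape with a relative threshold (default 0.1 of the global
maximum — the qualitative results are threshold-insensitive) and an
absolute noise floor (default 0.02 µm); plateaus are counted once via a
strict-rise/non-rise neighbor rule.  The coalescence time is the start of
the final persistent single-protrusion interval; runs that never coalesce
report it as undefined and are excluded (with a warning) from scaling
fits, which refuse to fit fewer than three points.

## Known limitations

* Two-dimensional contours only; no topology changes (fission/fusion).
* The flat geometry is linearized in the curvature force by construction;
  quantitative flat/round comparisons must account for the metric tension
  shift described above.
* Explicit Euler time stepping is the reference scheme; stiff parameter
  corners (fine grids, large κ) are integration-cost bound.
* Near the critical line the coalescence time diverges and exceeds any
  practical integration horizon; scans flag and exclude such points.
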