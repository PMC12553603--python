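# Methods

## Model

A rigid body of mass m, mean density ρ_b (displaced volume V = m/ρ_b)
moves in an incompressible fluid of density ρ_f under gravity **g**. Its
orientation is a unit quaternion (body → frame, scalar first), its
angular velocity **ω** lives in the body frame, and its inertia tensor
I_o (about the centre of gravity, body frame) is symmetric positive
definite. The centre of buoyancy sits at e **r̂** from the centre of
gravity, with **r̂** a body-frame unit vector (e ≥ 0). Coordinates:
x vertical up (streamwise in the tunnel), y horizontal along the gust,
z completing the right-handed triad into the viewing plane; a positive
rotation angle about z is a clockwise tilt of the body top towards +y as
seen by a camera.

A uniform irrotational transverse gust is a rigid horizontal motion
u_G(t) of the far-field fluid. The package never solves the flow
equations: the fact that the ambient flow is unchanged in the frame
translating with the fluid is taken as a contract, and the aerodynamic
loads F, T_o are supplied by a pluggable quasi-steady closure (see
below). The rigid-body equations are integrated dimensionally in one of
two frames:

**Tunnel frame** (translating at u_G, zero angular velocity, so no
Coriolis/Euler/centripetal terms):

    m du'_b/dt = F + m g* ĝ − m (1 − ρ_f/ρ_b) du_G/dt
    I_o dω/dt + ω × I_o ω = T_o + R^T { e R r̂ × [ −ρ_f V (g − du_G/dt) ] }

**Inertial frame**: the ambient fluid moves at inflow + u_G(t); the
gust's uniform pressure gradient exerts +ρ_f V du_G/dt on the displaced
volume at the centre of buoyancy; gravity m g acts at the centre of
gravity and buoyancy −ρ_f V g at the centre of buoyancy.

Both descriptions are algebraically identical after the Galilean map
(subtract ∫u_G dt and u_G); `equivalence_deviation` measures the residual
the integrator leaves, and the test suite requires agreement within ten
times the integration tolerance over five seconds for every combination
of closure (none/linear/quadratic), gust (step/ramp/sine) and density
ratio (ρ < 1 and ρ > 1).

### Force placement and signs

All buoyancy-type forces (ordinary and gust pressure-gradient) act at the
centre of buoyancy in the instantaneous *effective gravity*
g_eff = g − du_G/dt; gravity and the fictitious force act at the centre
of gravity. Signs are anchored by two physical requirements rather than
by a nondimensional torque factor: (i) a tilted bottom-heavy body
(e > 0, r̂ = +x̂) experiences a restoring torque and returns upright;
(ii) a rightward (+y) gust acceleration on an upright bottom-heavy body
produces a positive (clockwise) angular acceleration about z while the
reduced gust force pushes the body towards −y. The torque form printed in
the source derivation carries a /(ρ−1) nondimensional factor with
ambiguous brace placement; the dimensional formulation above sidesteps
it.

### Neutral buoyancy

At ρ_f = ρ_b the reduced gust force vanishes identically — the gust
pressure impulse accelerates the body exactly with the fluid, whatever
the gust. The gust *buoyancy torque* e r̂ × ρ_f V du_G/dt, however, does
not vanish at ρ = 1 unless e = 0 (just as a neutrally buoyant submarine
still has a righting moment). The simulator therefore short-circuits the
gust event list — guaranteeing a bit-identical run against the ungusted
case — only when ρ_f = ρ_b *and* e = 0; eccentric neutrally buoyant
bodies keep the torque. The null-response property is asserted for the
concentric case.

### Gust profiles and impulses

Step profiles carry their velocity jump as an explicit impulse record
rather than a Dirac spike. The integrator applies the jump analytically:
body velocity += (ρ_f/ρ_b) Δv in the inertial frame, −(1 − ρ_f/ρ_b) Δv
in the tunnel frame (whose own velocity jumps too), plus the angular
impulse I_o^{-1} R^T [e R r̂ × ρ_f V Δv]. This preserves the ρ → 1
cancellation exactly and avoids stiff-spike integration error. Profiles
are right-continuous at the jump, and trajectory samples falling exactly
on an impulse time report the post-jump state. Tabulated profiles
interpolate linearly, extrapolate by their end values, and differentiate
by centred second-order finite differences.

## Aerodynamic closures

The methodology is closure-agnostic: the real loads come from experiment
or CFD. Two explicit quasi-steady stand-ins are shipped, both with
closed-form terminal velocities used as oracles:

- linear isotropic drag F = −c u_rel (u_t = m g*/c, relaxation time
  τ = m/c) — the analytic reference;
- quadratic drag F = −½ ρ_f C_D A |u_rel| u_rel
  (u_t = √(2 m g*/(ρ_f C_D A))) — diaspore-like: a transverse slip
  increases the *speed* and hence the vertical drag component, which is
  the mechanism of the transient altitude gain; the linear isotropic
  closure provably produces zero vertical response and serves as the
  discriminating control.

Both add a rotational damping torque −c_ω ω. Closures act at the centre
of gravity; buoyancy effects are handled by the dynamics, keeping the
loads/buoyancy decomposition intact. No added-mass or history (Basset)
forces are modelled — a known limitation, relevant for ρ near 1 and
strongly accelerated motion. `terminal_velocity` solves the vertical
force balance by bracketed root finding (Brent, relative tolerance at
machine level) and agrees with the closed forms to better than 1e-9;
`calibrate_closure_to_terminal_velocity` inverts the closed forms.

## Integration

State (x, u, q, ω) ∈ R¹³, adaptive Runge–Kutta 4(5) via
`scipy.integrate.solve_ivp`, default tolerances rtol 1e-8 / atol 1e-10.
Because step-wise error control under-estimates accumulated global
error (plain RK45 left frame-equivalence residuals slightly above ten
times the requested tolerance over five seconds), the step controller
runs a fixed factor 0.1 below the requested tolerances; the advertised
tolerance then bounds the solution error with comfortable margin while
deviations still scale linearly when the tolerance is tightened. The
integration interval is split at every profile breakpoint and impulse
time so no step crosses a derivative discontinuity. The quaternion is
renormalised at each output sample; planar demonstrations remain planar
to roundoff because the out-of-plane torque components are identically
zero.

## Flow statistics

Uniformity: each velocity component is time-averaged pointwise; the
speed of the averaged vector is normalised by its spatial mean over a
stated window (default 40 mm × 80 mm, matching the facility's averaging
region; grid spacing of the synthetic fields is 2 mm, a resolution
choice). Turbulence intensity is the RMS of both fluctuation components
over two, divided by the *local* time-mean speed, pointwise; points with
zero local mean speed are masked rather than reported. Fluctuation
variances are computed after subtracting the first frame (variance is
translation invariant), so a strictly constant field reports exactly
zero intensity. The frame shift u' = u − u_G(t) subtracts the spatially
uniform tunnel speed from the streamnormal component only and leaves all
spatial gradients untouched. Pressure reconstruction adds the vertical
hydrostatic term −g(x − x_out) and, in the gust frame, the horizontal
hydrostatic term −u̇_G y'; the printed form of the latter in the source
uses the gust *velocity*, which is dimensionally inconsistent with its
own derivation, so the acceleration is used. Similarly the printed tilt
"tan(u̇_G/g)" of the effective gravity is implemented as the arctangent,
which dimensional analysis forces.

## Tracking pipeline

Tracks are pixel coordinates at constant frame rate (defaults 750 fps,
0.0805 mm/px). De-noising uses a ten-point moving average; the window is
centred (the source does not state centred vs trailing), realised with
half-weighted end samples so the even-length window is symmetric and
straight lines are invariant, and with symmetrically shrinking windows
at the edges so series length and event timestamps are preserved.
Differentiation is second-order accurate everywhere (centred interior,
one-sided ends). The description "second-order time derivative of the
marker's position" is read as a second-order-*accurate* first derivative,
since the quantity it yields is called an instantaneous velocity. The
stem angle is the signed angle of the tip→centroid axis from vertical,
positive clockwise; mirroring y negates it.

## Synthetic data

Generators are pure functions of parameters and seed (NumPy
`default_rng`), and byte-reproducible. The field generator superposes a
uniform vertical mean flow and independent Gaussian fluctuations of
standard deviation intensity × mean speed on both components, so the
expected intensity equals the prescribed value up to O(intensity²) bias;
2000 frames at intensity 0.008 emulate the facility's sub-1% regime. The
tunnel-track generator integrates a gust profile to displacement,
samples at the frame rate, converts to pixels and adds Gaussian pixel
noise (default RMS 1 px).

The virtual diaspore is bottom-heavy (r̂ = +x̂): mass 0.8 mg, mean
density 400 kg/m³, reference length 14 mm, eccentricity 5 mm, spherical
inertia 2e-11 kg m², rotational damping 1e-10 N m s — plausible
order-of-magnitude values flagged `assumed_defaults`; only the terminal
velocity (0.38 m/s, enforced by calibration of the quadratic closure)
and the imaging parameters are measured quantities. The demonstration
profile translates at exactly −2 u_t = −0.76 m/s (the printed "≈ −0.8"
is this value rounded to one decimal), starts stopping at 0.1 s and is
at rest at 0.27 s. The stated 11 m/s² is treated as the *peak* of a
smooth pulse, not a constant (a constant 11 m/s² would stop the tunnel
in 0.069 s): the deceleration is a_pk sin^p(π(t−t₀)/Δt) with p ≈ 3.3
chosen in closed form (via the Gamma-function mean of sinᵖ) so the pulse
both peaks at 11 m/s² and integrates to 0.76 m/s over 0.17 s. The
acceleration is continuous, so the integrator sees no impulses.

What the fixtures do *not* emulate: real PIV noise correlation in space
and time, stitching of multiple camera windows, wake shedding and
unsteady aerodynamics of a real pappus, added-mass effects, and image
segmentation errors beyond Gaussian centroid jitter. Passing tests
therefore validate the rigid-body/gust mechanics, the statistics and the
pipelines — not any particular aerodynamic model of a real diaspore.

## Problem sizes and tolerances

Default suite sizes: 5 s frame-equivalence runs over an 18-case matrix
at rtol 1e-8; 2000-frame turbulence recovery judged within three
standard errors of the RMS estimator (σ/√(2N)); closed-form oracles at
1e-7 relative; terminal-velocity round trips at 1e-8; the demonstration
integrates 4 s, by which the over-critically damped righting
(stiffness e ρ_f V g, damping c_ω) has decayed below 0.01 rad. The
tunnel-track plateau estimate averages the 0.02–0.08 s window; with
1 px RMS noise its sampling error is ≈ 0.5% of the plateau speed, well
inside the 2% round-trip bound asserted.

## Known limitations

- Quasi-steady closures only; no coupling to an unsteady flow solver
  (the closure interface is the extension point).
- Single-window rectangular fields; no stitching, no PIV
  cross-correlation.
- Gusts are shear-free by construction; sharp-edged (shear-layer
  crossing) gusts are out of scope.
- The dimensionless report is unavailable at exact neutral buoyancy
  (u_g is singular there); the simulator itself handles ρ = 1.
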