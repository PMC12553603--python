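# gustfall

Simulation and analysis toolkit for the *accelerating-frame* method of
studying uniform, irrotational transverse gusts acting on untethered
free-falling bodies — plant diaspores, spores, and diaspore-inspired
microdrones.

## The problem and the method

A transverse gust is an abrupt change of the far-field flow velocity
perpendicular to a flyer's direction of motion; for a body settling
vertically it is a horizontal wind fluctuation. When such a gust is
*uniform and irrotational* — a rigid acceleration **u̇**_G of the whole
fluid volume, carrying a uniform pressure gradient and no shear — the
flow field observed in a frame translating with the fluid is unchanged.
In that (non-rotating, hence Coriolis-free) frame the entire gust acts on
an immersed rigid body as:

- a **reduced gust force** at the centre of gravity,
  −m (1 − ρ_f/ρ_b) **u̇**_G — the fictitious force net of the gust's own
  buoyancy (the pressure-gradient force ρ_f V **u̇**_G on the displaced
  volume);
- a **buoyancy torque**, e **r** × [−ρ_f V (**g** − **u̇**_G)], because
  buoyancy-type forces act at the centre of buoyancy, offset e **r** from
  the centre of gravity.

Equivalently, the gust temporarily replaces gravity by the *effective
gravity* **g** − **u̇**_G: for a horizontal gust its magnitude is
(g² + u̇_G²)^{1/2}, tilted by arctan(u̇_G/g) away from the gust direction.
At neutral buoyancy (ρ_f = ρ_b) the reduced force vanishes for any gust:
the body simply rides along with the fluid.

This is the principle behind a horizontally translating vertical wind
tunnel: hover the body in an upward airstream matched to its terminal
velocity u_t, then accelerate the whole tunnel horizontally with the
desired gust profile. The package implements, in dimensional SI form:

- the settling scales and dimensionless groups: reduced gravity
  g\* = (1 − ρ_f/ρ_b) g, gravitational velocity
  u_g = (m g\*/ρ_f l²)^{1/2}, Galilei number Ga = u_g l/ν, Reynolds
  number Re = u_t l/ν, density ratio ρ = ρ_f/ρ_b (`gustfall.scales`);
- gust profiles (step, ramp, sine, tabulated) with exact impulse records
  for velocity jumps (`gustfall.gusts`);
- rigid-body six-degree-of-freedom integration (quaternion orientation,
  adaptive RK45) in either the Earth frame or the tunnel frame, with
  pluggable quasi-steady aerodynamic closures and a frame-equivalence
  check (`gustfall.bodies_aero`, `gustfall.dynamics`);
- facility-characterisation statistics: flow-uniformity maps, turbulence
  intensity T = (1/|ū|)·√[((u−ū)²̄ + (v−v̄)²̄)/2], Galilean shifting of
  measured fields into the tunnel frame, and physical-pressure
  reconstruction (`gustfall.flow_analysis`);
- the high-speed-track pipeline: pixel→metre conversion, ten-point
  moving-average de-noising, second-order differentiation, tunnel-speed
  extraction and stem-angle series (`gustfall.tracking`);
- seeded synthetic fixtures emulating the facility (750 fps imaging at
  0.0805 mm/px, sub-1% turbulence intensity) and a virtual dandelion-like
  diaspore with u_t = 0.38 m/s (`gustfall.fixtures`).

## Worked example

Simulate the demonstration: the diaspore hovers, the tunnel translates at
−2 u_t = −0.76 m/s and is smoothly stopped (peak deceleration 11 m/s²,
gust ratio 2), all in the tunnel frame:

```python
from gustfall.fixtures import demo_scenario
import math

res = demo_scenario().run(t_end=4.0)
print(f"gust ratio          : {res.gust_ratio:.1f}")
print(f"peak stem angle     : {math.degrees(res.max_theta):.2f} deg clockwise")
print(f"final stem angle    : {math.degrees(res.final_theta):.4f} deg")
print(f"altitude gain       : {1e3 * res.final_height_gain:.2f} mm")
```

prints

```
gust ratio          : 2.0
peak stem angle     : 3.88 deg clockwise
final stem angle    : 0.0155 deg
altitude gain       : 3.17 mm
```

i.e. the three signatures of the gust response: the gust-buoyancy torque
first tips the body clockwise (stem angle θ > 0), the ordinary buoyancy
torque rights it after the gust ends, and the transverse slip increases
the speed-dependent drag so the body finishes *higher* than it started.
An isotropic linear-drag control run shows zero vertical response — the
altitude gain is specific to speed-coupled (e.g. quadratic) drag.

The same scenario is available from the shell:

```
gustfall make-fixtures --out-dir fx --seed 1
gustfall simulate --config fx/demo.toml --out-dir out
gustfall characterise fx/field_series.csv
gustfall kinematics fx/tunnel_track.csv
```

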