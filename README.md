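# bristlewing

Flight mechanics of miniature bristled-wing insects: a Python toolkit that
turns rigid-body wing/elytra kinematics and aerodynamic force records of a
sub-millimetre beetle into the quantities that describe how it flies.

The smallest flying insects (featherwing beetles, body length ~400 µm)
carry *bristled* wings — a narrow blade fringed with setae — instead of
membranous ones, and beat them in an unusual cycle: two fast, flat-on
power half-strokes joined by slow recovery phases in which the wings
nearly clap above and below the body, while the elytra (hardened
forewings) oscillate as an inertial brake against body-pitch rocking.
This package implements the analysis chain for that system, for
biomechanists and comparative physiologists who have (or simulate)
kinematic and force recordings:

* **morphology → mass properties** — wing mass m_w, centre of mass and
  inertia tensor **I** from composite geometry: membrane patches of
  constant thickness h and cuticle density ρ_c (σ = ρ_c h, clipped
  midpoint quadrature) plus setae as thin rods of linear density λ
  (rod formula + parallel-axis theorem), and "membranous substitute"
  wings whose outline extends the blade to the seta tips;
* **kinematics** — Euler angles (stroke deviation θ, positional φ,
  pitch ψ) in a total-least-squares stroke plane; wingbeat cycles from
  φ(t) = 0 crossings, phase averages over cycles and sides, geometric
  angle of attack and Reynolds number Re = Ū_g c̄ / ν at the radius of
  gyration R_g = √(∫r²dS/S);
* **forces** — lift/drag decomposition of any force record
  (drag = (F·v̂)v̂, lift = F − drag), cycle-averaged vertical-force
  budget per body part in weight equivalents, and a quasi-steady
  surrogate force model for desk-scale experiments;
* **power & dynamics** — inertial power ω·(Iα + ω×(Iω)), aerodynamic
  power −τ_b·ω, body-mass-specific totals with elastic-storage
  scenarios, and single-axis body-pitch integration
  I_b χ̈ = τ_aero + τ_recoil with the elytra recoil −d(I_e ω_e)/dt;
* **synthetic data** — a seed-deterministic generator producing
  protocols, morphologies and force series with the phase structure of
  the real wingbeat, with ground-truth labels, so the entire chain is
  testable without recordings.

## Worked example

```python
from bristlewing import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1))
m = report["morphology"]; k = report["kinematics"]
print(f"wing mass {m['wing_mass_ug']:.4f} ug "
      f"({m['wing_to_body_mass_pct']:.2f}% of body), Izz {m['wing_izz_ug_um2']:.0f} ug um^2")
print(f"substitute Izz {m['substitute_izz_ug_um2'][0]:.0f}-{m['substitute_izz_ug_um2'][2]:.0f} ug um^2")
print(f"f = {k['frequency_khz']*1e3:.0f} Hz, Re mean {k['re_mean']:.1f} peak {k['re_peak']:.1f}")
print(f"AoA {k['aoa_downstroke_max_deg']:.0f} / {k['aoa_upstroke_max_deg']:.0f} deg, "
      f"clap {k['clap_distance_um']:.0f} um")
print(f"vertical force {report['vertical_force']['total_mean_weight_ug']:.2f} ug-eq, "
      f"power mean {report['power']['bristled']['mean_total_w_kg']:.0f} "
      f"peak {report['power']['bristled']['peak_total_w_kg']:.0f} W/kg")
print(f"pitch amplitude with/without elytra = "
      f"{report['pitch_dynamics']['amplitude_ratio_pct']:.0f}%")
```

prints (seed 1):

```
wing mass 0.0240 ug (0.99% of body), Izz 1912 ug um^2
substitute Izz 13150-20175 ug um^2
f = 250 Hz, Re mean 9.0 peak 19.0
AoA 89 / -89 deg, clap 36 um
vertical force 2.81 ug-eq, power mean 31 peak 167 W/kg
pitch amplitude with/without elytra = 57%
```

Read: the bristled wing weighs ~1% of the 2.43 µg body and carries an
order of magnitude less inertia than a membranous wing of the same
outline (1,912 vs 13,150–20,175 µg·µm²); the wingbeat frequency was
recovered from noisy angle series to 0.1%; the cycle-averaged Reynolds
number is ~9 and the wings run nearly flat-on (|AoA| near 90°) during
both power strokes; the cycle-mean vertical force supports the body
weight with margin; and the elytra recoil cuts the body-pitch
oscillation to 57% of what it would be without them.

The same stages are available as a CLI
(`bristlewing run|synth|massprops|kinematics --help`), reading and
writing plain CSV/YAML/JSON dialects.

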