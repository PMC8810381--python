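# Methods

This note documents the models, conventions and numerical choices behind
`bristlewing`, and what the synthetic study conditions do and do not
represent.

## Units

All internal quantities are in a µg–µm–ms system (`bristlewing.units`),
chosen so that the numbers describing a sub-millimetre insect are of
order unity: 1 internal force unit is 1 nN, 1 internal power unit 1 pW,
and 1 µm/ms² equals 1 m/s² exactly. Conversion constants to SI are
exported; user-facing outputs state their unit explicitly.

## Wing mass and inertia

A wing is a rigid composite: petiole and blade as flat patches of
constant thickness h (surface density σ = ρ_c h, cuticle density ρ_c =
1200 kg/m³ by default, configurable ±100 kg/m³ for error propagation),
plus a fringe of setae as straight thin rods with linear mass density
λ = 0.96 µg/m. λ already absorbs the mass of the setae's secondary
outgrowths; they are not modelled geometrically. Each rod contributes
(mL²/12)(E − uuᵀ) about its centre, shifted by the parallel-axis theorem;
patches are integrated by a midpoint quadrature on a square grid whose
boundary cells are clipped against the polygon (exact area at the exact
centroid per cell), which converges to the exact polygon integrals as the
step shrinks. The default step is 2 µm: a petiole a few tens of µm wide
needs a step of that order to resolve its own second moments, while
whole-wing totals are insensitive to it; a coarser step can be passed
wherever only totals matter.

The membranous substitute wing shares the bristled wing's outline — the
blade extended by the polyline through the seta tips, implemented as the
union of the patches with the quadrilaterals spanned by consecutive
setae — and inherits ρ_c, so substitute mass is exactly linear in the
chosen membrane thickness. The tip polyline is required to be
non-self-intersecting (the offending segment pair is named otherwise);
setae are taken in list order, which must follow the wing margin.

## Kinematics

Euler angles follow the standard hovering-insect convention: positional
angle φ about the stroke-plane normal, then stroke deviation θ out of
plane, then pitch ψ about the spanwise axis (R = Rz(φ)·Ry(−θ)·Rx(ψ)).
The stroke plane is the major-axis (total-least-squares) plane of the
wing-tip cloud through the wing base — appropriate because the tip cloud
of this flight style is wide, not line-like. Left and right wings use
mirror-symmetric right-handed frames; mapping a right-side series into
the left convention is the sign flip (θ, −φ, −ψ), applied before
left/right averaging.

Cycles are the intervals between rising zero crossings of φ. Each
crossing is refined by a straight-line fit over a window (default one
eighth of the dominant period, taken from the spectrum); fits with
non-positive slope are rejected — they are noise wiggles on the falling
flank, the dominant failure mode at realistic noise levels — and
candidates closer than half a period are merged. The period is the slope
of crossing time against crossing index. Crossings whose fit window would
be truncated by the ends of the record are discarded, so records should
carry a margin of ~¼ cycle beyond the cycles to be analysed (the
synthetic generator does).

Phase averaging splines each detected cycle onto a common phase grid,
averages across cycles, then across sides. An optional truncated-Fourier
projection (`smooth_harmonics`) makes the averaged cycle exactly periodic
and suppresses residual noise before differentiation; the pipeline uses
12 harmonics (the generator's protocols contain at most 8), while the
plain average — whose residual noise follows the σ/√(2n) law — remains
the default.

Angle of attack is the angle between the wing chord plane and the
velocity of the radius-of-gyration point: 0° edge-on, ±90° flat-on. The
sign is that of the velocity component along the wing's material normal,
so the ascent of a wing that keeps the same surface facing down carries
negative AoA. (A chordwise-velocity sign convention is equivalent away
from the extremes but ill-conditioned exactly where AoA is largest, which
is why the normal component is used.) At stroke reversals the speed
vanishes and AoA is reported as a gap, never interpolated. R_g is
area-based (second moment of the effective planform about the wing base),
because it scales aerodynamic velocity, not mass. Re(t) = U_g(t)·c̄/ν with
c̄ = S/R; the cycle average uses the mean speed. Wing speed is the speed
of the rotating wing in the body frame; the slow whole-body translation
(~0.06 m/s against ~0.5 m/s wing speed) is reported separately from the
loess-filtered body track and not added to the wing velocity.

## Forces

The decomposition is algebraic and exact: drag = (F·v̂)v̂ along the
velocity at R_g, lift = F − drag. Both are undefined at zero-velocity
samples (the definition divides by |v|), which propagate as gaps.
Loaded force files must declare units and the torque reference point;
torques are re-referenced with τ' = τ + (r_ref − r_new) × F.

The quasi-steady surrogate is a desk-scale stand-in for flow
computations, not a flow model: drag ½ρC_D(α)SU² anti-aligned with the
velocity, lift ½ρC_L(α)SU² normal to it in the chord–velocity plane,
applied at R_g. The default coefficient shapes (C_D = 0.35 + 1.1 sin²α,
C_L = 1.3 sin 2α, both inflated by 1 + 5/Re) are generic flat-plate-like
package defaults chosen to land hovering-scale forces at Re ≈ 9; they are
caller-replaceable and carry no measured authority. Two known
consequences: the surrogate's vertical force is drag-dominated (~95%
drag share on the default protocol, whereas resolved-flow analyses of
this animal attribute roughly two thirds to lift), and its peak powers
exceed resolved-flow values. The drag/lift share *accounting* is
validated independently against constructed force series with injected
shares, which it recovers to 1e-6.

## Power and pitch dynamics

Inertial power is the rate of change of rotational kinetic energy of the
rigid wing about its base, P = ω·(Iα + ω×(Iω)) in wing axes (the
gyroscopic term is retained though it is orthogonal to ω). Aerodynamic
power is −τ_b·ω with the torque about the wing base; for a drag-only
force this is non-negative by construction. Elastic-storage scenarios:
no storage rectifies negative total power (mean of max(P, 0)); perfect
storage takes the plain mean; when total power never goes negative the
two coincide and storage is irrelevant — the bristled-wing regime, which
the ~10× smaller wing inertia makes reachable. Body translation work is
not merged into these terms.

Body pitch is a single-degree-of-freedom torque balance
I_b χ̈ = τ_aero(t) + τ_recoil(t), integrated by fixed-step RK4 with the
step equal to the kinematic grid step (convergence is verified by step
halving). The elytra enter only through the recoil of their
angular-momentum change, −d(R I_e ω_e)/dt projected on the pitch axis;
"without elytra" zeroes the recoil while keeping their (negligible)
aerodynamic torque, with a flag to drop that too. Feedback of body pitch
onto the prescribed wing kinematics is not modelled. The body pitch
moment of inertia is not derivable from the package's inputs and is a
configuration value (default 3·10⁴ µg·µm², a uniform-rod estimate for a
2.43 µg, ~400 µm body). Oscillation amplitudes are peak-to-peak after
discarding the first cycle and removing the secular drift, which is
fitted through per-cycle means — exact for polynomial drift and
orthogonal to any periodic component, unlike a naive polynomial fit to
the trajectory, which leaks the oscillation into the trend.

## Synthetic study conditions

The generator's defaults emulate a ~400 µm featherwing beetle in slow
hovering: wing length 493 µm, body mass 2.43 µg, λ = 0.96 µg/m,
ρ_c = 1200 kg/m³, candidate membrane thicknesses 0.73/0.85/1.12 µm
(measured minimal thicknesses of the smallest membranous-winged insects),
ν = 1.54·10⁻⁵ m²/s, four analysed wingbeat cycles, 200 samples per cycle,
1° i.i.d. Gaussian angle noise (a simple model of manual frame-by-frame
registration error; it has no temporal correlation and no outliers,
so passing tests bound estimator behaviour under that model only).

The wingbeat frequency is deliberately not a constant: it is calibrated
at generation time so the cycle-averaged Re of the protocol equals 9
(Re is exactly linear in f for a fixed protocol shape, so one reference
evaluation suffices); the default fixture yields ~250 Hz. The default
harmonics produce the qualitative cycle structure of this flight style:
a fast descending half-stroke and a slow extended ascent (2f skew of the
sweep), pitch that keeps one wing surface facing down all cycle (nonzero
mean ψ with a 2f oscillation — this is what makes ascent AoA large and
negative), a 2f deviation that dips the wings toward the midline at both
claps and phase-shifts the sagittal tip path into a self-intersecting
figure of eight, and elytra sweeping once per wingbeat with their recoil
counter-phased to the wings' pitching torque. The elytron fixture
(250 × 150 µm, 12 µm thick, ~0.4 µg) is deliberately massive enough for
its recoil to brake the pitch oscillation appreciably (~57% remaining
amplitude with the default torques); the braking mechanism, not the
exact percentage, is the modelled phenomenon.

The bristled-wing fixture (56 setae fanning ±35°, narrow blade and
petiole) lands at 0.024 µg total mass (~1% of body mass), a setal share
of ~96% of the effective area, and I_zz ≈ 1.9·10³ against
1.3–2.0·10⁴ µg·µm² for its membranous substitutes — the mass/inertia
contrast that makes elastic storage unnecessary for the bristled wing.

Constructed force series (`make_forces`) inject known drag/lift vertical
shares by building exactly anti-aligned and exactly orthogonal parts on
the protocol's own kinematics; they are the ground truth for the budget
accounting, independent of the surrogate.

## Degenerate inputs and tie-breaks

Zero-length rods, zero-area polygons (for integration), collinear tip
clouds, constant positional angle, and force files without units are
rejected with specific errors; zero-area placeholder patches are allowed
in composites and contribute nothing. Gimbal lock (|θ| = 90°) makes φ
indeterminate and raises on inversion. Cycle detection requires at least
two qualifying crossings. Rising crossings define cycle starts (any
consistent direction works; one had to be fixed).

## Limitations

No flow solving, wake/vortex analysis or added-mass modelling; no image
processing or landmark digitisation; wings are rigid (no deformation
estimation); the pitch model is single-axis with prescribed kinematics.
The surrogate's absolute force levels and drag/lift proportions carry no
measured authority — conclusions that depend on resolved aerodynamics
(e.g. the true lift share) require loading computed or measured force
records through the file interface.
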