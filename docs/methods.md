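# Model and methods

## The system

`mpsim` simulates a magnetic polymersome (MPS): a hollow vesicle whose
diblock-copolymer membrane confines a monolayer of magnetic nanoparticles
between its two polar interfaces. The membrane is coarse-grained as a pair
of concentric closed triangular meshes whose nodes are finite-size soft
spheres ("blobs"); the nanoparticles (MNPs) are soft dipolar spheres that
move freely in the fluid layer between the meshes. The layer width barely
exceeds one particle diameter, so the magnetic phase is effectively a
two-dimensional fluid wrapped on a sphere.

All quantities are reduced: thermal energy kT = 1, the MNP diameter is
`a_red = 1.2` reduced lengths. The default geometry — outer/inner shell
diameters 24/16, blob diameters 3.1/2, accessible layer width
ℓ = (24 − 3.1 − 16 − 2)/2 = 1.45 — maps onto a ~200 nm vesicle with a
~33 nm membrane and 10 nm maghemite particles when one reduced length is
10 nm / 1.2 ≈ 8.3 nm (see `mpsim.units`).

## Interactions

* **Mesh edges** carry the neo-Hookean centre-to-centre force
  `F = ks · [(x^1/2 + x^-5/2)/(x + x^-3)] · (r − r0)/r0`, `x = r/r0` —
  linear at small strain, stiffening under extension. The pair energy has
  no elementary antiderivative; where an energy is needed (plateau
  detection, gradient tests) it is evaluated by quadrature, tabulated once
  and interpolated with a cubic spline.
* **Local area**: vertex `i` of triangle `k` feels
  `−kal (S_k − S0_k)/S_k` along the unit vector from the triangle centroid
  to the vertex. This printed law is a constraint-restoring force, not an
  exact gradient of a scalar energy: it performs nonzero work around closed
  loops, violates global action–reaction for irregular triangles, and in
  steady state injects a few percent of kT of excess kinetic energy, which
  the thermostat drains. We keep the law as defined; its force is verified
  by a finite-difference check along the uniform-dilation mode of an
  equilateral triangle, where it is an exact 1-D gradient.
* **Tethers**: corresponding nodes of the two shells are joined by harmonic
  springs `kh (r − r0)`, with r0 = (Dout − Din)/2 = 4 for the concentric
  build. Bending rigidity, global-area and volume constraints are
  deliberately absent (a soft membrane, freely permeable to solvent).
* **Excluded volume**: WCA (truncated-shifted Lennard-Jones), cutoff
  `R = (d_i + d_j)/2`, `σ = R/2^(1/6)`, shift `cshift = ε` so U(R) = 0.
  Applied to every element pair except edge-connected blobs: at the working
  mesh resolution rest edge lengths (≈2.3 outer, ≈1.5 inner) are smaller
  than the blob diameters (3.1, 2.0), so bonded pairs must be excluded or
  the blob wall would burst its own springs. Non-bonded second neighbours
  never overlap at rest.
* **Magnetics**: reduced pair energy
  `λ a³ [e_i·e_j − 3(e_i·n̂)(e_j·n̂)]/r³` summed directly over all MNP
  pairs (single box, no periodic images, no cutoff), plus the Zeeman term
  `−ξ (e_i·ĥ)`. Forces are the analytic gradients; the torque on a dipole
  is `e_i × h_i` with `h_i` the applied-plus-dipolar local field conjugate
  to the orientation. λ is the contact dipole–dipole energy over kT in the
  SI convention `μ0 μ²/(4π a³ kT)` (the convention that makes 10 nm
  maghemite come out at λ ≈ 1); ξ = μ0 μ H/kT.

## Dynamics

Each element follows the underdamped Langevin equation
`m r̈ = F − ζ ṙ + f(t)`, `⟨f_a(t) f_b(t′)⟩ = 2 ζ kT δ_ab δ(t−t′)`,
discretised with the BAOAB splitting (a stochastic velocity-Verlet with one
force evaluation per step and an exact Ornstein–Uhlenbeck friction/noise
substep). Orientations follow the rotational analogue
`I ω̇ = τ − ζ_r ω + τ_th`, with Rodrigues rotation of the unit dipole and
renormalisation each half step; without rotational dynamics the dipoles
could never align with the field. Frictions follow Stokes scaling:
`ζ = 3π a η` translates to a per-element friction proportional to the
element diameter, referenced to `zeta_t` for one MNP; `ζ_r = π η a³`
defaults to `zeta_r = 1`.

Defaults `dt = 0.005`, `m = I = 1`, `ζ = ζ_r = 1` satisfy `dt ≪ m/ζ` and
keep WCA contacts stable at kT = 1. The absolute time scale of the reduced
dynamics is arbitrary (mass, viscosity and time step are not constrained by
the physical mapping), so kinetic quantities such as MSD are meaningful up
to a global time rescaling; their *shape* (diffusive exponent, hindered
motion) is invariant.

Randomness comes from a counter-based Philox generator carried inside the
state; noise is drawn once per step in a fixed order, so runs are bitwise
reproducible, chunk-size independent, and resumable from checkpoints
(which store the generator state).

The hot loop is compiled with numba (`mpsim._kernels`): WCA pairs go
through a Verlet neighbour list with displacement-triggered rebuilds
(skin 0.3; forces are exact regardless of list age, and summation order is
fixed, so trajectories are independent of when the list is rebuilt). The
numpy implementation in `mpsim.forcefield` is the readable reference; a
test pins the two against each other at 1e-10.

## Elastic constants

The membrane interfaces of a real polymersome are nearly inextensible on
the thermal scale: the reduced surface tension is σ_s a²/kT ~ 5·10². The
mesh must inherit that property, because the model's central premise is
that the blob walls are impermeable to the particles. With order-one edge
and area constants a thermal mesh is entropically floppy (edge-length
fluctuations of order one reduced length) and particles squeeze straight
through; we verified this empirically. The defaults are therefore stiff on
the thermal scale but small compared to the reduced surface tension:
`ks = 50`, `kal = 50` (reduced force), `kh = 20` (reduced force/length),
`ε = 1` kT. These leave the area-preserving global elongation mode soft —
a sphere can deform into a prolate shape at constant local area — while
keeping thermal wall gaps closed. All four are exposed in the config and
remain calibration knobs.

Mesh resolution matters for the same reason: the wall is tight only if the
triangle circumradius stays below the blob–particle contact distance. With
blob diameters 3.1/2.0 that requires roughly ≥300 nodes per shell; the
default (and working) resolution is 393 nodes, at which the rigid-wall
barrier at a face centre is several hundred kT. Coarser shells (162–260
nodes) with these blob sizes leak particles over ~10⁴–10⁵ steps and are
not used for production or validation runs.

## Preparation and magnetisation protocol

1. **Build**: Fibonacci-spiral nodes on each sphere, convex-hull
   triangulation (outward-oriented), identity node pairing, random
   sequential insertion of N particles at uniform solid angle and uniform
   admissible radius with hard rejection of overlaps; orientations uniform
   on the unit sphere. N = round(φ V_layer / v_p) from the target volume
   fraction φ of magnetic phase in the layer: 105 at φ = 5.5 vol.%, 210 at
   11 vol.% (cap 393).
2. **Stage A**: thermalise with magnetics off.
3. **Stage B**: enable dipole–dipole coupling at H = 0 and run until the
   trailing-window mean of the total energy changes by < 1e-3 (relative)
   between 1e4-step windows, or a window budget is hit (flagged, not
   fatal).
4. **Ramp**: increase ξ through a non-decreasing schedule (default
   {0, 0.5, 1, 2, 3, 5, 7, 10}), equilibrating then measuring at each
   level; independent realisations use different build seeds.

## Observables

* **MSD** over particles and all time origins; the log-log slope over a lag
  window classifies free (≈1) vs chain-hindered (<1) motion. The window
  must start past the inertial crossover (t ≳ m/ζ) and end before
  curvature/confinement saturation.
* **Aspect ratio**: primary estimator `sqrt(λ_∥ / gm(λ_⊥))` from the
  outer-shell node covariance (variance along the field over the geometric
  mean of the two transverse principal variances) — exactly the affine
  stretch factor for an affinely deformed sphere, 1 for isotropy; a
  central-slab 2-D covariance estimator (δ = 1 reduced) is the
  cross-check.
* **Clusters**: single-linkage components with bond criterion
  r < 1.3 a (the common dipolar-fluid convention); the histogram, largest
  cluster and bonded fraction are reported. At φ = 11% the *geometric*
  bonded fraction of even an ideal gas is ≈ 0.5–0.6, so chain formation is
  read from the increase above that baseline (≈1.0 at λ = 5).
* **Magnetization**: mean alignment ⟨e·ĥ⟩.
* **Sigmoid fits**: 4-parameter logistic
  `AR(ξ) = ar0 + (ar_inf − ar0)/(1 + exp(−(ξ − ξ_half)/w))`, least squares,
  degenerate/non-converged fits flagged.

## Validation scales and what they show

The fast checks (parameter mapping, mesh conformance, force-vs-gradient
oracles at 1e-6, thermostat statistical mechanics: equipartition within 5%,
harmonic-well variance within 3%, Einstein slope within 5%,
Maxwell–Boltzmann KS) are exact-science tests and run in seconds to
minutes.

The structural behaviours are validated on scaled-down runs sized for a
desktop: 393-node shells (resolution cannot be reduced, see above),
φ = 11%, λ ∈ {0, 1, 5}, with ~3.5–5.5·10⁴ steps of preparation per
scenario, 2·10⁴ measured steps at H = 0, and a three-level ramp
{0, 3, 10} totalling ~3·10⁴ further steps. At this scale the package
reproduces, as strict inequalities: more bonded particles at λ = 5 than at
λ = 1; a lower zero-field MSD exponent at λ = 5 than at λ = 0; elongation
at ξ = 10 over ξ = 0 for λ = 5; and at least as much elongation at
φ = 11% as at 5.5%. These short ramps land at AR ≈ 1.06 at ξ = 10
(φ = 11%, λ = 5, one realisation) — the saturation value of the full
protocol (longer ramps, averaging over ten realisations,
`mps study --which elongation --scale full`, several CPU-hours) is larger
(≈1.1–1.2); the desk-scale suite intentionally asserts only the
inequalities, not the saturation magnitude.

What the synthetic system does *not* emulate: hydrodynamic interactions
through the carrier fluid, viscoelasticity of the intra-membrane fluid,
bending rigidity, polydispersity, and any chemistry of the real
polymersome wall. Passing tests therefore validate the coarse-grained
model's mechanics and statistics, not quantitative kinetics of a specific
experimental system.

## Numerical edge cases

* Degenerate triangles, coincident nodes/dipoles and zero edge lengths
  raise singular-configuration errors rather than returning infinities.
* Non-finite forces abort the run with the state synchronised for
  post-mortem inspection.
* The WCA neighbour list demands 1.5× headroom at chunk entry so a
  mid-chunk rebuild can never overflow silently.
* `fit_sigmoid` flags constant data as degenerate and non-convergence
  explicitly instead of raising.
* Empty ensembles (φ = 0) are legal everywhere except observables that are
  undefined without particles (magnetization).
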