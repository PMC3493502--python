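# Methods

## Model

`mapcrystal` integrates the gradient-descent dynamics of an energy
functional for interacting cortical feature maps. The orientation-preference
(OP) map is a complex field z(x) whose phase encodes the preferred
orientation θ = ½ arg z and whose modulus encodes selectivity; ocular
dominance (OD) or other columnar systems are real fields o_i(x). Each field
alone follows supercritical Swift-Hohenberg dynamics, the canonical
pattern-forming model with a preferred wavelength:

    ∂t z      = L̂_z z − |z|² z − δU/δz̄
    c_i ∂t o_i = L̂_i o_i − o_i³ + γ_i − δU/δo_i

with L̂ = r − (k_c² + Δ)²/k_c⁴. The linear spectrum λ(k) = r − (k_c² − k²)²/k_c⁴
peaks (value r) on the critical circle |k| = k_c, so a pattern of wavelength
Λ = 2π/k_c grows once r > 0. The cubic terms saturate the growth at stripe
amplitude √r (OP stripe power P = ⟨|z|²⟩ = r); γ_i is a constant bias (the
contralateral-eye bias of the OD map). Units: lengths in Λ_z (k_c,z = 2π),
time reported in the intrinsic scale τ = 1/r_z.

The inter-map coupling energy U is one of a symmetry-classified family,
summed over coupled field pairs:

    product2   α o² |z|²          product4   τ o⁴ |z|⁴
    gradient2  β |∇z·∇o|²         gradient4  ε |∇z·∇o|⁴

with ∇z·∇o = ∂x z ∂x o + ∂y z ∂y o a complex scalar. The high-order gradient
coupling (`gradient4`) is the default experimental choice: it favors locally
perpendicular map gradients, cannot collapse the OP pattern, and with a
biased (hexagonal) OD map its strong-coupling optima are hexagonal pinwheel
crystals (hPWCs). Functional derivatives of U are evaluated spectrally and
are exact discrete gradients of the discretized energy (spectral derivatives
are skew-adjoint on the periodic grid); the test suite enforces this
energy/force consistency by central finite differences rather than trusting
any hand-derived formula.

## Numerical integration

The dynamics is stiff (λ ~ −k⁴ at large k), so steps are taken with a
Crank-Nicolson discretization, solved by an inexact Newton method:

* residual F(u') = u' − u − (dt/2)[N(u') + N(u)] on the stacked real state
  (Re z, Im z, o_1..o_m);
* Jacobian action by one-sided finite differences with
  ε = √(machine ε)(1+‖u‖)/‖v‖ (matrix-free);
* restarted GMRES (modified Gram-Schmidt Arnoldi, Hessenberg least squares;
  subspace 30, relative tolerance 1e-4, 2 restarts);
* left preconditioning by the inverse of the Fourier-diagonal linear part,
  [(1 − (dt/2)(λ_f(k) − a_f)/c_f) + η]⁻¹ with shift η = 0.01. The damping
  a_f augments the bare spectrum with a mean-field estimate of the cubic
  Jacobian (2⟨|z|²⟩, 3⟨o²⟩) and, for gradient couplings, the quadratic form
  s·p(2p−1)⟨|S|^{2p−2} ∂_α b ∂_β b⟩ k_α k_β. Without this augmentation the
  preconditioner ignores the saturated-state stiffness and GMRES iteration
  counts grow by an order of magnitude once dt·λ_max ≫ 1;
* backtracking line search (halving, plain decrease of ½‖F‖²) for global
  convergence; Newton tolerance 1e-8 on the RMS residual;
* step-doubling error control: one dt step is compared against two dt/2
  steps, the RMS difference must stay below step_rtol = 1e-4 relative to
  (1 + RMS(u)), the two-half-step solution is kept, and dt is rescaled by
  the standard third-root rule (growth capped at 1.5×, shrink at 0.5×).
  Near attractors dt grows to hundreds of intrinsic time units.

Snapshots are stored on an exponential schedule t_j = t_0 (t_f/t_0)^{j/(J−1)}
(default J = 150, t_0 = 0.1 τ; the initial condition is frame 0), matching
the multi-scale kinetics: fast linear growth, saturation, then slow
crystalline ordering. A run is declared stationary when the RMS of the rhs
stays below 1e-6 for one τ; remaining scheduled frames then repeat the
stationary state at their nominal times.

Degenerate inputs: Newton failure or error-control rejection shrinks dt and
retries; dt underflow (< 1e-10) aborts with diagnostics. Real fields remain
exactly real because every operator used maps real fields to real fields.

## Synthetic initial conditions

The generators encode the standard study conditions and are deterministic in
(spec, seed):

* **Band-pass Gaussian white noise** — white noise filtered to the annulus
  |k/k_c − 1| ≤ bandwidth/2 (default relative bandwidth 0.2), normalized so
  the realized power is exact. This emulates the weakly selective, spatially
  irregular early OP map; its mean pinwheel density is bounded below by π.
  Default initial power: 2% of the stripe power r (the "few percent"
  regime).
* **Stripes** — pinwheel-free plane waves on an exact lattice mode.
* **Hexagons** — three lattice wavevectors as close to mutual 120° as the
  torus allows, summing exactly to zero (resonant phases φ₁+φ₂+φ₃ = 0 by
  default). OD initial conditions use amplitude −0.25 about mean +0.2,
  mimicking the settled patch pattern of the biased OD dynamics.

The grid enforces an integer number of wavelengths of every field in each
domain direction and ≥ 8 mesh points per wavelength; this keeps the discrete
critical circle balanced (detuned-wavelength experiments pick rational
ratios for the same reason).

What the generator does **not** emulate: measurement noise, anisotropy,
cortical boundary effects, and biologically derived correlations (retinal
mosaics); passing tests say nothing about those aspects of real maps.

## Pinwheel detection and statistics

Pinwheels are the common zeros of Re z and Im z. Both components are
interpolated bilinearly per mesh cell; their zero contours intersect where a
quadratic (obtained by eliminating one local coordinate) has roots inside
the cell, giving subcell positions without global contour assembly. A
bilinear function attains its extrema at cell corners, so scanning cells
whose corner values straddle zero in both components finds every crossing.
Charges are assigned from the sign of the Jacobian det(∂(Re z, Im z)/∂(x,y))
of the interpolants at the zero — exact for simple zeros and strictly local,
which makes the torus-wide charge sum vanish identically (Poincaré-Hopf for
the piecewise-bilinear field). The standalone winding-number routine
(½ × winding of arg z on a loop of 1.5 mesh cells, retried at 3 cells)
agrees with the Jacobian sign for isolated defects and is used to flag
non-simple zeros (|q| ≠ ½). Cells that are identically zero are flagged,
not dropped.

Statistics follow the standard definitions: density ρ = N Λ²/area;
charge-resolved nearest-neighbor distances under the minimal-image torus
metric; density variability from uniformly sized/positioned circular
regions (up to 1000 per area bin, 30 log-spaced bins over [0.25, 9] Λ² by
default) with a log-log least-squares fit of SD(A) = c A^(−γ_v); matching
of pinwheels across frames restricted to equal charge within 0.2 Λ (greedy
by increasing distance, one-to-one), which yields lineages, creation and
annihilation rates per hypercolumn and unit time, survival fractions
s(t₀, t), and preserved fractions p(t). The per-frame-pair conservation
N(t_{j+1}) = N(t_j) + created − annihilated holds by construction and is
asserted. Maturation time T is the interior peak of the OP power or, for
monotone curves, the interpolated first crossing of 90% of the final power;
developmental time is t′ = t/T.

## Study conditions and scale

The canonical two-map experiment uses r_z = 0.05, r_o = 0.25 (OD dominant,
r_z/r_o ≪ 1), bias γ = 0.2 — the center of the range [0.15, 0.25] in which
the uncoupled OD dynamics at r_o = 0.25 selects hexagons (below it stripes,
above it the biased uniform state). Coupling strengths were fixed by a
decade sweep of the uncoupled-to-crystal transition at these amplitudes:
ε = 1e-3 ("strong", every tested seed forms an hPWC with ρ ≈ 5.2) and
ε = 1e-5 ("weak", stripes, rhombic crystals at ρ ≈ 3.5, and hexagonal
crystals compete). Note the small numerical values simply compensate the
k⁸ amplitude factor in |∇z·∇o|⁴ ~ (k_c² A_z A_o)⁴; all qualitative behavior
is invariant under a common positive rescaling of ε.

Production analyses in this package run on periodic domains of 8–16 Λ at
8 mesh points per Λ (64²–128²), integrated to 500 τ with 150 exponentially
spaced frames — sizes chosen so a full tracked ensemble completes on a
single CPU in minutes. Attractor densities (5.2 and 3.5 per Λ²) are lattice
properties and insensitive to the domain; kinetic quantities (survival
fractions, rates) retain finite-size effects, discussed below.

## Known limitations

* Small domains crystallize and globally align quickly. The fraction of
  pinwheels surviving from t = 0 decreases with domain size (≈ 0.5 at 8 Λ,
  ≈ 0.3 at 12 Λ); the fraction surviving from the OP power-saturation time
  is close to 1 on desk-scale domains because little rearrangement remains
  after saturation, whereas much larger domains keep annihilating and
  creating pinwheels during the long-range alignment epoch.
* The greedy charge-restricted matcher can mislabel a fast symmetric
  exchange of two like-charge pinwheels between coarse frames; the
  frame-doubling stability check bounds the effect on event rates.
* Hexagonal/rhombic wavevector triads are distorted to the nearest torus
  lattice modes; on ≥ 8 Λ domains the distortion is below 4°.
* The stationarity criterion (RMS rhs < 1e-6 over one τ) can freeze slow
  domain-wall motion that would continue on astronomically long timescales;
  this matches the "attractor reached for practical purposes" reading.
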