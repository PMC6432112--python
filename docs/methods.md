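# Methods

## Model

The chain is an inextensible worm-like chain (WLC): a space curve r(s),
s ∈ [0, L], with unit tangent u(s) = ∂r/∂s and bending energy

    EB = (κ/2) ∫₀ᴸ |∂u/∂s|² ds,

κ the bending modulus.  The persistence length lp = κ/kBT sets the
tangent correlation length.  A compressive load f couples to the
end-to-end *distance* R = |r(L) − r(0)| through Ef = f R, which favors
bringing the ends together.  Everything internal runs in natural units:
lengths in 2 lp (so the dimensionless contour length is N = L/(2 lp)
and end separations are r = R/(2 lp)), energies in kBT, forces in
kBT/(2 lp).  In these units the hinged-rod Euler force is
f̃E = π²/(2N²).

End tangents are free (hinged) throughout: the path integral behind the
Green function integrates freely over end orientations, the elastica
reference uses moment-free ends (that is the boundary condition under
which the quoted Euler load π²κ/L² is exact), and the fixed-extension
Monte Carlo pins end *positions* only.  The three components are
therefore mutually consistent.

Excluded volume, twist, hydrodynamics and any kinetics are outside the
model.

## Exact end-to-end distribution

The Fourier–Laplace transform of the end-to-end distribution has the
exact continued-fraction form

    G(K;p) = 1/(P₀ + (a₁K)²/(P₁ + (a₂K)²/(P₂ + ⋯))),
    P_l = p + l(l+1),   a_l = l/√((2l+1)(2l−1)),

with K conjugate to r (convention G(K;N) = ⟨sin(Kr)/(Kr)⟩, so
G(0;N) = 1) and p conjugate to N.  The truncated fraction is the (0,0)
resolvent element of a tridiagonal operator; after a diag(iˡ)
similarity this operator is real, with eigenvalues −p_j giving the
poles of G(K;p) and residues available from right eigenvectors alone
through the parity identity res_j = v_j[0]²/Σ_l(−1)ˡ v_j[l]².

**Inverse Laplace (p → N).**  Three routes, used where each is sound:

* *Pole/residue sum* — exact structure, G(K;N) = Σ res_j e^{p_j N}.
  Default wherever the retained poles are well separated.
* *Fourier-series Bromwich inversion* (Abate–Whitt "Euler" algorithm,
  vertical line Re p = A/(2N), A = 23, Euler-accelerated truncation) —
  used in the wavevector zone where pairs of real poles are merging
  into complex-conjugate pairs (residues diverge pairwise at the
  exceptional points); fixed precision is sufficient there because
  G(K;N) is not yet exponentially small.  Discretization error is
  ~e^{−A} relative.
* *High-precision de Hoog contour* (mpmath, precision raised until two
  levels agree) — the independent cross-check oracle.  A Talbot contour
  is *not* usable here: at large K the leading poles carry imaginary
  parts comparable to K and fall outside a Talbot contour's reach.

**Inverse Fourier (K → r).**  G(r;N) = (1/2π²r) ∫₀^∞ K sin(Kr) G(K;N) dK.
G(K;N) is tabulated on a fine uniform K grid (ΔK = 0.033/N, resolving
its own oscillation scale ~1/N) by *pole marching*: the few poles
inside the decay window Re p·N > −33 are continued in K with Newton
polishing on the continued fraction, seeded and periodically resynced
against dense eigendecompositions while real poles remain in the
window, and running free once every windowed pole is a clean conjugate
pair (their real parts descend monotonically with K, so no pole can
enter the window unseen).  Poles whose residues fall below 10⁻⁵ are
dormant — their zero of 1/G nearly cancels against an adjacent pole of
1/G, leaving a Newton basin smaller than any usable seed — and are
carried by extrapolation only; anchors re-activate them.  The grid
extends until the spectral envelope falls below 10⁻⁸ of its peak
(K_max ≈ 8000 at N = 0.25, ≈ 45 at N = 4), with a closed-form linear-
exponential model of the leading branch supplying the truncated tail.
Each cubic-spline piece of K·G(K;N) is then integrated against
sin(Kr) exactly (Filon quadrature), so kernel oscillation costs
nothing.  Contracts enforced on every inversion: 3D normalization
∫4πr²G dr = 1 within 10⁻³ and second moment equal to the closed form
⟨r²⟩ = N − (1−e^{−2N})/2 within 10⁻³ relative (both typically hold to
10⁻⁸); residual negative ringing is clipped only below 10⁻⁶ of the
peak, larger negativity is an error.

The radial grid is interior to (0, N) (F = −log r²G diverges at both
ends), 400 points by default, square-root-stretched toward r = N.
Free energies are only trusted where the density exceeds 10⁻¹² of its
peak (the double-precision quadrature noise floor); outside this
credible window F is reported as +inf and minima touching the window
edge are flagged.

**Stiff chains (N < 0.15).**  The density collapses onto a shell of
width O(N²) near full extension and the required K_max grows like
1/N²; the exact route becomes numerically meaningless in double
precision.  Instead the weakly-bending limit of the same Green function
is used: with free ends the Laplace transform of the retraction
η = N − r is ⟨e^{−μη}⟩ = z/sinh z, z = √(2μ)·N, giving

    P(η) = 2α Σ_{k≥1} (−1)^{k+1} k² e^{−k²αη},   α = π²/(2N²),

evaluated through a Jacobi theta transformation for small αη.  (Note
α is exactly the dimensionless Euler force: the stiff free energy rises
as fE per unit retraction, the second-order-transition energetics.)
The relative error of this branch is O(N).  Its free energy is only
controlled near full extension, so beyond a matched retraction
η_c = 2/α the landscape is continued by the constrained elastica
bending energy, spliced continuously (both behave as αη + O(η²) at the
splice).  Consequence: very stiff post-buckling *retraction amplitudes*
are only as accurate as the elastica there, but the critical force —
which lives at small retraction — is unaffected.

## Buckling observables

F(r; f) = −log(r²G) + f r.  Rmin(f) is found by continuous minimization
on a cubic spline of F₀ = −log(r²G) (dense scan plus bracketed root of
F₀′ + f = 0), the response αF = −dRmin/df from the derivative of a
cubic spline through Rmin(f), and fc from a quadratically refined
argmax that must lie strictly inside the usable force range.  Defaults:
121 forces spanning [−1, 4]·fE (the tension branch is kept for
continuity checks), αF in (2 lp)²/kBT units (its normalization does not
move the argmax).  Profile curvature at each minimum is recorded so the
post-buckling flatness (the driver of the large conformational
fluctuations) is visible downstream.

## Zero-temperature reference

Hinged–hinged elastica via complete elliptic integrals: modulus m from
2K(m) = π√(f/fE); extension R/L = 2E(m)/K(m) − 1; shape
sin(θ/2) = √m · sn(K(1−2s/L)|m); bending energy EB = 2fL(E/K − 1 + m).
An independent brute-force oracle minimizes the discretized energy over
201 segments: fixed-load minimization ramps the load from just above fE
(warm starts keep descent on the buckled branch; the transverse end
displacement is pinned by a stiff quadratic penalty so smooth descent
cannot hop the bending barrier to the reversed-rod branch), and the
fixed-extension minimizer uses SLSQP with the end-to-end vector
gauge-fixed along one axis.  Parametric and brute-force solutions agree
to ~3·10⁻⁴ relative over f/fE ∈ [1.05, 4].

## Monte Carlo

Rigid bonds of length ds = N/(Nb−1), bending-only joint energy
k(1 − u_i·u_{i+1}) with k = lp/ds — the direct discretization of EB.
Fixed-extension sampling uses crankshaft moves only (rotation of the
sub-chain between two anchor beads about their axis), which conserve
the end distance exactly; fixed-force sampling adds end pivots and the
weight e^{−(EB + fR)}.  Move amplitude is tuned to ≈40% acceptance
during equilibration and then frozen (tuning during production would
violate detailed balance).  Defaults: 2·10⁴ equilibration sweeps,
2·10⁵ production sweeps, one sweep = Nb attempted moves, samples every
10 sweeps, errors from ≥20-block averaging.  One seeded RNG stream per
run: identical seed and configuration reproduce the sample stream
bit-for-bit.  Initial states: circular arc with the target chord
(fixed-R), straight chain (fixed-f).

Analytic oracles for the free chain (independent joints): per-joint
⟨u_i·u_{i+1}⟩ = coth k − 1/k, ⟨Epoly⟩ = (Nb−2)(k + 1 − k coth k), and
the freely-rotating ⟨R²⟩ closed form, which differs from the continuum
⟨r²⟩ by O(ds) — that gap is computed exactly and used as the allowance
when simulation is compared against the continuum.

**Reference energy.**  ⟨Epoly⟩ grows linearly with Nb at fixed
deformation (equipartition of the bending modes); subtracting a linear
reference E0 exposes the Nb-invariant deformation energy.  The default
keeps the convention E0 = (5/2)kBT(Nb−4).  For *this* rigid-bond model
the empirically regressed slope is ≈1.0 kBT per bead (two ≈kBT/2
bending modes per interior joint); a (5/2) slope would correspond to a
discretization with additional quadratic modes per bead (e.g.
extensible bonds).  The empirical mode regresses ⟨Epoly⟩ against Nb at
fixed R across ≥3 bead counts and reports slope and intercept, and the
discretization-invariance checks use that fitted slope; the
discrepancy with the (5/2) convention is surfaced in outputs rather
than hidden.  E0 is additive, so at fixed Nb the entropy decomposition

    T S(R) = ⟨Epoly⟩(R) − E0 − F(R)

is shifted uniformly by the choice of E0; the location of the entropy
maximum and all R-dependence are E0-independent.

## What the synthetic conditions do and do not show

All inputs are physical parameters; there is no external data.  The
Monte Carlo emulates the ideal WLC only — no excluded volume, no
sequence heterogeneity, no salt effects, no twist — so agreement
between simulation and the exact pipeline validates the numerics and
the statistical mechanics of the ideal model, not the behavior of any
specific biopolymer beyond the regime where the WLC describes it.
Comparisons against histograms use decorrelated samples (stride chosen
so the lag-1 autocorrelation is small) with binomial errors on the
effective sample count.

## Problem sizes

Default study conditions: chain lengths N ∈ [0.25, 2] on a 15-point
grid with 121 forces each for the critical-force sweep (the stiff
branch covers N = 0.01 for the Euler-limit check); Nb ∈ {11, 31, 51}
beads, 2·10⁵ production sweeps for Monte Carlo comparisons at N = 0.25
(L = lp/2); 400-point radial grids (1200 for the stiff branch).  These
sizes keep every quantity's statistical or quadrature uncertainty well
below the tolerances asserted in the test suite.

## Known limitations

* The credible-window floor (~10⁻¹² of the density peak) caps usable
  free-energy depths at ≈27 kBT; at N = 0.25 the largest compressions
  (f → 4fE) probe close to that depth.  fc extraction is unaffected
  (the response maximum sits at much shallower depths).
* The stiff branch's post-buckling landscape is elastica-continued
  (see above); below N ≈ 0.15 the retraction branch is a controlled
  approximation, not exact.
* Pole marching assumes the real parts of Green-function poles descend
  monotonically in K (verified numerically over the working range);
  the Fourier-series zone plus dense-eigendecomposition anchors make
  the collision-rich region independent of that assumption.
* The elastica reference excludes self-contact; extensions below
  R/L ≈ −1 + ε are rejected.
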