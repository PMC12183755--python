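# Methods

## Coordinates and units

All computation is in Hartree atomic units with mass-weighted Cartesian
coordinates Q_(A,k) = √m_A · x_(A,k) (units √mₑ·bohr), in which the
kinetic operator is −½∇² and the Hessian eigenvalues are squared angular
frequencies ω². I/O uses Å, amu and cm⁻¹ with the conversions
1 amu = 1822.888486 mₑ, 1 Å = 1.8897261255 bohr,
1 hartree = 219474.6313705 cm⁻¹. Abstract systems of arbitrary dimension D
(model potentials) are first class; they carry no atom structure and no
rigid-body subspace, which is what the 1D/2D oracle comparisons need.

## Basis functions and width regularization

A basis is G(Q) = exp[−(Q−Q₀)ᵀα(Q−Q₀) + ζ] with α = ½√(V″_reg) and
ζ = ¼ ln det(2α/π), the exact ground-state Gaussian of the local harmonic
oscillator when V″ is positive definite. The regularization of the raw
Hessian works on its eigenvalues:

* negative eigenvalues are sign-flipped — a steep negative curvature means
  a sharply peaked wavefunction, which a narrow basis represents better
  than a wide one;
* eigenvalues close to zero are replaced by ω_c², where ω_c is a
  user-chosen frequency (`v_const_wavenumber`, default 700 cm⁻¹).

"Close to zero" is by default measured against the inserted constant
itself, |λ| < ω_c², so ω_c² acts as a curvature floor: no direction of the
basis is ever wider than a mode of frequency ω_c. This is what makes the
choice of the constant matter in practice — it should sit somewhat below
the frequency of the mode of interest (the double-well fixture uses
2800 cm⁻¹ against a 3141 cm⁻¹ well frequency; a molecular system with a
≈950 cm⁻¹ inversion mode would use ≈700 cm⁻¹). Without the floor, regions
of small curvature (e.g. quartic inflection points, where V″ → 0) produce
enormously wide Gaussians for which the local harmonic approximation of
the potential breaks down; on the double-well fixture this error reaches
10⁻³ hartree on diagonal potential elements (verified against quadrature)
and wrecks the spectrum. A strict nullspace-only tolerance
(|λ| < (10 cm⁻¹)², `STRICT_ZERO_TOL`) remains available for callers who
only want the exact translation/rotation zero modes replaced.
Regularization affects only the basis widths; potential matrix elements
always use the raw Hessian.

## Matrix elements

With A = α₁+α₂, B = α₁A⁻¹α₂ and d = Q₁−Q₂:

* overlap: ⟨G₁|G₂⟩ = e^{ζ₁+ζ₂} √(π^D/det A) · e^{−dᵀBd};
* momentum moments: ⟨G₁|P_a P_b|G₂⟩ = ⟨G₁|G₂⟩ (2B − 4(Bd)(Bd)ᵀ)_{ab};
* vibrational kinetic energy: ½Tr[(1 − O_tra − O_rot) M] with M the
  moment matrix; O_tra/O_rot are the idempotent projectors onto rigid
  translations (3) and rotations (3, or 2 for collinear references), built
  from mass-weighted translation vectors and Gram–Schmidt-orthonormalized
  rotation vectors at a single reference geometry per run;
* potential (local harmonic approximation, LHA): the energy plus
  ¼Tr[(α₁+α₂)⁻¹V″] at the width-weighted pair midpoint, times the overlap.

All closed forms are gated by adaptive Gauss–Hermite quadrature oracles
(D ≤ 3, tolerance 10⁻⁸) in the test suite; the derivations are trusted
only through those tests. The projected kinetic operator uses a constant
projector (operator ordering P̂ᵀOP̂ with position-independent O) built at
one reference structure; per-pair references would make T_vib
non-Hermitian.

## Solver

The generalized eigenproblem is solved by canonical orthogonalization:
eigendecompose S, drop directions below `s_tol` × (largest eigenvalue),
diagonalize the transformed Hamiltonian in the retained subspace. The
default `s_tol` is 1e-4. This is deliberately more aggressive than the
1e-8 of exact-Hamiltonian practice: the LHA potential matrix is accurate
to roughly 10⁻³ relative, and overlap eigendirections weighted below that
scale amplify the LHA error nonvariationally (with 1e-8 a redundant chain
of 0.9-overlap bases produces meaningless spectra). The retained rank and
smallest kept overlap eigenvalue are always reported.

Because the LHA is not a true operator expectation, the method is not
strictly variational: computed ground states can fall below the exact
value (≈35 cm⁻¹ on the double-well fixture, ≈2.4% of the ZPE), and adding
bases lowers the energy only to within LHA accuracy (~10⁻⁵ hartree on the
fixture). Property tests assert monotonicity at that tolerance and do not
assert a strict variational bound.

Tunneling doublets are labeled by gap ratio (consecutive levels whose gap
is < 20% of the gap to the next level); parity labels come from the sign
of ⟨χ|σ|χ⟩ when a reflection operation is supplied.

## Automatic basis construction

1. `n_irc_bases` bases equally spaced in arc length on the path,
   endpoints included.
2. PCA on the path resampled to ≥ 20 × `n_irc_bases` structures, uniform
   in arc length (making variances resolution independent). The
   covariance is the plain sum of outer products of mean-centered
   structures; only variance ratios λ_n/λ₁ are used, so normalization is
   immaterial. Components with λ_n/λ₁ ≥ `pc_ratio_threshold` (default
   10⁻³) are selected.
3. First-order candidates Q ± d·PCn per center with d solving
   overlap = `target_overlap` (default 0.75; bisection, cross-checked
   against the closed form d = √(−2 ln s₀ / uᵀαu)); second-order
   candidates Q ± (d_n PCn ± d_n′ PCn′) for distinct component pairs
   only — no ±2d single-component shifts. Optionally each component is
   first orthogonalized to the local path tangent.
4. Widths are recomputed from the Hessian at each candidate center;
   candidates are visited in a deterministic order (center index, then
   component indices, then sign pattern) and kept iff their largest
   overlap with all accepted bases is ≤ `prune_overlap_max` (default 0.9,
   duplicates removed first). Greedy deterministic pruning was chosen over
   a global criterion for reproducibility; identical runs produce
   identical basis files.

A reference "all local normal modes" construction uses the eigenvectors
of the regularized Hessian at each center (trans/rot modes excluded) with
the same shift scheme.

The cost metric is the number of unique potential evaluations: orbits of
unordered basis pairs under the index permutation induced by a symmetry
operation (pairs mode), or orbits of centers when the interpolator
supplies midpoints (centers mode). Pair information is propagated to
symmetric images by transforming energy/gradient/Hessian
(E, Mg, MHMᵀ) instead of re-evaluating; images whose transformed midpoint
does not coincide with the actual pair midpoint fall back to direct
evaluation.

## Gaussian-process interpolation

Targets per training center: the energy plus the D(D+1)/2 upper-triangle
Hessian elements, centered and scaled per column (energies and Hessian
elements differ by orders of magnitude; the kernel amplitude τ then acts
on unit-variance targets). One shared squared-exponential kernel
k = τ² exp(−‖ΔQ‖²/2β²) serves all columns with a single Cholesky
factorization. Hyperparameters are selected on a grid (τ ∈ {0.3, 1, 3};
β over the {10, 25, 50, 75, 90}th percentiles of pairwise training
distances) by the closed-form leave-one-out identity, with the objective
the summed squared LOO error of the scalar
V(Qᵢ) + ¼Tr[(2αᵢ)⁻¹V″(Qᵢ)] — the quantity that actually enters the
potential matrix element — reconstructed from the per-column residuals.

σ is a conditioning constant, not a noise model (the training targets are
deterministic): default 10⁻⁵ in scaled-target units (σ² = 10⁻¹⁰), small
enough to stay in the interpolation regime, large enough that the Gram
matrix remains factorizable and the closed-form LOO stays numerically
honest at the longest grid length scales. Predicted Hessians are
symmetric by construction. The provider-compatible GPR source returns the
stored exact information at registered training centers and regression
output elsewhere, logging which path served each request.

## Fixtures and oracles

* **Quartic double well** V = V₀(Q₁²−a²)²/a⁴ + Σ_k ½ω_k²(Q_k + c_k Q₁²)²
  with analytic gradients and Hessians; defaults V₀ = 1.6·10⁻² hartree,
  a = 25 √mₑ·bohr, one transverse ω = 4·10⁻³ a.u. put the ground doublet
  splitting (≈44 cm⁻¹) at ≈1.4% of the well frequency — the
  tunneling-dominated regime of an umbrella inversion, at desk scale.
  The c_k coupling bends the reaction path off the Q₁ axis, giving the
  PCA a genuine second component to find.
* **Steepest-descent path generator**: normalized-gradient Euler steps
  (default 0.05 a.u.) from the saddle, displaced ±10⁻⁴ along the
  negative-curvature eigenvector, per branch until the energy stops
  decreasing, then a quasi-Newton polish of the endpoint to gradient norm
  < 10⁻⁸ (plain Euler oscillates around a quadratic minimum without
  converging); branches concatenated minima-to-minima.
* **Sinc-DVR eigensolver** (1D/2D) as the independent grid oracle, with a
  doubling self-convergence check. Box sizes must leave the classical
  turning points well inside the grid; truncation, not grid spacing, is
  the usual accuracy limit for soft modes.
* **Pseudo-triatomic**: a bent 3-atom molecule with V quadratic in exact
  internal coordinates (two bonds, one angle), so the Cartesian Hessian at
  equilibrium is J ᵀKJ with an exact 6-dimensional rigid-body nullspace.
  Gradients are analytic; off-equilibrium Hessians come from central
  differences of the analytic gradient. This is the test bed for the
  kinetic projections: the single-basis ZPE equals ½Σωᵢ of the three
  internal modes to 10⁻¹², and spectra are invariant under rigid
  translations of all centers.

What the fixtures do **not** emulate: real electronic-structure noise in
energies/Hessians, anharmonic mode–mode couplings beyond the quartic
reaction coordinate and the bilinear path-bending term, rovibrational
coupling, and high densities of states. Passing tests therefore
demonstrate correctness of the machinery and the advertised convergence
behavior on tunneling-dominated model landscapes, not quantitative
accuracy for any specific molecule.

## Problem sizes

The default test-suite and acceptance-script runs use 1D/2D model systems
with ≤ 23 bases, ≤ 512-point DVR grids and ≤ 40-point GPR training sets;
a full build-solve cycle takes well under a second, and the whole suite
runs in seconds.

## Known limitations

* The LHA is second order; quartic landscapes need the width floor and
  moderate basis redundancy (pairwise overlaps ≲ 0.9) to stay accurate.
* The rotational projector is built once per run at a single reference
  structure (default behavior; per-pair references would break
  Hermiticity). For strongly bent paths this is an approximation.
* One shared (τ, β) pair for all GPR target columns; per-column
  hyperparameters and gradient-enhanced kernels are out of scope.
* Time propagation of the expansion coefficients is not implemented; the
  package computes eigenstates.
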