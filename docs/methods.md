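# Methods

This note records the model assumptions, unit conventions, numerical
choices, and the design decisions behind `nuclens`, together with what the
synthetic fixtures do and do not establish about real systems.

## Line-shape model and absolute scale

The band is modelled as the ensemble average of Gaussian-broadened stick
spectra.  Two conventions fix everything else:

- **Gaussian width.** g(ΔE, δ) = exp(−ΔE²/δ²)/(δ√π), i.e. δ is the 1/e
  half-width (the Gaussian standard deviation is δ/√2), and g has unit area
  in energy.  A convention treating δ as the standard deviation would
  rescale peak heights by √2 but leave integrated intensities and relative
  band shapes unchanged, since the sum rule below is width-independent.
- **Prefactor.** C = πe²ħ/(2mcε₀), evaluated from CODATA constants
  (`scipy.constants`) and expressed in eV·cm²: 1.0976×10⁻¹⁶.  This makes
  ∫σ(E)dE = C × (mean over geometries of Σ_l f) exactly, which the test
  suite verifies at δ ∈ {0.001, 0.2, 0.5} to 1e-6 relative — reconvolution
  with a drastically smaller δ redistributes but never creates or destroys
  intensity.

Defaults: δ = 0.2 eV (small enough not to wash out electronic structure,
large enough not to fake rovibrational peaks the model cannot predict);
evaluation grid 0.5–10 eV in 0.01 eV steps, which covers visible and deep-UV
bands of small organic chromophores.  Gaussians are accumulated only within
±8δ of each line; the neglected tail area is erfc(8) ≈ 1.1×10⁻²⁹ of a line.

The sampling error δσ(E) is, by default, the standard error of the mean of
the per-geometry signals σ_k(E) (sample standard deviation over √N_p),
because the quantity it shades is the uncertainty of the mean spectrum; a
`population-std` mode returns the raw spread instead for readers who want
the ensemble dispersion itself.  ε(E) = σ(E)·N_A/(10³ ln 10) ≈
σ·2.6154×10²⁰ converts to the decadic molar convention.  Photolysis rates
use the trapezoidal rule on the quantum-yield/irradiance wavelength grid
with σ interpolated linearly in λ; halving the grid step on a smooth band
changes J by < 10⁻⁶ relative.

## Normal modes

Hessians are taken in Hartree/Bohr² with masses in amu; eigenvalues of the
mass-weighted Hessian convert to wavenumbers by
sqrt(E_h/(amu·a₀²))/(2πc) ≈ 5140.49 cm⁻¹.  Rigid translations and rotations
are removed by projecting onto the orthogonal complement of the six (five,
if linear) mass-weighted rigid-motion vectors built at the input geometry
(Eckart frame); the internal block is then diagonalized exactly, so the
retained eigenvalue count is always 3N−6/3N−5 with no near-zero leakage.
Whether a quantum-chemistry program's own modes were projected this way or
not cannot be recovered from a frequency file, so imported Cartesian modes
are mass-weighted, checked for orthonormality (Gram deviation < 10⁻³), and
symmetrically (Löwdin) re-orthonormalized — the closest orthonormal set to
the input.  A file carrying one more mode than 3N−6 for a nonlinear
geometry is accepted with a warning and `n_projected` inferred from the
file, since some programs project only five rigid modes.

Linearity is detected by the smallest principal moment of inertia falling
below 10⁻⁸ amu·Å², robust for both toys and real molecules.  Imaginary
frequencies are encoded as negative wavenumbers (lossless, no complex
arithmetic); policy is deferred to the sampler.

## Wigner sampling

Only the coordinate marginal is sampled — absorption needs geometries, not
momenta.  At T = 0 each retained normal coordinate is Gaussian with
variance ħ/(2ω); the thermal factor coth(ħω/2k_BT) is available because
condensed-phase MD comparisons run at 300 K.  Modes below a 10 cm⁻¹ cutoff
are skipped and recorded: their widths diverge as 1/√ω and their harmonic
treatment is meaningless anyway.  Imaginary modes above the cutoff raise an
error unless the caller opts into skipping them.  One seeded generator
fills the normal-coordinate matrix in mode-major order, which makes
ensembles bit-reproducible and stable under changes of sample count
downstream.  Because mode vectors are orthogonal to the rigid-motion space,
the ensemble has exactly zero mass-weighted centroid displacement and zero
net angular displacement before any alignment — a property the tests check
to 10⁻⁸.

Dihedral diagnostics use circular statistics (mean from the resultant
vector angle, std = √(−2 ln R)) on the (−180°, 180°] branch, so planar
equilibria centered at ±180° do not suffer branch-cut artifacts.

## Alignment (absolute orientation)

The rotation is obtained from the SVD of the weighted cross-correlation
matrix A = Σ w x̃ ỹᵀ of the centered sets, with the singular direction of
smallest singular value sign-corrected so det R = +1.  This is the
proper-rotation polar factor of A and attains the global minimum of the
weighted least-squares objective over SO(3); when det A < 0 the optimum is
not the unconstrained orthogonal polar factor (a reflection) but the
flipped one, which the test suite validates against an exhaustive 2° Euler
rotation grid.  Weights default to uniform over atom positions; mass
weighting is a flag.  Rank-deficient A (collinear sets) and near-ties of
the decisive singular values are flagged `degenerate`: the returned
rotation is still orthogonal and still a minimizer, but no longer unique.

## Insertion protocol

Wigner geometries are dealt to snapshots by a seeded uniform permutation
taken round-robin, which reproduces the even 100-into-10 and 100-into-25
splits exactly and spreads any remainder within one geometry.  Each
geometry is aligned onto the chromophore's *instantaneous* pose in its
snapshot — substitution in place — and swapped in; solvent coordinates,
ordering, and charges are bit-identical before and after, which is the
exact-case core of the solvent-shell (g(r)) validation.  The short
frozen-chromophore solvent-relaxation MD that a production workflow runs
after substitution requires an MD engine and is deliberately out of scope;
in its place the package emits a clash report (default threshold 1.5 Å,
minimum-image in orthorhombic boxes) and engine-ready electrostatic-
embedding files (chromophore XYZ + solvent `x y z q`), so the relaxation
step can be handed to any engine.

g(r) is normalized by the ideal-gas shell expectation at the mean number
density of the partner group, with self-pairs excluded where the groups
overlap; a box volume is therefore required.  Only orthorhombic periodicity
is supported.

## Synthetic fixtures: what they do and do not show

The toy molecules (diatomic; bent triatomic; a planar 4-atom O=C–C=C-like
chain with a torsional spring) have Hessians assembled exactly as
H = Σ_t k_t B_tᵀB_t from Wilson B rows at equilibrium, so symmetry and
translational invariance hold to machine precision, and their vibrational
frequencies are available through an independent route — the Wilson
GF-matrix eigenproblem (F^{1/2}GF^{1/2}) for the polyatomics and the
literal reduced-mass closed form for the diatomic.  Default force constants
(0.3 Hartree/Bohr² bonds, 0.15 Hartree/rad² angles, 0.02 Hartree/rad²
torsion) put wavenumbers in the 200–3000 cm⁻¹ range of organic
chromophores.  Transition ensembles draw E and f from stated Gaussians
(f clipped at zero); the toy water boxes pack rigid 3-point waters
(0.9572 Å / 104.52°, charges −0.834/+0.417 e, matching the common 3-point
model) with a 2 Å minimum separation.

These fixtures validate unit chains, statistical estimators, bookkeeping,
and the alignment/sampling algebra.  They do not contain anharmonicity,
vibronic (Franck–Condon/Herzberg–Teller) structure, state reordering along
the ensemble, charge-transfer solvent shifts, or real solvation-shell
structure — so passing tests demonstrate correctness of the protocol, not
spectroscopic accuracy for any particular molecule, which is inherited
from the quality of the (E_va, f) inputs.

## Problem sizes

Default test and reproduction runs use ensembles of 10–400 geometries for
spectra, 2×10⁴–2×10⁵ Wigner samples for variance recovery, 100 random
configurations against the full 2° rotation grid (evaluated through the
trace identity rmsd²(R) = (S_xx+S_yy−2 tr(RA))/W, which makes the ~3M-point
grid cheap), and 20–25-water toy boxes.  These sizes were chosen so the
statistical tolerances above are meaningful while a full run stays
desk-scale.

## Known limitations

- Harmonic Wigner sampling only: no anharmonic (PIMD-style) corrections,
  no excited-state sampling, no sampling from trajectories (ensembles read
  from file are accepted, not generated).
- No rovibrational resolution: δ is phenomenological and the model cannot
  produce vibronic fine structure.
- N_fs may vary per geometry (states dropping below thresholds); the
  convolution then uses each geometry's own state count and warns.
- Quantum-chemistry log files are not parsed; frequency data enters via
  Molden blocks or the JSON schema (docs/frequency_schema.md).
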