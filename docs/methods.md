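# Methods

## The model

`coswater` implements a rigid, four-site, explicitly polarizable water
model and the full pipeline used to parameterize and validate it.  The
molecule has

* an oxygen that carries the single van der Waals site (no static charge),
* two hydrogens with charge `q_H = 0.539 e`,
* a massless off-atom site M on the H–O–H bisector, `d_OM = 0.0225 nm`
  from the oxygen, carrying `q_M = −1.078 e`,
* a charge-on-spring (COS) particle of charge `q_COS = −8 e` tethered to M
  by a harmonic spring.  In the simulation topology M carries the
  effective charge `q_M − q_COS = +6.922 e` so the molecule stays neutral.

The spring constant is fixed by the isotropic polarizability volume α:
`k = f_elec q_COS² / α` with `f_elec = 138.935458 kJ mol⁻¹ nm e⁻²`, so a
displaced COS particle represents an induced point dipole
`μ_ind = q_COS d = α E / f_elec`.  The default `α = 1.05×10⁻³ nm³` is the
condensed-phase value produced by the consensus fitting procedure below.
The large magnitude of `q_COS` keeps displacements small enough that the
driving field can be evaluated at the *host* site M rather than at the COS
particle itself; that convention is part of the model definition and is
retained here (its energetic consequences are quantified below).

Van der Waals interactions between oxygens use a C6–C8–C11 potential

    V(r) = −C6/r⁶ − C8/r⁸ + C11/r¹¹

with molecular `C6 = 43.44 a.u.` and `C8 = 1201.3 a.u.` obtained by
re-partitioning atomic exchange-hole-dipole-moment (XDM) coefficients
onto the oxygen via square-root summation,
`C6_comb = (√C6_O + 2√C6_H)²` (likewise C8).  The repulsive constant is
not free: it is fixed by requiring `V(σ) = 0` at the sum of van der Waals
radii, which reduces algebraically to `C11 = C6 σ⁵ + C8 σ³`.  With the
oxygen radius `r_O = 0.1605 nm` (the model's single calibrated
parameter), `σ = 0.321 nm` and `C11 ≈ 1.495×10⁻⁵ kJ mol⁻¹ nm¹¹`.
Atomic-unit coefficients convert to internal units (nm, kJ mol⁻¹) with
`E_h = 2625.4996 kJ mol⁻¹` and `a₀ = 0.052917721 nm`.

The rigid geometry defaults are `r_OH = 0.0962 nm`, `θ_HOH = 105.4°`.
These are reconstructed from the published charge set, M-site offset and
gas-phase dipole rather than read from a machine-readable source; with
them the model's static dipole evaluates to 1.8535 D (the reference
gas-phase value is 1.855–1.856 D).  Both are config-overridable, and all
fitting utilities accept arbitrary geometries.

## Consensus polarizability fitting

The condensed-phase polarizability is estimated from induced molecular
electrostatic potentials (MEPs).  For each solvent configuration
(a "frame"), the difference `φ_induced = φ_solv − φ_vac` on a surface grid
is modeled as the potential of a point dipole at the polarizable center
(the oxygen, by convention, during fitting; the final model attaches the
polarizability to M — the two sites are 0.0225 nm apart and the choice is
a config option):

    φ(n) = f_elec μ·r_n / r_n³ ,    μ_k = α_k E_k / f_elec ,

with E the external field at the center summed over *all* shell charges,
deliberately without any cutoff, so the field is consistent with the
charge set that generated the MEP.

Two estimators are provided:

* **free fit** — per frame, unconstrained linear least squares for μ;
  `α_k = f_elec μ_k / E_k`.  When `|E_k|` is small the ratio is
  ill-conditioned (it can even change sign); frame-dimensions with
  `|E_k| < 1 kJ mol⁻¹ nm⁻¹ e⁻¹` are flagged unusable for the ratio but
  still contribute grid equations elsewhere.
* **consensus fit** — the ratio is constrained to be identical across a
  subset of n frames (default 20, non-overlapping subsets drawn at
  random).  Substituting the constraint into the dipole-potential model
  leaves only (α_xx, α_yy, α_zz) as unknowns over the pooled grid
  equations of all member frames.  This reduced 3-parameter least squares
  is the production path; an explicit Lagrange-multiplier (KKT) solve of
  the equivalent constrained problem over all per-frame dipole components
  is kept in the test suite as an independent oracle (the two agree to
  1e-8; the reduced form is preferred purely for conditioning).

χ² is the unweighted sum of squared potential residuals over grid points;
by construction χ²(consensus) ≥ χ²(free) on the same frames.  Summary
statistics use type-7 (linear-interpolation) quantiles with box-plot
whiskers capped at 4.0 interquartile ranges; pooled R² is the squared
Pearson correlation of μ_k vs E_k per dimension.

Static charges are fitted to a vacuum MEP by equality-constrained least
squares (total charge exact to 1e-12 via one Lagrange multiplier, the two
hydrogens sharing one parameter), and the M-site position is selected by
scanning displacements 0.007–0.03 nm along the bisector and minimizing
the MEP RMSD of the refitted charge model.

## Synthetic QM/MM inputs

In production use the MEPs come from QM/MM software.  The
`synthetic` module replaces that stage for development and validation:

* **Surface grids**: four layers of scaled Bondi spheres
  (scales 1.4/1.6/1.8/2.0, configurable — the literature source for the
  exact factors is not restated in the protocol) sampled at 5 points per
  bohr² with a deterministic golden-spiral layout; points buried inside a
  sibling sphere of the same layer are removed.
* **Solvent shells**: rigid three-charge (SPC-geometry) waters placed by
  random sequential insertion with random orientations inside a
  0.26–1.4 nm shell around the solute, subject to a 0.24 nm hard-core
  separation between any pair of sites.  Random insertion jams below
  liquid density, so the default shell density is 23 nm⁻³ (liquid water
  is ≈33 nm⁻³); the fitter needs representative field magnitudes and
  geometric diversity, not liquid structure.  Typical fields at the
  oxygen are a few hundred kJ mol⁻¹ nm⁻¹ e⁻¹ per Cartesian component,
  zero-mean over frames — unlike real hydration shells, which produce a
  structured, biased field along the molecular axis.  Passing recovery
  tests therefore demonstrates correctness of the estimators under
  realistic field magnitudes and noise, not the value of the
  polarizability of real water.
* **Induced signal**: `φ_solv = φ_vac + dipole potential of
  μ = α∘E(center)/f_elec`, with two optional perturbations: additive
  Gaussian grid noise (specified absolutely or relative to the induced
  signal RMS) and a per-frame multiplicative factor `(1+ε)`,
  `ε ~ N(0, 0.3)` by default, on μ.  The latter emulates per-frame
  responses beyond point-field linear response; amplitude 0.3 reproduces
  a free-fit pooled R² ≈ 0.9 while the consensus fit restores R² > 0.99.
  With both perturbations off the data satisfy exact linear response and
  the fitters recover the ground truth to ≤1e-10 relative.

## MD engine

Internal units are nm, ps, e, kJ mol⁻¹, K (GROMOS-style conventions).

* **Integration**: leap-frog, `dt = 2 fs`; SHAKE on the three distance
  constraints (O–H1, O–H2, H1–H2) with relative geometric tolerance 1e-4
  (tests that probe energy conservation tighten this to 1e-8).  M is
  rebuilt each step on the bisector; forces on M and on the COS particle
  are redistributed to the massive sites by the transpose of the
  virtual-site Jacobian, preserving net force and torque.
* **Electrostatics**: all intermolecular charge-site pairs (H, H, M_eff,
  COS) of molecule pairs whose oxygens lie within the cutoff interact via
  the Barker–Watts reaction-field kernel
  `q_i q_j f_elec [1/r + C_rf r²/(2 r_c³) − (1 + C_rf/2)/r_c]` with
  `C_rf = 2(ε−1)/(2ε+1)`, `ε = 78.4`.  Intramolecular pairs are fully
  excluded, and no reaction-field self/excluded-pair terms are added.
  The cutoff is `min(1.4 nm, L/2)`; at the desk scales used here
  (64–125 molecules, L ≈ 1.25–1.6 nm) the box, not the model, limits the
  cutoff.  A twin-range pairlist is an efficiency device only and is not
  implemented.
* **Molecular switching (opt-in)**: site-pair interactions of a molecular
  pair can be scaled by a C² switching function of the oxygen–oxygen
  distance over a window below the cutoff (`switch_width`, default 0 =
  hard cutoff).  With a hard molecular cutoff, pairs enter/leave the pair
  list with finite energy jumps — at L/2 ≈ 0.6–0.8 nm this produces NVE
  heating of order 1e3 kJ mol⁻¹ ns⁻¹ per molecule, and a 0.1 nm switch
  suppresses it to a few kJ mol⁻¹ ns⁻¹ (forces remain exact gradients of
  the switched energy, verified against central differences to 1e-6; the
  SCF field kernel applies the same factor).  The switch is *not* used by
  default because its derivative term contributes ≈ −500 bar of spurious
  attraction to the virial at these cutoffs (the pair energy at the
  window is predominantly attractive), visibly biasing NpT densities,
  whereas the weak-coupling thermostat absorbs the hard-cutoff energy
  noise without measurable bias: at 125 molecules and the reference
  density the hard-cutoff mean pressure is ≈ +100 bar versus ≈ −650 bar
  with a 0.1 nm switch.
* **Dispersion tail**: analytic g(r)=1 corrections to energy and virial
  beyond the cutoff for the C6, C8 (and the negligible C11) terms,
  enabled by default.  At r_c ≈ 0.78 nm the missing C6/C8 attraction is
  ≈0.3 kJ mol⁻¹ per molecule, enough to bias the barostat noticeably at
  desk scale.
* **SCF**: COS displacements iterated `d ← α E(M)/(f_elec q_COS)` with
  the field at M from all other molecules (switched RF kernel) plus any
  external field; warm-started from the previous step; convergence when
  the largest displacement change is below 1e-6 nm (max 60 iterations,
  error on non-convergence).  Energy conservation in NVE is limited by
  two effects: the finite SCF tolerance (the warm-started iteration
  leaves a correlated displacement lag each step) and the model's
  field-at-M convention, under which the converged displacement is not
  exactly variational.  Measured at 64 molecules over 10 ps, the
  total-energy drift is of order 5 kJ mol⁻¹ ns⁻¹ per molecule at
  `scf_tol = 1e-8` and below 1 at 1e-10; note that the linear-fit drift
  estimator itself has a noise floor of several kJ mol⁻¹ ns⁻¹ per
  molecule at this run length (energy fluctuation sd ≈ 0.07 kJ mol⁻¹ per
  molecule with strong autocorrelation), so substantially smaller drift
  rates cannot even be resolved on a 10 ps window.
* **Ensembles**: Berendsen weak coupling; thermostat
  `λ = √(1 + dt/τ_T (T₀/T − 1))` with `τ_T = 0.1 ps`; barostat scales the
  box and molecular centers of mass isotropically with
  `μ = (1 − κ dt/τ_p (P₀ − P))^{1/3}`, `τ_p = 0.5 ps`,
  compressibility 4.5e-5 bar⁻¹ (a literature value for water; the
  protocol source does not state one), per-step scaling clamped to ±2%.
  Pressure uses the molecular virial (COM kinetic energy plus
  intermolecular pair forces dotted with COM separations), which needs no
  constraint-force bookkeeping for rigid molecules.  A uniform external
  field E_z adds `q E_z` to every charged site and enters the SCF field;
  its energy is `−E_z Σ μ_mol,z`.
* **Start-up**: simple-cubic lattice at 860 kg m⁻³ with random molecular
  orientations, steepest-descent minimization with frozen (zero) COS
  displacements (close contacts must be relaxed before polarization is
  switched on), then a five-stage NVT warm-up ramping 50 → 298.15 K with
  1 ps per stage (the published five-step schedule is not detailed; equal
  ramp stages are this package's choice), then NpT equilibration.

## Property estimators

All in `liquid`, consuming engine time series; every mean carries a
5-block standard error.

* density `ρ = N M_w /(N_A ⟨V⟩)`;
* heat of vaporization `ΔH_vap = ⟨E_gas⟩ − ⟨E_liq⟩ + RT + C_vib + C_ni`
  per molecule.  For this rigid model the gas reference energy is zero,
  so a gas-phase run is optional.  The vibrational and non-ideality
  corrections are consumed from a user-supplied table (none is bundled;
  defaults are zero with a loud log message);
* static dielectric permittivity from the box-dipole response to an
  applied field, `ε(0) = 1 + 4π f_elec ⟨M_z⟩/(⟨V⟩ E_z)`; the default
  field for such runs is 5 kJ mol⁻¹ nm⁻¹ e⁻¹ with a half-field linearity
  check recommended (no magnitude is given in the protocol source);
* self-diffusion from the Einstein relation: MSD over multiple origins
  (every 10th frame), least-squares slope on the 10–50% lag window,
  `D_pbc = slope/6`, with a nonlinearity flag comparing local slopes; the
  periodic-box correction `D = D_pbc + 2.837297 k_B T/(6π η L)` takes the
  shear viscosity η as an input (η is not computed here — a Green–Kubo
  estimator is out of scope);
* mean molecular dipole (static sites + COS contribution) and
  self-polarization energy `U_selfpol = ½ k Σ|d|²`;
* fluctuation secondary properties from NpT series of H = U + K + pV and
  V: `C_p = ⟨δH²⟩/(N R T²)`, `α_p = cov(V,H)/(R T² ⟨V⟩)`,
  `κ_T = ⟨δV²⟩/(k_B T ⟨V⟩)`.  Finite-difference (temperature-scan)
  alternatives exist in the literature; the fluctuation forms are fixed
  here.

## Problem sizes and what desk-scale runs show

The validation suite uses reduced problem sizes chosen as this package's
study conditions: consensus fitting on 500 synthetic frames in 25
subsets of 20; liquid validation on 125-molecule NpT runs with a few ps
of staged warm-up and equilibration and 10–14 ps of production.  At this
box size the cutoff is L/2 ≈ 0.78 nm rather than 1.4 nm.  Density and
the mean molecular dipole are short-ranged enough to be meaningful at
this scale (within a few percent / 0.1 D); dielectric permittivity,
heat-capacity and compressibility fluctuations, diffusion constants and
the temperature scan of the density need the full-scale (1024-molecule,
multi-ns) protocol and are provided as estimators plus property-based
tests only.

Two desk-scale artifacts are worth knowing.  First, hard-cutoff
pair-list crossings inject heat that the weak-coupling thermostat
removes only up to a steady-state offset `ΔT = h τ_T / dt`: ≈ +4 K at
125 molecules (≈ +12 K at 64), visible in the reported temperatures but
negligible for density/dipole at these magnitudes.  Second, NVE energy
conservation at desk scale requires the opt-in switching function; the
hard cutoff is reserved for thermostatted runs.

## Known limitations

* No polarization damping at high fields; the model relies on the vdW
  core to prevent polarization catastrophe (a displacement guard raises
  on SCF divergence).
* Reaction-field electrostatics only; no lattice-sum option.
* The free-fit design matrix supports multiple polarizable centers, but
  only the single-center mode is validated; the consensus fitter is
  single-center by design.
* Shear viscosity, Hirshfeld-I/XDM coefficient generation and the
  quantum-chemical stages of the original protocol are inputs, not
  computations, throughout.
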