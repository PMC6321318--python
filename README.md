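# coswater

A charge-on-spring (COS) polarizable four-site water model for classical
molecular simulation, together with the complete pipeline used to
parameterize and validate it: consensus fitting of condensed-phase
polarizabilities from induced surface potentials, force-field assembly
with higher-order dispersion, a reaction-field polarizable MD engine,
and pure-liquid property estimators.

## Who this is for

Force-field developers and simulation methodologists who want a small,
fully inspectable implementation of

* the **consensus (multi-frame constrained) polarizability fit**, which
  extracts a well-defined diagonal polarizability tensor from noisy
  per-configuration induced dipoles even when local electric fields are
  weak;
* a **C6–C8–C11 van der Waals model** whose repulsive constant is fixed
  by the van der Waals radius instead of being a free parameter;
* a minimal but complete **polarizable MD engine** (leap-frog, SHAKE,
  virtual M site, SCF charge-on-spring dipoles, Barker–Watts reaction
  field, Berendsen NVT/NpT, external-field mode).

## The model and the method in brief

Rigid four-site water: O (van der Waals site), H/H (`q_H = 0.539 e`),
massless M site on the bisector at 0.0225 nm (`q_M = −1.078 e`), and a
COS particle (`q_COS = −8 e`) sprung to M with
`k = f_elec q_COS²/α`, so its displacement represents an induced dipole
`μ = α E/f_elec` with isotropic polarizability `α = 1.05×10⁻³ nm³`.

Dispersion acts between oxygens only,

```
V(r) = −C6/r⁶ − C8/r⁸ + C11/r¹¹ ,   C11 = C6 σ⁵ + C8 σ³ ,  σ = 2 r_O ,
```

with molecular `C6 = 43.44 a.u.`, `C8 = 1201.3 a.u.` re-partitioned from
atomic XDM coefficients via `√C6_comb = √C6_O + 2√C6_H`, and
`r_O = 0.1605 nm` the model's single empirically calibrated parameter.

The polarizability is fitted from induced molecular electrostatic
potentials `φ_induced = φ_solv − φ_vac` on a surface grid.  The free fit
estimates one induced dipole per solvent configuration and forms
`α_k = f_elec μ_k / E_k`; the consensus fit constrains this ratio to be
identical across subsets of 20 configurations (Lagrange-constrained
least squares, solved in reduced 3-parameter form), which collapses the
spread of the per-subset estimates without biasing the mean.  See
`docs/methods.md` for the full treatment.

## Worked example

```python
import numpy as np
from coswater.forcefield import default_forcefield
from coswater.liquid import yeh_hummer_correct
from coswater.md import box_for_density
from coswater.synthetic import SoluteSpec, generate_dataset, NoiseSpec
from coswater.polfit import run_consensus_pipeline

ff = default_forcefield()
print(f"sigma          = {ff.vdw.sigma:.4f} nm")
print(f"C11            = {ff.vdw.c11:.4e} kJ/mol nm^11")
print(f"static dipole  = {ff.static_dipole:.4f} D")

# synthetic induced-potential data: 100 solvent shells around a solute
# whose true polarizability is the model value, with 5% grid noise and a
# per-frame inhomogeneity perturbation
solute = SoluteSpec.from_forcefield(ff)
ds = generate_dataset(100, solute, seed=7,
                      noise=NoiseSpec(inhomogeneity=0.3), relative_grid_noise=0.05)
free, cons, stats = run_consensus_pipeline(ds, subset_size=20, seed=11)
print(f"alpha_iso (consensus, {len(cons)} subsets) = {stats.alpha_iso_consensus:.4e} nm^3")
print("per-dim sd  free      :", ["%.2e" % s.sd for s in stats.free])
print("per-dim sd  consensus :", ["%.2e" % s.sd for s in stats.consensus])
print("pooled R2   free      :", np.round(stats.r2_free, 3))
print("pooled R2   consensus :", np.round(stats.r2_consensus, 4))

# finite-size correction of a periodic-box diffusion constant
L = box_for_density(1024, 993.0)
print(f"D corrected = {yeh_hummer_correct(1.90, 0.72, 298.15, L):.3f} x 1e-5 cm^2/s")
```

prints

```
sigma          = 0.3210 nm
C11            = 1.4950e-05 kJ/mol nm^11
static dipole  = 1.8535 D
alpha_iso (consensus, 5 subsets) = 1.0777e-03 nm^3
per-dim sd  free      : ['2.91e-04', '2.83e-04', '2.86e-04']
per-dim sd  consensus : ['1.06e-04', '1.63e-04', '1.12e-04']
pooled R2   free      : [0.919 0.933 0.914]
pooled R2   consensus : [0.9919 0.9849 0.9908]
D corrected = 2.174 x 1e-5 cm^2/s
```

Reading this: the consensus fit recovers the ground-truth polarizability
(1.05×10⁻³ nm³) within the subset sampling error while shrinking the
per-fit spread by ~2–3× relative to the free fit, and it restores a
clean linear dipole–field response (R² > 0.98 versus ≈ 0.92) in the
presence of per-frame perturbations.  The last line converts a
periodic-box diffusion constant of 1.90×10⁻⁵ cm² s⁻¹ into the
infinite-box estimate 2.17×10⁻⁵ cm² s⁻¹ using the system viscosity
(0.72 cP) and box edge.

A desk-scale liquid run (125 molecules, NpT, 298.15 K / 1 atm, ~7 min on
one core):

```bash
coswater simulate --n 125 --ensemble npt --steps 5000 --out run/
coswater analyze --energies run/energies.csv --n 125
```

The same pipeline executed by the test suite yields a density of
988 ± 2 kg m⁻³ and a mean molecular dipole of 2.46 D at this box size
(the full-scale reference values are 993 kg m⁻³ and 2.47 D).

## Command-line interface

`coswater build-ff` (TOML config → validated JSON force field, see
`examples/ff.toml`), `coswater synth-qmm` (synthetic shells/grids),
`coswater fit-polarizability` (free + consensus fits from CSV exports),
`coswater simulate`, `coswater analyze`.  All commands are thin wrappers
over the library modules.

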