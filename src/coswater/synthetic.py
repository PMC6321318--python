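"""Synthetic stand-in for the QM/MM polarizability-fitting inputs.

In the real protocol the inputs are produced by MD sampling of solvent
shells around a geometry-constrained solute plus quantum evaluations of
the solute's molecular electrostatic potential (MEP) on a Connolly grid,
in vacuum and embedded in each shell's point charges.  This module
emulates exactly those data from a ground-truth linearly polarizable
solute, so the fitting machinery can be exercised and validated without
quantum software:

* layered Connolly-style surface grids from scaled Bondi spheres,
* solvent shells of rigid three-charge waters placed randomly inside a
  1.4 nm shell (rejection-sampled against overlap),
* vacuum and "solvated" MEPs where the induced signal is the point-dipole
  potential of mu = alpha o E(center) / f_elec, with optional Gaussian
  grid noise and a per-frame field-inhomogeneity perturbation.

With all noise off the generated data satisfy exact linear response, so
the fitter must recover the ground-truth polarizability to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import BOHR_NM, BONDI_RADII_NM, F_ELEC
from .forcefield import ForceField, RigidWaterGeometry

__all__ = [
    "SoluteSpec",
    "SolventShell",
    "MEPGrid",
    "NoiseSpec",
    "SpcSolvent",
    "connolly_grid",
    "sample_solvent_shells",
    "evaluate_field",
    "synth_mep",
    "generate_dataset",
    "PolarizationDataset",
]

DEFAULT_LAYER_SCALES = (1.4, 1.6, 1.8, 2.0)


@dataclass(frozen=True)
class SoluteSpec:
    """Ground truth solute: geometry, static charges and polarizability.

    ``atom_positions``/``atom_elements`` define the physical atoms that
    carry surface-grid spheres; ``charge_positions``/``charges`` the static
    charge sites (which may include off-atom sites); ``alpha_diag`` the
    ground-truth diagonal polarizability tensor (nm^3) located at
    ``center`` (the oxygen by default, matching the fitting convention).
    """

    atom_positions: np.ndarray
    atom_elements: tuple
    charge_positions: np.ndarray
    charges: np.ndarray
    alpha_diag: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def from_forcefield(
        cls,
        ff: ForceField,
        alpha_diag: Optional[Sequence[float]] = None,
        center: str = "O",
    ) -> "SoluteSpec":
        pos = ff.geometry.site_positions()  # O, H1, H2, M
        if alpha_diag is None:
            alpha_diag = [ff.pol.alpha_iso] * 3
        centers = {"O": pos[0], "M": pos[3]}
        return cls(
            atom_positions=pos[:3].copy(),
            atom_elements=("O", "H", "H"),
            charge_positions=pos[1:].copy(),
            charges=np.array([ff.charges.q_H, ff.charges.q_H, ff.charges.q_M]),
            alpha_diag=np.asarray(alpha_diag, dtype=float),
            center=np.asarray(centers[center], dtype=float),
        )


@dataclass
class SolventShell:
    """External point charges of one solvent configuration (one MD frame)."""

    frame_id: int
    positions: np.ndarray  # (n_sites, 3) nm
    charges: np.ndarray  # (n_sites,) e
    mol_ids: np.ndarray  # (n_sites,) int


@dataclass
class MEPGrid:
    """Surface grid with vacuum and per-frame solvated potentials."""

    points: np.ndarray  # (n_pts, 3) nm
    phi_vac: Optional[np.ndarray] = None  # (n_pts,) kJ mol^-1 e^-1
    phi_solv: Optional[np.ndarray] = None  # (n_frames, n_pts)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for the synthetic MEPs.

    ``grid_sd``: additive Gaussian noise on the solvated potential
    (kJ mol^-1 e^-1).  ``inhomogeneity``: sd of the per-frame multiplicative
    perturbation (1 + eps) applied to the induced dipole, emulating
    responses beyond pure linear response to the point field.
    """

    grid_sd: float = 0.0
    inhomogeneity: float = 0.0

    def __post_init__(self):
        if self.grid_sd < 0 or self.inhomogeneity < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class SpcSolvent:
    """Rigid three-charge solvent geometry/charges (SPC water by default)."""

    r_OH: float = 0.1
    theta: float = 109.47
    q_O: float = -0.82
    q_H: float = 0.41

    def site_template(self) -> np.ndarray:
        half = math.radians(self.theta) / 2.0
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [self.r_OH * math.cos(half), self.r_OH * math.sin(half), 0.0],
                [self.r_OH * math.cos(half), -self.r_OH * math.sin(half), 0.0],
            ]
        )

    def site_charges(self) -> np.ndarray:
        return np.array([self.q_O, self.q_H, self.q_H])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-spiral layout)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = 2.0 * math.pi * i / phi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def connolly_grid(
    atom_positions: np.ndarray,
    elements: Sequence[str],
    radii: Optional[dict] = None,
    layer_scales: Sequence[float] = DEFAULT_LAYER_SCALES,
    density: float = 5.0,
) -> np.ndarray:
    """Layered surface grid from scaled atomic spheres.

    For each layer scale s, points are laid out on spheres of radius
    s * r_vdw(element) around every atom at the requested surface density
    (points per bohr^2); points falling strictly inside any other atom's
    sphere of the same layer are discarded.  Deterministic for fixed input.
    """
    if len(layer_scales) < 1:
        raise ValueError("need at least one layer")
    if density <= 0:
        raise ValueError("density must be > 0")
    radii = radii or BONDI_RADII_NM
    atom_positions = np.asarray(atom_positions, dtype=float)
    base_r = np.array([radii[el] for el in elements])
    if np.any(base_r <= 0):
        raise ValueError("atomic radii must be > 0")

    kept = []
    for scale in layer_scales:
        layer_r = scale * base_r
        for a, (pos_a, r_a) in enumerate(zip(atom_positions, layer_r)):
            area_bohr2 = 4.0 * math.pi * (r_a / BOHR_NM) ** 2
            n_pts = max(int(math.ceil(area_bohr2 * density)), 8)
            pts = pos_a + r_a * _fibonacci_sphere(n_pts)
            # prune points buried inside a sibling sphere of this layer
            inside = np.zeros(len(pts), dtype=bool)
            for b, (pos_b, r_b) in enumerate(zip(atom_positions, layer_r)):
                if b == a:
                    continue
                d = np.linalg.norm(pts - pos_b, axis=1)
                inside |= d < r_b * (1.0 - 1e-9)
            kept.append(pts[~inside])
    return np.vstack(kept)


def _sample_shell_radii(rng, n: int, r_in: float, r_out: float) -> np.ndarray:
    u = rng.random(n)
    return (r_in**3 + u * (r_out**3 - r_in**3)) ** (1.0 / 3.0)


def sample_solvent_shells(
    n_frames: int,
    solute: SoluteSpec,
    seed: int,
    shell_inner: float = 0.26,
    shell_outer: float = 1.4,
    solvent: SpcSolvent = SpcSolvent(),
    number_density: float = 23.0,
    min_sep: float = 0.24,
    max_batches: int = 400,
) -> list[SolventShell]:
    """Random rigid-solvent shells emulating MD-sampled configurations.

    Molecules are inserted sequentially with random position and
    orientation; an insertion is accepted when the oxygen lies within
    [shell_inner, shell_outer] of the nearest solute atom and every site
    keeps ``min_sep`` from all previously placed solvent sites and solute
    atoms.  The target count is ``number_density`` (nm^-3) times the shell
    volume.  Random insertion jams below liquid density, hence the reduced
    default density; the fitter only needs representative field magnitudes
    and geometric diversity.  Fully reproducible from ``seed``.
    """
    if shell_inner >= shell_outer:
        raise ValueError("shell_inner must be < shell_outer")
    rng = np.random.default_rng(seed)
    v_shell = 4.0 / 3.0 * math.pi * (shell_outer**3 - shell_inner**3)
    n_target = int(round(number_density * v_shell))
    template = solvent.site_template()
    q_mol = solvent.site_charges()
    solute_tree = cKDTree(solute.atom_positions)

    def _build_frame(rng) -> Optional[list]:
        placed_sites: list[np.ndarray] = [solute.atom_positions]
        site_tree = cKDTree(np.vstack(placed_sites))
        oxygens: list[np.ndarray] = []
        mol_sites: list[np.ndarray] = []
        batches = 0
        while len(mol_sites) < n_target and batches < max_batches:
            batches += 1
            n_prop = min(256, 4 * (n_target - len(mol_sites)) + 16)
            dirs = rng.normal(size=(n_prop, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            r = _sample_shell_radii(rng, n_prop, shell_inner, shell_outer)
            o_pos = dirs * r[:, None]
            # shell criterion relative to the nearest solute atom
            d_near, _ = solute_tree.query(o_pos)
            ok = (d_near >= shell_inner) & (d_near <= shell_outer)
            rots = Rotation.random(n_prop, random_state=rng).as_matrix()
            cand_sites = o_pos[:, None, :] + np.einsum("nij,kj->nki", rots, template)
            accepted_this_batch = []
            for c in np.nonzero(ok)[0]:
                sites = cand_sites[c]
                d, _ = site_tree.query(sites)
                if np.min(d) < min_sep:
                    continue
                if accepted_this_batch:
                    prev = np.vstack(accepted_this_batch)
                    dd = np.linalg.norm(sites[:, None, :] - prev[None, :, :], axis=-1)
                    if dd.min() < min_sep:
                        continue
                accepted_this_batch.append(sites)
                oxygens.append(o_pos[c])
                mol_sites.append(sites)
                if len(mol_sites) >= n_target:
                    break
            if accepted_this_batch:
                placed_sites.extend(accepted_this_batch)
                site_tree = cKDTree(np.vstack(placed_sites))
        return mol_sites if len(mol_sites) >= n_target else None

    shells = []
    max_restarts = 5
    for frame in range(n_frames):
        mol_sites = None
        for attempt in range(max_restarts):
            mol_sites = _build_frame(rng)
            if mol_sites is not None:
                break  # a fresh RSA realization usually un-jams the packing
        if mol_sites is None:
            raise RuntimeError(
                f"frame {frame}: could not place {n_target} solvent molecules in "
                f"{max_restarts} attempts; lower number_density or min_sep"
            )
        positions = np.vstack(mol_sites)
        charges = np.tile(q_mol, len(mol_sites))
        mol_ids = np.repeat(np.arange(len(mol_sites)), 3)
        shells.append(SolventShell(frame, positions, charges, mol_ids))
    return shells


def evaluate_field(shell: SolventShell, center: np.ndarray) -> np.ndarray:
    """Electric field (kJ mol^-1 nm^-1 e^-1) at ``center`` from ALL shell
    charges — no cutoff, consistent with the charges entering the MEPs."""
    center = np.asarray(center, dtype=float)
    if shell.positions.shape[0] == 0:
        return np.zeros(3)
    rvec = center[None, :] - shell.positions
    r = np.linalg.norm(rvec, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("external charge coincides with the field point")
    return F_ELEC * np.einsum("j,ji->i", shell.charges / r**3, rvec)


def _point_charge_potential(points: np.ndarray, positions: np.ndarray, charges: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - positions[None, :, :], axis=-1)
    if np.any(d < 1e-12):
        raise ValueError("grid point coincides with a charge site")
    return F_ELEC * (charges[None, :] / d).sum(axis=1)


def dipole_potential(points: np.ndarray, center: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Point-dipole potential f_elec * mu . r / r^3 (kJ mol^-1 e^-1)."""
    rvec = points - center[None, :]
    r = np.linalg.norm(rvec, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("grid point coincides with the dipole center")
    return F_ELEC * (rvec @ mu) / r**3


def synth_mep(
    solute: SoluteSpec,
    shell: SolventShell,
    grid_points: np.ndarray,
    noise: Optional[NoiseSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vacuum and solvated MEPs of the ground-truth solute on the grid.

    phi_vac is the static-charge potential.  phi_solv adds the point-dipole
    potential of mu = alpha o E(center) / f_elec (with E from the full
    shell), the optional per-frame inhomogeneity perturbation on mu, and
    optional Gaussian grid noise.
    """
    noise = noise or NoiseSpec()
    if (noise.grid_sd > 0 or noise.inhomogeneity > 0) and rng is None:
        raise ValueError("an rng is required when noise is enabled")
    phi_vac = _point_charge_potential(grid_points, solute.charge_positions, solute.charges)
    e_center = evaluate_field(shell, solute.center)
    mu = solute.alpha_diag * e_center / F_ELEC  # e nm
    if noise.inhomogeneity > 0:
        mu = mu * (1.0 + rng.normal(0.0, noise.inhomogeneity))
    phi_solv = phi_vac + dipole_potential(grid_points, solute.center, mu)
    if noise.grid_sd > 0:
        phi_solv = phi_solv + rng.normal(0.0, noise.grid_sd, size=len(grid_points))
    return phi_vac, phi_solv


@dataclass
class PolarizationDataset:
    """Bundle of synthetic fitting inputs for a fixed solute and grid."""

    solute: SoluteSpec
    grid: MEPGrid
    fields: np.ndarray  # (n_frames, 3) field at the center per frame
    shells: Optional[list] = None

    @property
    def n_frames(self) -> int:
        return self.grid.phi_solv.shape[0]


def generate_dataset(
    n_frames: int,
    solute: SoluteSpec,
    seed: int,
    noise: Optional[NoiseSpec] = None,
    grid_points: Optional[np.ndarray] = None,
    keep_shells: bool = False,
    relative_grid_noise: Optional[float] = None,
    **shell_kwargs,
) -> PolarizationDataset:
    """End-to-end synthetic dataset: shells, fields, vacuum/solvated MEPs.

    ``relative_grid_noise`` scales the grid noise sd to the given fraction
    of the noiseless induced-signal RMS (estimated from the first frame),
    overriding ``noise.grid_sd``.
    """
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    noise = noise or NoiseSpec()
    if grid_points is None:
        grid_points = connolly_grid(solute.atom_positions, solute.atom_elements)
    shells = sample_solvent_shells(n_frames, solute, seed=seed, **shell_kwargs)

    if relative_grid_noise is not None and n_frames > 0:
        e0 = evaluate_field(shells[0], solute.center)
        mu0 = solute.alpha_diag * e0 / F_ELEC
        rms = float(np.sqrt(np.mean(dipole_potential(grid_points, solute.center, mu0) ** 2)))
        noise = NoiseSpec(grid_sd=relative_grid_noise * rms, inhomogeneity=noise.inhomogeneity)

    phi_vac = None
    phi_solv = np.empty((n_frames, len(grid_points)))
    fields = np.empty((n_frames, 3))
    for i, shell in enumerate(shells):
        pv, ps = synth_mep(solute, shell, grid_points, noise=noise, rng=rng)
        phi_vac = pv if phi_vac is None else phi_vac
        phi_solv[i] = ps
        fields[i] = evaluate_field(shell, solute.center)
    if phi_vac is None:  # n_frames == 0
        phi_vac = _point_charge_potential(grid_points, solute.charge_positions, solute.charges)
    grid = MEPGrid(points=grid_points, phi_vac=phi_vac, phi_solv=phi_solv)
    return PolarizationDataset(
        solute=solute, grid=grid, fields=fields, shells=shells if keep_shells else None
    )
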