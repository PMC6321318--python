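"""Minimal polarizable MD engine for the rigid four-site COS water model.

Integration is leap-frog with SHAKE distance constraints (O-H1, O-H2,
H1-H2) keeping each molecule rigid.  The off-atom M site is a massless
virtual site rebuilt every step on the H-O-H bisector; forces collected
on it (and on its charge-on-spring particle) are redistributed to the
massive sites through the transpose of the construction Jacobian, which
preserves the net force and torque on the molecule.

Electrostatics use a molecular (oxygen-distance) cutoff with a
Barker-Watts reaction field for the dielectric continuum beyond it; van
der Waals interactions are the C6-C8-C11 potential between oxygens, with
an optional analytic long-range (tail) correction to energy and virial.
The COS displacements are relaxed to self-consistency (SCF) every step
before forces are evaluated.  Weak-coupling (Berendsen) thermostat and
barostat provide NVT/NpT sampling; a uniform external field along z can
be applied for dielectric-permittivity runs.  A gas-phase mode (no
periodic images, no cutoff) supports single-molecule reference runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (
    BAR_PER_ATM,
    DEBYE_E_NM,
    F_ELEC,
    KB_KJMOL,
    M_WATER,
    MASS_H,
    MASS_O,
    N_AVOGADRO,
    PRESSURE_INTERNAL_TO_BAR,
)
from .forcefield import ForceField, default_forcefield

__all__ = [
    "Topology",
    "MDConfig",
    "SystemState",
    "EnergyReport",
    "Trajectory",
    "place_virtual_site",
    "redistribute_force",
    "compute_forces",
    "scf_cos",
    "shake",
    "leapfrog_step",
    "berendsen_thermostat_factor",
    "berendsen_barostat_factor",
    "initial_lattice",
    "assign_velocities",
    "minimize_energy",
    "thermalize",
    "run_simulation",
]

logger = logging.getLogger(__name__)


@dataclass
class Topology:
    """Molecule count, masses and constraint network for rigid water."""

    ff: ForceField
    n_mol: int

    @property
    def masses(self) -> np.ndarray:
        """Masses of the massive sites O, H1, H2 (g mol^-1)."""
        return np.array([MASS_O, MASS_H, MASS_H])

    @property
    def constraints(self) -> list:
        """(site_a, site_b, reference length) triplets."""
        g = self.ff.geometry
        return [(0, 1, g.r_OH), (0, 2, g.r_OH), (1, 2, g.r_HH)]


@dataclass
class MDConfig:
    dt: float = 0.002  # ps
    cutoff: float = 1.4  # nm, capped at L/2 at run time
    eps_rf: float = 78.4
    temperature: float = 298.15  # K
    tau_t: float = 0.1  # ps
    pressure: float = 1.0  # atm
    tau_p: float = 0.5  # ps
    compressibility: float = 4.5e-5  # bar^-1
    thermostat: bool = True
    barostat: bool = False
    scf_tol: float = 1e-6  # nm, max COS displacement change
    scf_max_iter: int = 60
    e_field_z: float = 0.0  # kJ mol^-1 nm^-1 e^-1
    dispersion_tail: bool = True
    # Molecular switching region below the cutoff (nm); 0 = hard cutoff.
    # The hard cutoff is the reference scheme: switching smooths pair-list
    # crossings for energy-conservation studies, but its derivative term
    # biases the virial noticeably at desk-scale cutoffs, so it is opt-in.
    switch_width: float = 0.0
    max_box_scaling: float = 0.02  # per-step cap on |mu - 1|
    seed: int = 0

    def effective_cutoff(self, box: float) -> float:
        return min(self.cutoff, 0.5 * box)

    @property
    def c_rf(self) -> float:
        """Reaction-field coefficient 2(eps-1)/(2 eps + 1)."""
        return 2.0 * (self.eps_rf - 1.0) / (2.0 * self.eps_rf + 1.0)


@dataclass
class SystemState:
    """Positions/velocities of massive sites plus COS displacements."""

    pos: np.ndarray  # (N, 3, 3) O, H1, H2 in nm
    vel: np.ndarray  # (N, 3, 3) nm ps^-1
    cos_disp: np.ndarray  # (N, 3) COS displacement from M, nm
    box: float  # cubic edge, nm
    time: float = 0.0
    pbc: bool = True

    @property
    def n_mol(self) -> int:
        return self.pos.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            self.pos.copy(), self.vel.copy(), self.cos_disp.copy(), self.box, self.time, self.pbc
        )


@dataclass
class EnergyReport:
    """Per-call energy decomposition (kJ mol^-1) and virial diagnostics."""

    u_coulomb: float
    u_vdw: float
    u_selfpol: float
    u_field: float
    virial: float  # sum F_ij . R_ij over molecular pairs (+ tail), kJ mol^-1
    m_z: float  # box dipole z component, e nm
    mean_dipole: float  # mean molecular dipole norm, D

    @property
    def u_potential(self) -> float:
        return self.u_coulomb + self.u_vdw + self.u_selfpol + self.u_field


def place_virtual_site(pos: np.ndarray, d_om: float) -> np.ndarray:
    """M positions on the H-O-H bisector at distance d_OM from oxygen."""
    s = pos[:, 1] + pos[:, 2] - 2.0 * pos[:, 0]
    norm = np.linalg.norm(s, axis=1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("degenerate (collinear) water geometry")
    return pos[:, 0] + d_om * s / norm


def redistribute_force(pos: np.ndarray, f_m: np.ndarray, d_om: float) -> np.ndarray:
    """Spread forces acting on M to O, H1, H2 (transpose of the Jacobian).

    Returns an (N, 3, 3) array of force increments that preserve the net
    force and net torque of ``f_m`` applied at the M position.
    """
    s = pos[:, 1] + pos[:, 2] - 2.0 * pos[:, 0]
    norm = np.linalg.norm(s, axis=1, keepdims=True)
    u = s / norm
    # dM/ds = (d/|s|) (I - u u^T); F_s = (dM/ds)^T F_M
    f_par = (f_m * u).sum(axis=1, keepdims=True) * u
    f_s = (d_om / norm) * (f_m - f_par)
    out = np.zeros_like(pos)
    out[:, 0] = f_m - 2.0 * f_s
    out[:, 1] = f_s
    out[:, 2] = f_s
    return out


def _charge_sites(state: SystemState, ff: ForceField) -> tuple[np.ndarray, np.ndarray]:
    """Charged-site coordinates (N,4,3) [H1,H2,M,COS] and their charges."""
    m_pos = place_virtual_site(state.pos, ff.geometry.d_OM)
    x = np.empty((state.n_mol, 4, 3))
    x[:, 0] = state.pos[:, 1]
    x[:, 1] = state.pos[:, 2]
    x[:, 2] = m_pos
    x[:, 3] = m_pos + state.cos_disp
    q = np.array(
        [
            ff.charges.q_H,
            ff.charges.q_H,
            ff.charges.q_M_effective,
            ff.charges.q_COS,
        ]
    )
    return x, q


def _pair_list(o_pos: np.ndarray, box: float, rc: float, pbc: bool):
    """Molecular pairs (i<j) within the oxygen-distance cutoff.

    Returns (i, j, shift) where ``shift`` translates molecule j to the
    image nearest molecule i.
    """
    n = len(o_pos)
    d = o_pos[:, None, :] - o_pos[None, :, :]
    if pbc:
        img = np.round(d / box)
        d = d - box * img
    r2 = (d**2).sum(axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    mask = r2[iu, ju] < rc * rc
    i, j = iu[mask], ju[mask]
    shift = (box * img[i, j]) if pbc else np.zeros((len(i), 3))
    return i, j, shift


def _switch(r: np.ndarray, rc: float, width: float) -> tuple[np.ndarray, np.ndarray]:
    """C2 molecular switching function S(r) on [rc - width, rc] and dS/dr.

    S = 1 below the switching region and 0 at the cutoff, so molecular
    pairs enter and leave the pair list with continuous energy and force.
    """
    if width <= 0 or not np.isfinite(rc):
        return np.ones_like(r), np.zeros_like(r)
    rs = rc - width
    x = np.clip((r - rs) / width, 0.0, 1.0)
    s = 1.0 - x**3 * (10.0 - 15.0 * x + 6.0 * x**2)
    ds = -30.0 * x**2 * (1.0 - x) ** 2 / width
    return s, ds


def _molecule_com(pos: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (pos * masses[None, :, None]).sum(axis=1) / masses.sum()


def _molecular_dipoles(state: SystemState, ff: ForceField) -> np.ndarray:
    """Per-molecule dipole vectors (e nm): static sites + COS contribution."""
    m_pos = place_virtual_site(state.pos, ff.geometry.d_OM)
    rel_h1 = state.pos[:, 1] - state.pos[:, 0]
    rel_h2 = state.pos[:, 2] - state.pos[:, 0]
    rel_m = m_pos - state.pos[:, 0]
    q = ff.charges
    return (
        q.q_H * (rel_h1 + rel_h2)
        + q.q_M * rel_m
        + q.q_COS * state.cos_disp
    )


def _tail_corrections(n_mol: int, volume: float, rc: float, ff: ForceField):
    """Analytic dispersion energy/pressure beyond the cutoff (g(r) = 1)."""
    pref = 2.0 * math.pi * n_mol**2 / volume
    u6 = -pref * ff.vdw.c6 / (3.0 * rc**3)
    u8 = -pref * ff.vdw.c8 / (5.0 * rc**5)
    u11 = pref * ff.vdw.c11 / (8.0 * rc**8)
    u_tail = u6 + u8 + u11
    # each r^-n term contributes (n/3) U_n / V to the pressure
    p_tail = (2.0 * u6 + (8.0 / 3.0) * u8 + (11.0 / 3.0) * u11) / volume
    return u_tail, p_tail


def compute_forces(
    state: SystemState, topo: Topology, config: MDConfig
) -> tuple[np.ndarray, EnergyReport]:
    """Forces on the massive sites and the energy/virial decomposition.

    Uses the COS displacements currently stored in ``state`` (normally the
    SCF-converged ones).  Forces on M and on the COS particle are carried
    to M (torque-free at SCF convergence, and exact for a lab-frame-fixed
    displacement vector) and redistributed to O, H1, H2.
    """
    ff = topo.ff
    n = state.n_mol
    x, q4 = _charge_sites(state, ff)
    rc = config.effective_cutoff(state.box) if state.pbc else np.inf
    crf = config.c_rf if state.pbc else 0.0
    rc3 = rc**3 if np.isfinite(rc) else np.inf

    f4 = np.zeros((n, 4, 3))  # forces on charged sites
    f_massive = np.zeros_like(state.pos)
    u_coul = 0.0
    u_vdw = 0.0
    virial = 0.0

    if n > 1:
        i, j, shift = _pair_list(state.pos[:, 0], state.box, rc, state.pbc)
        if len(i):
            d_oo = state.pos[i, 0] - (state.pos[j, 0] + shift)
            r_oo = np.linalg.norm(d_oo, axis=1)
            s_sw, ds_sw = _switch(r_oo, rc, config.switch_width if state.pbc else 0.0)

            a = x[i]  # (p, 4, 3)
            b = x[j] + shift[:, None, :]
            dvec = a[:, :, None, :] - b[:, None, :, :]  # (p, 4, 4, 3)
            r = np.linalg.norm(dvec, axis=-1)
            if np.any(r < 1e-6):
                raise FloatingPointError("charged site pair at near-zero separation")
            qq = F_ELEC * q4[:, None] * q4[None, :]
            if np.isfinite(rc):
                u_pair = qq[None] * (1.0 / r + crf * r**2 / (2.0 * rc3) - (1.0 + crf / 2.0) / rc)
                kern = qq[None] * (1.0 / r**3 - crf / rc3)
            else:
                u_pair = qq[None] / r
                kern = qq[None] / r**3
            u_elec_pair = u_pair.sum(axis=(1, 2))  # (p,)
            u_coul = float((s_sw * u_elec_pair).sum())
            fvec = (s_sw[:, None, None, None] * kern[..., None]) * dvec
            f_on_i = fvec.sum(axis=2)  # (p, 4, 3)
            f_on_j = -fvec.sum(axis=1)
            np.add.at(f4, i, f_on_i)
            np.add.at(f4, j, f_on_j)

            # vdW between oxygens (same molecular pair list and switch)
            c6, c8, c11 = ff.vdw.c6, ff.vdw.c8, ff.vdw.c11
            inv = 1.0 / r_oo
            inv6 = inv**6
            inv8 = inv6 * inv * inv
            inv11 = inv8 * inv**3
            u_vdw_pair = -c6 * inv6 - c8 * inv8 + c11 * inv11
            u_vdw = float((s_sw * u_vdw_pair).sum())
            fmag_over_r = (-6.0 * c6 * inv6 - 8.0 * c8 * inv8 + 11.0 * c11 * inv11) * inv * inv
            f_oo = (s_sw * fmag_over_r)[:, None] * d_oo
            # switching-function force acts along the O-O vector
            u_sum_pair = u_elec_pair + u_vdw_pair
            f_sw = -(u_sum_pair * ds_sw / r_oo)[:, None] * d_oo
            f_oo_tot = f_oo + f_sw
            np.add.at(f_massive, (i, np.zeros_like(i)), f_oo_tot)
            np.add.at(f_massive, (j, np.zeros_like(j)), -f_oo_tot)

            # molecular virial: total pair force dotted with COM separation
            f_pair = f_on_i.sum(axis=1) + f_oo_tot  # force on molecule i from j
            com = _molecule_com(state.pos, topo.masses)
            r_com = com[i] - (com[j] + shift)
            virial = float(np.einsum("pd,pd->", f_pair, r_com))

    # uniform external field along z acts on every charged site
    u_field = 0.0
    if config.e_field_z != 0.0:
        f4[:, :, 2] += q4[None, :] * config.e_field_z
        mz_mol = _molecular_dipoles(state, ff)[:, 2]
        u_field = float(-config.e_field_z * mz_mol.sum())

    # COS self-polarization energy (spring); spring forces are internal
    k_spring = ff.pol.k_spring
    u_selfpol = float(0.5 * k_spring * (state.cos_disp**2).sum())

    # collect charged-site forces onto massive sites
    f_massive[:, 1] += f4[:, 0]
    f_massive[:, 2] += f4[:, 1]
    f_m_total = f4[:, 2] + f4[:, 3]
    f_massive += redistribute_force(state.pos, f_m_total, ff.geometry.d_OM)

    if state.pbc and config.dispersion_tail and np.isfinite(rc):
        vol = state.box**3
        u_tail, p_tail = _tail_corrections(n, vol, rc, ff)
        u_vdw += u_tail
        virial += 3.0 * vol * p_tail

    dip = _molecular_dipoles(state, ff)
    report = EnergyReport(
        u_coulomb=u_coul,
        u_vdw=u_vdw,
        u_selfpol=u_selfpol,
        u_field=u_field,
        virial=virial,
        m_z=float(dip[:, 2].sum()),
        mean_dipole=float(np.mean(np.linalg.norm(dip, axis=1)) / DEBYE_E_NM),
    )
    return f_massive, report


def _field_at_m(state: SystemState, topo: Topology, config: MDConfig) -> np.ndarray:
    """Electric field at each M site from all other molecules' charges
    (reaction-field kernel within the molecular cutoff) plus the external
    field."""
    ff = topo.ff
    n = state.n_mol
    x, q4 = _charge_sites(state, ff)
    m_pos = x[:, 2]
    e = np.zeros((n, 3))
    e[:, 2] += config.e_field_z
    if n < 2:
        return e
    rc = config.effective_cutoff(state.box) if state.pbc else np.inf
    crf = config.c_rf if state.pbc else 0.0
    rc3 = rc**3 if np.isfinite(rc) else np.inf
    i, j, shift = _pair_list(state.pos[:, 0], state.box, rc, state.pbc)
    if len(i) == 0:
        return e
    d_oo = state.pos[i, 0] - (state.pos[j, 0] + shift)
    s_sw, _ = _switch(np.linalg.norm(d_oo, axis=1), rc, config.switch_width if state.pbc else 0.0)
    # field at M_i from sites of molecule j (nearest image), and vice versa
    d_i = m_pos[i][:, None, :] - (x[j] + shift[:, None, :])  # (p, 4, 3)
    d_j = m_pos[j][:, None, :] - (x[i] - shift[:, None, :])
    for idx, dvec in ((i, d_i), (j, d_j)):
        r = np.linalg.norm(dvec, axis=-1)
        if np.isfinite(rc):
            kern = 1.0 / r**3 - crf / rc3
        else:
            kern = 1.0 / r**3
        contrib = F_ELEC * np.einsum("pb,pbd->pd", (s_sw[:, None] * q4[None, :]) * kern, dvec)
        np.add.at(e, idx, contrib)
    return e


def scf_cos(state: SystemState, topo: Topology, config: MDConfig) -> tuple[int, float]:
    """Relax COS displacements to self-consistency.

    Iterates d_i <- alpha E(M_i) / (f_elec q_COS) until the largest
    displacement change is below ``scf_tol``.  Returns (iterations,
    self-polarization energy).  The previous displacements serve as warm
    start.  Raises on non-convergence.
    """
    ff = topo.ff
    alpha = ff.pol.alpha_iso
    q_cos = ff.pol.q_COS
    for it in range(1, config.scf_max_iter + 1):
        e = _field_at_m(state, topo, config)
        d_new = alpha * e / (F_ELEC * q_cos)
        delta = float(np.max(np.linalg.norm(d_new - state.cos_disp, axis=1)))
        state.cos_disp = d_new
        if delta < config.scf_tol:
            u_selfpol = 0.5 * ff.pol.k_spring * float((state.cos_disp**2).sum())
            return it, u_selfpol
    raise RuntimeError(
        f"SCF did not converge in {config.scf_max_iter} iterations "
        f"(last max displacement change {delta:.3e} nm, tol {config.scf_tol:g})"
    )


def shake(
    pos_new: np.ndarray,
    pos_old: np.ndarray,
    topo: Topology,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Iteratively restore the rigid constraints on trial positions.

    ``tol`` is the relative geometric tolerance |r - r_ref| / r_ref.
    ``pos_old`` supplies the constraint directions (pre-step geometry).
    """
    pos = pos_new.copy()
    invm = 1.0 / topo.masses
    for _ in range(max_iter):
        converged = True
        for a, b, dref in topo.constraints:
            d = pos[:, a] - pos[:, b]
            r2 = (d**2).sum(axis=1)
            diff = r2 - dref**2
            viol = np.abs(np.sqrt(r2) / dref - 1.0) > tol
            if not np.any(viol):
                continue
            converged = False
            d_old = pos_old[:, a] - pos_old[:, b]
            denom = 2.0 * (invm[a] + invm[b]) * (d * d_old).sum(axis=1)
            g = np.where(viol, diff / denom, 0.0)
            pos[:, a] -= (g * invm[a])[:, None] * d_old
            pos[:, b] += (g * invm[b])[:, None] * d_old
        if converged:
            return pos
    raise RuntimeError("SHAKE did not converge")


def _project_constraint_velocities(
    vel: np.ndarray, pos: np.ndarray, topo: Topology, n_sweeps: int = 50
) -> np.ndarray:
    """Remove relative velocity components along the constrained bonds."""
    v = vel.copy()
    invm = 1.0 / topo.masses
    for _ in range(n_sweeps):
        worst = 0.0
        for a, b, dref in topo.constraints:
            d = pos[:, a] - pos[:, b]
            r2 = (d**2).sum(axis=1)
            dv = v[:, a] - v[:, b]
            proj = (dv * d).sum(axis=1) / (r2 * (invm[a] + invm[b]))
            v[:, a] -= (proj * invm[a])[:, None] * d
            v[:, b] += (proj * invm[b])[:, None] * d
            worst = max(worst, float(np.max(np.abs(proj))))
        if worst < 1e-12:
            break
    return v


def kinetic_energy(vel: np.ndarray, topo: Topology) -> float:
    """Kinetic energy of the massive sites (kJ mol^-1)."""
    return float(0.5 * (topo.masses[None, :, None] * vel**2).sum())


def n_dof(n_mol: int) -> int:
    """Degrees of freedom: 6 per rigid nonlinear molecule, minus COM drift."""
    return 6 * n_mol - 3 if n_mol > 1 else 6


def temperature(vel: np.ndarray, topo: Topology) -> float:
    return 2.0 * kinetic_energy(vel, topo) / (n_dof(len(vel)) * KB_KJMOL)


def berendsen_thermostat_factor(t_inst: float, t_target: float, tau: float, dt: float) -> float:
    """Weak-coupling velocity scaling factor lambda."""
    if t_inst <= 0:
        raise ValueError("instantaneous temperature must be > 0")
    return math.sqrt(1.0 + dt / tau * (t_target / t_inst - 1.0))


def berendsen_barostat_factor(
    p_inst_bar: float, p_target_bar: float, tau: float, dt: float, compressibility: float
) -> float:
    """Isotropic box scaling factor mu (applied to L and COM positions)."""
    return (1.0 - compressibility * dt / tau * (p_target_bar - p_inst_bar)) ** (1.0 / 3.0)


def pressure_internal(state: SystemState, topo: Topology, virial: float) -> float:
    """Instantaneous pressure (bar) from the molecular virial theorem."""
    com_vel = (state.vel * topo.masses[None, :, None]).sum(axis=1) / topo.masses.sum()
    k_com = 0.5 * topo.masses.sum() * float((com_vel**2).sum())
    vol = state.box**3
    p_int = (2.0 * k_com + virial) / (3.0 * vol)
    return p_int * PRESSURE_INTERNAL_TO_BAR


def leapfrog_step(
    state: SystemState,
    forces: np.ndarray,
    topo: Topology,
    config: MDConfig,
    lam: float = 1.0,
    shake_tol: float = 1e-4,
) -> None:
    """One leap-frog step with optional thermostat scaling and SHAKE."""
    inv_m = 1.0 / topo.masses[None, :, None]
    vel = lam * state.vel + forces * inv_m * config.dt
    trial = state.pos + vel * config.dt
    new_pos = shake(trial, state.pos, topo, tol=shake_tol)
    state.vel = (new_pos - state.pos) / config.dt
    state.pos = new_pos
    state.time += config.dt


@dataclass
class Trajectory:
    """Sampled time series from a run (per sample stride)."""

    time: list = field(default_factory=list)
    box: list = field(default_factory=list)
    volume: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    pressure: list = field(default_factory=list)
    u_potential: list = field(default_factory=list)
    u_coulomb: list = field(default_factory=list)
    u_vdw: list = field(default_factory=list)
    u_selfpol: list = field(default_factory=list)
    u_field: list = field(default_factory=list)
    kinetic: list = field(default_factory=list)
    m_z: list = field(default_factory=list)
    mean_dipole: list = field(default_factory=list)
    scf_iters: list = field(default_factory=list)
    o_positions: list = field(default_factory=list)  # (N,3) oxygen coords per frame

    def to_dataframe(self):
        import pandas as pd

        cols = {
            k: getattr(self, k)
            for k in (
                "time",
                "box",
                "volume",
                "temperature",
                "pressure",
                "u_potential",
                "u_coulomb",
                "u_vdw",
                "u_selfpol",
                "u_field",
                "kinetic",
                "m_z",
                "mean_dipole",
                "scf_iters",
            )
        }
        return pd.DataFrame(cols)

    @property
    def arrays(self):
        return {k: np.asarray(v) for k, v in self.__dict__.items() if k != "o_positions"}


def run_simulation(
    topo: Topology,
    config: MDConfig,
    n_steps: int,
    state: SystemState,
    sample_stride: int = 10,
    position_stride: Optional[int] = None,
    shake_tol: float = 1e-4,
) -> Trajectory:
    """Propagate the system, returning sampled energies/box/dipole series.

    Per-step order: SCF -> forces -> thermostat/barostat -> leap-frog ->
    SHAKE -> virtual-site rebuild (implicit in the next force call).
    """
    traj = Trajectory()
    box0 = state.box
    cutoff_honored = config.cutoff <= 0.5 * box0  # user cutoff fits the initial box
    for step in range(n_steps):
        iters, _ = scf_cos(state, topo, config)
        forces, report = compute_forces(state, topo, config)
        t_inst = temperature(state.vel, topo)
        p_bar = pressure_internal(state, topo, report.virial) if state.pbc else math.nan

        if step % sample_stride == 0:
            traj.time.append(state.time)
            traj.box.append(state.box)
            traj.volume.append(state.box**3)
            traj.temperature.append(t_inst)
            traj.pressure.append(p_bar)
            traj.u_potential.append(report.u_potential)
            traj.u_coulomb.append(report.u_coulomb)
            traj.u_vdw.append(report.u_vdw)
            traj.u_selfpol.append(report.u_selfpol)
            traj.u_field.append(report.u_field)
            traj.kinetic.append(kinetic_energy(state.vel, topo))
            traj.m_z.append(report.m_z)
            traj.mean_dipole.append(report.mean_dipole)
            traj.scf_iters.append(iters)
            if position_stride and (step // sample_stride) % position_stride == 0:
                traj.o_positions.append(state.pos[:, 0].copy())

        lam = 1.0
        if config.thermostat and t_inst > 0:
            lam = berendsen_thermostat_factor(t_inst, config.temperature, config.tau_t, config.dt)

        if config.barostat and state.pbc:
            mu = berendsen_barostat_factor(
                p_bar,
                config.pressure * BAR_PER_ATM,
                config.tau_p,
                config.dt,
                config.compressibility,
            )
            mu = float(np.clip(mu, 1.0 - config.max_box_scaling, 1.0 + config.max_box_scaling))
            com = _molecule_com(state.pos, topo.masses)
            state.pos = state.pos + (mu - 1.0) * com[:, None, :]
            state.box *= mu
            if cutoff_honored and config.cutoff > 0.5 * state.box:
                raise RuntimeError(
                    f"box shrank to {state.box:.3f} nm; cutoff {config.cutoff} nm exceeds L/2"
                )
            if state.box < 0.7 * box0:
                raise RuntimeError(
                    f"box collapsed from {box0:.3f} to {state.box:.3f} nm; aborting"
                )

        leapfrog_step(state, forces, topo, config, lam=lam, shake_tol=shake_tol)
    return traj


def initial_lattice(
    topo: Topology,
    box: float,
    seed: int = 0,
) -> SystemState:
    """Simple-cubic lattice of randomly oriented molecules in a cubic box."""
    n = topo.n_mol
    n_side = math.ceil(n ** (1.0 / 3.0))
    spacing = box / n_side
    template = topo.ff.geometry.site_positions()[:3]  # O, H1, H2
    template = template - template.mean(axis=0)
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n, random_state=rng).as_matrix()
    pos = np.empty((n, 3, 3))
    count = 0
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                if count >= n:
                    break
                origin = (np.array([ix, iy, iz]) + 0.5) * spacing
                pos[count] = origin[None, :] + template @ rots[count].T
                count += 1
    vel = np.zeros_like(pos)
    return SystemState(pos=pos, vel=vel, cos_disp=np.zeros((n, 3)), box=box)


def box_for_density(n_mol: int, density_kg_m3: float, molar_mass: float = M_WATER) -> float:
    """Cubic box edge (nm) for a given mass density."""
    v_m3 = n_mol * molar_mass * 1e-3 / (N_AVOGADRO * density_kg_m3)
    return (v_m3 * 1e27) ** (1.0 / 3.0)


def assign_velocities(state: SystemState, topo: Topology, t_target: float, seed: int = 0) -> None:
    """Maxwell-Boltzmann velocities, constraint-projected, COM-drift free."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB_KJMOL * t_target / topo.masses)  # nm/ps per site
    vel = rng.normal(size=state.pos.shape) * sigma[None, :, None]
    vel = _project_constraint_velocities(vel, state.pos, topo)
    m = topo.masses[None, :, None]
    vel -= (vel * m).sum(axis=(0, 1)) / (m.sum() * state.n_mol)
    t_now = temperature(vel, topo)
    if t_now > 0:
        vel *= math.sqrt(t_target / t_now)
    state.vel = vel


def minimize_energy(
    state: SystemState,
    topo: Topology,
    config: MDConfig,
    n_iter: int = 200,
    step0: float = 2e-5,
    freeze_cos: bool = True,
) -> float:
    """Steepest-descent relaxation to remove initial overlaps.

    COS displacements stay frozen (zero) by default so that close contacts
    cannot trigger a polarization catastrophe before relaxation.
    """
    cfg = config
    step = step0
    forces, report = compute_forces(state, topo, cfg)
    energy = report.u_potential
    for _ in range(n_iter):
        fmax = float(np.max(np.abs(forces)))
        if fmax < 1e-3:
            break
        trial = state.pos + step * forces / fmax
        trial = shake(trial, state.pos, topo)
        trial_state = SystemState(trial, state.vel, state.cos_disp, state.box, state.time, state.pbc)
        if not freeze_cos:
            scf_cos(trial_state, topo, cfg)
        f_new, rep_new = compute_forces(trial_state, topo, cfg)
        if rep_new.u_potential < energy:
            state.pos = trial
            state.cos_disp = trial_state.cos_disp
            forces, energy = f_new, rep_new.u_potential
            step = min(step * 1.2, 5e-4)
        else:
            step *= 0.5
            if step < 1e-9:
                break
    return energy


def thermalize(
    state: SystemState,
    topo: Topology,
    config: MDConfig,
    t_final: float,
    stages: int = 5,
    ps_per_stage: float = 1.0,
    t_start: float = 50.0,
    seed: int = 0,
) -> None:
    """Staged NVT warm-up: velocities reassigned and T ramped per stage."""
    temps = np.linspace(t_start, t_final, stages)
    steps = int(round(ps_per_stage / config.dt))
    for k, t_k in enumerate(temps):
        cfg = MDConfig(**{**config.__dict__, "temperature": float(t_k), "barostat": False})
        assign_velocities(state, topo, float(t_k), seed=seed + k)
        run_simulation(topo, cfg, steps, state, sample_stride=max(steps, 1))
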