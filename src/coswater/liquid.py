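"""Pure-liquid property estimators for the polarizable water model.

All estimators consume the time series produced by the MD engine
(volumes, energies, box dipole, oxygen trajectories) and report in the
conventional experimental units: density kg m^-3, heat of vaporization
kJ mol^-1, diffusion 1e-5 cm^2 s^-1, dipoles Debye, Cp J mol^-1 K^-1,
thermal expansion 1e-4 K^-1, compressibility 1e-6 atm^-1.  Every mean is
accompanied by a block-averaged standard error (5 blocks by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import (
    BAR_PER_ATM,
    F_ELEC,
    KB_KJMOL,
    KB_SI,
    M_WATER,
    N_AVOGADRO,
)

__all__ = [
    "VapCorrections",
    "block_average",
    "density",
    "heat_of_vaporization",
    "dielectric_from_field",
    "diffusion_msd",
    "yeh_hummer_correct",
    "mean_molecular_dipole",
    "secondary_properties",
    "SecondaryProperties",
]

logger = logging.getLogger(__name__)


def block_average(series, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and standard error from non-overlapping block means."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if n_blocks < 2 or x.size < n_blocks:
        return float(np.mean(x)), float("nan")
    usable = (x.size // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(np.mean(x)), float(np.std(blocks, ddof=1) / math.sqrt(n_blocks))


@dataclass
class VapCorrections:
    """Vibrational (C_vib) and non-ideality (C_ni) corrections vs T.

    Values are user supplied (tabulated in the literature); interpolation
    is linear and restricted to the covered temperature range.
    """

    temperatures: np.ndarray
    c_vib: np.ndarray
    c_ni: np.ndarray

    def at(self, t: float) -> tuple[float, float]:
        ts = np.asarray(self.temperatures, dtype=float)
        if not (ts.min() <= t <= ts.max()):
            raise ValueError(f"T={t} K outside correction table range [{ts.min()}, {ts.max()}]")
        return (
            float(np.interp(t, ts, self.c_vib)),
            float(np.interp(t, ts, self.c_ni)),
        )


def density(volumes_nm3, n_mol: int, molar_mass: float = M_WATER) -> tuple[float, float]:
    """Mass density (kg m^-3) from the volume series: N M / (N_A <V>)."""
    v = np.asarray(volumes_nm3, dtype=float)
    if v.size == 0:
        raise ValueError("empty trajectory")
    if np.any(v <= 0):
        raise ValueError("volumes must be > 0")
    v_mean, v_err = block_average(v)
    rho = n_mol * molar_mass * 1e-3 / (N_AVOGADRO * v_mean * 1e-27)
    rho_err = rho * v_err / v_mean if np.isfinite(v_err) else float("nan")
    return rho, rho_err


def heat_of_vaporization(
    e_gas: float,
    e_liq: float,
    t: float,
    corrections: Optional[VapCorrections] = None,
) -> float:
    """Delta H_vap = <E_gas> - <E_liq> + RT + C_vib + C_ni (kJ mol^-1).

    Energies are potential energies per molecule.  With no correction
    table supplied, C_vib = C_ni = 0 and a message is logged loudly.
    """
    if corrections is None:
        logger.warning("heat_of_vaporization: no correction table supplied; C_vib = C_ni = 0")
        c_vib = c_ni = 0.0
    else:
        c_vib, c_ni = corrections.at(t)
    return e_gas - e_liq + KB_KJMOL * t + c_vib + c_ni


def dielectric_from_field(m_z_series, v_mean_nm3: float, e_z: float) -> tuple[float, float]:
    """Static dielectric permittivity from the box-dipole response.

    eps(0) = 1 + 4 pi f_elec <M_z> / (<V> E_z) with M_z in e nm, V in nm^3
    and E_z in kJ mol^-1 nm^-1 e^-1.  Requires a field-on trajectory.
    """
    if e_z == 0:
        raise ValueError("dielectric_from_field requires a nonzero applied field")
    mz_mean, mz_err = block_average(m_z_series)
    pref = 4.0 * math.pi * F_ELEC / (v_mean_nm3 * e_z)
    return 1.0 + pref * mz_mean, pref * mz_err if np.isfinite(mz_err) else float("nan")


def diffusion_msd(
    positions,
    dt_frame: float,
    fit_window: tuple = (0.1, 0.5),
    origin_stride: int = 10,
) -> tuple[float, dict]:
    """Self-diffusion coefficient from the Einstein relation.

    ``positions``: unwrapped coordinates, shape (n_frames, n_particles, 3),
    nm; ``dt_frame`` in ps.  The MSD is averaged over particles and
    multiple time origins, then D_pbc = slope/6 is fitted on the lag
    window ``fit_window`` (fractions of the maximum lag).  Returns D in
    1e-5 cm^2 s^-1 plus diagnostics (lags, msd curve, nonlinearity flag).
    """
    pos = np.asarray(positions, dtype=float)
    n_frames = pos.shape[0]
    if n_frames < 10:
        raise ValueError("trajectory too short for an MSD fit")
    max_lag = n_frames // 2
    lags = np.arange(1, max_lag + 1)
    origins = np.arange(0, n_frames - max_lag, origin_stride)
    if len(origins) == 0:
        origins = np.array([0])
    msd = np.empty(len(lags))
    for li, lag in enumerate(lags):
        disp = pos[origins + lag] - pos[origins]
        msd[li] = float(np.mean((disp**2).sum(axis=-1)))
    t = lags * dt_frame

    lo = max(int(fit_window[0] * max_lag), 1) - 1
    hi = max(int(fit_window[1] * max_lag), lo + 2)
    slope, intercept = np.polyfit(t[lo:hi], msd[lo:hi], 1)

    # nonlinearity check: compare local slope in first vs second half of window
    mid = (lo + hi) // 2
    s1, _ = np.polyfit(t[lo:mid], msd[lo:mid], 1) if mid - lo > 1 else (slope, 0.0)
    s2, _ = np.polyfit(t[mid:hi], msd[mid:hi], 1) if hi - mid > 1 else (slope, 0.0)
    denom = max(abs(slope), 1e-300)
    nonlinear = bool(abs(s2 - s1) / denom > 0.5)

    d_nm2_ps = slope / 6.0
    d_1e5_cm2_s = d_nm2_ps * 1e3  # 1 nm^2/ps = 1e-2 cm^2/s = 1e3 * 1e-5 cm^2/s
    return d_1e5_cm2_s, {
        "lags_ps": t,
        "msd_nm2": msd,
        "slope_nm2_ps": slope,
        "intercept_nm2": intercept,
        "nonlinear": nonlinear,
    }


def yeh_hummer_correct(d_pbc_1e5: float, eta_cp: float, t: float, box_nm: float) -> float:
    """Finite-size (periodic-box) correction to the diffusion coefficient.

    D = D_pbc + 2.837297 k_B T / (6 pi eta L); viscosity in cP, box edge
    in nm, input and output in 1e-5 cm^2 s^-1.
    """
    if eta_cp <= 0:
        raise ValueError("viscosity must be > 0")
    if box_nm <= 0:
        raise ValueError("box edge must be > 0")
    corr_m2_s = 2.837297 * KB_SI * t / (6.0 * math.pi * eta_cp * 1e-3 * box_nm * 1e-9)
    return d_pbc_1e5 + corr_m2_s * 1e4 / 1e-5  # m^2/s -> units of 1e-5 cm^2/s


def mean_molecular_dipole(mean_dipole_series, u_selfpol_series=None, n_mol: int = 1):
    """Trajectory averages of the molecular dipole norm (D) and, when the
    self-polarization series is given, of U_selfpol per molecule."""
    mu, mu_err = block_average(mean_dipole_series)
    if u_selfpol_series is None:
        return (mu, mu_err)
    us, us_err = block_average(np.asarray(u_selfpol_series) / n_mol)
    return (mu, mu_err), (us, us_err)


@dataclass
class SecondaryProperties:
    cp: float  # J mol^-1 K^-1
    alpha_p: float  # 1e-4 K^-1
    kappa_t: float  # 1e-6 atm^-1


def secondary_properties(
    enthalpy_kjmol,
    volumes_nm3,
    t: float,
    n_mol: int,
    is_npt: bool = True,
) -> SecondaryProperties:
    """Fluctuation-formula secondary properties from an NpT trajectory.

    Cp      = <dH^2> / (N R T^2)                (per molecule, molar)
    alpha_p = cov(V, H) / (R T^2 <V>)           (H per system, kJ mol^-1)
    kappa_T = <dV^2> / (k_B T <V>)              (absolute units)

    The enthalpy series is the instantaneous H = U + K + pV of the whole
    system in kJ mol^-1.  NVT input is refused for alpha_p / kappa_T.
    """
    if not is_npt:
        raise ValueError("volume-fluctuation properties require an NpT trajectory")
    h = np.asarray(enthalpy_kjmol, dtype=float)
    v = np.asarray(volumes_nm3, dtype=float)
    if h.shape != v.shape:
        raise ValueError("enthalpy and volume series must have equal length")
    dh = h - h.mean()
    dv = v - v.mean()

    cp_kjmolk = float(np.mean(dh**2)) / (n_mol * KB_KJMOL * t**2)
    cp = cp_kjmolk * 1e3  # J mol^-1 K^-1

    alpha_p = float(np.mean(dv * dh)) / (KB_KJMOL * t**2 * v.mean())  # K^-1

    var_v_m6 = float(np.mean(dv**2)) * 1e-54
    kappa_pa = var_v_m6 / (KB_SI * t * v.mean() * 1e-27)  # Pa^-1
    kappa_atm = kappa_pa * BAR_PER_ATM * 1e5

    return SecondaryProperties(
        cp=cp,
        alpha_p=alpha_p / 1e-4,
        kappa_t=kappa_atm / 1e-6,
    )
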