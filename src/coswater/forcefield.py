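"""Four-site charge-on-spring water model: parameters and closed forms.

The model is a rigid four-site water: oxygen (van der Waals site, no static
charge), two hydrogens carrying ``q_H``, and a massless off-atom M site on
the H-O-H bisector carrying ``q_M``.  Polarization is represented by a
charge-on-spring (COS) particle of charge ``q_COS`` tethered to M with a
harmonic spring whose constant is fixed by the isotropic polarizability.
Van der Waals interactions act between oxygens through a C6-C8-C11
potential whose repulsive constant is derived from the zero-crossing at
the sum of the van der Waals radii.

The molecular frame convention: oxygen at the origin, hydrogens at
positive x, molecule in the x-y plane, M on the +x axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

from .constants import BOHR_NM, DEBYE_E_NM, F_ELEC, HARTREE_KJMOL, M_WATER

__all__ = [
    "ConfigError",
    "RigidWaterGeometry",
    "ChargeModel",
    "DispersionSet",
    "VdwSite",
    "PolarizableSite",
    "ForceField",
    "combine_dispersion",
    "convert_au_to_internal",
    "c11_from_radius",
    "vdw_energy",
    "static_dipole",
    "build_forcefield",
    "default_forcefield",
]

# internal-unit conversion factors for dispersion coefficients
C6_AU_TO_INTERNAL = HARTREE_KJMOL * BOHR_NM**6  # kJ mol^-1 nm^6 per a.u.
C8_AU_TO_INTERNAL = HARTREE_KJMOL * BOHR_NM**8  # kJ mol^-1 nm^8 per a.u.


class ConfigError(ValueError):
    """A force-field configuration is missing a field or violates an invariant."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class RigidWaterGeometry:
    """Rigid water geometry; distances in nm, angle in degrees."""

    r_OH: float = 0.0962
    theta_HOH: float = 105.4
    d_OM: float = 0.0225

    def __post_init__(self):
        if not (0.0 < self.d_OM < self.r_OH):
            raise ConfigError("d_OM", f"must lie in (0, r_OH); got {self.d_OM}")
        if not (0.0 < self.theta_HOH < 180.0):
            raise ConfigError("theta_HOH", f"must lie in (0, 180); got {self.theta_HOH}")

    @property
    def r_HH(self) -> float:
        """H-H distance implied by r_OH and theta_HOH (the third constraint)."""
        return 2.0 * self.r_OH * math.sin(math.radians(self.theta_HOH) / 2.0)

    def site_positions(self) -> np.ndarray:
        """Aligned site coordinates, rows O, H1, H2, M (nm).

        Oxygen at the origin; hydrogens mirror-symmetric about +x in the
        x-y plane; M on the bisector (+x) at d_OM.
        """
        half = math.radians(self.theta_HOH) / 2.0
        xh = self.r_OH * math.cos(half)
        yh = self.r_OH * math.sin(half)
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [xh, yh, 0.0],
                [xh, -yh, 0.0],
                [self.d_OM, 0.0, 0.0],
            ]
        )


@dataclass(frozen=True)
class ChargeModel:
    """Static partial charges (e).  The COS charge is balanced internally by a
    counter charge +|q_COS| on its host site, so the molecule stays neutral."""

    q_H: float = 0.539
    q_M: float = -1.078
    q_O: float = 0.0
    q_COS: float = -8.0

    def __post_init__(self):
        if abs(self.net_charge) > 1e-10:
            raise ConfigError(
                "charges", f"molecule not neutral: q_O + 2 q_H + q_M = {self.net_charge:g} e"
            )

    @property
    def net_charge(self) -> float:
        return self.q_O + 2.0 * self.q_H + self.q_M

    @property
    def q_M_effective(self) -> float:
        """Charge carried by the M site when the COS particle is split off."""
        return self.q_M - self.q_COS


@dataclass(frozen=True)
class DispersionSet:
    """Atomic and combined dispersion coefficients.

    Atomic C6/C8 are in atomic units (Hartree Bohr^6 / Hartree Bohr^8) as
    delivered by exchange-hole dipole moment (XDM) analyses; combined
    molecular values live both in a.u. and internal units.
    """

    c6_O_au: float
    c8_O_au: float
    c6_H_au: float = 0.0
    c8_H_au: float = 0.0
    c6_comb_au: float = field(default=math.nan)
    c8_comb_au: float = field(default=math.nan)

    def __post_init__(self):
        for name in ("c6_O_au", "c8_O_au", "c6_H_au", "c8_H_au"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "dispersion coefficients must be >= 0")

    @property
    def c6_internal(self) -> float:
        """Combined C6 in kJ mol^-1 nm^6."""
        return self.c6_comb_au * C6_AU_TO_INTERNAL

    @property
    def c8_internal(self) -> float:
        """Combined C8 in kJ mol^-1 nm^8."""
        return self.c8_comb_au * C8_AU_TO_INTERNAL


def combine_dispersion(atomic: DispersionSet) -> DispersionSet:
    """Re-partition hydrogen dispersion onto the single oxygen site.

    The combined molecular coefficient sums square roots of the atomic
    ones: C6_comb = (sqrt(C6_O) + 2 sqrt(C6_H))^2, likewise for C8, so a
    single van der Waals site reproduces the molecular dispersion strength.
    """
    c6 = (math.sqrt(atomic.c6_O_au) + 2.0 * math.sqrt(atomic.c6_H_au)) ** 2
    c8 = (math.sqrt(atomic.c8_O_au) + 2.0 * math.sqrt(atomic.c8_H_au)) ** 2
    return DispersionSet(
        c6_O_au=atomic.c6_O_au,
        c8_O_au=atomic.c8_O_au,
        c6_H_au=atomic.c6_H_au,
        c8_H_au=atomic.c8_H_au,
        c6_comb_au=c6,
        c8_comb_au=c8,
    )


def convert_au_to_internal(c6_au: float, c8_au: float) -> tuple[float, float]:
    """Convert C6 (a.u.) and C8 (a.u.) to kJ mol^-1 nm^6 / nm^8."""
    if c6_au < 0 or c8_au < 0:
        raise ValueError("dispersion coefficients must be >= 0")
    return c6_au * C6_AU_TO_INTERNAL, c8_au * C8_AU_TO_INTERNAL


def c11_from_radius(c6: float, c8: float, sigma: float) -> float:
    """Repulsive C11 from the zero of the pair potential at separation sigma.

    Requiring -C6/s^6 - C8/s^8 + C11/s^11 = 0 gives
    C11 = (C6/s^6 + C8/s^8) * s^11 = C6 s^5 + C8 s^3.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return c6 * sigma**5 + c8 * sigma**3


def vdw_energy(r, c6: float, c8: float, c11: float):
    """C6-C8-C11 pair energy and force magnitude at separation r (nm).

    Returns ``(V, F)`` with V = -C6/r^6 - C8/r^8 + C11/r^11 (kJ mol^-1) and
    F = -dV/dr (kJ mol^-1 nm^-1, positive = repulsive).  Accepts arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be > 0")
    inv = 1.0 / r
    inv6 = inv**6
    inv8 = inv6 * inv * inv
    inv11 = inv8 * inv**3
    v = -c6 * inv6 - c8 * inv8 + c11 * inv11
    # dV/dr = 6 C6/r^7 + 8 C8/r^9 - 11 C11/r^12
    dvdr = 6.0 * c6 * inv6 * inv + 8.0 * c8 * inv8 * inv - 11.0 * c11 * inv11 * inv
    force = -dvdr
    if v.ndim == 0:
        return float(v), float(force)
    return v, force


def static_dipole(geometry: RigidWaterGeometry, charges: ChargeModel) -> float:
    """Static molecular dipole moment (Debye) of the aligned rigid molecule.

    Refuses non-neutral charge sets, for which the dipole would be
    origin-dependent.
    """
    pos = geometry.site_positions()
    q = np.array([charges.q_O, charges.q_H, charges.q_H, charges.q_M])
    if abs(q.sum()) > 1e-10:
        raise ValueError("dipole undefined for a non-neutral charge set")
    mu = q @ pos  # e nm
    return float(np.linalg.norm(mu) / DEBYE_E_NM)


@dataclass(frozen=True)
class VdwSite:
    """Oxygen van der Waals site.  C6/C8 in internal units; C11 derived."""

    r_vdw: float
    c6: float
    c8: float

    def __post_init__(self):
        if self.r_vdw <= 0:
            raise ConfigError("r_vdw", "must be > 0")

    @property
    def sigma(self) -> float:
        """Zero-energy separation of the homo pair: 2 * r_vdw."""
        return 2.0 * self.r_vdw

    @property
    def c11(self) -> float:
        return c11_from_radius(self.c6, self.c8, self.sigma)


@dataclass(frozen=True)
class PolarizableSite:
    """Isotropic polarizable site hosted on M with a COS particle attached."""

    alpha_iso: float = 1.05e-3  # polarizability volume, nm^3
    q_COS: float = -8.0
    host: str = "M"

    def __post_init__(self):
        if self.alpha_iso <= 0:
            raise ConfigError("alpha_iso", "must be > 0")

    @property
    def k_spring(self) -> float:
        """Harmonic spring constant, kJ mol^-1 nm^-2."""
        return F_ELEC * self.q_COS**2 / self.alpha_iso


@dataclass(frozen=True)
class ForceField:
    """Complete parameter set of the polarizable four-site water model."""

    geometry: RigidWaterGeometry
    charges: ChargeModel
    vdw: VdwSite
    pol: PolarizableSite
    molar_mass: float = M_WATER

    def to_dict(self) -> dict:
        return {
            "geometry": asdict(self.geometry),
            "charges": asdict(self.charges),
            "vdw": asdict(self.vdw),
            "pol": asdict(self.pol),
            "molar_mass": self.molar_mass,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(
            geometry=RigidWaterGeometry(**d["geometry"]),
            charges=ChargeModel(**d["charges"]),
            vdw=VdwSite(**d["vdw"]),
            pol=PolarizableSite(**d["pol"]),
            molar_mass=d.get("molar_mass", M_WATER),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ForceField":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def static_dipole(self) -> float:
        return static_dipole(self.geometry, self.charges)


_REQUIRED_SECTIONS = ("geometry", "charges", "vdw")


def build_forcefield(config: Union[dict, str, Path]) -> ForceField:
    """Assemble and validate a ForceField from a config mapping or TOML file.

    The config supplies geometry, charges, the polarizability and either
    atomic C6/C8 (a.u., re-partitioned onto oxygen) or already-combined
    molecular values, plus the oxygen van der Waals radius.  C11 is always
    derived from the zero-crossing condition.
    """
    if not isinstance(config, dict):
        import tomllib

        with open(config, "rb") as fh:
            config = tomllib.load(fh)

    for sec in _REQUIRED_SECTIONS:
        if sec not in config:
            raise ConfigError(sec, "missing config section")

    geometry = RigidWaterGeometry(**config["geometry"])
    charges = ChargeModel(**config["charges"])

    vdw_cfg = dict(config["vdw"])
    if "r_vdw" not in vdw_cfg:
        raise ConfigError("vdw.r_vdw", "missing van der Waals radius")
    if "c6_O_au" in vdw_cfg:  # atomic a.u. route
        disp = combine_dispersion(
            DispersionSet(
                c6_O_au=vdw_cfg.pop("c6_O_au"),
                c8_O_au=vdw_cfg.pop("c8_O_au", 0.0),
                c6_H_au=vdw_cfg.pop("c6_H_au", 0.0),
                c8_H_au=vdw_cfg.pop("c8_H_au", 0.0),
            )
        )
        c6, c8 = disp.c6_internal, disp.c8_internal
    elif "c6_au" in vdw_cfg:  # combined molecular a.u. route
        c6, c8 = convert_au_to_internal(vdw_cfg.pop("c6_au"), vdw_cfg.pop("c8_au", 0.0))
    elif "c6" in vdw_cfg:  # already internal
        c6, c8 = vdw_cfg.pop("c6"), vdw_cfg.pop("c8", 0.0)
    else:
        raise ConfigError("vdw.c6", "no dispersion coefficients supplied")

    vdw = VdwSite(r_vdw=vdw_cfg.pop("r_vdw"), c6=c6, c8=c8)

    pol_cfg = dict(config.get("pol", {}))
    pol_cfg.setdefault("q_COS", charges.q_COS)
    pol = PolarizableSite(**pol_cfg)
    if abs(pol.q_COS - charges.q_COS) > 1e-12:
        raise ConfigError("pol.q_COS", "COS charge differs between [charges] and [pol]")

    return ForceField(
        geometry=geometry,
        charges=charges,
        vdw=vdw,
        pol=pol,
        molar_mass=config.get("molar_mass", M_WATER),
    )


def default_forcefield() -> ForceField:
    """The final water model of this package.

    Combined molecular dispersion C6 = 43.44 a.u., C8 = 1201.3 a.u.;
    oxygen van der Waals radius 0.1605 nm; q_H = 0.539 e, q_M = -1.078 e;
    isotropic polarizability 1.05e-3 nm^3 on the M site with a -8 e COS
    particle; M offset 0.0225 nm.
    """
    return build_forcefield(
        {
            "geometry": {"r_OH": 0.0962, "theta_HOH": 105.4, "d_OM": 0.0225},
            "charges": {"q_H": 0.539, "q_M": -1.078, "q_O": 0.0, "q_COS": -8.0},
            "vdw": {"r_vdw": 0.1605, "c6_au": 43.44, "c8_au": 1201.3},
            "pol": {"alpha_iso": 1.05e-3},
        }
    )
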