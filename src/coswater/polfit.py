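"""Condensed-phase polarizability fitting from induced surface potentials.

Given vacuum/solvated MEPs on a grid and the external electric field at a
polarizable center, the induced potential phi_induced = phi_solv - phi_vac
is represented by a point dipole at the center.  Two estimators of the
diagonal polarizability tensor are provided:

free fit
    per solvent configuration, an unconstrained linear least squares for
    the induced dipole mu; the per-dimension polarizability follows as the
    ratio alpha_k = f_elec * mu_k / E_k.  Noisy and even sign-unstable
    when |E_k| is small.

consensus fit
    the ratio alpha_k is constrained to be identical across a subset of n
    configurations (default 20), i.e. mu_k^i = alpha_k E_k^i / f_elec is
    substituted into the dipole-potential model and only (alpha_xx,
    alpha_yy, alpha_zz) are fitted against the pooled grid equations of
    all member frames — a reduced least squares equivalent to the
    Lagrange-multiplier constrained problem, with far better conditioning.

The module also covers the static electrostatics workflow of the same
pipeline: constrained static-charge fitting against a vacuum MEP and the
scan of the off-atom M-site displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import F_ELEC
from .forcefield import RigidWaterGeometry, static_dipole, ChargeModel
from .synthetic import PolarizationDataset

__all__ = [
    "InducedPotentialSample",
    "FreeFitResult",
    "ConsensusFitResult",
    "PolarizabilityStats",
    "ChargeFitResult",
    "MSiteScanResult",
    "induced_potential",
    "fit_induced_dipoles_free",
    "partition_subsets",
    "consensus_fit",
    "isotropic",
    "fit_stats",
    "fit_static_charges",
    "scan_msite",
    "samples_from_dataset",
    "run_consensus_pipeline",
]

logger = logging.getLogger(__name__)

# |E_k| below this (kJ mol^-1 nm^-1 e^-1) makes the free ratio alpha_k = f mu_k/E_k
# meaningless; such frame-dimensions are flagged but still enter consensus fits.
LOW_FIELD_THRESHOLD = 1.0


@dataclass
class InducedPotentialSample:
    """One frame's induced potential plus the field at each center."""

    frame_id: int
    grid_points: np.ndarray  # (n_pts, 3)
    phi_induced: np.ndarray  # (n_pts,)
    e_field: np.ndarray  # (3,) or (n_centers, 3)
    centers: np.ndarray  # (3,) or (n_centers, 3)

    def __post_init__(self):
        self.e_field = np.atleast_2d(np.asarray(self.e_field, dtype=float))
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if len(self.phi_induced) != len(self.grid_points):
            raise ValueError("phi_induced and grid length mismatch")


@dataclass
class FreeFitResult:
    frame_id: int
    mu: np.ndarray  # (n_centers, 3) e nm
    alpha: np.ndarray  # (n_centers, 3) nm^3; nan where flagged
    e_field: np.ndarray  # (n_centers, 3)
    chi2: float
    low_field_flags: np.ndarray  # (n_centers, 3) bool
    rank_deficient: bool = False


@dataclass
class ConsensusFitResult:
    subset_id: int
    frame_ids: list
    alpha: np.ndarray  # (3,) nm^3, nan where undetermined
    chi2: float
    mu: np.ndarray  # (n_frames, 3) implied dipoles
    e_field: np.ndarray  # (n_frames, 3)


@dataclass
class DimensionSummary:
    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class PolarizabilityStats:
    """Distribution summaries of per-fit polarizabilities plus fit quality."""

    free: list  # DimensionSummary per dimension (x, y, z)
    consensus: list
    alpha_iso_free: float
    alpha_iso_consensus: float
    r2_free: np.ndarray  # (3,) pooled per dimension
    r2_consensus: np.ndarray
    chi2_ratio: float  # mean consensus chi2 / mean free chi2 (matched frames)


@dataclass
class ChargeFitResult:
    charges: dict  # site label -> fitted charge (e)
    rmsd: float  # kJ mol^-1 e^-1
    constraint_residual: float


@dataclass
class MSiteScanResult:
    displacements: np.ndarray
    rmsd: np.ndarray
    dipoles: np.ndarray  # Debye, per displacement
    optimal_displacement: float
    optimal_dipole: float
    optimal_charges: dict


def induced_potential(phi_solv: np.ndarray, phi_vac: np.ndarray) -> np.ndarray:
    """Pointwise induced potential phi_solv - phi_vac."""
    phi_solv = np.asarray(phi_solv, dtype=float)
    phi_vac = np.asarray(phi_vac, dtype=float)
    if phi_solv.shape[-1] != phi_vac.shape[-1]:
        raise ValueError("potential arrays have mismatched grid lengths")
    return phi_solv - phi_vac


def _dipole_design_matrix(grid_points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Design matrix A with A[n, 3i+k] = f_elec (r_in)_k / r_in^3."""
    rvec = grid_points[:, None, :] - centers[None, :, :]  # (n, c, 3)
    r3 = np.linalg.norm(rvec, axis=-1) ** 3
    if np.any(r3 < 1e-30):
        raise ValueError("grid point coincides with a polarizable center")
    a = F_ELEC * rvec / r3[:, :, None]
    return a.reshape(len(grid_points), -1)


def fit_induced_dipoles_free(sample: InducedPotentialSample) -> FreeFitResult:
    """Unconstrained least-squares induced dipole(s) for one frame."""
    n_centers = len(sample.centers)
    if len(sample.grid_points) <= 3 * n_centers:
        raise ValueError("need more grid points than fit parameters")
    a = _dipole_design_matrix(sample.grid_points, sample.centers)
    mu_flat, res, rank, _ = np.linalg.lstsq(a, sample.phi_induced, rcond=None)
    mu = mu_flat.reshape(n_centers, 3)
    resid = sample.phi_induced - a @ mu_flat
    chi2 = float(resid @ resid)
    flags = np.abs(sample.e_field) < LOW_FIELD_THRESHOLD
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = F_ELEC * mu / sample.e_field
    alpha = np.where(flags, np.nan, alpha)
    return FreeFitResult(
        frame_id=sample.frame_id,
        mu=mu,
        alpha=alpha,
        e_field=sample.e_field.copy(),
        chi2=chi2,
        low_field_flags=flags,
        rank_deficient=rank < a.shape[1],
    )


def partition_subsets(
    frame_ids: Sequence[int], subset_size: int = 20, seed: int = 0
) -> list[list[int]]:
    """Random disjoint subsets of frames; the remainder is dropped."""
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    frame_ids = list(frame_ids)
    if len(frame_ids) < subset_size:
        raise ValueError("fewer frames than subset_size")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(frame_ids))
    n_subsets = len(frame_ids) // subset_size
    dropped = len(frame_ids) - n_subsets * subset_size
    if dropped:
        logger.warning("partition_subsets: dropping %d remainder frame(s)", dropped)
    return [
        [frame_ids[j] for j in perm[i * subset_size : (i + 1) * subset_size]]
        for i in range(n_subsets)
    ]


def consensus_fit(
    samples: Sequence[InducedPotentialSample], subset_id: int = 0
) -> ConsensusFitResult:
    """Multi-frame constrained fit of a single diagonal polarizability.

    Substituting mu_k^i = alpha_k E_k^i / f_elec into the dipole-potential
    model turns the constrained problem into a least squares with only
    (alpha_xx, alpha_yy, alpha_zz) as unknowns over the pooled grid
    equations of all member frames.  chi2 is the pooled squared potential
    residual.  A dimension with zero field in every frame is undetermined
    and reported as nan.
    """
    if len(samples) == 0:
        raise ValueError("empty subset")
    if any(len(s.centers) != 1 for s in samples):
        raise NotImplementedError("consensus fit is validated for a single center")
    blocks = []
    rhs = []
    for s in samples:
        rvec = s.grid_points - s.centers[0][None, :]
        r3 = np.linalg.norm(rvec, axis=1) ** 3
        # phi = sum_k alpha_k E_k (r_n)_k / r_n^3  (f_elec cancels between
        # the dipole potential prefactor and mu = alpha E / f_elec)
        blocks.append(s.e_field[0][None, :] * rvec / r3[:, None])
        rhs.append(s.phi_induced)
    a = np.vstack(blocks)
    y = np.concatenate(rhs)

    e_all = np.vstack([s.e_field[0] for s in samples])
    determined = np.any(np.abs(e_all) > 0, axis=0)
    if not np.all(determined):
        logger.warning(
            "consensus_fit subset %d: dimension(s) %s have zero field in all frames",
            subset_id,
            np.nonzero(~determined)[0].tolist(),
        )
    alpha = np.full(3, np.nan)
    cols = np.nonzero(determined)[0]
    sol, _, _, _ = np.linalg.lstsq(a[:, cols], y, rcond=None)
    alpha[cols] = sol
    pred = a[:, cols] @ sol
    chi2 = float(np.sum((y - pred) ** 2))
    mu = np.where(determined[None, :], alpha[None, :], 0.0) * e_all / F_ELEC
    return ConsensusFitResult(
        subset_id=subset_id,
        frame_ids=[s.frame_id for s in samples],
        alpha=alpha,
        chi2=chi2,
        mu=mu,
        e_field=e_all,
    )


def isotropic(alpha_diag) -> float:
    """Isotropic polarizability: one third of the tensor trace."""
    alpha_diag = np.asarray(alpha_diag, dtype=float)
    if alpha_diag.shape[-1] != 3:
        raise ValueError("expected three diagonal components")
    return float(np.mean(alpha_diag)) if alpha_diag.ndim == 1 else np.mean(alpha_diag, axis=-1)


def _summarize(values: np.ndarray, whisker_factor: float = 4.0) -> DimensionSummary:
    """Five-number summary with whiskers at most ``whisker_factor`` IQRs
    beyond the quartiles (linear-interpolation quantiles)."""
    v = values[np.isfinite(values)]
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - whisker_factor * iqr, q3 + whisker_factor * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return DimensionSummary(
        mean=float(np.mean(v)),
        median=float(med),
        sd=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=v[(v < lo_lim) | (v > hi_lim)],
    )


def _pooled_r2(mu: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of mu_k vs E_k per dimension."""
    out = np.full(3, np.nan)
    for k in range(3):
        x, y = e[:, k], mu[:, k]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() > 2 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            out[k] = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
    return out


def fit_stats(
    free_results: Sequence[FreeFitResult],
    consensus_results: Sequence[ConsensusFitResult],
    whisker_factor: float = 4.0,
) -> PolarizabilityStats:
    """Distribution and fit-quality summary of free vs consensus fits."""
    if len(free_results) < 2 or len(consensus_results) < 2:
        raise ValueError("need at least two results of each kind")
    free_alpha = np.vstack([r.alpha[0] for r in free_results])
    cons_alpha = np.vstack([r.alpha for r in consensus_results])

    free_mu = np.vstack([r.mu[0] for r in free_results])
    free_e = np.vstack([r.e_field[0] for r in free_results])
    cons_mu = np.vstack([r.mu for r in consensus_results])
    cons_e = np.vstack([r.e_field for r in consensus_results])

    # compare chi2 on the frames that actually entered consensus fits
    cons_frames = {f for r in consensus_results for f in r.frame_ids}
    free_chi2 = np.array([r.chi2 for r in free_results if r.frame_id in cons_frames])
    n_cons_frames = sum(len(r.frame_ids) for r in consensus_results)
    mean_cons_chi2 = sum(r.chi2 for r in consensus_results) / n_cons_frames
    chi2_ratio = float(mean_cons_chi2 / np.mean(free_chi2)) if len(free_chi2) else np.nan

    return PolarizabilityStats(
        free=[_summarize(free_alpha[:, k], whisker_factor) for k in range(3)],
        consensus=[_summarize(cons_alpha[:, k], whisker_factor) for k in range(3)],
        alpha_iso_free=float(np.nanmean(np.nanmean(free_alpha, axis=0))),
        alpha_iso_consensus=float(np.mean(np.nanmean(cons_alpha, axis=0))),
        r2_free=_pooled_r2(free_mu, free_e),
        r2_consensus=_pooled_r2(cons_mu, cons_e),
        chi2_ratio=chi2_ratio,
    )


def fit_static_charges(
    grid_points: np.ndarray,
    phi_vac: np.ndarray,
    site_positions: np.ndarray,
    site_labels: Sequence[str] = ("H1", "H2", "M"),
    net_charge: float = 0.0,
    symmetric_pairs: Sequence[tuple] = (("H1", "H2"),),
) -> ChargeFitResult:
    """Equality-constrained least-squares static charges against a MEP.

    Symmetric hydrogen sites share one parameter; the total charge is
    constrained exactly through a single Lagrange multiplier.
    """
    grid_points = np.asarray(grid_points, dtype=float)
    site_positions = np.asarray(site_positions, dtype=float)
    if len(grid_points) <= len(site_labels):
        raise ValueError("need more grid points than charge sites")
    d = np.linalg.norm(grid_points[:, None, :] - site_positions[None, :, :], axis=-1)
    if np.any(d < 1e-12):
        raise ValueError("a charge site lies on a grid point")
    a_full = F_ELEC / d  # (n_pts, n_sites)

    # merge symmetric sites into shared parameters
    labels = list(site_labels)
    root_of = {lbl: lbl for lbl in labels}
    for a_lbl, b_lbl in symmetric_pairs:
        root_of[b_lbl] = a_lbl
    group_index: dict[str, list[int]] = {}
    for i, lbl in enumerate(labels):
        group_index.setdefault(root_of[lbl], []).append(i)
    groups = list(group_index.values())
    a = np.column_stack([a_full[:, g].sum(axis=1) for g in groups])
    mult = np.array([len(g) for g in groups], dtype=float)

    n_par = a.shape[1]
    kkt = np.zeros((n_par + 1, n_par + 1))
    kkt[:n_par, :n_par] = 2.0 * a.T @ a
    kkt[:n_par, n_par] = mult
    kkt[n_par, :n_par] = mult
    rhs = np.concatenate([2.0 * a.T @ phi_vac, [net_charge]])
    sol = np.linalg.solve(kkt, rhs)
    q_par = sol[:n_par]

    q_sites = np.empty(len(labels))
    for g, q in zip(groups, q_par):
        q_sites[g] = q
    resid = phi_vac - a @ q_par
    return ChargeFitResult(
        charges={lbl: float(qv) for lbl, qv in zip(site_labels, q_sites)},
        rmsd=float(np.sqrt(np.mean(resid**2))),
        constraint_residual=float(abs(q_sites.sum() - net_charge)),
    )


def scan_msite(
    grid_points: np.ndarray,
    phi_vac: np.ndarray,
    geometry: RigidWaterGeometry,
    displacements: Optional[np.ndarray] = None,
) -> MSiteScanResult:
    """Scan the M-site displacement along the bisector, refitting charges.

    For each displacement the static charges are refitted against the
    reference vacuum MEP; the optimum minimizes the MEP RMSD and its
    model dipole is reported.
    """
    if displacements is None:
        displacements = np.arange(0.007, 0.0305, 0.0005)
    displacements = np.asarray(displacements, dtype=float)
    if len(displacements) == 0:
        raise ValueError("empty displacement grid")
    if np.any(np.diff(displacements) <= 0):
        raise ValueError("displacement grid must be strictly increasing")
    if displacements[0] <= 0 or displacements[-1] >= geometry.r_OH:
        raise ValueError("displacements must lie in (0, r_OH)")

    rmsds = np.empty(len(displacements))
    dipoles = np.empty(len(displacements))
    fits = []
    for i, d_om in enumerate(displacements):
        geo = RigidWaterGeometry(r_OH=geometry.r_OH, theta_HOH=geometry.theta_HOH, d_OM=d_om)
        sites = geo.site_positions()[1:]  # H1, H2, M
        fit = fit_static_charges(grid_points, phi_vac, sites)
        rmsds[i] = fit.rmsd
        dipoles[i] = static_dipole(
            geo, ChargeModel(q_H=fit.charges["H1"], q_M=fit.charges["M"])
        )
        fits.append(fit)
    best = int(np.argmin(rmsds))
    return MSiteScanResult(
        displacements=displacements,
        rmsd=rmsds,
        dipoles=dipoles,
        optimal_displacement=float(displacements[best]),
        optimal_dipole=float(dipoles[best]),
        optimal_charges=fits[best].charges,
    )


def samples_from_dataset(ds: PolarizationDataset) -> list[InducedPotentialSample]:
    """Induced-potential samples for every frame of a synthetic dataset."""
    phi_ind = induced_potential(ds.grid.phi_solv, ds.grid.phi_vac)
    return [
        InducedPotentialSample(
            frame_id=i,
            grid_points=ds.grid.points,
            phi_induced=phi_ind[i],
            e_field=ds.fields[i],
            centers=ds.solute.center,
        )
        for i in range(ds.n_frames)
    ]


def run_consensus_pipeline(
    ds: PolarizationDataset, subset_size: int = 20, seed: int = 0
) -> tuple[list[FreeFitResult], list[ConsensusFitResult], PolarizabilityStats]:
    """Free fits, disjoint-subset consensus fits and summary statistics."""
    samples = samples_from_dataset(ds)
    free = [fit_induced_dipoles_free(s) for s in samples]
    subsets = partition_subsets([s.frame_id for s in samples], subset_size, seed)
    by_id = {s.frame_id: s for s in samples}
    cons = [
        consensus_fit([by_id[f] for f in subset], subset_id=i)
        for i, subset in enumerate(subsets)
    ]
    return free, cons, fit_stats(free, cons)
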