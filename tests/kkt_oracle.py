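"""Independent Lagrange-multiplier (KKT) solver for the consensus fit.

Solves the full constrained problem over all per-frame dipole components:
minimize sum_i ||A_i mu^i - phi^i||^2 subject to the pairwise ratio
constraints mu_k^i E_k^j - mu_k^j E_k^i = 0 (chained over consecutive
frames, per dimension).  Serves as the cross-check oracle for the reduced
3-parameter consensus solve; it is deliberately written against the raw
formulation rather than the production code path.
"""

import numpy as np

from coswater.constants import F_ELEC


def kkt_consensus_alpha(grid_points, center, phi_induced_list, e_fields):
    """Return (alpha, mu_all) from the explicit KKT system.

    grid_points: (n_pts, 3); center: (3,); phi_induced_list: list of
    (n_pts,) arrays; e_fields: (n_frames, 3).
    """
    n_frames = len(phi_induced_list)
    rvec = grid_points - center[None, :]
    r3 = np.linalg.norm(rvec, axis=1) ** 3
    a_frame = F_ELEC * rvec / r3[:, None]  # (n_pts, 3), same for all frames

    # scale the quadratic form to O(1) (minimizer unchanged) so the saddle
    # system is well conditioned in float64
    s_a = float(np.sqrt(np.mean(a_frame**2)))
    a_s = a_frame / s_a

    n_var = 3 * n_frames
    h = np.zeros((n_var, n_var))
    g = np.zeros(n_var)
    ata = 2.0 * a_s.T @ a_s
    for i, phi in enumerate(phi_induced_list):
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = ata
        g[3 * i : 3 * i + 3] = 2.0 * a_s.T @ (phi / s_a)

    rows = []
    for i in range(n_frames - 1):
        for k in range(3):
            row = np.zeros(n_var)
            row[3 * i + k] = e_fields[i + 1, k]
            row[3 * (i + 1) + k] = -e_fields[i, k]
            norm = np.linalg.norm(row)
            if norm > 0:  # unit-norm constraint rows (solution unchanged)
                rows.append(row / norm)
    c = np.array(rows) if rows else np.zeros((0, n_var))

    kkt = np.block([[h, c.T], [c, np.zeros((len(c), len(c)))]])
    rhs = np.concatenate([g, np.zeros(len(c))])
    sol = np.linalg.solve(kkt, rhs)
    mu = sol[:n_var].reshape(n_frames, 3)

    alpha = np.full(3, np.nan)
    for k in range(3):
        idx = np.argmax(np.abs(e_fields[:, k]))
        if np.abs(e_fields[idx, k]) > 0:
            alpha[k] = F_ELEC * mu[idx, k] / e_fields[idx, k]
    return alpha, mu
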