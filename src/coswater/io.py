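"""File interchange: shell/grid CSV schemas, energy CSV, GRO/XYZ export.

Solvent shells and MEP grids travel as plain CSV with the schemas

    shells:  frame_id, mol_id, site, x, y, z, q
    grids:   x, y, z, phi_vac, phi_solv_frame0, phi_solv_frame1, ...

so real QM/MM exports can be dropped in for the synthetic generator.
Coordinate export uses MDAnalysis when available (GRO), with a plain XYZ
fallback that needs no optional dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .synthetic import MEPGrid, SolventShell

__all__ = [
    "write_shells_csv",
    "read_shells_csv",
    "write_grid_csv",
    "read_grid_csv",
    "write_energy_csv",
    "write_xyz",
    "write_gro",
]


def write_shells_csv(shells: Sequence[SolventShell], path: Union[str, Path]) -> None:
    frames = []
    for shell in shells:
        n = len(shell.positions)
        frames.append(
            pd.DataFrame(
                {
                    "frame_id": np.full(n, shell.frame_id),
                    "mol_id": shell.mol_ids,
                    "site": np.tile(["O", "H1", "H2"], n // 3)[:n],
                    "x": shell.positions[:, 0],
                    "y": shell.positions[:, 1],
                    "z": shell.positions[:, 2],
                    "q": shell.charges,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_shells_csv(path: Union[str, Path]) -> list[SolventShell]:
    df = pd.read_csv(path)
    shells = []
    for fid, grp in df.groupby("frame_id", sort=True):
        shells.append(
            SolventShell(
                frame_id=int(fid),
                positions=grp[["x", "y", "z"]].to_numpy(),
                charges=grp["q"].to_numpy(),
                mol_ids=grp["mol_id"].to_numpy(),
            )
        )
    return shells


def write_grid_csv(grid: MEPGrid, path: Union[str, Path]) -> None:
    cols = {
        "x": grid.points[:, 0],
        "y": grid.points[:, 1],
        "z": grid.points[:, 2],
    }
    if grid.phi_vac is not None:
        cols["phi_vac"] = grid.phi_vac
    if grid.phi_solv is not None:
        for k in range(grid.phi_solv.shape[0]):
            cols[f"phi_solv_frame{k}"] = grid.phi_solv[k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_grid_csv(path: Union[str, Path]) -> MEPGrid:
    df = pd.read_csv(path)
    solv_cols = sorted(
        (c for c in df.columns if c.startswith("phi_solv_frame")),
        key=lambda c: int(c.rsplit("frame", 1)[1]),
    )
    return MEPGrid(
        points=df[["x", "y", "z"]].to_numpy(),
        phi_vac=df["phi_vac"].to_numpy() if "phi_vac" in df else None,
        phi_solv=df[solv_cols].to_numpy().T if solv_cols else None,
    )


def write_energy_csv(traj, path: Union[str, Path]) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def write_xyz(path: Union[str, Path], pos: np.ndarray, elements: Sequence[str], comment: str = "") -> None:
    """Plain XYZ (Angstrom) snapshot of one frame."""
    pos = np.asarray(pos, dtype=float).reshape(-1, 3)
    lines = [str(len(pos)), comment]
    for el, (x, y, z) in zip(elements, pos * 10.0):
        lines.append(f"{el} {x:.5f} {y:.5f} {z:.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gro(path: Union[str, Path], state, topo, name: str = "COS water") -> None:
    """GRO snapshot (O, H1, H2 per molecule) via MDAnalysis."""
    import MDAnalysis as mda

    n = state.n_mol
    u = mda.Universe.empty(
        n_atoms=3 * n, n_residues=n, atom_resindex=np.repeat(np.arange(n), 3), trajectory=True
    )
    u.add_TopologyAttr("names", ["OW", "HW1", "HW2"] * n)
    u.add_TopologyAttr("resnames", ["SOL"] * n)
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.atoms.positions = state.pos.reshape(-1, 3) * 10.0  # nm -> Angstrom
    u.dimensions = [state.box * 10.0] * 3 + [90.0, 90.0, 90.0]
    u.atoms.write(str(path))
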