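"""File writers: legacy-ASCII VTK structured grids and CSV time series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DomainGrid


def write_structured_vtk(path: str | Path, grid: DomainGrid, fields: dict[str, np.ndarray],
                         title: str = "iptsl field") -> Path:
    """Write cell-center fields as a legacy VTK STRUCTURED_GRID (r, z plane).

    Points are the (r_cyl, z) cell centers of the axisymmetric mesh; each
    field array may cover the full grid or the tumor sub-grid (smaller
    first dimension), in which case it is zero-padded outside the tumor.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    r_cyl, z = grid.cell_centers_rz()
    nr, nt = r_cyl.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nt} {nr} 1\n")
        fh.write(f"POINTS {nr * nt} float\n")
        for i in range(nr):
            for j in range(nt):
                fh.write(f"{r_cyl[i, j]:.7e} {z[i, j]:.7e} 0.0\n")
        fh.write(f"POINT_DATA {nr * nt}\n")
        for name, arr in fields.items():
            full = np.zeros((nr, nt))
            full[: arr.shape[0], :] = arr
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for i in range(nr):
                for j in range(nt):
                    fh.write(f"{full[i, j]:.7e}\n")
    return path


def write_series_csv(path: str | Path, columns: dict[str, np.ndarray]) -> Path:
    """Write named 1D series as CSV (17 significant digits, round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.17g")
    return path


def read_series_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
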