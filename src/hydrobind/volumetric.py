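"""Minimal OpenDX-dialect volumetric grid reader/writer.

Only regular, axis-aligned grids with a single scalar per voxel are supported
(the dialect produced by common solvent-density tools).  Values are stored
x-slowest / z-fastest, matching the OpenDX convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from hydrobind.hydration import PocketGrid

__all__ = ["read_dx", "write_dx"]


def read_dx(path: str | Path) -> PocketGrid:
    path = Path(path)
    dims = origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object 1"):
                dims = tuple(int(tok) for tok in line.split()[-3:])
            elif line.startswith("origin"):
                origin = np.array([float(t) for t in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append(np.array([float(t) for t in line.split()[1:4]]))
            elif line.startswith("object 3"):
                toks = line.split()
                n_items = int(toks[toks.index("items") + 1])
            elif line.startswith("object") or line.startswith("attribute"):
                continue
            else:
                values.extend(float(t) for t in line.split())
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX grid")
    spacings = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    off_diag = sum(abs(d[i]) for k, d in enumerate(deltas) for i in range(3) if i != k)
    if off_diag > 1e-9 or not np.allclose(spacings, spacings[0]):
        raise ValueError(f"{path}: only isotropic axis-aligned grids are supported")
    n_expected = dims[0] * dims[1] * dims[2]
    if n_items is not None and n_items != n_expected:
        raise ValueError(f"{path}: item count {n_items} != grid size {n_expected}")
    arr = np.array(values[:n_expected], dtype=float).reshape(dims)
    if arr.size != n_expected:
        raise ValueError(f"{path}: expected {n_expected} values, got {arr.size}")
    return PocketGrid(origin=origin, spacing=float(spacings[0]), dims=dims, values=arr)


def write_dx(path: str | Path, grid: PocketGrid) -> None:
    nx, ny, nz = grid.dims
    s = grid.spacing
    ox, oy, oz = grid.origin
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.reshape(-1)
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")
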