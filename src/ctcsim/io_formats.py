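"""Plain-text output writers: legacy-ASCII VTK, OFF/PLY meshes.

Legacy VTK is a simple line-oriented text format; fluid snapshots go out as
STRUCTURED_POINTS with point data (density, velocity, vorticity, flags) and
membranes as POLYDATA with optional per-vertex force arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "write_vtk_structured",
    "write_vtk_polydata",
    "write_off",
    "read_off",
    "write_ply",
]


def _vtk_header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def write_vtk_structured(path, scalars=None, vectors=None, spacing=1.0, title="ctcsim fluid"):
    """Write point-data fields on a regular lattice as legacy VTK.

    ``scalars``/``vectors`` map name -> array of shape (nx,ny,nz) /
    (3,nx,ny,nz).  VTK iterates x fastest, so arrays are transposed.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    shape = next(iter(list(scalars.values()) + [v[0] for v in vectors.values()])).shape
    nx, ny, nz = shape
    with open(path, "w") as fh:
        _vtk_header(fh, title)
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing} {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.asarray(arr).T.reshape(-1)[:, None].tofile(fh, sep="\n", format="%.7g")
            fh.write("\n")
        for name, arr in vectors.items():
            fh.write(f"VECTORS {name} float\n")
            flat = np.moveaxis(np.asarray(arr), 0, -1)  # (nx,ny,nz,3)
            flat = flat.transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.7g")


def write_vtk_polydata(path, vertices, faces, point_data=None, title="ctcsim membrane"):
    """Triangulated surface with optional per-vertex scalar/vector arrays."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        _vtk_header(fh, title)
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        np.savetxt(fh, vertices, fmt="%.7g")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {len(vertices)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr[:, None], fmt="%.7g")
                else:
                    fh.write(f"VECTORS {name} float\n")
                    np.savetxt(fh, arr, fmt="%.7g")


def write_off(path, vertices, faces) -> None:
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(vertices)} {len(faces)} 0\n")
        np.savetxt(fh, vertices, fmt="%.10g")
        np.savetxt(fh, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")


def read_off(path):
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    at = 4
    verts = np.array(tokens[at : at + 3 * nv], dtype=float).reshape(nv, 3)
    at += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[at])
        faces.append([int(t) for t in tokens[at + 1 : at + 1 + k]])
        at += k + 1
    return verts, np.array(faces, dtype=np.int64)


def write_ply(path, vertices, faces) -> None:
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        np.savetxt(fh, vertices, fmt="%.10g")
        np.savetxt(fh, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
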