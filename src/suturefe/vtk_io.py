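"""Legacy ASCII VTK unstructured-grid writer/reader.

Meshes and result fields are exchanged as legacy (``# vtk DataFile
Version 3.0``) ASCII files so runs can be inspected in ParaView.  Cell
data carries the integer ``tissue`` array plus any per-element scalar
fields; point data carries the displacement vector field, per-node
scalars and the named node sets encoded as 0/1 integer masks
(``set_<name>``).  The reader parses the same subset and is used for
round-trip checks; values survive the trip to better than 1e-6 relative
(written with 9 significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import CODE_TISSUES, TetMesh

_FMT = "%.9g"


@dataclass
class VtkData:
    """Contents of a legacy VTK unstructured-grid file."""

    points: np.ndarray
    cells: np.ndarray
    cell_data: dict[str, np.ndarray] = field(default_factory=dict)
    point_data: dict[str, np.ndarray] = field(default_factory=dict)


def _write_array(fh, arr: np.ndarray) -> None:
    a = np.atleast_2d(np.asarray(arr))
    if a.shape[0] == 1 and arr.ndim == 1:
        a = a.T
    np.savetxt(fh, a, fmt=_FMT)


def export_vtk(
    mesh: TetMesh,
    path,
    cell_fields: dict[str, np.ndarray] | None = None,
    point_fields: dict[str, np.ndarray] | None = None,
    displacement: np.ndarray | None = None,
    include_node_sets: bool = True,
    title: str = "suturefe unstructured grid",
) -> None:
    """Write a labelled mesh and result fields to a legacy ASCII file."""
    cell_fields = dict(cell_fields or {})
    point_fields = dict(point_fields or {})
    n, m = mesh.n_nodes, mesh.n_elements
    for name, arr in cell_fields.items():
        if np.asarray(arr).shape[0] != m:
            raise ValueError(f"cell field {name!r} not sized to the mesh")
    for name, arr in point_fields.items():
        if np.asarray(arr).shape[0] != n:
            raise ValueError(f"point field {name!r} not sized to the mesh")

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        _write_array(fh, mesh.nodes)
        fh.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4, dtype=np.int64), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10, dtype=np.int64), fmt="%d")

        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.tissue_codes(), fmt="%d")
        for name, arr in cell_fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            _write_array(fh, np.nan_to_num(np.asarray(arr, dtype=float), nan=-1.0))

        wrote_point_header = False
        if displacement is not None or point_fields or (include_node_sets and mesh.node_sets):
            fh.write(f"POINT_DATA {n}\n")
            wrote_point_header = True
        if displacement is not None:
            if np.asarray(displacement).shape != (n, 3):
                raise ValueError("displacement must be (n_nodes, 3)")
            fh.write("VECTORS displacement double\n")
            _write_array(fh, displacement)
        for name, arr in point_fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            _write_array(fh, np.asarray(arr, dtype=float))
        if include_node_sets and wrote_point_header:
            for name in sorted(mesh.node_sets):
                mask = np.zeros(n, dtype=np.int64)
                mask[mesh.node_sets[name]] = 1
                fh.write(f"SCALARS set_{name} int 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, mask, fmt="%d")


def read_vtk(path) -> VtkData:
    """Read the legacy ASCII unstructured-grid subset written above."""
    with open(path) as fh:
        tokens = fh.read().split()
    i = 0

    def expect(word):
        nonlocal i
        if tokens[i].upper() != word:
            raise ValueError(f"expected {word}, found {tokens[i]!r}")
        i += 1

    # header: '# vtk DataFile Version x.x' <title...> ASCII DATASET ...
    while tokens[i].upper() != "ASCII":
        i += 1
    expect("ASCII")
    expect("DATASET")
    expect("UNSTRUCTURED_GRID")
    expect("POINTS")
    n = int(tokens[i]); i += 2  # count, dtype
    points = np.array(tokens[i : i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("CELLS")
    m = int(tokens[i]); total = int(tokens[i + 1]); i += 2
    raw = np.array(tokens[i : i + total], dtype=np.int64)
    i += total
    if np.any(raw.reshape(m, -1)[:, 0] != 4):
        raise ValueError("only 4-node tetrahedral cells are supported")
    cells = raw.reshape(m, 5)[:, 1:]
    expect("CELL_TYPES")
    i += 1  # count
    ctypes = np.array(tokens[i : i + m], dtype=np.int64)
    i += m
    if np.any(ctypes != 10):
        raise ValueError("non-tetrahedral cell types present")

    data = VtkData(points=points, cells=cells)
    section, count = None, 0
    while i < len(tokens):
        word = tokens[i].upper()
        if word in ("CELL_DATA", "POINT_DATA"):
            section = word
            count = int(tokens[i + 1])
            i += 2
        elif word == "SCALARS":
            name, dtype = tokens[i + 1], tokens[i + 2].lower()
            i += 4  # SCALARS name type ncomp? -> we always write 1 comp
            if tokens[i].upper() == "LOOKUP_TABLE":
                i += 2
            vals = np.array(
                tokens[i : i + count], dtype=np.int64 if dtype == "int" else float
            )
            i += count
            target = data.cell_data if section == "CELL_DATA" else data.point_data
            target[name] = vals
        elif word == "VECTORS":
            name = tokens[i + 1]
            i += 3
            vals = np.array(tokens[i : i + 3 * count], dtype=float).reshape(count, 3)
            i += 3 * count
            target = data.cell_data if section == "CELL_DATA" else data.point_data
            target[name] = vals
        else:
            raise ValueError(f"unsupported VTK section {tokens[i]!r}")
    return data


def mesh_from_vtk(data: VtkData) -> TetMesh:
    """Rebuild a TetMesh (labels and node-set masks) from file contents."""
    if "tissue" not in data.cell_data:
        raise ValueError("VTK file has no 'tissue' cell array")
    tissue = np.array([CODE_TISSUES[int(c)] for c in data.cell_data["tissue"]],
                      dtype="<U10")
    node_sets = {
        name.removeprefix("set_"): np.flatnonzero(mask)
        for name, mask in data.point_data.items()
        if name.startswith("set_")
    }
    return TetMesh(nodes=data.points, elements=data.cells, tissue=tissue,
                   node_sets=node_sets)
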