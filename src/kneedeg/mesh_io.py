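"""Mesh and field I/O: legacy-ASCII VTK unstructured grids and Abaqus INP.

The VTK writer emits hexahedral cells with cell-data arrays (tissue, region,
layer and any stress fields); the reader parses files written here (and any
plain legacy-ASCII unstructured grid of hexahedra).  The INP reader handles
``*NODE``, ``*ELEMENT, TYPE=C3D8`` blocks and ``*ELSET`` labels — enough to
ingest an externally produced layered template.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np

from .geometry import CompartmentMesh

_VTK_HEX = 12


def write_vtk(mesh: CompartmentMesh, path, cell_data: dict | None = None) -> None:
    """Write a compartment mesh (plus optional per-element arrays) to VTK."""
    data = {
        "tissue": (mesh.tissue == "femoral_cartilage").astype(int),
        "region": np.searchsorted(
            np.array(["anterior", "central", "posterior"]), mesh.region
        ),
        "layer_index": mesh.layer_index,
    }
    if cell_data:
        data.update(cell_data)
    n, e = len(mesh.nodes), len(mesh.hexes)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"kneedeg {mesh.compartment} compartment\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        for p in mesh.nodes:
            f.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        f.write(f"CELLS {e} {e * 9}\n")
        for cell in mesh.hexes:
            f.write("8 " + " ".join(str(int(v)) for v in cell) + "\n")
        f.write(f"CELL_TYPES {e}\n")
        f.write("\n".join([str(_VTK_HEX)] * e) + "\n")
        f.write(f"CELL_DATA {e}\n")
        for name, values in data.items():
            values = np.asarray(values)
            kind = "int" if np.issubdtype(values.dtype, np.integer) else "double"
            f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(repr(float(v)) if kind == "double" else str(int(v))
                              for v in values) + "\n")


def read_vtk(path) -> SimpleNamespace:
    """Read a legacy-ASCII VTK unstructured grid of hexahedra.

    Returns nodes, hexes and cell_data; this is a raw-grid reader, not a
    full :class:`CompartmentMesh` round-trip (column metadata is rebuilt
    only by :func:`kneedeg.geometry.build_template`).
    """
    with open(path) as f:
        tokens = f.read().split("\n")
    i = 0

    def until(prefix):
        nonlocal i
        while not tokens[i].startswith(prefix):
            i += 1
        return tokens[i]

    header = until("POINTS").split()
    n = int(header[1])
    nodes = np.array(
        [[float(v) for v in tokens[i + 1 + j].split()] for j in range(n)]
    )
    i += n
    header = until("CELLS").split()
    e = int(header[1])
    hexes = np.array(
        [[int(v) for v in tokens[i + 1 + j].split()[1:]] for j in range(e)]
    )
    i += e
    cell_data = {}
    try:
        until("CELL_DATA")
        while True:
            line = until("SCALARS").split()
            name, kind = line[1], line[2]
            vals = []
            j = i + 2  # skip LOOKUP_TABLE
            while len(vals) < e:
                vals.extend(tokens[j].split())
                j += 1
            cast = int if kind == "int" else float
            cell_data[name] = np.array([cast(v) for v in vals])
            i = j
    except IndexError:
        pass
    return SimpleNamespace(nodes=nodes, hexes=hexes, cell_data=cell_data)


def read_inp(path) -> SimpleNamespace:
    """Read nodes, C3D8 hexahedra and element sets from an Abaqus INP file."""
    nodes: dict[int, list[float]] = {}
    elements: dict[int, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    section = None
    current_set = None
    with open(path) as f:
        for raw in f:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                key = line.upper()
                if key.startswith("*NODE"):
                    section = "node"
                elif key.startswith("*ELEMENT") and "C3D8" in key:
                    section = "element"
                    current_set = None
                    for part in line.split(","):
                        if part.strip().upper().startswith("ELSET="):
                            current_set = part.split("=")[1].strip()
                            elsets.setdefault(current_set, [])
                elif key.startswith("*ELSET"):
                    section = "elset"
                    current_set = None
                    for part in line.split(","):
                        if part.strip().upper().startswith("ELSET="):
                            current_set = part.split("=")[1].strip()
                            elsets.setdefault(current_set, [])
                else:
                    section = None
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if section == "node":
                nodes[int(parts[0])] = [float(v) for v in parts[1:4]]
            elif section == "element":
                eid = int(parts[0])
                elements[eid] = [int(v) for v in parts[1:9]]
                if current_set:
                    elsets[current_set].append(eid)
            elif section == "elset" and current_set:
                elsets[current_set].extend(int(v) for v in parts)
    node_ids = sorted(nodes)
    id_map = {nid: j for j, nid in enumerate(node_ids)}
    elem_ids = sorted(elements)
    eid_map = {eid: j for j, eid in enumerate(elem_ids)}
    return SimpleNamespace(
        nodes=np.array([nodes[nid] for nid in node_ids]),
        hexes=np.array([[id_map[v] for v in elements[eid]] for eid in elem_ids]),
        elsets={
            name: np.array(sorted(eid_map[e] for e in ids))
            for name, ids in elsets.items()
        },
    )
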