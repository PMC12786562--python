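"""Plain-text mesh and field export: legacy VTK and Gmsh MSH 2.2.

Both formats are written in ASCII so results can be inspected, diffed and
loaded in ParaView/Gmsh without binary dependencies.  The MSH reader is the
round-trip counterpart of the writer (volume elements with region tags plus
tagged surface triangles).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import TET10_EDGES, AssemblyMesh

__all__ = ["write_vtk", "write_msh", "read_msh", "write_manifest"]

_VTK_CELL = {4: 10, 10: 24}  # tet4, quadratic tet

#: Gmsh element types: 4 = tet4, 11 = tet10; 2 = tri3, 9 = tri6
_MSH_TET = {4: 4, 10: 11}
_MSH_TRI = {3: 2, 6: 9}

# Gmsh's tet10 midside ordering differs from ours (VTK) in the last three
# nodes: VTK lists edges (03,13,23), Gmsh lists (03,23,13).
_VTK_TO_GMSH_TET10 = np.array([0, 1, 2, 3, 4, 5, 6, 7, 9, 8])


def write_vtk(path, mesh: AssemblyMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with region tags and field arrays."""
    path = Path(path)
    nn = mesh.elements.shape[1]
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\nossicrimp mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.12g")
        ne = mesh.n_elements
        f.write(f"CELLS {ne} {ne * (nn + 1)}\n")
        cells = np.column_stack([np.full(ne, nn), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {ne}\n")
        np.savetxt(f, np.full(ne, _VTK_CELL[nn]), fmt="%d")
        f.write(f"CELL_DATA {ne}\n")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.region_tags, fmt="%d")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr)
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt="%.9g")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, np.nan_to_num(arr), fmt="%.9g")
                else:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, np.nan_to_num(arr), fmt="%.9g")


def write_msh(path, mesh: AssemblyMesh) -> None:
    """Gmsh MSH 2.2 ASCII with physical tags for regions and patches."""
    path = Path(path)
    nn = mesh.elements.shape[1]
    patch_names = sorted(mesh.patches)
    # physical ids: regions keep their tag; patches get 100 + index
    patch_phys = {name: 100 + i for i, name in enumerate(patch_names)}
    with path.open("w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n")
        f.write(f"{len(mesh.region_names) + len(patch_names)}\n")
        for rid, name in sorted(mesh.region_names.items()):
            f.write(f'3 {rid} "{name}"\n')
        for name in patch_names:
            f.write(f'2 {patch_phys[name]} "{name}"\n')
        f.write("$EndPhysicalNames\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.12g} {y:.12g} {z:.12g}\n")
        f.write("$EndNodes\n")
        n_surf = sum(p.shape[0] for p in mesh.patches.values())
        f.write(f"$Elements\n{mesh.n_elements + n_surf}\n")
        eid = 1
        for name in patch_names:
            facets = mesh.patches[name]
            etype = _MSH_TRI[facets.shape[1]]
            phys = patch_phys[name]
            for row in facets:
                nodes = " ".join(str(v + 1) for v in row)
                f.write(f"{eid} {etype} 2 {phys} {phys} {nodes}\n")
                eid += 1
        elems = mesh.elements
        if nn == 10:
            elems = elems[:, _VTK_TO_GMSH_TET10]
        etype = _MSH_TET[nn]
        for row, tag in zip(elems, mesh.region_tags):
            nodes = " ".join(str(v + 1) for v in row)
            f.write(f"{eid} {etype} 2 {tag} {tag} {nodes}\n")
            eid += 1
        f.write("$EndElements\n")


def read_msh(path) -> AssemblyMesh:
    """Read a mesh written by :func:`write_msh` (MSH 2.2 subset)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    it = iter(lines)
    phys_names: dict[int, str] = {}
    nodes = None
    vol_elems, vol_tags = [], []
    surf: dict[int, list[list[int]]] = {}
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, pid, name = next(it).split(maxsplit=2)
                phys_names[int(pid)] = name.strip('"')
            next(it)  # $End
        elif line == "$Nodes":
            n = int(next(it))
            nodes = np.empty((n, 3))
            for i in range(n):
                parts = next(it).split()
                nodes[i] = [float(v) for v in parts[1:4]]
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = [int(v) for v in next(it).split()]
                etype, ntags = parts[1], parts[2]
                phys = parts[3]
                conn = [v - 1 for v in parts[3 + ntags:]]
                if etype in (4, 11):
                    vol_elems.append(conn)
                    vol_tags.append(phys)
                elif etype in (2, 9):
                    surf.setdefault(phys, []).append(conn)
            next(it)
    if nodes is None or not vol_elems:
        raise ValueError(f"no volume mesh found in {path}")
    elements = np.array(vol_elems)
    if elements.shape[1] == 10:
        inv = np.argsort(_VTK_TO_GMSH_TET10)
        elements = elements[:, inv]
    region_tags = np.array(vol_tags)
    region_names = {rid: phys_names.get(rid, f"region{rid}")
                    for rid in np.unique(region_tags)}
    patches = {phys_names.get(pid, f"patch{pid}"): np.array(rows)
               for pid, rows in surf.items()}
    return AssemblyMesh(
        nodes=nodes, elements=elements, region_tags=region_tags,
        patches=patches, order=2 if elements.shape[1] == 10 else 1,
        region_names=region_names,
    )


def write_manifest(path, config: dict) -> None:
    """JSON run manifest capturing the full configuration for reproduction."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
        return str(o)

    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=_default))
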