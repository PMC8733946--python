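"""File exchange: VTU meshes/results, CSV tables, YAML configs.

The VTU writer emits plain ASCII XML unstructured grids (linear or
quadratic tetrahedra with optional point/cell data), enough for ParaView
inspection of meshes, displacement fields and strain invariants.
"""

from __future__ import annotations

import numpy as np

_VTK_TET4 = 10
_VTK_TET10 = 24


def write_vtu(path, nodes, tets, cell_data=None, point_data=None) -> None:
    """Write a tetrahedral mesh with named data arrays as ASCII VTU."""
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    ctype = _VTK_TET10 if tets.shape[1] == 10 else _VTK_TET4
    cell_data = cell_data or {}
    point_data = point_data or {}

    def arr_txt(a, fmt="%g"):
        return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row))
                         for row in a)

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(f'<Piece NumberOfPoints="{len(nodes)}" '
                 f'NumberOfCells="{len(tets)}">\n')
        fh.write('<Points>\n<DataArray type="Float64" '
                 'NumberOfComponents="3" format="ascii">\n')
        fh.write(arr_txt(nodes, "%.9g"))
        fh.write('\n</DataArray>\n</Points>\n<Cells>\n')
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        fh.write(arr_txt(tets, "%d"))
        fh.write('\n</DataArray>\n'
                 '<DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(arr_txt((np.arange(1, len(tets) + 1) * tets.shape[1])[:, None],
                         "%d"))
        fh.write('\n</DataArray>\n'
                 '<DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write(arr_txt(np.full((len(tets), 1), ctype), "%d"))
        fh.write('\n</DataArray>\n</Cells>\n')
        fh.write('<CellData>\n')
        for name, data in cell_data.items():
            data = np.asarray(data)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            fh.write(f'<DataArray type="Float64" Name="{name}" '
                     f'NumberOfComponents="{ncomp}" format="ascii">\n')
            fh.write(arr_txt(data, "%.9g"))
            fh.write('\n</DataArray>\n')
        fh.write('</CellData>\n<PointData>\n')
        for name, data in point_data.items():
            data = np.asarray(data)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            fh.write(f'<DataArray type="Float64" Name="{name}" '
                     f'NumberOfComponents="{ncomp}" format="ascii">\n')
            fh.write(arr_txt(data, "%.9g"))
            fh.write('\n</DataArray>\n')
        fh.write('</PointData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n')


def write_mesh_vtu(path, mesh, extra_cell_data=None) -> None:
    cd = {"region": mesh.region.astype(float)}
    cd.update(extra_cell_data or {})
    write_vtu(path, mesh.nodes, mesh.tets, cell_data=cd)


def write_result_vtu(path, result) -> None:
    """Displacement + per-element mean shear strain on the solved mesh."""
    model = result.model
    E = result.strains.mean(axis=0)
    ev = np.linalg.eigvalsh(E)
    gamma = 0.5 * (ev[:, 2] - ev[:, 0]) * 100.0
    write_vtu(path, model.nodes, model.tets,
              cell_data={"region": model.region.astype(float),
                         "max_shear_pct": gamma},
              point_data={"displacement": result.displacement_field()})
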