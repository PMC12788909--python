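"""Plain-text VTK XML output and run archives.

Writes unstructured-grid (.vtu) files in ASCII with hexahedron cells,
one per increment, plus a ParaView ``.series`` index, per-increment
region summaries as CSV, and a compact ``.npz`` checkpoint holding the
mesh, labels, and final-state arrays.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

_VTK_HEXAHEDRON = 12


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(f"{v:.10g}" for v in flat)


def _data_array(name: str | None, arr: np.ndarray, ncomp: int) -> str:
    kind = np.asarray(arr).dtype.kind
    vtype = "Int64" if kind in "iu" else "Float64"
    nm = f' Name="{name}"' if name else ""
    return (f'<DataArray type="{vtype}"{nm} NumberOfComponents="{ncomp}" '
            f'format="ascii">\n{_fmt(arr)}\n</DataArray>')


def write_vtu(path, node_coords, connectivity, point_data=None, cell_data=None):
    """Write one ASCII VTK unstructured grid of hexahedra."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    n_pts = len(node_coords)
    n_cells = len(connectivity)
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>", _data_array(None, np.asarray(node_coords, float), 3), "</Points>",
        "<Cells>",
        _data_array("connectivity", np.asarray(connectivity, np.int64), 1),
        _data_array("offsets", 8 * np.arange(1, n_cells + 1, dtype=np.int64), 1),
        _data_array("types", np.full(n_cells, _VTK_HEXAHEDRON, np.int64), 1),
        "</Cells>",
    ]
    parts.append("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        parts.append(_data_array(name, arr, arr.shape[1] if arr.ndim > 1 else 1))
    parts.append("</PointData>")
    parts.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        parts.append(_data_array(name, arr, arr.shape[1] if arr.ndim > 1 else 1))
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def mesh_hash(mesh) -> str:
    """Content hash of mesh geometry + labels (pairing identity check)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.node_coords).tobytes())
    h.update(np.ascontiguousarray(mesh.element_connectivity).tobytes())
    return h.hexdigest()[:16]


def geometry_hash(mesh) -> str:
    return mesh_hash(mesh)


def write_run(result, outdir) -> Path:
    """Write the VTU time series, summaries, and checkpoint of one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = result.mesh
    labels = sorted(set(mesh.element_region))
    code = {lab: i for i, lab in enumerate(labels)}
    region_codes = np.array([code[lab] for lab in mesh.element_region], np.int64)

    series = []
    for k, state in enumerate(result.states):
        ro = result.readouts[k]
        cell_data = {
            "region": region_codes,
            "theta": state.theta,
            "concentration": result.concentration.c,
            **{name: arr for name, arr in ro.as_dict().items()},
        }
        fname = f"step_{k}.vtu"
        write_vtu(outdir / fname, mesh.node_coords, mesh.element_connectivity,
                  point_data={"displacement": state.u}, cell_data=cell_data)
        series.append({"name": fname, "time": state.time})
    (outdir / "steps.vtu.series").write_text(
        json.dumps({"file-series-version": "1.0", "files": series}, indent=1))
    (outdir / "region_legend.json").write_text(json.dumps(code, indent=1))
    result.summaries.to_csv(outdir / "region_summaries.csv", index=False)

    final = result.final_state
    ro = result.readouts[-1]
    np.savez_compressed(
        outdir / "archive.npz",
        node_coords=mesh.node_coords,
        connectivity=mesh.element_connectivity,
        element_region=mesh.element_region.astype("<U32"),
        outer_boundary_nodes=mesh.outer_boundary_nodes,
        voxel_size=mesh.voxel_size,
        scheme=np.array(result.scheme),
        mesh_hash=np.array(mesh_hash(mesh)),
        times=np.array(result.times),
        u=final.u, theta=final.theta,
        concentration=result.concentration.c,
        **{f"readout_{k}": v for k, v in ro.as_dict().items()},
    )
    return outdir


def load_archive(rundir):
    """Load the arrays stored by :func:`write_run` (final increment)."""
    with np.load(Path(rundir) / "archive.npz", allow_pickle=False) as z:
        return {k: z[k] for k in z.files}
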