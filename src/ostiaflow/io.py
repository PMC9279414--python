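"""Standard-format I/O: Gmsh MSH v4.1, VTU (ASCII XML), CSV tables, and
hierarchical YAML run configurations.

Meshes round-trip through either format with node coordinates preserved to
1e-12 relative and connectivity/patch labels preserved exactly. Patch
name<->tag tables travel in a JSON sidecar (``<mesh>.patches.json``).
Solutions are written as VTU with point fields ``velocity_m_per_s`` and
``pressure_Pa`` and cell fields ``shear_rate_per_s`` and ``viscosity_Pa_s``;
WSS post-processing appends ``wss_Pa`` / ``wss_cgs`` cell data.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .geometry import VolumeMesh
from .rheology import ViscositySample

__all__ = [
    "write_mesh", "read_mesh", "write_solution", "read_solution_fields",
    "write_report", "write_viscosity_csv", "read_viscosity_csv",
    "load_config_file", "save_config_file",
]

_FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".patches.json")


def write_mesh(mesh: VolumeMesh, path) -> None:
    """Write a labeled mesh as .msh (Gmsh 4.1 ASCII) or .vtu, plus the
    patch-name sidecar JSON."""
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtu":
        _write_vtu_mesh(mesh, path)
    else:
        raise FormatError(f"unknown mesh extension {path.suffix!r} (use .msh or .vtu)")
    _sidecar(path).write_text(json.dumps(
        {str(k): v for k, v in mesh.patch_names.items()}, indent=1))


def read_mesh(path) -> VolumeMesh:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    if path.suffix == ".msh":
        mesh = _read_msh(path)
    elif path.suffix == ".vtu":
        mesh = _read_vtu_mesh(path)
    else:
        raise FormatError(f"unknown mesh extension {path.suffix!r} (use .msh or .vtu)")
    side = _sidecar(path)
    if side.exists():
        mesh.patch_names = {int(k): v for k, v in json.loads(side.read_text()).items()}
    return mesh


# ---------------------------------------------------------------------------
# Gmsh MSH v4.1 (ASCII)
# ---------------------------------------------------------------------------

def _write_msh(mesh: VolumeMesh, path: Path):
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    patch_ids = mesh.patch_ids()
    lines.append("$PhysicalNames")
    lines.append(str(len(patch_ids) + 1))
    for pid in patch_ids:
        lines.append(f'2 {pid} "{mesh.patch_names.get(pid, str(pid))}"')
    lines.append('3 100 "FLUID"')
    lines.append("$EndPhysicalNames")
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    box = " ".join(_FLOAT_FMT % v for v in (*lo, *hi))
    lines.append("$Entities")
    lines.append(f"0 0 {len(patch_ids)} 1")
    for pid in patch_ids:
        lines.append(f"{pid} {box} 1 {pid} 0")
    lines.append(f"1 {box} 1 100 0")
    lines.append("$EndEntities")
    n = mesh.n_nodes
    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"3 1 0 {n}")
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(" ".join(_FLOAT_FMT % c for c in row) for row in mesh.nodes)
    lines.append("$EndNodes")
    lines.append("$Elements")
    n_elem = mesh.n_tets + len(mesh.boundary_tris)
    blocks = []
    tag = 1
    for pid in patch_ids:
        idx = mesh.patch_faces(pid)
        rows = []
        for f in mesh.boundary_tris[idx]:
            rows.append(f"{tag} " + " ".join(str(v + 1) for v in f))
            tag += 1
        blocks.append((f"2 {pid} 2 {len(idx)}", rows))
    rows = []
    for t in mesh.tets:
        rows.append(f"{tag} " + " ".join(str(v + 1) for v in t))
        tag += 1
    blocks.append((f"3 1 4 {mesh.n_tets}", rows))
    lines.append(f"{len(blocks)} {n_elem} 1 {n_elem}")
    for head, rows in blocks:
        lines.append(head)
        lines.extend(rows)
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> VolumeMesh:
    lines = path.read_text().splitlines()
    try:
        return _parse_msh_lines(lines)
    except FormatError:
        raise
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed MSH file {path}: {exc}") from exc


def _parse_msh_lines(lines) -> VolumeMesh:
    def section(name):
        try:
            start = lines.index(f"${name}") + 1
            end = lines.index(f"$End{name}")
        except ValueError as exc:
            raise FormatError(f"missing ${name} section") from exc
        return lines[start:end]

    nsec = section("Nodes")
    n_blocks, n_nodes, _, _ = (int(v) for v in nsec[0].split())
    coords = np.empty((n_nodes, 3))
    tags = np.empty(n_nodes, dtype=int)
    row = 1
    filled = 0
    for _ in range(n_blocks):
        _, _, _, nb = (int(v) for v in nsec[row].split())
        row += 1
        for k in range(nb):
            tags[filled + k] = int(nsec[row + k])
        row += nb
        for k in range(nb):
            coords[filled + k] = [float(v) for v in nsec[row + k].split()]
        row += nb
        filled += nb
    if filled != n_nodes:
        raise FormatError(f"expected {n_nodes} nodes, parsed {filled}")
    order = np.argsort(tags)
    remap = np.empty(tags.max() + 1, dtype=int)
    remap[tags[order]] = np.arange(n_nodes)
    coords = coords[order]

    esec = section("Elements")
    n_blocks = int(esec[0].split()[0])
    row = 1
    tets, tris, labels = [], [], []
    for _ in range(n_blocks):
        dim, etag, etype, nb = (int(v) for v in esec[row].split())
        row += 1
        for k in range(nb):
            vals = [int(v) for v in esec[row + k].split()][1:]
            if etype == 4:
                tets.append(vals)
            elif etype == 2:
                tris.append(vals)
                labels.append(etag)
            else:
                raise FormatError(f"unsupported element type {etype}")
        row += nb
    tets = remap[np.asarray(tets, dtype=int)]
    tris = remap[np.asarray(tris, dtype=int)]
    return _finish_mesh(coords, tets, tris, np.asarray(labels, dtype=int))


# ---------------------------------------------------------------------------
# VTU (ASCII XML)
# ---------------------------------------------------------------------------

def _da(parent, name, data, n_comp=1, dtype="Float64"):
    el = ET.SubElement(parent, "DataArray", {
        "type": dtype, "Name": name, "NumberOfComponents": str(n_comp),
        "format": "ascii"})
    arr = np.asarray(data)
    if dtype.startswith("Float"):
        el.text = "\n" + "\n".join(
            " ".join(_FLOAT_FMT % v for v in np.atleast_1d(row))
            for row in arr) + "\n"
    else:
        el.text = "\n" + "\n".join(
            " ".join(str(int(v)) for v in np.atleast_1d(row))
            for row in arr) + "\n"
    return el


def _vtu_skeleton(mesh: VolumeMesh, include_tris=True):
    root = ET.Element("VTKFile", {"type": "UnstructuredGrid",
                                  "version": "0.1",
                                  "byte_order": "LittleEndian"})
    grid = ET.SubElement(root, "UnstructuredGrid")
    cells_conn = [mesh.tets]
    types = [np.full(mesh.n_tets, 10)]
    sizes = [np.full(mesh.n_tets, 4)]
    if include_tris and len(mesh.boundary_tris):
        cells_conn.append(mesh.boundary_tris)
        types.append(np.full(len(mesh.boundary_tris), 5))
        sizes.append(np.full(len(mesh.boundary_tris), 3))
    conn = np.concatenate([c.ravel() for c in cells_conn])
    sizes = np.concatenate(sizes)
    offsets = np.cumsum(sizes)
    types = np.concatenate(types)
    piece = ET.SubElement(grid, "Piece", {
        "NumberOfPoints": str(mesh.n_nodes), "NumberOfCells": str(len(types))})
    pts = ET.SubElement(piece, "Points")
    _da(pts, "Points", mesh.nodes, 3)
    cells = ET.SubElement(piece, "Cells")
    _da(cells, "connectivity", conn, dtype="Int64")
    _da(cells, "offsets", offsets, dtype="Int64")
    _da(cells, "types", types, dtype="UInt8")
    return root, piece


def _write_vtu_mesh(mesh: VolumeMesh, path: Path):
    root, piece = _vtu_skeleton(mesh)
    cd = ET.SubElement(piece, "CellData")
    labels = np.concatenate([np.zeros(mesh.n_tets, dtype=int),
                             mesh.boundary_labels])
    _da(cd, "patch_label", labels, dtype="Int32")
    ET.ElementTree(root).write(path, xml_declaration=True)


def write_solution(solution, path, wss_fields=()) -> None:
    """Write a FlowSolution as VTU: point velocity/pressure plus cell
    shear-rate/viscosity; optional WSSField objects add wss cell data."""
    path = Path(path)
    if path.suffix != ".vtu":
        raise FormatError(f"solutions are written as .vtu, got {path.suffix!r}")
    mesh = solution.mesh
    root, piece = _vtu_skeleton(mesh)
    pdata = ET.SubElement(piece, "PointData")
    _da(pdata, "velocity_m_per_s", solution.velocity, 3)
    _da(pdata, "pressure_Pa", solution.pressure)
    cdata = ET.SubElement(piece, "CellData")
    n_cells = mesh.n_tets + len(mesh.boundary_tris)
    gdot = np.zeros(n_cells)
    gdot[:mesh.n_tets] = solution.shear_rates()
    visc = np.zeros(n_cells)
    visc[:mesh.n_tets] = solution.element_viscosity()
    _da(cdata, "shear_rate_per_s", gdot)
    _da(cdata, "viscosity_Pa_s", visc)
    labels = np.concatenate([np.zeros(mesh.n_tets, dtype=int),
                             mesh.boundary_labels])
    _da(cdata, "patch_label", labels, dtype="Int32")
    if wss_fields:
        wss_pa = np.zeros(n_cells)
        for f in wss_fields:
            wss_pa[mesh.n_tets + f.face_indices] = f.wss_pa
        _da(cdata, "wss_Pa", wss_pa)
        _da(cdata, "wss_cgs", 10.0 * wss_pa)
    ET.ElementTree(root).write(path, xml_declaration=True)


def _parse_da(piece, name, dtype=float):
    for el in piece.iter("DataArray"):
        if el.get("Name") == name:
            vals = np.fromstring(el.text.replace("\n", " "), sep=" ", dtype=float)
            return vals.astype(dtype) if dtype is not float else vals
    raise FormatError(f"VTU file lacks DataArray {name!r}")


def _read_vtu(path: Path):
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"malformed VTU file {path}: {exc}") from exc
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise FormatError(f"VTU file {path} has no Piece element")
    pts = _parse_da(piece, "Points").reshape(-1, 3)
    conn = _parse_da(piece, "connectivity", int)
    offsets = _parse_da(piece, "offsets", int)
    types = _parse_da(piece, "types", int)
    cells = np.split(conn, offsets[:-1])
    tets = np.array([c for c, t in zip(cells, types) if t == 10], dtype=int)
    tris = np.array([c for c, t in zip(cells, types) if t == 5], dtype=int)
    if tets.size == 0:
        raise FormatError(f"VTU file {path} contains no tetrahedra")
    return piece, pts, tets.reshape(-1, 4), tris.reshape(-1, 3), types


def _read_vtu_mesh(path: Path) -> VolumeMesh:
    piece, pts, tets, tris, types = _read_vtu(path)
    labels_all = _parse_da(piece, "patch_label", int)
    labels = labels_all[types == 5]
    return _finish_mesh(pts, tets, tris, labels)


def read_solution_fields(path):
    """Read back the nodal fields of a solution VTU: (velocity, pressure)."""
    piece, *_ = _read_vtu(Path(path))
    u = _parse_da(piece, "velocity_m_per_s").reshape(-1, 3)
    p = _parse_da(piece, "pressure_Pa")
    return u, p


def _finish_mesh(coords, tets, tris, labels) -> VolumeMesh:
    from .geometry import PATCH_NAMES, _edge_length_stats
    return VolumeMesh(
        nodes=np.asarray(coords, dtype=float),
        tets=np.asarray(tets, dtype=int),
        boundary_tris=np.asarray(tris, dtype=int),
        boundary_labels=np.asarray(labels, dtype=int),
        characteristic_edge_length=_edge_length_stats(
            np.asarray(coords, dtype=float), np.asarray(tets, dtype=int)),
        patch_names=dict(PATCH_NAMES),
    )


# ---------------------------------------------------------------------------
# Tables, reports, configs
# ---------------------------------------------------------------------------

def write_viscosity_csv(samples, path) -> None:
    pd.DataFrame({
        "shear_rate_per_s": [s.shear_rate for s in samples],
        "viscosity_Pa_s": [s.viscosity for s in samples],
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_viscosity_csv(path):
    try:
        df = pd.read_csv(path)
        return [ViscositySample(float(g), float(m))
                for g, m in zip(df["shear_rate_per_s"], df["viscosity_Pa_s"])]
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed viscosity table {path}: {exc}") from exc


def write_report(report, json_path, csv_path=None) -> None:
    """ComparisonReport as JSON plus a flat CSV of per-patch mean WSS."""
    json_path = Path(json_path)
    json_path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    rows = []
    for label, scen in report.scenarios.items():
        for patch, stats in scen.get("patch_wss_cgs", {}).items():
            rows.append({"scenario": label, "patch": patch,
                         "mean_wss_cgs": stats["mean"],
                         "max_wss_cgs": stats["max"],
                         "mean_wss_Pa": stats["mean"] / 10.0})
        rows.append({"scenario": label, "patch": "LCA_ostium",
                     "mean_wss_cgs": scen.get("ostial_wss_cgs"),
                     "max_wss_cgs": None,
                     "mean_wss_Pa": (scen.get("ostial_wss_cgs") or 0.0) / 10.0})
    csv_path = Path(csv_path) if csv_path else json_path.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def load_config_file(path) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return data


def save_config_file(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
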