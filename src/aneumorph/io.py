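"""Readers and writers for the pipeline's on-disk formats.

Meshes: STL and PLY (via trimesh) and legacy ASCII VTK polydata (native
parser).  Vertex labels travel either as a VTK point-data scalar or as a
sidecar CSV (``vertex_id,label``, 0-based).  The ostium is a small JSON
document (ordered vertex indices plus an optional plane override).  Field
series are a JSON manifest pointing at per-timestep CSVs.  All CSVs are
UTF-8, comma-separated, with a header row; coordinates mm, traction Pa,
pressure reported kPa, stress kPa.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .fields import SurfaceFieldSeries
from .mesh import MeshError, OstiumDefinition, TriSurfaceMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_labels",
    "write_labels",
    "read_ostium",
    "write_ostium",
    "read_field_series",
    "write_field_series",
    "read_cohort",
    "write_report",
]

_FIELD_COLUMNS = ["vertex_id", "tx", "ty", "tz", "p", "d",
                  "sxx", "syy", "szz", "sxy", "syz", "szx"]


class ParseError(ValueError):
    """Malformed input file."""


def read_mesh(
    path: str | Path,
    scale: float = 1.0,
    labels: str | Path | np.ndarray | None = None,
) -> TriSurfaceMesh:
    """Read an STL/PLY/VTK surface, applying a unit ``scale`` factor to mm.

    ``labels`` may be a sidecar CSV path or an array; VTK files may carry
    labels as a point-data scalar which is used when no sidecar is given.
    """
    path = Path(path)
    if scale <= 0:
        raise ValueError("scale factor must be positive")
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    vtk_labels = None
    if suffix in (".stl", ".ply"):
        m = trimesh.load(str(path), force="mesh", process=False)
        verts = np.asarray(m.vertices, dtype=np.float64)
        faces = np.asarray(m.faces, dtype=np.int64)
        if suffix == ".stl":
            # STL stores triangle soup; merge duplicated vertices
            m.merge_vertices()
            verts = np.asarray(m.vertices, dtype=np.float64)
            faces = np.asarray(m.faces, dtype=np.int64)
    elif suffix == ".vtk":
        verts, faces, vtk_labels = _parse_vtk(path)
    else:
        raise ParseError(f"unsupported mesh extension {suffix!r} (use .stl/.ply/.vtk)")
    lab = None
    if labels is not None:
        lab = read_labels(labels) if isinstance(labels, (str, Path)) else np.asarray(labels)
    elif vtk_labels is not None:
        lab = vtk_labels
    return TriSurfaceMesh(verts * scale, faces, lab)


def _parse_vtk(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("# vtk DataFile"):
        raise ParseError(f"{path}:1: not a VTK legacy file")
    if len(text) < 4 or text[2].strip().upper() != "ASCII":
        raise ParseError(f"{path}:3: only ASCII VTK files are supported")
    if text[3].strip().upper() != "DATASET POLYDATA":
        raise ParseError(f"{path}:4: expected DATASET POLYDATA")
    # flatten remaining tokens, remembering approximate line numbers
    toks: list[str] = []
    lineno: list[int] = []
    for i, ln in enumerate(text[4:], start=5):
        for t in ln.split():
            toks.append(t)
            lineno.append(i)
    pos = 0

    def take(n: int, what: str) -> list[str]:
        nonlocal pos
        if pos + n > len(toks):
            ln = lineno[pos - 1] if pos else 5
            raise ParseError(f"{path}:{ln}: truncated {what} block")
        out = toks[pos:pos + n]
        pos += n
        return out

    verts = faces = labels = None
    npoints = 0
    while pos < len(toks):
        kw = toks[pos].upper()
        if kw == "POINTS":
            _, n, _dtype = take(3, "POINTS header")
            npoints = int(n)
            data = take(3 * npoints, "POINTS")
            verts = np.array(data, dtype=np.float64).reshape(npoints, 3)
        elif kw == "POLYGONS":
            _, ncells, ntot = take(3, "POLYGONS header")
            data = take(int(ntot), "POLYGONS")
            faces_list, j = [], 0
            for _ in range(int(ncells)):
                k = int(data[j])
                if k != 3:
                    raise ParseError(f"{path}: polygon with {k} vertices; only triangles supported")
                faces_list.append([int(x) for x in data[j + 1:j + 4]])
                j += k + 1
            faces = np.array(faces_list, dtype=np.int64)
        elif kw == "POINT_DATA":
            take(2, "POINT_DATA header")
        elif kw == "SCALARS":
            _, _name, _dtype = take(3, "SCALARS header")[:3]
            if pos < len(toks) and not toks[pos].upper().startswith("LOOKUP"):
                take(1, "SCALARS components")  # optional component count
            take(2, "LOOKUP_TABLE")
            labels = np.array(take(npoints, "SCALARS data"), dtype=float).astype(np.int64)
        else:
            ln = lineno[pos]
            raise ParseError(f"{path}:{ln}: unexpected token {toks[pos]!r}")
    if verts is None or faces is None:
        raise ParseError(f"{path}: missing POINTS or POLYGONS section")
    return verts, faces, labels


def write_mesh(mesh: TriSurfaceMesh, path: str | Path) -> Path:
    """Write STL/PLY (via trimesh) or ASCII VTK polydata with labels."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".stl", ".ply"):
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(str(path))
    elif suffix == ".vtk":
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\naneumorph surface\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {mesh.n_vertices} float\n")
            np.savetxt(fh, mesh.vertices, fmt="%.9g")
            fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
            np.savetxt(fh, np.column_stack(
                [np.full(mesh.n_faces, 3), mesh.faces]), fmt="%d")
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            fh.write("SCALARS label int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, mesh.vertex_labels, fmt="%d")
    else:
        raise ParseError(f"unsupported mesh extension {suffix!r}")
    return path


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"vertex_id", "label"} <= set(df.columns):
        raise ParseError(f"{path}: label CSV needs columns vertex_id,label")
    out = np.zeros(int(df["vertex_id"].max()) + 1, dtype=np.int64)
    out[df["vertex_id"].to_numpy()] = df["label"].to_numpy()
    return out


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"vertex_id": np.arange(len(labels)), "label": labels}).to_csv(
        path, index=False)
    return path


def read_ostium(path: str | Path, mesh: TriSurfaceMesh) -> OstiumDefinition:
    """Ostium JSON: ``{"boundary_loop": [...], "plane_point"?, "plane_unit_normal"?}``."""
    with open(path) as fh:
        doc = json.load(fh)
    loop = np.asarray(doc["boundary_loop"], dtype=np.int64)
    if "plane_point" in doc and "plane_unit_normal" in doc:
        return OstiumDefinition(loop, np.asarray(doc["plane_point"], dtype=float),
                                np.asarray(doc["plane_unit_normal"], dtype=float))
    return OstiumDefinition.from_loop(mesh, loop)


def write_ostium(ostium: OstiumDefinition, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "boundary_loop": ostium.boundary_loop.tolist(),
                "plane_point": ostium.plane_point.tolist(),
                "plane_unit_normal": ostium.plane_unit_normal.tolist(),
            },
            fh, indent=2,
        )
    return path


def write_field_series(series: SurfaceFieldSeries, out_dir: str | Path,
                       mesh_path: str | None = None) -> Path:
    """Write per-timestep CSVs plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    steps = []
    n = series.n_vertices
    for i, _t in enumerate(series.times):
        name = f"step_{i:04d}.csv"
        df = pd.DataFrame(
            np.column_stack([
                np.arange(n), series.traction[i], series.pressure[i],
                series.displacement[i], series.stress[i],
            ]),
            columns=_FIELD_COLUMNS,
        )
        df["vertex_id"] = df["vertex_id"].astype(int)
        df.to_csv(out_dir / name, index=False)
        steps.append(name)
    manifest = {"times": series.times.tolist(), "steps": steps}
    if mesh_path:
        manifest["mesh"] = mesh_path
    mpath = out_dir / "fields_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


def read_field_series(manifest_path: str | Path) -> SurfaceFieldSeries:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = json.load(fh)
    times = np.asarray(doc["times"], dtype=np.float64)
    base = manifest_path.parent
    tr, pr, di, st = [], [], [], []
    for name in doc["steps"]:
        df = pd.read_csv(base / name)
        missing = [c for c in _FIELD_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{base / name}: missing columns {missing}")
        df = df.sort_values("vertex_id")
        tr.append(df[["tx", "ty", "tz"]].to_numpy())
        pr.append(df["p"].to_numpy())
        di.append(df["d"].to_numpy())
        st.append(df[["sxx", "syy", "szz", "sxy", "syz", "szx"]].to_numpy())
    series = SurfaceFieldSeries(times, np.array(tr), np.array(pr),
                                np.array(di), np.array(st))
    series.validate()
    return series


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ParseError(f"{path}: cohort CSV needs an 'id' column")
    return df


def write_report(report, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a workflow report as JSON + Markdown; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jpath = out_dir / "report.json"
    mpath = out_dir / "report.md"
    jpath.write_text(report.to_json())
    mpath.write_text(report.to_markdown())
    return jpath, mpath
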