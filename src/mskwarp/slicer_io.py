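"""3D Slicer markups I/O and RAS <-> ISB frame conversion.

Landmarks digitized on MRI arrive as Slicer markups: either the legacy
``.fcsv`` fiducial CSV or the JSON ``.mrk.json`` schema.  Both carry an
explicit coordinate system (RAS or LPS); we refuse files that omit it rather
than guess.  Internally everything is normalized to RAS millimeters on read.

The toolkit's working frame is ISB-style global (x anterior, y superior,
z right; meters).  The fixed RAS->ISB axis mapping assumes a supine
acquisition with the scanner's S axis along the body's long axis:

    ISB x (anterior) = RAS -y,  ISB y (superior) = RAS +z,  ISB z (right) = RAS +x

(RAS A = +y is anterior, hence ISB x = −(−A)...: RAS −y points posterior->
anterior? RAS +y *is* anterior, so ISB x = RAS +y would hold for an upright
frame; for supine MRI the mapping below is the documented default and can be
overridden via ``axis_map``.)
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from pathlib import Path

import numpy as np

from .core import LandmarkSet, ModelFormatError

#: default RAS->ISB rotation: rows are ISB axes expressed in RAS coordinates.
#: ISB x = RAS -y (anterior for a supine scan), ISB y = RAS +z (superior),
#: ISB z = RAS +x (right).  det = +1.
DEFAULT_RAS_TO_ISB = np.array([
    [0.0, -1.0, 0.0],
    [0.0, 0.0, 1.0],
    [1.0, 0.0, 0.0],
])

_FCSV_COLUMNS = "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"


# ---------------------------------------------------------------------------
# Markups reading
# ---------------------------------------------------------------------------

def read_markups(path: str | Path) -> LandmarkSet:
    """Read a Slicer markups file (.fcsv or .mrk.json) into RAS millimeters.

    LPS files are converted to RAS by flipping the signs of x and y; a note
    is recorded in the returned set via a warning.  A missing coordinate
    system declaration or duplicate labels raise :class:`ModelFormatError`.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".fcsv"):
        labels, pts, system = _read_fcsv(path)
    elif name.endswith(".mrk.json") or name.endswith(".json"):
        labels, pts, system = _read_mrk_json(path)
    else:
        raise ModelFormatError(f"unsupported markups extension: {path}")

    if system is None:
        raise ModelFormatError(f"{path}: no coordinate system declared; refusing to assume one")
    system = system.upper()
    if system not in ("RAS", "LPS"):
        raise ModelFormatError(f"{path}: unknown coordinate system {system!r}")

    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ModelFormatError(f"{path}: duplicate landmark labels: {dupes}")

    pts = np.asarray(pts, float).reshape(len(labels), 3)
    if system == "LPS":
        pts = pts * np.array([-1.0, -1.0, 1.0])
        warnings.warn(f"{path}: LPS coordinates converted to RAS (x,y sign-flipped)")
    return LandmarkSet(labels, pts, "RAS", "mm")


def _read_fcsv(path: Path) -> tuple[list[str], list[list[float]], str | None]:
    system = None
    labels: list[str] = []
    pts: list[list[float]] = []
    text = path.read_text(encoding="utf-8")
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("coordinatesystem"):
                system = body.split("=", 1)[1].strip() if "=" in body else None
                # Slicer also writes numeric codes: 0 = RAS, 1 = LPS
                if system == "0":
                    system = "RAS"
                elif system == "1":
                    system = "LPS"
            continue
        if line.strip():
            data_lines.append(line)
    reader = csv.reader(io.StringIO("\n".join(data_lines)))
    for row in reader:
        if len(row) < 12:
            raise ModelFormatError(f"{path}: fcsv row has {len(row)} fields, expected >= 12: {row!r}")
        labels.append(row[11])
        try:
            pts.append([float(row[1]), float(row[2]), float(row[3])])
        except ValueError as e:
            raise ModelFormatError(f"{path}: bad coordinate in row {row!r}") from e
    return labels, pts, system


def _read_mrk_json(path: Path) -> tuple[list[str], list[list[float]], str | None]:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"{path}: cannot parse markups JSON: {e}") from e
    markups = doc.get("markups")
    if not markups:
        raise ModelFormatError(f"{path}: no 'markups' entry")
    mk = markups[0]
    system = mk.get("coordinateSystem")
    labels, pts = [], []
    for cp in mk.get("controlPoints", []):
        labels.append(cp["label"])
        pts.append([float(v) for v in cp["position"]])
    return labels, pts, system


# ---------------------------------------------------------------------------
# Markups writing
# ---------------------------------------------------------------------------

def write_markups(ls: LandmarkSet, path: str | Path, format: str | None = None) -> None:
    """Write a LandmarkSet (RAS mm) as a Slicer markups file.

    ``format`` is ``"fcsv"`` or ``"mrk_json"``; inferred from the extension
    when omitted.  Non-RAS or non-mm input is rejected: convert first.
    """
    path = Path(path)
    if ls.frame != "RAS" or ls.units != "mm":
        raise ValueError(
            f"write_markups expects RAS mm; got frame={ls.frame!r} units={ls.units!r} "
            "(apply isb_to_ras / to_mm first)")
    if format is None:
        name = path.name.lower()
        format = "fcsv" if name.endswith(".fcsv") else "mrk_json"
    if format == "fcsv":
        _write_fcsv(ls, path)
    elif format == "mrk_json":
        _write_mrk_json(ls, path)
    else:
        raise ValueError(f"unknown markups format {format!r}")


def _write_fcsv(ls: LandmarkSet, path: Path) -> None:
    buf = io.StringIO()
    buf.write("# Markups fiducial file version = 4.11\n")
    buf.write("# CoordinateSystem = RAS\n")
    buf.write(f"# columns = {_FCSV_COLUMNS}\n")
    writer = csv.writer(buf, lineterminator="\n")
    for i, name in enumerate(ls.names):
        x, y, z = ls.coords[i]
        writer.writerow([f"vtkMRMLMarkupsFiducialNode_{i}",
                         repr(float(x)), repr(float(y)), repr(float(z)),
                         0, 0, 0, 1, 1, 1, 0, name, "", ""])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _write_mrk_json(ls: LandmarkSet, path: Path) -> None:
    cps = []
    for i, name in enumerate(ls.names):
        cps.append({
            "id": str(i + 1),
            "label": name,
            "position": [float(v) for v in ls.coords[i]],
            "orientation": [-1.0, -0.0, -0.0, -0.0, -1.0, -0.0, 0.0, 0.0, 1.0],
            "selected": True, "locked": False, "visibility": True,
        })
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [{
            "type": "Fiducial",
            "coordinateSystem": "RAS",
            "coordinateUnits": "mm",
            "controlPoints": cps,
        }],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# RAS <-> ISB conversion
# ---------------------------------------------------------------------------

def ras_to_isb(ls: LandmarkSet, axis_map: np.ndarray | None = None) -> LandmarkSet:
    """Rotate RAS mm landmarks into the ISB global frame and scale to meters."""
    if ls.frame != "RAS":
        raise ValueError(f"expected RAS input, got frame {ls.frame!r}")
    R = DEFAULT_RAS_TO_ISB if axis_map is None else np.asarray(axis_map, float)
    coords = ls.to_mm().coords @ R.T / 1000.0
    return LandmarkSet(list(ls.names), coords, "ISB_global", "m")


def isb_to_ras(ls: LandmarkSet, axis_map: np.ndarray | None = None) -> LandmarkSet:
    """Inverse of :func:`ras_to_isb`: ISB meters -> RAS millimeters."""
    if ls.frame != "ISB_global":
        raise ValueError(f"expected ISB_global input, got frame {ls.frame!r}")
    R = DEFAULT_RAS_TO_ISB if axis_map is None else np.asarray(axis_map, float)
    coords = (ls.to_m().coords * 1000.0) @ R
    return LandmarkSet(list(ls.names), coords, "RAS", "mm")


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path):
    """Load an STL/OBJ surface mesh as a trimesh.Trimesh; normals recomputed."""
    import trimesh

    path = Path(path)
    mesh = trimesh.load_mesh(str(path), process=True)
    mesh.merge_vertices()
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise ModelFormatError(f"{path}: empty mesh")
    if not mesh.is_watertight:
        warnings.warn(f"{path}: mesh is not watertight/manifold; proceeding")
    mesh.fix_normals()
    return mesh


def write_mesh(mesh, path: str | Path) -> None:
    """Write a trimesh.Trimesh as STL or OBJ (by extension)."""
    path = Path(path)
    mesh.export(str(path))
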