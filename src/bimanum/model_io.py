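"""Readers and writers for the file dialects the toolkit touches.

* ``.osim`` — the OpenSim 3.3 XML model dialect. Only the elements the
  pipeline transforms are parsed into :class:`~bimanum.model.ModelDef`
  (Body, CustomJoint/WeldJoint, Coordinate, muscle actuators with path
  points, WeldConstraint); every other element is preserved as an opaque
  XML blob and written back verbatim, so files survive a round trip.
* ``.mot`` / ``.sto`` — tabular motion/storage files with the
  ``nRows``/``nColumns``/``inDegrees``/``endheader`` header discipline.
* ``.trc`` — marker trajectories (read-only).
* ``.vtp`` (XML PolyData, ASCII) and ``.stl`` — triangle display meshes.
"""
from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
from lxml import etree

from .model import (
    BodyDef,
    ConstraintDef,
    CoordinateDef,
    JointDef,
    Mesh,
    MeshRef,
    ModelDef,
    ModelValidationError,
    MotionTable,
    MuscleDef,
    PathPoint,
    TransformAxis,
)

_JOINT_CLASSES = ("CustomJoint", "WeldJoint", "PinJoint")
_MUSCLE_TAG_HINTS = ("Muscle", "muscle")


class FileFormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# .osim models
# --------------------------------------------------------------------------

def _fmt_vec(v) -> str:
    return " ".join(format(float(x), ".12g") for x in np.asarray(v, float).ravel())


def _parse_vec(text: str | None, n: int) -> np.ndarray:
    if text is None:
        return np.zeros(n)
    parts = text.split()
    if len(parts) != n:
        raise FileFormatError(f"expected {n} numbers, got {text!r}")
    return np.array([float(p) for p in parts])


def _child_text(el, tag: str, default: str | None = None) -> str | None:
    c = el.find(tag)
    if c is None or c.text is None:
        return default
    return c.text.strip()


def _bool(text: str | None, default: bool = False) -> bool:
    if text is None:
        return default
    return text.strip().lower() in ("true", "1", "yes")


def _parse_coordinate(el) -> CoordinateDef:
    rng = _child_text(el, "range", "-3.141592653589793 3.141592653589793")
    lo, hi = (float(x) for x in rng.split())
    return CoordinateDef(
        name=el.get("name", "coord"),
        kind=_child_text(el, "motion_type", "rotational"),
        range=(lo, hi),
        default=float(_child_text(el, "default_value", "0")),
        locked=_bool(_child_text(el, "locked")),
    )


def _parse_spatial_transform(el) -> list[TransformAxis]:
    axes: list[TransformAxis] = []
    for ax_el in el.findall("TransformAxis"):
        name = ax_el.get("name", "")
        kind = "rotation" if name.startswith("rotation") else "translation"
        coord_text = _child_text(ax_el, "coordinates", "") or ""
        coord = coord_text.split()[0] if coord_text.split() else None
        axes.append(
            TransformAxis(
                name=name,
                kind=kind,
                axis=_parse_vec(_child_text(ax_el, "axis", "0 0 1"), 3),
                coordinate=coord,
            )
        )
    return axes


def _parse_joint(joint_container, child_body: str) -> JointDef | None:
    for jel in joint_container:
        if not isinstance(jel.tag, str) or jel.tag not in _JOINT_CLASSES:
            continue
        coords: list[CoordinateDef] = []
        cs = jel.find("CoordinateSet/objects")
        if cs is not None:
            coords = [_parse_coordinate(c) for c in cs.findall("Coordinate")]
        st = jel.find("SpatialTransform")
        axes = _parse_spatial_transform(st) if st is not None else []
        return JointDef(
            name=jel.get("name", f"{child_body}_joint"),
            joint_class=jel.tag,
            parent=_child_text(jel, "parent_body", "ground"),
            child=child_body,
            location_in_parent=_parse_vec(_child_text(jel, "location_in_parent", "0 0 0"), 3),
            orientation_in_parent=_parse_vec(_child_text(jel, "orientation_in_parent", "0 0 0"), 3),
            location_in_child=_parse_vec(_child_text(jel, "location", "0 0 0"), 3),
            orientation_in_child=_parse_vec(_child_text(jel, "orientation", "0 0 0"), 3),
            coordinates=coords,
            spatial_transform=axes,
        )
    return None


_BODY_KNOWN = {
    "mass", "mass_center", "inertia_xx", "inertia_yy", "inertia_zz",
    "inertia_xy", "inertia_xz", "inertia_yz", "Joint", "VisibleObject",
}


def _parse_body(el) -> tuple[BodyDef, JointDef | None]:
    name = el.get("name", "body")
    inertia = [
        float(_child_text(el, f"inertia_{k}", "0"))
        for k in ("xx", "yy", "zz", "xy", "xz", "yz")
    ]
    mesh_refs: list[MeshRef] = []
    vis = el.find("VisibleObject")
    if vis is not None:
        for dg in vis.findall(".//DisplayGeometry"):
            f = _child_text(dg, "geometry_file")
            if f:
                mesh_refs.append(
                    MeshRef(file=f, scale=_parse_vec(_child_text(dg, "scale_factors", "1 1 1"), 3))
                )
    extra = [c for c in el if isinstance(c.tag, str) and c.tag not in _BODY_KNOWN]
    body = BodyDef(
        name=name,
        mass=float(_child_text(el, "mass", "0")),
        com=_parse_vec(_child_text(el, "mass_center", "0 0 0"), 3),
        inertia=inertia,
        mesh_refs=mesh_refs,
        extra_xml=extra,
    )
    jc = el.find("Joint")
    joint = _parse_joint(jc, name) if jc is not None else None
    return body, joint


def _parse_muscle(el) -> MuscleDef:
    pts: list[PathPoint] = []
    for p in el.findall(".//PathPoint"):
        pts.append(
            PathPoint(
                body=_child_text(p, "body", "ground"),
                location=_parse_vec(_child_text(p, "location", "0 0 0"), 3),
            )
        )
    known = {"GeometryPath", "max_isometric_force", "optimal_fiber_length", "tendon_slack_length"}
    extra = [c for c in el if isinstance(c.tag, str) and c.tag not in known]
    return MuscleDef(
        name=el.get("name", "muscle"),
        max_isometric_force=float(_child_text(el, "max_isometric_force", "0")),
        path=pts,
        optimal_fiber_length=float(_child_text(el, "optimal_fiber_length", "0.1")),
        tendon_slack_length=float(_child_text(el, "tendon_slack_length", "0.05")),
        class_name=el.tag,
        extra_xml=extra,
    )


def _parse_constraint(el) -> ConstraintDef:
    return ConstraintDef(
        name=el.get("name", "constraint"),
        body_1=_child_text(el, "body_1", "ground"),
        body_2=_child_text(el, "body_2", "ground"),
        location_body_1=_parse_vec(_child_text(el, "location_body_1", "0 0 0"), 3),
        orientation_body_1=_parse_vec(_child_text(el, "orientation_body_1", "0 0 0"), 3),
        location_body_2=_parse_vec(_child_text(el, "location_body_2", "0 0 0"), 3),
        orientation_body_2=_parse_vec(_child_text(el, "orientation_body_2", "0 0 0"), 3),
    )


def read_model(path: str | os.PathLike) -> ModelDef:
    """Read an OpenSim 3.3 ``.osim`` file into a :class:`ModelDef`.

    Raises :class:`FileFormatError` for malformed XML (with the line number
    from the parser) and :class:`ModelValidationError` for dangling
    cross-references.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise FileFormatError(f"malformed XML in {path}: {e}") from e
    root = tree.getroot()
    model_el = root.find("Model") if root.tag == "OpenSimDocument" else root
    if model_el is None or model_el.tag != "Model":
        raise FileFormatError(f"{path}: no <Model> element found")

    model = ModelDef(name=model_el.get("name", "model"))
    model.gravity = _parse_vec(_child_text(model_el, "gravity", "0 -9.80665 0"), 3)

    handled = {"gravity", "BodySet", "ForceSet", "ConstraintSet"}
    model.extra_xml = [c for c in model_el
                       if isinstance(c.tag, str) and c.tag not in handled]

    body_objs = model_el.find("BodySet/objects")
    if body_objs is not None:
        for bel in body_objs.findall("Body"):
            body, joint = _parse_body(bel)
            if body.name == "ground":
                continue
            model.bodies.append(body)
            if joint is not None:
                model.joints.append(joint)

    force_objs = model_el.find("ForceSet/objects")
    if force_objs is not None:
        for fel in force_objs:
            if isinstance(fel.tag, str) and any(h in fel.tag for h in _MUSCLE_TAG_HINTS):
                model.muscles.append(_parse_muscle(fel))
            elif isinstance(fel.tag, str):
                model.extra_xml.append(fel)

    con_objs = model_el.find("ConstraintSet/objects")
    if con_objs is not None:
        for cel in con_objs.findall("WeldConstraint"):
            model.constraints.append(_parse_constraint(cel))

    model.validate()
    return model


def _sub(parent, tag: str, text: str | None = None, **attrib):
    el = etree.SubElement(parent, tag, attrib)
    if text is not None:
        el.text = text
    return el


def _coordinate_xml(parent, c: CoordinateDef) -> None:
    el = _sub(parent, "Coordinate", name=c.name)
    _sub(el, "motion_type", c.kind)
    _sub(el, "default_value", format(c.default, ".12g"))
    _sub(el, "range", _fmt_vec(c.range))
    _sub(el, "locked", "true" if c.locked else "false")


def _joint_xml(parent, j: JointDef) -> None:
    holder = _sub(parent, "Joint")
    jel = _sub(holder, j.joint_class, name=j.name)
    _sub(jel, "parent_body", j.parent)
    _sub(jel, "location_in_parent", _fmt_vec(j.location_in_parent))
    _sub(jel, "orientation_in_parent", _fmt_vec(j.orientation_in_parent))
    _sub(jel, "location", _fmt_vec(j.location_in_child))
    _sub(jel, "orientation", _fmt_vec(j.orientation_in_child))
    if j.coordinates:
        objs = _sub(_sub(jel, "CoordinateSet"), "objects")
        for c in j.coordinates:
            _coordinate_xml(objs, c)
    if j.spatial_transform:
        st = _sub(jel, "SpatialTransform")
        for ax in j.spatial_transform:
            ax_el = _sub(st, "TransformAxis", name=ax.name)
            _sub(ax_el, "coordinates", ax.coordinate or "")
            _sub(ax_el, "axis", _fmt_vec(ax.axis))


def write_model(model: ModelDef, path: str | os.PathLike) -> None:
    """Write a :class:`ModelDef` as OpenSim 3.3 XML; refuses invalid models."""
    model.validate()
    root = etree.Element("OpenSimDocument", Version="30000")
    mel = _sub(root, "Model", name=model.name)
    _sub(mel, "gravity", _fmt_vec(model.gravity))

    body_objs = _sub(_sub(mel, "BodySet"), "objects")
    joints_by_child = {j.child: j for j in model.joints}
    for b in model.bodies:
        bel = _sub(body_objs, "Body", name=b.name)
        _sub(bel, "mass", format(b.mass, ".12g"))
        _sub(bel, "mass_center", _fmt_vec(b.com))
        for k, v in zip(("xx", "yy", "zz", "xy", "xz", "yz"), b.inertia):
            _sub(bel, f"inertia_{k}", format(float(v), ".12g"))
        j = joints_by_child.get(b.name)
        if j is not None:
            _joint_xml(bel, j)
        if b.mesh_refs:
            vis = _sub(bel, "VisibleObject", name=b.name)
            objs = _sub(_sub(vis, "GeometrySet"), "objects")
            for mref in b.mesh_refs:
                dg = _sub(objs, "DisplayGeometry")
                _sub(dg, "geometry_file", mref.file)
                _sub(dg, "scale_factors", _fmt_vec(mref.scale))
        for blob in b.extra_xml:
            bel.append(blob)

    force_objs = _sub(_sub(mel, "ForceSet"), "objects")
    for m in model.muscles:
        mel2 = _sub(force_objs, m.class_name, name=m.name)
        gp = _sub(mel2, "GeometryPath", name="path")
        pts = _sub(_sub(gp, "PathPointSet"), "objects")
        for i, p in enumerate(m.path, 1):
            pel = _sub(pts, "PathPoint", name=f"{m.name}-P{i}")
            _sub(pel, "location", _fmt_vec(p.location))
            _sub(pel, "body", p.body)
        _sub(mel2, "max_isometric_force", format(m.max_isometric_force, ".12g"))
        _sub(mel2, "optimal_fiber_length", format(m.optimal_fiber_length, ".12g"))
        _sub(mel2, "tendon_slack_length", format(m.tendon_slack_length, ".12g"))
        for blob in m.extra_xml:
            mel2.append(blob)

    if model.constraints:
        con_objs = _sub(_sub(mel, "ConstraintSet"), "objects")
        for c in model.constraints:
            cel = _sub(con_objs, "WeldConstraint", name=c.name)
            _sub(cel, "body_1", c.body_1)
            _sub(cel, "body_2", c.body_2)
            _sub(cel, "location_body_1", _fmt_vec(c.location_body_1))
            _sub(cel, "orientation_body_1", _fmt_vec(c.orientation_body_1))
            _sub(cel, "location_body_2", _fmt_vec(c.location_body_2))
            _sub(cel, "orientation_body_2", _fmt_vec(c.orientation_body_2))

    for blob in model.extra_xml:
        mel.append(blob)

    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# --------------------------------------------------------------------------
# .mot / .sto motion tables
# --------------------------------------------------------------------------

def read_motion(path: str | os.PathLike) -> MotionTable:
    """Read a ``.mot``/``.sto`` file (``endheader`` dialect)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    name = Path(path).stem
    in_degrees = False
    n_rows = n_cols = None
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        low = s.lower()
        if low.startswith("indegrees"):
            in_degrees = low.split("=", 1)[1].strip() == "yes"
        elif low.startswith("nrows"):
            n_rows = int(s.split("=")[-1])
        elif low.startswith("ncolumns"):
            n_cols = int(s.split("=")[-1])
        elif low == "endheader":
            break
    else:
        raise FileFormatError(f"{path}: no 'endheader' line")
    header = lines[i + 1].split()
    if not header or header[0].lower() != "time":
        raise FileFormatError(f"{path}: first data column must be 'time'")
    data_lines = [ln for ln in lines[i + 2:] if ln.strip()]
    data = np.array([[float(x) for x in ln.split()] for ln in data_lines]) if data_lines else \
        np.empty((0, len(header)))
    if n_cols is not None and data.size and data.shape[1] != n_cols:
        raise FileFormatError(f"{path}: header declares {n_cols} columns, data has {data.shape[1]}")
    if n_rows is not None and data.shape[0] != n_rows:
        raise FileFormatError(f"{path}: header declares {n_rows} rows, data has {data.shape[0]}")
    if data.size and data.shape[1] != len(header):
        raise FileFormatError(f"{path}: column label/data width mismatch")
    try:
        return MotionTable(
            time=data[:, 0] if data.size else np.empty(0),
            column_names=header[1:],
            values=data[:, 1:] if data.size else np.empty((0, len(header) - 1)),
            in_degrees=in_degrees,
            name=name,
        )
    except ValueError as e:
        raise FileFormatError(f"{path}: {e}") from e


def write_motion(table: MotionTable, path: str | os.PathLike) -> None:
    table.validate()
    with open(path, "w") as fh:
        fh.write(f"{table.name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={table.n_rows}\n")
        fh.write(f"nColumns={len(table.column_names) + 1}\n")
        fh.write(f"inDegrees={'yes' if table.in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(table.column_names) + "\n")
        for t, row in zip(table.time, table.values):
            fh.write("\t".join(format(v, ".6g") for v in (t, *row)) + "\n")


def read_trc(path: str | os.PathLike) -> MotionTable:
    """Read a ``.trc`` marker file into a table with ``<marker>_<axis>`` columns."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise FileFormatError(f"{path}: truncated .trc file")
    marker_row = lines[3].split("\t")
    markers = [m.strip() for m in marker_row[2:] if m.strip()]
    columns = [f"{m}_{ax}" for m in markers for ax in ("x", "y", "z")]
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    rows, times = [], []
    for ln in data_lines:
        parts = ln.split()
        times.append(float(parts[1]))
        vals = [float(x) for x in parts[2:2 + 3 * len(markers)]]
        if len(vals) != 3 * len(markers):
            raise FileFormatError(f"{path}: row with {len(vals)} values, expected {3 * len(markers)}")
        rows.append(vals)
    return MotionTable(
        time=np.array(times), column_names=columns, values=np.array(rows),
        in_degrees=False, name=Path(path).stem,
    )


# --------------------------------------------------------------------------
# Meshes (VTP ASCII PolyData + STL via trimesh)
# --------------------------------------------------------------------------

def read_mesh(path: str | os.PathLike) -> Mesh:
    p = Path(path)
    if p.suffix.lower() == ".vtp":
        return _read_vtp(p)
    if p.suffix.lower() == ".stl":
        import trimesh

        tm = trimesh.load_mesh(str(p), file_type="stl")
        return Mesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    raise FileFormatError(f"unsupported mesh format: {p.suffix}")


def write_mesh(mesh: Mesh, path: str | os.PathLike) -> None:
    p = Path(path)
    if p.suffix.lower() == ".vtp":
        _write_vtp(mesh, p)
    elif p.suffix.lower() == ".stl":
        import trimesh

        trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False).export(
            str(p), file_type="stl_ascii"
        )
    else:
        raise FileFormatError(f"unsupported mesh format: {p.suffix}")


def _read_vtp(path: Path) -> Mesh:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise FileFormatError(f"malformed VTP XML in {path}: {e}") from e
    piece = tree.find(".//Piece")
    if piece is None:
        raise FileFormatError(f"{path}: no <Piece> element")
    pts_el = piece.find("Points/DataArray")
    verts = np.array([float(x) for x in (pts_el.text or "").split()]).reshape(-1, 3)
    conn_el = piece.find("Polys/DataArray[@Name='connectivity']")
    offs_el = piece.find("Polys/DataArray[@Name='offsets']")
    conn = np.array([int(x) for x in (conn_el.text or "").split()])
    offs = np.array([int(x) for x in (offs_el.text or "").split()])
    counts = np.diff(np.concatenate([[0], offs]))
    if np.any(counts != 3):
        raise FileFormatError(f"{path}: non-triangular faces present")
    return Mesh(vertices=verts, faces=conn.reshape(-1, 3))


def _write_vtp(mesh: Mesh, path: Path) -> None:
    n_v, n_f = mesh.vertices.shape[0], mesh.faces.shape[0]
    root = etree.Element("VTKFile", type="PolyData", version="0.1")
    pd = etree.SubElement(root, "PolyData")
    piece = etree.SubElement(
        pd, "Piece", NumberOfPoints=str(n_v), NumberOfPolys=str(n_f),
        NumberOfVerts="0", NumberOfLines="0", NumberOfStrips="0",
    )
    pts = etree.SubElement(piece, "Points")
    da = etree.SubElement(pts, "DataArray", type="Float64",
                          NumberOfComponents="3", format="ascii")
    da.text = "\n" + "\n".join(_fmt_vec(v) for v in mesh.vertices) + "\n"
    polys = etree.SubElement(piece, "Polys")
    conn = etree.SubElement(polys, "DataArray", type="Int64",
                            Name="connectivity", format="ascii")
    conn.text = "\n" + "\n".join(" ".join(str(i) for i in f) for f in mesh.faces) + "\n"
    offs = etree.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = "\n" + " ".join(str(3 * (i + 1)) for i in range(n_f)) + "\n"
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")
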