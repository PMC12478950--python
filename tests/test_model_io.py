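"""Round trips and validation for the .osim / .mot / mesh readers."""
import numpy as np
import pytest
from lxml import etree

from bimanum.model import Mesh, ModelValidationError, MotionTable
from bimanum.model_io import (
    FileFormatError,
    read_mesh,
    read_model,
    read_motion,
    read_trc,
    write_mesh,
    write_model,
    write_motion,
)
from bimanum.mirroring import build_bilateral


def test_fixture_model_counts(model):
    assert len(model.bodies) == 3
    assert len(model.free_coordinate_names()) == 4
    assert len(model.muscles) == 14


def test_model_roundtrip_identity(model, tmp_path):
    p = tmp_path / "m.osim"
    write_model(model, p)
    again = read_model(p)
    assert model.equals(again)
    # write -> read -> write -> read is stable
    p2 = tmp_path / "m2.osim"
    write_model(again, p2)
    assert read_model(p2).equals(again)


def test_bilateral_file_lists_28_muscle_elements(bilateral, tmp_path):
    p = tmp_path / "bil.osim"
    write_model(bilateral, p)
    # independent scan of the raw XML text
    tree = etree.parse(str(p))
    names = [el.get("name") for el in tree.findall(".//ForceSet/objects/Thelen2003Muscle")]
    assert len(names) == 28
    assert len([n for n in names if n.endswith("_l")]) == 14


def test_zero_mass_body_roundtrip(model, tmp_path):
    m = model.copy()
    m.bodies[1].mass = 0.0
    p = tmp_path / "z.osim"
    write_model(m, p)
    assert read_model(p).bodies[1].mass == 0.0


def test_dangling_joint_reference_rejected(model, tmp_path):
    m = model.copy()
    m.joints[1].parent = "humerusX"
    with pytest.raises(ModelValidationError, match="humerusX"):
        m.validate()
    with pytest.raises(ModelValidationError):
        write_model(m, tmp_path / "bad.osim")


@pytest.mark.parametrize("mutate", [
    lambda m: setattr(m.joints[2], "child", "nowhere"),
    lambda m: setattr(m.muscles[0].path[0], "body", "nowhere"),
    lambda m: setattr(m.muscles[3].path[1], "body", "nowhere"),
])
def test_each_corrupted_reference_is_caught(model, mutate):
    m = model.copy()
    mutate(m)
    with pytest.raises(ModelValidationError, match="nowhere"):
        m.validate()


def test_malformed_xml_reports_parse_error(tmp_path):
    p = tmp_path / "broken.osim"
    p.write_text("<OpenSimDocument><Model name='x'>")
    with pytest.raises(FileFormatError):
        read_model(p)


def test_opaque_elements_survive_roundtrip(model, tmp_path):
    p = tmp_path / "m.osim"
    write_model(model, p)
    tree = etree.parse(str(p))
    body = tree.find(".//Body[@name='humerus_r']")
    wrap = etree.SubElement(body, "WrapObjectSet")
    etree.SubElement(wrap, "objects").text = "opaque-payload"
    tree.write(str(p))
    m2 = read_model(p)
    assert any(e.tag == "WrapObjectSet" for e in m2.body("humerus_r").extra_xml)
    p2 = tmp_path / "m2.osim"
    write_model(m2, p2)
    assert b"WrapObjectSet" in p2.read_bytes()


# -- motion tables ----------------------------------------------------------

def test_motion_roundtrip(tmp_path):
    t = MotionTable(
        time=[0.0, 0.01, 0.02],
        column_names=["a", "b"],
        values=[[1.0, -2.5], [1.1, -2.4], [1.234567, 80.0]],
        in_degrees=True,
    )
    p = tmp_path / "t.mot"
    write_motion(t, p)
    back = read_motion(p)
    assert back.in_degrees
    assert back.column_names == ["a", "b"]
    np.testing.assert_allclose(back.values, t.values, rtol=1e-5)
    np.testing.assert_allclose(back.time, t.time, rtol=1e-5)


def test_motion_nonincreasing_time_rejected():
    with pytest.raises(ValueError, match="strictly increasing"):
        MotionTable(time=[0.0, 0.0], column_names=["a"], values=[[1.0], [2.0]])


def test_degrees_header_respected(tmp_path):
    p = tmp_path / "deg.mot"
    p.write_text(
        "deg\nnRows=2\nnColumns=2\ninDegrees=yes\nendheader\n"
        "time\tang\n0.0\t80\n0.1\t80\n"
    )
    t = read_motion(p)
    assert t.in_degrees
    np.testing.assert_array_equal(t.column("ang"), [80.0, 80.0])
    np.testing.assert_allclose(t.in_radians().column("ang"), np.deg2rad([80.0, 80.0]))


def test_motion_count_mismatch_rejected(tmp_path):
    p = tmp_path / "bad.mot"
    p.write_text("x\nnRows=3\nnColumns=2\nendheader\ntime\ta\n0.0\t1\n0.1\t2\n")
    with pytest.raises(FileFormatError, match="3 rows"):
        read_motion(p)


def test_trc_reader(tmp_path):
    p = tmp_path / "markers.trc"
    p.write_text(
        "PathFileType\t4\t(X/Y/Z)\tmarkers.trc\n"
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\n"
        "100\t100\t2\t2\tm\n"
        "Frame#\tTime\tACR\t\t\tC7\t\t\n"
        "\t\tX1\tY1\tZ1\tX2\tY2\tZ2\n"
        "1\t0.00\t0.1\t1.4\t0.2\t0.0\t1.5\t0.0\n"
        "2\t0.01\t0.1\t1.4\t0.2\t0.0\t1.5\t0.0\n"
    )
    t = read_trc(p)
    assert t.column_names == ["ACR_x", "ACR_y", "ACR_z", "C7_x", "C7_y", "C7_z"]
    assert t.n_rows == 2
    assert t.column("ACR_y")[0] == 1.4


# -- meshes -----------------------------------------------------------------

TETRA = Mesh(
    vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
    faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
)


@pytest.mark.parametrize("ext", ["vtp", "stl"])
def test_mesh_roundtrip(tmp_path, ext):
    p = tmp_path / f"tet.{ext}"
    write_mesh(TETRA, p)
    back = read_mesh(p)
    assert back.vertices.shape == (4, 3)
    assert back.faces.shape == (4, 3)
    assert np.isclose(abs(back.signed_volume()), abs(TETRA.signed_volume()))


def test_fixture_humerus_mesh_vertices_preserved(meshes, tmp_path):
    p = tmp_path / "humerus.vtp"
    write_mesh(meshes["humerus.vtp"], p)
    back = read_mesh(p)
    assert back.vertices.shape[0] == 8
    np.testing.assert_allclose(back.vertices, meshes["humerus.vtp"].vertices, rtol=1e-9)
    np.testing.assert_array_equal(back.faces, meshes["humerus.vtp"].faces)


def test_empty_mesh_rejected():
    with pytest.raises(ValueError, match="no vertices"):
        Mesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3)))


def test_nontriangular_vtp_rejected(tmp_path):
    p = tmp_path / "quad.vtp"
    p.write_text(
        """<?xml version="1.0"?>
<VTKFile type="PolyData"><PolyData><Piece NumberOfPoints="4" NumberOfPolys="1">
<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">
0 0 0 1 0 0 1 1 0 0 1 0</DataArray></Points>
<Polys><DataArray type="Int64" Name="connectivity" format="ascii">0 1 2 3</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">4</DataArray></Polys>
</Piece></PolyData></VTKFile>"""
    )
    with pytest.raises(FileFormatError, match="non-triangular"):
        read_mesh(p)
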