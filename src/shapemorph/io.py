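"""Readers and writers for ASCII mesh formats: OFF, PLY and legacy VTK polydata.

All three dialects are plain-text.  PLY and VTK carry per-vertex scalar fields
(PLY vertex properties; VTK POINT_DATA SCALARS blocks), which this package uses
for subregion labels and statistical overlays; OFF carries geometry only.

Round-trips preserve face lists exactly and coordinates to full double
precision (values are printed with 17 significant digits).  Parse failures
report the offending line number.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np

from .mesh import MeshValidationError, TriangleMesh

__all__ = ["read_mesh", "write_mesh", "MeshParseError", "FORMATS"]

FORMATS = ("off", "ply", "vtk")


class MeshParseError(ValueError):
    """Malformed mesh file; carries the path and 1-based line number."""

    def __init__(self, path: str, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


class _Tokens:
    """Whitespace token stream over a text file that tracks line numbers."""

    def __init__(self, path: str, keep_comments: bool = False):
        self.path = path
        self.line = 0
        self._buf: list[str] = []
        self._fh = open(path, "r", encoding="utf-8")
        self._keep_comments = keep_comments

    def close(self) -> None:
        self._fh.close()

    def _fill(self) -> bool:
        while not self._buf:
            raw = self._fh.readline()
            if raw == "":
                return False
            self.line += 1
            text = raw
            if not self._keep_comments:
                # '#' starts a comment in OFF; VTK uses '#' only in its header line
                text = raw.split("#", 1)[0]
            self._buf = text.split()
        return True

    def next(self, what: str = "token") -> str:
        if not self._fill():
            raise MeshParseError(self.path, self.line, f"unexpected end of file, expected {what}")
        return self._buf.pop(0)

    def skip_rest_of_line(self) -> None:
        """Discard any tokens remaining on the current line."""
        self._buf = []

    def read_raw_line(self) -> str:
        """Consume and return the next physical line verbatim."""
        self._buf = []
        raw = self._fh.readline()
        if raw == "":
            raise MeshParseError(self.path, self.line, "unexpected end of file")
        self.line += 1
        return raw.rstrip("\n")

    def next_int(self, what: str = "integer") -> int:
        tok = self.next(what)
        try:
            return int(tok)
        except ValueError:
            raise MeshParseError(self.path, self.line, f"expected {what}, got {tok!r}") from None

    def next_float(self, what: str = "number") -> float:
        tok = self.next(what)
        try:
            return float(tok)
        except ValueError:
            raise MeshParseError(self.path, self.line, f"expected {what}, got {tok!r}") from None

    def at_eof(self) -> bool:
        return not self._fill()


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; choose from {FORMATS}")
    return fmt


# ---------------------------------------------------------------------------
# reading


def read_mesh(
    path: str,
    fmt: str | None = None,
    validate: bool = True,
    return_point_data: bool = False,
):
    """Read a triangle mesh (and optional per-vertex scalar fields).

    Parameters
    ----------
    fmt : "off" | "ply" | "vtk" or None
        Inferred from the file extension when None.
    validate : bool
        Run closed-manifold validation after parsing.
    return_point_data : bool
        When True, return ``(mesh, fields)`` where ``fields`` maps field name
        to a per-vertex float array (empty for OFF).
    """
    fmt = _detect_format(path, fmt)
    tok = _Tokens(path, keep_comments=(fmt != "off"))
    try:
        if fmt == "off":
            mesh, fields = _read_off(tok), {}
        elif fmt == "ply":
            mesh, fields = _read_ply(tok)
        else:
            mesh, fields = _read_vtk(tok)
    finally:
        tok.close()
    if validate:
        try:
            mesh.validate()
        except MeshValidationError:
            raise
    return (mesh, fields) if return_point_data else mesh


def _check_face_indices(tok: _Tokens, idx: list[int], n_vertices: int) -> None:
    for i in idx:
        if i < 0 or i >= n_vertices:
            raise MeshParseError(
                tok.path, tok.line, f"face references vertex {i}, valid range [0, {n_vertices})"
            )


def _read_off(tok: _Tokens) -> TriangleMesh:
    magic = tok.next("OFF header")
    if magic.upper() != "OFF":
        raise MeshParseError(tok.path, tok.line, f"not an OFF file (header {magic!r})")
    nv = tok.next_int("vertex count")
    nf = tok.next_int("face count")
    tok.next_int("edge count")  # conventionally present, value ignored
    verts = np.empty((nv, 3))
    for i in range(nv):
        verts[i] = [tok.next_float("coordinate") for _ in range(3)]
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        k = tok.next_int("face vertex count")
        if k != 3:
            raise MeshParseError(tok.path, tok.line, f"only triangles supported, face has {k} vertices")
        idx = [tok.next_int("vertex index") for _ in range(3)]
        _check_face_indices(tok, idx, nv)
        faces[i] = idx
    return TriangleMesh(verts, faces)


_PLY_SCALAR_TYPES = {
    "char", "uchar", "int8", "uint8", "short", "ushort", "int16", "uint16",
    "int", "uint", "int32", "uint32", "float", "float32", "double", "float64",
}


def _read_ply(tok: _Tokens):
    if tok.next("ply magic") != "ply":
        raise MeshParseError(tok.path, tok.line, "not a PLY file")
    if [tok.next(), tok.next(), tok.next()] != ["format", "ascii", "1.0"]:
        raise MeshParseError(tok.path, tok.line, "only 'format ascii 1.0' PLY is supported")

    elements: list[tuple[str, int, list]] = []  # (name, count, [props])
    while True:
        kw = tok.next("header keyword")
        if kw == "comment":
            tok.skip_rest_of_line()
        elif kw == "element":
            name = tok.next("element name")
            count = tok.next_int("element count")
            elements.append((name, count, []))
        elif kw == "property":
            if not elements:
                raise MeshParseError(tok.path, tok.line, "property before any element")
            ptype = tok.next("property type")
            if ptype == "list":
                tok.next("list count type")
                tok.next("list value type")
                pname = tok.next("property name")
                elements[-1][2].append(("list", pname))
            else:
                if ptype not in _PLY_SCALAR_TYPES:
                    raise MeshParseError(tok.path, tok.line, f"unknown property type {ptype!r}")
                pname = tok.next("property name")
                elements[-1][2].append(("scalar", pname))
        elif kw == "end_header":
            break
        else:
            raise MeshParseError(tok.path, tok.line, f"unexpected header keyword {kw!r}")

    verts = None
    faces = None
    fields: dict[str, np.ndarray] = {}
    for name, count, props in elements:
        if name == "vertex":
            scalar_names = [p[1] for p in props if p[0] == "scalar"]
            for needed in ("x", "y", "z"):
                if needed not in scalar_names:
                    raise MeshParseError(tok.path, tok.line, f"vertex element lacks property {needed!r}")
            data = np.empty((count, len(scalar_names)))
            for i in range(count):
                for j in range(len(scalar_names)):
                    data[i, j] = tok.next_float("vertex property")
            verts = np.column_stack([data[:, scalar_names.index(c)] for c in "xyz"])
            for j, pname in enumerate(scalar_names):
                if pname not in ("x", "y", "z"):
                    fields[pname] = data[:, j].copy()
        elif name == "face":
            faces = np.empty((count, 3), dtype=np.int64)
            for i in range(count):
                k = tok.next_int("face vertex count")
                if k != 3:
                    raise MeshParseError(tok.path, tok.line, f"only triangles supported, face has {k} vertices")
                idx = [tok.next_int("vertex index") for _ in range(3)]
                _check_face_indices(tok, idx, 0 if verts is None else len(verts))
                faces[i] = idx
        else:
            # skip unknown element payload (scalars only)
            n_scalar = sum(1 for p in props if p[0] == "scalar")
            for _ in range(count * n_scalar):
                tok.next("skipped value")
    if verts is None or faces is None:
        raise MeshParseError(tok.path, tok.line, "PLY file lacks vertex or face element")
    return TriangleMesh(verts, faces), fields


def _read_vtk(tok: _Tokens):
    header = tok.next("'#' header")
    if header != "#":
        raise MeshParseError(tok.path, tok.line, "missing '# vtk DataFile' header")
    if tok.next().lower() != "vtk":
        raise MeshParseError(tok.path, tok.line, "missing '# vtk DataFile' header")
    tok.skip_rest_of_line()  # rest of the version line
    tok.read_raw_line()  # title line (free text)
    if tok.next("encoding").upper() != "ASCII":
        raise MeshParseError(tok.path, tok.line, "only ASCII VTK files are supported")
    if tok.next("DATASET").upper() != "DATASET" or tok.next("type").upper() != "POLYDATA":
        raise MeshParseError(tok.path, tok.line, "expected 'DATASET POLYDATA'")

    verts = None
    faces = None
    fields: dict[str, np.ndarray] = {}
    while not tok.at_eof():
        kw = tok.next("section keyword").upper()
        if kw == "POINTS":
            n = tok.next_int("point count")
            tok.next("dtype")
            verts = np.empty((n, 3))
            for i in range(n):
                verts[i] = [tok.next_float("coordinate") for _ in range(3)]
        elif kw == "POLYGONS":
            m = tok.next_int("polygon count")
            tok.next_int("total size")
            faces = np.empty((m, 3), dtype=np.int64)
            for i in range(m):
                k = tok.next_int("polygon vertex count")
                if k != 3:
                    raise MeshParseError(tok.path, tok.line, f"only triangles supported, polygon has {k} vertices")
                idx = [tok.next_int("vertex index") for _ in range(3)]
                _check_face_indices(tok, idx, 0 if verts is None else len(verts))
                faces[i] = idx
        elif kw == "POINT_DATA":
            n = tok.next_int("point-data count")
            if verts is not None and n != len(verts):
                raise MeshParseError(tok.path, tok.line, f"POINT_DATA count {n} != point count {len(verts)}")
            # one or more SCALARS blocks follow
            while not tok.at_eof():
                sub = tok.next("SCALARS").upper()
                if sub != "SCALARS":
                    raise MeshParseError(tok.path, tok.line, f"unsupported attribute block {sub!r}")
                name = tok.next("scalar name")
                tok.next("dtype")
                # optional numComponents token then LOOKUP_TABLE
                nxt = tok.next("LOOKUP_TABLE")
                if nxt.upper() != "LOOKUP_TABLE":
                    ncomp = int(nxt)
                    if ncomp != 1:
                        raise MeshParseError(tok.path, tok.line, "only 1-component scalars supported")
                    if tok.next().upper() != "LOOKUP_TABLE":
                        raise MeshParseError(tok.path, tok.line, "expected LOOKUP_TABLE")
                tok.next("table name")
                fields[name] = np.array([tok.next_float("scalar value") for _ in range(n)])
        else:
            raise MeshParseError(tok.path, tok.line, f"unsupported VTK section {kw!r}")
    if verts is None or faces is None:
        raise MeshParseError(tok.path, tok.line, "VTK file lacks POINTS or POLYGONS")
    return TriangleMesh(verts, faces), fields


# ---------------------------------------------------------------------------
# writing


def _fmt_floats(row: Iterable[float]) -> str:
    return " ".join(format(x, ".17g") for x in row)


def write_mesh(
    mesh: TriangleMesh,
    path: str,
    fmt: str | None = None,
    point_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write a mesh, optionally with named per-vertex scalar fields.

    PLY stores fields as extra double vertex properties, VTK as POINT_DATA
    SCALARS blocks.  OFF cannot carry fields and rejects them.
    """
    fmt = _detect_format(path, fmt)
    fields = dict(point_data or {})
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (mesh.n_vertices,):
            raise ValueError(f"field {name!r} must be ({mesh.n_vertices},), got {arr.shape}")
        fields[name] = arr
    if fmt == "off":
        if fields:
            raise ValueError("OFF cannot store per-vertex scalar fields; use PLY or VTK")
        _write_off(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, fields)
    else:
        _write_vtk(mesh, path, fields)


def _write_off(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for row in mesh.vertices:
            fh.write(_fmt_floats(row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_ply(mesh: TriangleMesh, path: str, fields: Mapping[str, np.ndarray]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in fields:
            fh.write(f"property double {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        cols = [mesh.vertices] + [arr[:, None] for arr in fields.values()]
        data = np.hstack(cols)
        for row in data:
            fh.write(_fmt_floats(row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_vtk(mesh: TriangleMesh, path: str, fields: Mapping[str, np.ndarray]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("shapemorph surface\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for row in mesh.vertices:
            fh.write(_fmt_floats(row) + "\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if fields:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in fields.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in arr:
                    fh.write(format(x, ".17g") + "\n")
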