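"""Minimal PLY reader/writer for triangle meshes (ascii + binary little endian).

Only the elements this package writes are understood: a ``vertex`` element
with float/double ``x, y, z`` (extra scalar properties are skipped) and a
``face`` element with a ``vertex_indices`` list property.  Header problems
raise :class:`~shapestage.errors.MeshFormatError` carrying the offending
1-based line number; non-triangle faces are rejected.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import MeshFormatError
from .mesh import SurfaceMesh

__all__ = ["read_mesh", "write_mesh"]

_SCALAR = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def write_mesh(mesh: SurfaceMesh, path: str | Path, binary: bool = False) -> None:
    """Write a triangle mesh as PLY; ascii by default, binary little endian
    when ``binary`` is set.  Vertex coordinates are stored as doubles, so the
    round trip is lossless to float64 precision."""
    path = Path(path)
    header = [
        "ply",
        "format binary_little_endian 1.0" if binary else "format ascii 1.0",
        f"comment structure {mesh.structure_name or 'unnamed'}"
        + (f" {mesh.hemisphere}" if mesh.hemisphere else ""),
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(mesh.vertices.astype("<f8").tobytes())
            for f in mesh.faces:
                fh.write(struct.pack("<B3i", 3, *f))
        else:
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n".encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


def _parse_header(lines: list[str]):
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError("missing 'ply' magic", line=1)
    fmt = None
    elements = []  # (name, count, [(prop_kind, ...)...])
    comment_name = None
    i = 1
    while i < len(lines):
        tok = lines[i].strip().split()
        lineno = i + 1
        if not tok:
            raise MeshFormatError("blank line in header", line=lineno)
        if tok[0] == "format":
            if len(tok) != 3 or tok[1] not in ("ascii", "binary_little_endian"):
                raise MeshFormatError(f"unsupported format {' '.join(tok[1:])!r}", line=lineno)
            fmt = tok[1]
        elif tok[0] == "comment":
            if tok[1:2] == ["structure"] and len(tok) >= 3:
                comment_name = tok[2:]
        elif tok[0] == "element":
            if len(tok) != 3 or not tok[2].isdigit():
                raise MeshFormatError("malformed element declaration", line=lineno)
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise MeshFormatError("property before any element", line=lineno)
            if tok[1] == "list":
                if len(tok) != 5 or tok[2] not in _SCALAR or tok[3] not in _SCALAR:
                    raise MeshFormatError("malformed list property", line=lineno)
                elements[-1][2].append(("list", _SCALAR[tok[2]], _SCALAR[tok[3]], tok[4]))
            else:
                if len(tok) != 3 or tok[1] not in _SCALAR:
                    raise MeshFormatError(f"unknown property type {tok[1]!r}", line=lineno)
                elements[-1][2].append(("scalar", _SCALAR[tok[1]], tok[2]))
        elif tok[0] == "end_header":
            if fmt is None:
                raise MeshFormatError("end_header before format line", line=lineno)
            return fmt, elements, comment_name, i + 1
        else:
            raise MeshFormatError(f"unknown header keyword {tok[0]!r}", line=lineno)
        i += 1
    raise MeshFormatError("missing end_header", line=len(lines))


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a PLY triangle mesh (ascii or binary little endian)."""
    path = Path(path)
    raw = path.read_bytes()
    # header is ascii text up to 'end_header'
    end = raw.find(b"end_header")
    if end < 0:
        raise MeshFormatError("missing end_header", line=1)
    nl = raw.find(b"\n", end)
    header_bytes = raw[: nl + 1]
    try:
        header_lines = header_bytes.decode("ascii").splitlines()
    except UnicodeDecodeError as exc:
        raise MeshFormatError(f"non-ascii header: {exc}", line=1) from None
    fmt, elements, comment_name, _ = _parse_header(header_lines)
    body = raw[nl + 1 :]

    names = {name for name, _, _ in elements}
    if "vertex" not in names or "face" not in names:
        raise MeshFormatError("PLY must declare vertex and face elements", line=1)

    vertices = None
    faces = None
    if fmt == "ascii":
        rows = body.decode("ascii").split("\n")
        cursor = 0
        for name, count, props in elements:
            take = rows[cursor : cursor + count]
            cursor += count
            if len(take) < count:
                raise MeshFormatError(f"truncated {name} data", line=len(header_lines))
            if name == "vertex":
                cols = {p[2]: k for k, p in enumerate(props) if p[0] == "scalar"}
                if not {"x", "y", "z"} <= set(cols):
                    raise MeshFormatError("vertex element lacks x/y/z", line=1)
                arr = np.array([[float(t) for t in r.split()] for r in take])
                vertices = arr[:, [cols["x"], cols["y"], cols["z"]]]
            elif name == "face":
                fl = []
                for r in take:
                    t = r.split()
                    if not t or int(t[0]) != 3 or len(t) != 4:
                        raise MeshFormatError("non-triangle face encountered")
                    fl.append([int(t[1]), int(t[2]), int(t[3])])
                faces = np.array(fl, dtype=np.int64)
    else:
        offset = 0
        for name, count, props in elements:
            if name == "vertex":
                if any(p[0] != "scalar" for p in props):
                    raise MeshFormatError("list property in vertex element", line=1)
                dt = np.dtype([(p[2], "<" + p[1]) for p in props])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                if not {"x", "y", "z"} <= set(arr.dtype.names):
                    raise MeshFormatError("vertex element lacks x/y/z", line=1)
                vertices = np.column_stack(
                    [arr["x"], arr["y"], arr["z"]]
                ).astype(np.float64)
            elif name == "face":
                if len(props) != 1 or props[0][0] != "list":
                    raise MeshFormatError("face element must be a single list", line=1)
                _, cnt_t, idx_t, _pname = props[0]
                cnt_dt = np.dtype("<" + cnt_t)
                idx_dt = np.dtype("<" + idx_t)
                fl = np.empty((count, 3), dtype=np.int64)
                for k in range(count):
                    n = int(
                        np.frombuffer(body, cnt_dt, count=1, offset=offset)[0]
                    )
                    offset += cnt_dt.itemsize
                    if n != 3:
                        raise MeshFormatError("non-triangle face encountered")
                    fl[k] = np.frombuffer(body, idx_dt, count=3, offset=offset)
                    offset += idx_dt.itemsize * 3
                faces = fl
    if vertices is None or faces is None:
        raise MeshFormatError("incomplete PLY (vertex or face data missing)", line=1)
    structure_name = comment_name[0] if comment_name else ""
    hemisphere = comment_name[1] if comment_name and len(comment_name) > 1 else ""
    return SurfaceMesh(vertices, faces, structure_name, hemisphere)
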