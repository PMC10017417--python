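"""Point-cloud file IO: PLY (ascii + binary_little_endian), PCD (ascii), XYZ.

Readers return :class:`~podskel.types.PointCloud`; non-coordinate vertex
attributes (color, normals, ...) are preserved in ``cloud.extra`` so a
read → write round trip keeps them.  An integer ``label`` property maps to
``cloud.labels``.
"""
from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .types import PointCloud

__all__ = ["read_cloud", "write_cloud", "CloudFormatError"]


class CloudFormatError(ValueError):
    """Raised when a cloud file cannot be parsed."""


_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}
_PLY_NAMES = {v: k for k, v in [
    ("char", "i1"), ("uchar", "u1"), ("short", "i2"), ("ushort", "u2"),
    ("int", "i4"), ("uint", "u4"), ("float", "f4"), ("double", "f8"),
]}


def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("ply", "pcd", "xyz", "txt"):
        return "xyz" if ext == "txt" else ext
    raise CloudFormatError(f"cannot infer point-cloud format from path {path!r}")


def read_cloud(path: str, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from PLY, PCD (ascii) or whitespace XYZ.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``{"ply", "pcd", "xyz"}``; inferred from the suffix when
        omitted.
    """
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise CloudFormatError(f"unknown format {fmt!r}")


def write_cloud(path: str, cloud: PointCloud, format: Optional[str] = None,
                binary: bool = False) -> None:
    """Write a cloud; labels are emitted as an integer ``label`` PLY property."""
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(path, cloud, binary=binary)
    elif fmt == "pcd":
        _write_pcd(path, cloud)
    elif fmt == "xyz":
        _write_xyz(path, cloud)
    else:
        raise CloudFormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------- XYZ

def _read_xyz(path: str) -> PointCloud:
    try:
        data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError:
        # slow path purely to name the offending line in the error
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                try:
                    [float(p) for p in parts[:3]]
                except ValueError:
                    raise CloudFormatError(
                        f"{path}: line {lineno} is not numeric: {line.strip()!r}")
        raise CloudFormatError(f"{path}: malformed XYZ file")
    if data.size == 0:
        return PointCloud(np.empty((0, 3)))
    if data.shape[1] < 3:
        raise CloudFormatError(f"{path}: XYZ rows need at least 3 columns")
    return PointCloud(data[:, :3])


def _write_xyz(path: str, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.points, fmt="%.17g")


# ---------------------------------------------------------------- PLY

def _read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudFormatError(f"{path}: missing 'ply' magic line")
        fmt = None
        elements = []  # (name, count, [(prop_name, dtype_code)])
        while True:
            raw = fh.readline()
            if not raw:
                raise CloudFormatError(f"{path}: unterminated PLY header")
            line = raw.decode("ascii", "replace").strip()
            if not line or line.startswith("comment") or line.startswith("obj_info"):
                continue
            tok = line.split()
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append([tok[1], int(tok[2]), []])
            elif tok[0] == "property":
                if not elements:
                    raise CloudFormatError(f"{path}: property before element: {line!r}")
                if tok[1] == "list":
                    elements[-1][2].append((tok[-1], ("list", tok[2], tok[3])))
                else:
                    if tok[1] not in _PLY_TYPES:
                        raise CloudFormatError(f"{path}: unknown PLY type in {line!r}")
                    elements[-1][2].append((tok[-1], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
            else:
                raise CloudFormatError(f"{path}: unexpected header line {line!r}")
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise CloudFormatError(f"{path}: PLY file has no vertex element")
        if elements[0][0] != "vertex":
            raise CloudFormatError(f"{path}: vertex must be the first PLY element")
        name, count, props = vertex
        if any(isinstance(d, tuple) for _, d in props):
            raise CloudFormatError(f"{path}: list properties on vertices unsupported")
        dtype = np.dtype([(n, ("<" + d) if fmt.startswith("binary") else d)
                          for n, d in props])
        if fmt == "ascii":
            rows = []
            for i in range(count):
                raw = fh.readline()
                if not raw:
                    raise CloudFormatError(f"{path}: vertex record {i} missing")
                parts = raw.split()
                if len(parts) != len(props):
                    raise CloudFormatError(
                        f"{path}: vertex record {i} has {len(parts)} fields, "
                        f"expected {len(props)}")
                rows.append(tuple(float(p) for p in parts))
            data = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
        else:
            buf = fh.read(dtype.itemsize * count)
            if len(buf) < dtype.itemsize * count:
                raise CloudFormatError(f"{path}: truncated binary vertex data")
            data = np.frombuffer(buf, dtype=dtype, count=count)
    for axis in ("x", "y", "z"):
        if axis not in data.dtype.names:
            raise CloudFormatError(f"{path}: vertex element lacks '{axis}' property")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    labels = None
    extra = {}
    for n in data.dtype.names:
        if n in ("x", "y", "z"):
            continue
        if n == "label":
            labels = data["label"].astype(np.int64)
        else:
            extra[n] = np.array(data[n])
    return PointCloud(pts, labels, extra)


def _write_ply(path: str, cloud: PointCloud, binary: bool = False) -> None:
    n = len(cloud)
    fields = [("x", "f8"), ("y", "f8"), ("z", "f8")]
    columns = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    for name, values in cloud.extra.items():
        arr = np.asarray(values)
        code = arr.dtype.str.lstrip("<>|=")
        if code not in _PLY_NAMES:
            arr = arr.astype(np.float64)
            code = "f8"
        fields.append((name, code))
        columns.append(arr)
    if cloud.labels is not None:
        fields.append(("label", "i4"))
        columns.append(cloud.labels.astype(np.int32))
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {n}"]
    header += [f"property {_PLY_NAMES[c]} {name}" for name, c in fields]
    header.append("end_header")
    if binary:
        dtype = np.dtype([(name, "<" + c) for name, c in fields])
        rec = np.empty(n, dtype=dtype)
        for (name, _), col in zip(fields, columns):
            rec[name] = col
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            fmts = ["%d" if c.startswith(("i", "u")) else "%.17g" for _, c in fields]
            for i in range(n):
                fh.write(" ".join(f % col[i] for f, col in zip(fmts, columns)) + "\n")


# ---------------------------------------------------------------- PCD

def _read_pcd(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        fields = sizes = types = counts = None
        n_points = None
        data_mode = None
        while True:
            raw = fh.readline()
            if not raw:
                raise CloudFormatError(f"{path}: unterminated PCD header")
            line = raw.decode("ascii", "replace").strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            key = tok[0].upper()
            if key == "FIELDS":
                fields = tok[1:]
            elif key == "SIZE":
                sizes = [int(t) for t in tok[1:]]
            elif key == "TYPE":
                types = tok[1:]
            elif key == "COUNT":
                counts = [int(t) for t in tok[1:]]
            elif key == "POINTS":
                n_points = int(tok[1])
            elif key == "DATA":
                data_mode = tok[1].lower()
                break
        if data_mode != "ascii":
            raise CloudFormatError(f"{path}: only ascii PCD DATA is supported")
        if fields is None or n_points is None:
            raise CloudFormatError(f"{path}: PCD header lacks FIELDS/POINTS")
        if counts is not None and any(c != 1 for c in counts):
            raise CloudFormatError(f"{path}: PCD COUNT > 1 unsupported")
        rows = []
        for i in range(n_points):
            raw = fh.readline()
            if not raw:
                raise CloudFormatError(f"{path}: point record {i} missing")
            parts = raw.split()
            if len(parts) != len(fields):
                raise CloudFormatError(
                    f"{path}: record {i} has {len(parts)} fields, expected {len(fields)}")
            rows.append([float(p) for p in parts])
    data = np.asarray(rows, dtype=np.float64) if rows else np.empty((0, len(fields)))
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise CloudFormatError(f"{path}: PCD lacks '{axis}' field")
    cols = {f: data[:, i] for i, f in enumerate(fields)}
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = cols["label"].astype(np.int64) if "label" in cols else None
    extra = {f: cols[f] for f in fields if f not in ("x", "y", "z", "label")}
    return PointCloud(pts, labels, extra)


def _write_pcd(path: str, cloud: PointCloud) -> None:
    fields = ["x", "y", "z"] + list(cloud.extra) + (
        ["label"] if cloud.labels is not None else [])
    n = len(cloud)
    columns = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    types, sizes = ["F", "F", "F"], [8, 8, 8]
    for name in cloud.extra:
        arr = np.asarray(cloud.extra[name]).astype(np.float64)
        columns.append(arr)
        types.append("F")
        sizes.append(8)
    if cloud.labels is not None:
        columns.append(cloud.labels)
        types.append("I")
        sizes.append(4)
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write("FIELDS " + " ".join(fields) + "\n")
        fh.write("SIZE " + " ".join(map(str, sizes)) + "\n")
        fh.write("TYPE " + " ".join(types) + "\n")
        fh.write("COUNT " + " ".join(["1"] * len(fields)) + "\n")
        fh.write(f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n")
        for i in range(n):
            vals = []
            for col, t in zip(columns, types):
                vals.append("%d" % col[i] if t == "I" else "%.17g" % col[i])
            fh.write(" ".join(vals) + "\n")
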