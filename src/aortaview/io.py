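"""Centerline and result I/O: CSV/TSV, legacy-ASCII VTK polyline, JSON.

CSV/TSV is the canonical exchange format (one x,y,z row per point, header
optional, delimiter autodetected).  The legacy VTK POLYDATA reader
understands ASCII files with a POINTS block and LINES connectivity and
returns the points in polyline order.  JSON round-trips the full
container including zone bounds.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import numpy as np

from .centerline import Centerline3D
from .exceptions import DegenerateInputError, ParseError, ValidationError

__all__ = ["read_centerline", "write_centerline", "detect_format"]

_FORMATS = ("csv", "vtk_legacy", "json")


def detect_format(path: str) -> str:
    """Guess the on-disk format from the file extension, then content."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".csv", ".tsv", ".txt", ".dat", ".xyz"):
        return "csv"
    if ext == ".vtk":
        return "vtk_legacy"
    if ext == ".json":
        return "json"
    with open(path, "r", errors="replace") as fh:
        head = fh.read(64).lstrip()
    if head.startswith("# vtk"):
        return "vtk_legacy"
    if head.startswith("{"):
        return "json"
    return "csv"


def read_centerline(path: str, format: str = "auto") -> Centerline3D:
    """Read an ordered 3D centerline from CSV/TSV, legacy VTK, or JSON.

    Units are taken as millimetres and passed through unchanged.  Point
    order is file order (CSV/JSON) or polyline connectivity order (VTK).
    """
    if format == "auto":
        format = detect_format(path)
    if format not in _FORMATS:
        raise ValidationError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "csv":
        c = _read_csv(path)
    elif format == "vtk_legacy":
        c = _read_vtk(path)
    else:
        c = _read_json(path)
    if len(c) < 2:
        raise DegenerateInputError(f"{path}: centerline has fewer than 2 points")
    return c


def write_centerline(c: Centerline3D, path: str, format: str = "auto") -> None:
    """Write a centerline; CSV keeps 12 significant digits, JSON is exact."""
    if format == "auto":
        format = detect_format_for_write(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("x,y,z\n")
            for p in c.points:
                fh.write(f"{p[0]:.12g},{p[1]:.12g},{p[2]:.12g}\n")
    elif format == "json":
        payload = {"label": c.label, "points": c.points.tolist()}
        if c.zone_bounds:
            payload["zone_bounds"] = {k: list(v) for k, v in c.zone_bounds.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)
    elif format == "vtk_legacy":
        _write_vtk(c, path)
    else:
        raise ValidationError(f"unknown format {format!r}; choose from {_FORMATS}")


def detect_format_for_write(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".vtk":
        return "vtk_legacy"
    if ext == ".json":
        return "json"
    return "csv"


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def _parse_row(fields: Iterable[str]):
    vals = [float(f) for f in fields]
    if len(vals) < 3:
        raise ValueError("fewer than 3 numeric columns")
    return vals[:3]


def _read_csv(path: str) -> Centerline3D:
    pts = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            delim = "\t" if "\t" in line else ("," if "," in line else None)
            fields = [f for f in line.split(delim) if f != ""]
            try:
                pts.append(_parse_row(fields))
            except ValueError as exc:
                if lineno == 1 and not pts:
                    continue  # header row
                raise ParseError(f"malformed row ({exc}): {line!r}", path, lineno)
    if not pts:
        raise ParseError("no data rows found", path)
    arr = np.asarray(pts, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
        raise ValidationError(f"{path}: non-finite coordinate in data row {bad + 1}")
    return Centerline3D(arr, label=os.path.splitext(os.path.basename(path))[0])


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------


def _read_json(path: str) -> Centerline3D:
    with open(path, "r") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc.msg}", path, exc.lineno)
    if not isinstance(payload, dict) or "points" not in payload:
        raise ParseError("JSON centerline must be an object with a 'points' key", path)
    zones = payload.get("zone_bounds")
    if zones is not None:
        zones = {k: (int(v[0]), int(v[1])) for k, v in zones.items()}
    arr = np.asarray(payload["points"], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ParseError("'points' must be an n x 3 array", path)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path}: non-finite coordinate in JSON points")
    return Centerline3D(arr, label=str(payload.get("label", "")), zone_bounds=zones)


# ---------------------------------------------------------------------------
# legacy ASCII VTK POLYDATA with LINES
# ---------------------------------------------------------------------------


def _read_vtk(path: str) -> Centerline3D:
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    tokens: list[tuple[str, int]] = []  # (token, source line number)
    dataset_seen = False
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 2 or line.startswith("#"):
            continue  # version line and title
        for tok in line.split():
            tokens.append((tok, lineno))
        if "DATASET" in line:
            dataset_seen = True
    toks = [t for t, _ in tokens]
    upper = [t.upper() for t in toks]
    if "POLYDATA" not in upper or not dataset_seen:
        raise ParseError("not an ASCII VTK POLYDATA file", path)

    def _ints_floats(start: int, count: int, cast):
        out = []
        for j in range(start, start + count):
            if j >= len(toks):
                raise ParseError("unexpected end of file", path, tokens[-1][1])
            try:
                out.append(cast(toks[j]))
            except ValueError:
                raise ParseError(
                    f"expected a number, got {toks[j]!r}", path, tokens[j][1]
                )
        return out

    try:
        ip = upper.index("POINTS")
    except ValueError:
        raise ParseError("POINTS block missing", path)
    npts = int(toks[ip + 1])
    coords = _ints_floats(ip + 3, 3 * npts, float)
    pts = np.asarray(coords, dtype=float).reshape(npts, 3)

    try:
        il = upper.index("LINES")
    except ValueError:
        raise ParseError("LINES block missing (no polyline connectivity)", path)
    n_cells = int(toks[il + 1])
    cursor = il + 3
    order: list[int] = []
    if upper[cursor : cursor + 1] == ["OFFSETS"]:
        # VTK >= 5.1 layout: OFFSETS <dtype> ... CONNECTIVITY <dtype> ...
        offsets = _ints_floats(cursor + 2, n_cells, int)
        ic = upper.index("CONNECTIVITY", cursor)
        conn = _ints_floats(ic + 2, offsets[-1], int)
        order = conn
    else:
        for _ in range(n_cells):
            m = int(toks[cursor])
            order.extend(_ints_floats(cursor + 1, m, int))
            cursor += 1 + m
    if any(i < 0 or i >= npts for i in order):
        raise ParseError("LINES connectivity index out of range", path)
    arr = pts[np.asarray(order, dtype=int)]
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path}: non-finite coordinate in VTK points")
    return Centerline3D(arr, label=os.path.splitext(os.path.basename(path))[0])


def _write_vtk(c: Centerline3D, path: str) -> None:
    n = len(c)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write((c.label or "centerline") + "\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in c.points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"LINES 1 {n + 1}\n")
        fh.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")
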