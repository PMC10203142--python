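"""File I/O: legacy ASCII VTK, CSV traces, JSON run manifests.

Legacy ASCII VTK is used for its inspectability: finite-volume meshes are
written as point clouds of cell centroids (VTK_VERTEX cells) carrying the
cell data, structural meshes with their real connectivity (lines,
triangles, tetrahedra).  Indices are 0-based internally and on disk (VTK
convention).  Units are declared in the dataset header comment: SI for
fluid/mechanics files, mV/ms/mm for electrophysiology files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_vtk_unstructured", "read_vtk_unstructured",
           "write_trace_csv", "read_trace_csv", "write_manifest",
           "write_outputs"]

_VTK_CELL_TYPES = {1: 1, 2: 3, 3: 5, 4: 10}   # n_nodes -> VTK type
_VTK_TYPE_NODES = {1: 1, 3: 2, 5: 3, 10: 4}


def write_vtk_unstructured(path, points, cells=None, point_data=None,
                           cell_data=None, comment="cardiokit mesh"):
    """Write a legacy ASCII VTK unstructured grid.

    ``cells``: (m, k) connectivity (k in {1, 2, 3, 4}: vertex, line,
    triangle, tetra); default one VTK_VERTEX per point.  ``point_data`` /
    ``cell_data``: dicts of name -> (n,) or (n, 3) float arrays.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if cells is None:
        cells = np.arange(points.shape[0])[:, None]
    cells = np.atleast_2d(np.asarray(cells, dtype=int))
    k = cells.shape[1]
    vtk_type = _VTK_CELL_TYPES[k]
    lines = ["# vtk DataFile Version 3.0", str(comment)[:255], "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {points.shape[0]} double"]
    for p in points:
        lines.append("%.12g %.12g %.12g" % tuple(p))
    m = cells.shape[0]
    lines.append(f"CELLS {m} {m * (k + 1)}")
    for c in cells:
        lines.append(" ".join([str(k)] + [str(i) for i in c]))
    lines.append(f"CELL_TYPES {m}")
    lines.extend([str(vtk_type)] * m)
    for tag, data in (("POINT_DATA", point_data), ("CELL_DATA", cell_data)):
        if not data:
            continue
        n = points.shape[0] if tag == "POINT_DATA" else m
        lines.append(f"{tag} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend("%.12g" % x for x in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend("%.12g %.12g %.12g" % tuple(row)
                             for row in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_unstructured(path):
    """Read back what ``write_vtk_unstructured`` produces.

    Returns dict with ``points``, ``cells``, ``point_data``, ``cell_data``.
    """
    tok = Path(path).read_text().splitlines()
    out = {"points": None, "cells": None, "point_data": {}, "cell_data": {}}
    i = 0
    target = None
    while i < len(tok):
        line = tok[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            pts = [list(map(float, tok[i + 1 + j].split()))
                   for j in range(n)]
            out["points"] = np.asarray(pts)
            i += n + 1
        elif key == "CELLS":
            m = int(parts[1])
            rows = []
            for j in range(m):
                vals = list(map(int, tok[i + 1 + j].split()))
                rows.append(vals[1:])
            out["cells"] = np.asarray(rows)
            i += m + 1
        elif key == "CELL_TYPES":
            i += int(parts[1]) + 1
        elif key in ("POINT_DATA", "CELL_DATA"):
            target = "point_data" if key == "POINT_DATA" else "cell_data"
            i += 1
        elif key == "SCALARS" and target:
            name = parts[1]
            n = (out["points"].shape[0] if target == "point_data"
                 else out["cells"].shape[0])
            vals = [float(tok[i + 2 + j]) for j in range(n)]
            out[target][name] = np.asarray(vals)
            i += n + 2
        elif key == "VECTORS" and target:
            name = parts[1]
            n = (out["points"].shape[0] if target == "point_data"
                 else out["cells"].shape[0])
            vals = [list(map(float, tok[i + 1 + j].split()))
                    for j in range(n)]
            out[target][name] = np.asarray(vals)
            i += n + 1
        else:
            i += 1
    return out


def write_trace_csv(path, columns: dict) -> None:
    """Time-series CSV: dict of column name -> 1-D array."""
    pd.DataFrame(columns).to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, outputs: dict) -> dict:
    """JSON run manifest: configuration hash, seed, package version and the
    produced files with their declared columns/fields."""
    from . import __version__

    manifest = {
        "package": "cardiokit",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str)
                          + "\n")
    return manifest


def write_outputs(results: dict, outdir, config: dict = None,
                  seed: int = 0) -> dict:
    """Write a run-output bundle.

    ``results`` may contain ``mesh`` (+ per-frame cell data under
    ``frames``: list of dicts name -> array), ``traces`` (dict of column
    arrays incl. ``t``), and anything JSON-serializable under ``scalars``.
    Returns the manifest dict.  An empty results dict writes the manifest
    only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced = {}
    mesh = results.get("mesh")
    for k, frame in enumerate(results.get("frames", [])):
        name = f"frame_{k:04d}.vtk"
        write_vtk_unstructured(
            outdir / name, mesh.centroids, point_data=frame,
            comment="cardiokit EP frame; units mV, ms, mm")
        produced[name] = sorted(frame)
    if "traces" in results:
        write_trace_csv(outdir / "traces.csv", results["traces"])
        produced["traces.csv"] = sorted(results["traces"])
    if "scalars" in results:
        (outdir / "scalars.json").write_text(
            json.dumps(results["scalars"], indent=2, default=float) + "\n")
        produced["scalars.json"] = sorted(results["scalars"])
    return write_manifest(outdir / "manifest.json", config or {}, seed,
                          produced)
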