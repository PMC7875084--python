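"""Plain-text readers and writers for elements, matrices and manifests.

Two interchangeable element-set layouts:

* **directory layout** — one delimited matrix file per element plus a
  manifest table with columns ``element_id, label, dof, path``;
* **triangle table** — a single table with columns
  ``element_id, label, dof`` followed by the p(p+1)/2 entries of each
  matrix's lower triangle (row-major, diagonal included), headed
  ``v_<i>_<j>``.

All files are delimited text (CSV by default). Indices in file names
and headers are 0-based.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .class_model import ElementSample
from .exceptions import SpecError
from .timeseries import BatchSeries
from .wishart import validate_spd

__all__ = [
    "write_elements_dir",
    "read_elements_dir",
    "write_triangle_table",
    "read_triangle_table",
    "write_batches",
    "read_batches",
    "write_truth_record",
    "read_truth_record",
]


# --- directory layout -------------------------------------------------------

def write_elements_dir(elements: Sequence[ElementSample], out_dir: str | Path) -> Path:
    """Write one matrix file per element plus ``manifest.csv``; returns
    the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in elements:
        fname = f"{e.element_id}.csv"
        np.savetxt(out / fname, e.matrix.values, delimiter=",")
        rows.append({"element_id": e.element_id, "label": e.label, "dof": e.dof, "path": fname})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_elements_dir(manifest_path: str | Path, ridge: float = 0.0) -> list[ElementSample]:
    """Load elements from a manifest; matrix paths are resolved
    relative to the manifest's directory."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    elements = []
    for row in df.itertuples(index=False):
        mat = np.loadtxt(base / str(row.path), delimiter=",", ndmin=2)
        elements.append(
            ElementSample(
                matrix=validate_spd(mat, ridge=ridge),
                dof=int(row.dof),
                label=row.label,
                element_id=str(row.element_id),
            )
        )
    return elements


# --- lower-triangle table ---------------------------------------------------

def _tri_columns(p: int) -> list[str]:
    return [f"v_{i}_{j}" for i in range(p) for j in range(i + 1)]


def write_triangle_table(elements: Sequence[ElementSample], path: str | Path) -> Path:
    """Vectorize each element's lower triangle into one table row."""
    if not elements:
        raise SpecError("no elements to write")
    p = elements[0].matrix.p
    cols = _tri_columns(p)
    il = np.tril_indices(p)
    rows = []
    for e in elements:
        if e.matrix.p != p:
            raise SpecError("all elements must share one dimension p")
        row = {"element_id": e.element_id, "label": e.label, "dof": e.dof}
        row.update(dict(zip(cols, e.matrix.values[il])))
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_triangle_table(path: str | Path, ridge: float = 0.0) -> list[ElementSample]:
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("v_")]
    k = len(value_cols)
    # k = p(p+1)/2  =>  p = (sqrt(8k+1) - 1) / 2
    p = int((np.sqrt(8 * k + 1) - 1) / 2 + 0.5)
    if p * (p + 1) // 2 != k:
        raise SpecError(f"{k} value columns is not a triangular number")
    il = np.tril_indices(p)
    elements = []
    for row in df.itertuples(index=False):
        vals = np.array([getattr(row, c) for c in value_cols], dtype=float)
        mat = np.zeros((p, p))
        mat[il] = vals
        mat = mat + np.tril(mat, -1).T
        elements.append(
            ElementSample(
                matrix=validate_spd(mat, ridge=ridge),
                dof=int(row.dof),
                label=row.label,
                element_id=str(row.element_id),
            )
        )
    return elements


# --- labeled series batches -------------------------------------------------

def write_batches(batches: Sequence[BatchSeries], out_dir: str | Path) -> Path:
    """Write per-batch series files plus ``batches.csv`` manifest with
    columns element_id, label, dof, t_start, t_end, path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, b in enumerate(batches):
        eid = f"b{i:04d}_{b.t_start}_{b.t_end}"
        fname = f"{eid}.csv"
        header = ",".join(b.channel_names) if b.channel_names else ",".join(
            f"ch{j}" for j in range(b.p)
        )
        np.savetxt(out / fname, b.data, delimiter=",", header=header, comments="")
        rows.append(
            {
                "element_id": eid,
                "label": b.label,
                "dof": b.length,
                "t_start": b.t_start,
                "t_end": b.t_end,
                "path": fname,
            }
        )
    manifest = out / "batches.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_batches(manifest_path: str | Path) -> list[BatchSeries]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    batches = []
    for row in df.itertuples(index=False):
        frame = pd.read_csv(base / str(row.path))
        batches.append(
            BatchSeries(
                data=frame.to_numpy(dtype=float),
                label=row.label,
                t_start=int(row.t_start),
                t_end=int(row.t_end),
                channel_names=tuple(frame.columns),
            )
        )
    return batches


# --- truth records ----------------------------------------------------------

def write_truth_record(truth: dict, path: str | Path) -> Path:
    """Key-value text dump of a synthetic truth record; matrices are
    flattened row-major with their shape recorded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in truth.items():
            if isinstance(val, np.ndarray):
                fh.write(f"{key}.shape = {val.shape[0]} {val.shape[1]}\n")
                flat = " ".join(repr(float(x)) for x in val.ravel())
                fh.write(f"{key}.values = {flat}\n")
            elif isinstance(val, (list, tuple)):
                fh.write(f"{key} = {' '.join(str(v) for v in val)}\n")
            else:
                fh.write(f"{key} = {val}\n")
    return path


def read_truth_record(path: str | Path) -> dict:
    """Inverse of :func:`write_truth_record`; matrices come back as
    arrays, integer-like scalar fields as int, lists as string lists."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, val = line.split("=", 1)
            raw[key.strip()] = val.strip()

    truth: dict = {}
    shapes = {k[: -len(".shape")]: tuple(int(x) for x in v.split()) for k, v in raw.items() if k.endswith(".shape")}
    for key, val in raw.items():
        if key.endswith(".shape"):
            continue
        if key.endswith(".values"):
            name = key[: -len(".values")]
            arr = np.array([float(x) for x in val.split()])
            truth[name] = arr.reshape(shapes[name])
        else:
            parts = val.split()
            if len(parts) > 1:
                truth[key] = parts
            else:
                try:
                    f = float(val)
                    truth[key] = int(f) if f.is_integer() else f
                except ValueError:
                    truth[key] = val
    return truth
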