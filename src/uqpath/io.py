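"""On-disk formats: sample matrices, score tables and PNG patches.

All tabular artefacts are UTF-8 TSV with a header row and ``.`` decimals.
Floats are printed with 17 significant digits so that write→read is an
exact round trip.  Malformed input is rejected with the offending line
number in the error message.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .samplers import Patch, SampleMatrix

__all__ = [
    "write_samples",
    "read_samples",
    "write_scores",
    "read_scores",
    "write_patch_png",
    "read_patch_png",
]

_FLOAT_FMT = "%.17g"
_METHOD_COMMENT = "# uqpath-samples method="


def write_samples(matrix: SampleMatrix, path: str | os.PathLike) -> None:
    """Serialise as TSV: comment line with the method, then a header row
    ``id  label  s_1 .. s_T``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_METHOD_COMMENT}{matrix.method}\n")
        cols = "\t".join(f"s_{t + 1}" for t in range(matrix.T))
        fh.write(f"id\tlabel\t{cols}\n")
        for i in range(matrix.n):
            vals = "\t".join(_FLOAT_FMT % v for v in matrix.samples[i])
            fh.write(f"{matrix.ids[i]}\t{matrix.labels[i]}\t{vals}\n")


def _fail(path, lineno: int, msg: str) -> None:
    raise ValueError(f"{path}, line {lineno}: {msg}")


def read_samples(path: str | os.PathLike) -> SampleMatrix:
    """Read a sample-matrix TSV written by :func:`write_samples`.

    Files without the method comment line are accepted; the method then
    defaults to ``single`` (T = 1) or ``ensemble`` (T > 1).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    method = None
    lineno = 0
    if lines and lines[0].startswith(_METHOD_COMMENT):
        method = lines[0][len(_METHOD_COMMENT):].strip()
        lineno = 1
    if lineno >= len(lines):
        raise ValueError(f"{path}: missing header row")
    header = lines[lineno].split("\t")
    if header[:2] != ["id", "label"] or any(
            h != f"s_{k + 1}" for k, h in enumerate(header[2:])):
        _fail(path, lineno + 1, "header must be id, label, s_1..s_T")
    T = len(header) - 2
    if T < 1:
        _fail(path, lineno + 1, "at least one sample column s_1 is required")

    ids: list[str] = []
    labels: list[int] = []
    rows: list[list[float]] = []
    for k, line in enumerate(lines[lineno + 1:], start=lineno + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != T + 2:
            _fail(path, k, f"expected {T + 2} columns, found {len(parts)}")
        if parts[1] not in ("0", "1"):
            _fail(path, k, f"label must be 0 or 1, found {parts[1]!r}")
        try:
            vals = [float(v) for v in parts[2:]]
        except ValueError:
            _fail(path, k, "non-numeric score")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            _fail(path, k, "score outside [0, 1]")
        ids.append(parts[0])
        labels.append(int(parts[1]))
        rows.append(vals)

    samples = np.array(rows, dtype=np.float64).reshape(len(rows), T)
    if method is None:
        method = "single" if T == 1 else "ensemble"
    return SampleMatrix(samples, np.array(labels, dtype=np.int64),
                        method=method, ids=tuple(ids))


def write_scores(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a score table (columns ``id``, ``label``, then float columns)."""
    if list(frame.columns[:2]) != ["id", "label"]:
        raise ValueError("score table must start with columns id, label")
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    """Read a score table, validating labels and numeric columns."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(frame.columns[:2]) != ["id", "label"]:
        raise ValueError(f"{path}: score table must start with id, label")
    bad = frame.index[~frame["label"].isin((0, 1))]
    if len(bad):
        _fail(path, int(bad[0]) + 2, "label must be 0 or 1")
    for col in frame.columns[2:]:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna()]
        if len(bad):
            _fail(path, int(bad[0]) + 2, f"non-numeric value in column {col!r}")
        frame[col] = vals
    return frame


def write_patch_png(patch: Patch, path: str | os.PathLike) -> None:
    """Write a patch as 8-bit RGB PNG (values rescaled from [0, 1])."""
    arr = np.clip(np.rint(patch.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def read_patch_png(path: str | os.PathLike,
                   identifier: str | None = None) -> Patch:
    """Read an 8-bit RGB PNG, rescaling channel values to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    name = identifier if identifier is not None else os.path.splitext(
        os.path.basename(os.fspath(path)))[0]
    return Patch(arr, identifier=name)


def read_patches_dir(directory: str | os.PathLike) -> list[Patch]:
    """Read every ``*.png`` in a directory, sorted by filename."""
    names: Iterable[str] = sorted(
        f for f in os.listdir(directory) if f.lower().endswith(".png"))
    return [read_patch_png(os.path.join(directory, f)) for f in names]
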