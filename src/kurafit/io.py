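"""File formats and run manifests.

All matrices (SC, PL, FC) travel as whitespace/tab-delimited numeric text,
N rows x N columns, no header; BOLD as T x N delimited text with a one-line
header of region labels.  Floats are serialized at 17 significant digits so
write-read round trips are exact.  Every CLI run writes a JSON manifest
recording the command, configuration snapshot, master seed, child seeds,
package version and input-file digests, sufficient to replay a fixed-noise
run bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "load_square_matrix",
    "save_matrix",
    "load_bold",
    "save_bold",
    "RunManifest",
]

FLOAT_FMT = "%.17g"


def load_square_matrix(path, expected_n: int | None = None,
                       require_symmetric: bool = False) -> np.ndarray:
    """Read an N x N delimited-text matrix, validating shape and numeric content."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            if not line.strip():
                continue
            vals = []
            for c, tok in enumerate(line.split()):
                try:
                    v = float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {tok!r} at row {r}, column {c}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(f"{path}: non-finite cell at row {r}, column {c}")
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1 or ncols.pop() != len(rows):
        shape = (len(rows), len(rows[0]))
        raise ValueError(f"{path}: matrix is not square (shape {shape[0]}x{shape[1]})")
    m = np.asarray(rows, dtype=float)
    if expected_n is not None and m.shape[0] != expected_n:
        raise ValueError(f"{path}: expected {expected_n} regions, found {m.shape[0]}")
    if require_symmetric and not np.allclose(m, m.T, atol=1e-9):
        raise ValueError(f"{path}: matrix is not symmetric")
    return m


def save_matrix(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt=FLOAT_FMT, delimiter="\t")


def save_bold(path, bold: np.ndarray, region_ids: list[str]) -> None:
    bold = np.asarray(bold, dtype=float)
    if bold.shape[1] != len(region_ids):
        raise ValueError("one region label per column required")
    np.savetxt(path, bold, fmt=FLOAT_FMT, delimiter="\t",
               header="\t".join(region_ids), comments="")


def load_bold(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        labels = header.split("\t") if header else []
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if labels and data.size and data.shape[1] != len(labels):
        raise ValueError(f"{path}: header lists {len(labels)} regions, data has {data.shape[1]}")
    return data, labels


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    master_seed: int
    child_seeds: dict = field(default_factory=dict)
    version: str = ""
    input_digests: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def add_input(self, name: str, path) -> None:
        self.input_digests[name] = {"path": str(path), "sha256": file_digest(path)}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
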