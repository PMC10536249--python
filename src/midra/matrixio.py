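"""Named-matrix containers and TSV round-trip I/O.

All similarity matrices in this package (disease semantic SSD, miRNA
functional FSM, Gaussian interaction profile GSM/GSD, fused MM/DD) share one
shape contract: square, symmetric, unit diagonal, values in [0, 1].
:class:`NamedMatrix` carries the values plus an ordered name registry so that
every intermediate artifact can be written to, and re-read from, a
human-diffable TSV with bit-exact fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NamedMatrix", "SimilarityMatrix", "write_matrix", "read_matrix"]


@dataclass
class NamedMatrix:
    """A 2-D float array with row and column name registries.

    Parameters
    ----------
    values
        Array of shape ``(len(row_names), len(col_names))``.
    row_names, col_names
        Ordered, unique entity names.
    kind
        Free-form label (e.g. ``"SSD"``, ``"GSM"``, ``"A"``).
    """

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_names = list(self.row_names)
        self.col_names = list(self.col_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match names "
                f"({len(self.row_names)}, {len(self.col_names)})"
            )
        for names, axis in ((self.row_names, "row"), (self.col_names, "column")):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {axis} names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, name: str) -> int:
        return self.row_names.index(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NamedMatrix):
            return NotImplemented
        return (
            self.row_names == other.row_names
            and self.col_names == other.col_names
            and np.array_equal(self.values, other.values)
        )


class SimilarityMatrix(NamedMatrix):
    """Square symmetric named matrix over a single entity set."""

    def __init__(self, values: np.ndarray, names: list[str], kind: str = "") -> None:
        super().__init__(values=values, row_names=list(names), col_names=list(names), kind=kind)

    @property
    def names(self) -> list[str]:
        return self.row_names

    def validate(self, atol: float = 1e-12) -> None:
        """Assert the similarity-matrix contract (symmetry, unit diagonal, [0,1])."""
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError(f"{self.kind or 'matrix'} is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError(f"{self.kind or 'matrix'} diagonal is not 1")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError(f"{self.kind or 'matrix'} values outside [0,1]")


def write_matrix(matrix: NamedMatrix, path: str | Path) -> None:
    """Write a named matrix as TSV with full-precision floats.

    Values are written with ``repr`` precision (17 significant digits) so
    that ``read_matrix(write_matrix(x)) == x`` bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\t".join(["name"] + matrix.col_names) + "\n")
        for name, row in zip(matrix.row_names, matrix.values):
            fh.write(name + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_matrix(path: str | Path, kind: str = "") -> NamedMatrix:
    """Read a named-matrix TSV written by :func:`write_matrix`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_names = header[1:]  # pandas would mangle duplicate headers
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, skiprows=1, header=None)
    row_names = [str(r) for r in df.index]
    if len(set(col_names)) != len(col_names) or len(set(row_names)) != len(row_names):
        raise ValueError(f"{path}: duplicate names in matrix header")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix body: {exc}") from exc
    if values.shape[1] != len(col_names):
        raise ValueError(f"{path}: header/body column count mismatch")
    if row_names == col_names:
        return SimilarityMatrix(values, row_names, kind=kind)
    return NamedMatrix(values, row_names, col_names, kind=kind)
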