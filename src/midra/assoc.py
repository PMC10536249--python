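"""Association data: parsing, deduplication, and the binary matrix A.

The raw input is a two-or-more column text export of experimentally
supported miRNA-disease associations (one pair per line, extra evidence
columns ignored). Pairs are whitespace-normalized, case-folded for matching,
and deduplicated; the binary association matrix A has A[i, j] = 1 iff miRNA
m_i is associated with disease d_j. Row i of A is the interaction profile
IP(m_i) of miRNA m_i; column j is the profile IP'(d_j) of disease d_j —
these profiles feed the Gaussian interaction profile kernels downstream.

Indices are sorted lexicographically (by case-folded name) so every
downstream matrix is reproducible regardless of input record order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrixio import NamedMatrix, read_matrix, write_matrix

__all__ = [
    "AssociationTable",
    "AssociationMatrix",
    "parse_associations",
    "build_association_matrix",
    "write_matrix",
    "read_matrix",
]


@dataclass
class AssociationTable:
    """Deduplicated (miRNA, disease) name pairs in first-seen order."""

    records: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AssociationMatrix:
    """Binary n_m x n_d matrix with ordered name registries.

    ``mirna_index`` / ``disease_index`` map name -> row/column position.
    """

    A: np.ndarray
    mirna_names: list[str]
    disease_names: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        vals = np.unique(self.A)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary")

    @property
    def n_m(self) -> int:
        return self.A.shape[0]

    @property
    def n_d(self) -> int:
        return self.A.shape[1]

    @property
    def mirna_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.mirna_names)}

    @property
    def disease_index(self) -> dict[str, int]:
        return {n: j for j, n in enumerate(self.disease_names)}

    def interaction_profile(self, mirna: str) -> np.ndarray:
        """IP(m_i): row of A for one miRNA."""
        return self.A[self.mirna_index[mirna]]

    def disease_profile(self, disease: str) -> np.ndarray:
        """IP'(d_j): column of A for one disease."""
        return self.A[:, self.disease_index[disease]]

    def disease_sets(self) -> dict[str, list[str]]:
        """Per-miRNA associated disease name sets (in column order)."""
        out: dict[str, list[str]] = {}
        for i, m in enumerate(self.mirna_names):
            out[m] = [self.disease_names[j] for j in np.flatnonzero(self.A[i])]
        return out

    def to_named(self) -> NamedMatrix:
        return NamedMatrix(self.A, self.mirna_names, self.disease_names, kind="A")

    @classmethod
    def from_named(cls, m: NamedMatrix) -> "AssociationMatrix":
        return cls(m.values, m.row_names, m.col_names)


def _normalize(name: str) -> str:
    return " ".join(name.split())


def parse_associations(path: str | Path, dialect: str = "tsv") -> AssociationTable:
    """Parse an association file into deduplicated (miRNA, disease) pairs.

    Lines starting with ``#`` and a single leading header line whose first
    field case-insensitively contains "mirna" are skipped. Matching is
    case-insensitive; the first-seen casing of each name is preserved.

    Raises
    ------
    FileNotFoundError
        If the file is missing.
    ValueError
        On a line with fewer than two fields (the error names the line).
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    seen: set[tuple[str, str]] = set()
    records: list[tuple[str, str]] = []
    canon: dict[str, str] = {}  # case-folded -> first-seen casing
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(sep)]
            if lineno == 1 and fields and "mirna" in fields[0].casefold():
                continue
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed line (need >=2 fields)")
            m, d = _normalize(fields[0]), _normalize(fields[1])
            key = (m.casefold(), d.casefold())
            canon.setdefault(key[0], m)
            canon.setdefault(key[1], d)
            if key in seen:
                continue
            seen.add(key)
            records.append((canon[key[0]], canon[key[1]]))
    return AssociationTable(records)


def build_association_matrix(table: AssociationTable) -> AssociationMatrix:
    """Build the binary matrix A from an association table.

    Rows (miRNAs) and columns (diseases) are sorted lexicographically by
    case-folded name, so the construction is invariant to record order.
    """
    if not table.records:
        raise ValueError("empty association table: cannot build matrix")
    mirnas = sorted({m for m, _ in table.records}, key=str.casefold)
    diseases = sorted({d for _, d in table.records}, key=str.casefold)
    mi = {m: i for i, m in enumerate(mirnas)}
    di = {d: j for j, d in enumerate(diseases)}
    A = np.zeros((len(mirnas), len(diseases)))
    for m, d in table.records:
        A[mi[m], di[d]] = 1.0
    return AssociationMatrix(A, mirnas, diseases)
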