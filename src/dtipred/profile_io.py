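"""Reading and normalizing PSI-BLAST ASCII evolutionary profiles.

A PSSM (position-specific scoring matrix) is the L x 20 integer log-odds
profile PSI-BLAST writes with ``-out_ascii_pssm``: one row per residue of
the query, one column per canonical amino acid, entries typically in
[-9, 11]. Only the first (log-odds) 20-column block of the file is used;
the second block of weighted observed percentages is ignored.

Raw scores are mapped into (0, 1) with the logistic function
``1 / (1 + exp(-E))`` before any feature extraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Canonical amino-acid column order (PSI-BLAST header order).
AMINO_ACIDS = ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
               "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V")


class PssmParseError(ValueError):
    """Raised when a PSI-BLAST ASCII PSSM file cannot be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class ProfileMatrix:
    """Raw L x 20 integer evolutionary profile for one protein.

    ``scores[i, j]`` is the log-odds of residue i mutating to the j-th
    canonical amino acid (column order :data:`AMINO_ACIDS`).
    """

    protein_id: str
    residues: str
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.int64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got shape {scores.shape}")
        if scores.shape[0] < 1:
            raise ValueError("profile must have at least one row")
        if len(self.residues) != scores.shape[0]:
            raise ValueError(
                f"residue count {len(self.residues)} != row count {scores.shape[0]}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class NormalizedProfile:
    """Logistic-normalized profile; every entry strictly in (0, 1)."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValueError(f"normalized profile must be L x 20, got {values.shape}")
        if not ((values > 0.0) & (values < 1.0)).all():
            raise ValueError("normalized entries must lie strictly in (0, 1)")

    @property
    def length(self) -> int:
        return self.values.shape[0]


_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z\*])\s+(.*)$")


def read_pssm(path: str | Path) -> ProfileMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`ProfileMatrix`.

    The 20 log-odds columns are remapped from the file's header order to the
    canonical order :data:`AMINO_ACIDS`; the trailing percentage block and
    per-row statistics are ignored. The protein id is the file stem.

    Raises
    ------
    PssmParseError
        If the header is missing, a score cell is not an integer, or a data
        row is truncated; the error names the offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    header_lineno = None
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in AMINO_ACIDS for t in tokens[:20]):
            header_cols = tokens[:20]
            header_lineno = lineno
            break
    if header_cols is None:
        raise PssmParseError(f"no PSSM header row with amino-acid columns found in {path}")
    # remap: output column c (canonical) <- file column holding that letter
    col_of = {aa: i for i, aa in enumerate(header_cols)}
    if len(col_of) != 20:
        raise PssmParseError("duplicate amino-acid columns in header", header_lineno)
    perm = [col_of[aa] for aa in AMINO_ACIDS]

    residues: list[str] = []
    rows: list[list[int]] = []
    for lineno in range(header_lineno + 1, len(lines) + 1):
        line = lines[lineno - 1]
        if not line.strip():
            break
        m = _ROW_RE.match(line)
        if m is None:
            break  # footer (Lambda / K statistics) or other trailing text
        idx, residue, rest = m.groups()
        cells = rest.split()
        if len(cells) < 20:
            raise PssmParseError(
                f"truncated PSSM row for position {idx}: expected >= 20 score "
                f"columns, found {len(cells)}", lineno)
        try:
            scores = [int(c) for c in cells[:20]]
        except ValueError as exc:
            raise PssmParseError(f"non-integer score cell in row {idx}: {exc}", lineno) from None
        residues.append(residue.upper())
        rows.append([scores[p] for p in perm])

    if not rows:
        raise PssmParseError("PSSM header found but no data rows follow", header_lineno)
    return ProfileMatrix(protein_id=path.stem, residues="".join(residues),
                         scores=np.array(rows, dtype=np.int64))


def normalize_profile(p: ProfileMatrix) -> NormalizedProfile:
    """Map each integer score E through the logistic function 1/(1+e^-E)."""
    with np.errstate(over="ignore"):
        values = 1.0 / (1.0 + np.exp(-p.scores.astype(float)))
    return NormalizedProfile(protein_id=p.protein_id, values=values)


def write_pssm(p: ProfileMatrix, path: str | Path) -> Path:
    """Write ``p`` in the PSI-BLAST ASCII dialect that :func:`read_pssm` reads.

    Emits the log-odds block plus a zero percentage block, so the file is
    shaped like genuine ``-out_ascii_pssm`` output. Intended for tests and
    synthetic fixtures; ``read_pssm(write_pssm(p)) == p`` up to protein id.
    """
    path = Path(path)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
    ]
    header = " " * 11 + "  ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS)
    lines.append(header)
    for i, (residue, row) in enumerate(zip(p.residues, p.scores), start=1):
        scores = " ".join(f"{v:3d}" for v in row)
        pcts = " ".join(f"{0:3d}" for _ in range(20))
        lines.append(f"{i:5d} {residue}  {scores}  {pcts}  0.00 0.00")
    lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path
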