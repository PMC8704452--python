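"""FP2 fingerprint handling for drug compounds.

Drugs are represented by 1024-bit FP2 path-based fingerprints, consumed
here as 256-character hexadecimal strings (e.g. Open Babel's hex output)
and expanded into 256 nibble values in 0..15, leftmost hex character first.
Generating the hex string from a structure is delegated to an external
fingerprinting tool::

    obabel drugs.smi -ofpt -xfFP2   # or the Open Babel API's hex dump

and is never run by this package; tests and fixtures use generated strings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

FP2_HEX_LENGTH = 256
_HEX_DIGITS = set("0123456789abcdef")


class FingerprintFormatError(ValueError):
    """Raised for malformed fingerprint hex strings or tables."""


@dataclass(frozen=True)
class FingerprintVector:
    """256 nibble values (each 0-15) for one drug."""

    drug_id: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", values)
        if values.shape != (FP2_HEX_LENGTH,):
            raise ValueError(f"expected {FP2_HEX_LENGTH} nibbles, got shape {values.shape}")
        if values.min() < 0 or values.max() > 15:
            raise ValueError("nibble values must lie in 0..15")

    def to_hex(self) -> str:
        return "".join(f"{v:x}" for v in self.values)


def parse_fp2_hex(drug_id: str, hex_string: str) -> FingerprintVector:
    """Expand a 256-character hex fingerprint into its nibble vector.

    Case-insensitive; position i of the output is the value of hex
    character i. Raises :class:`FingerprintFormatError` naming the drug and
    the offending position for wrong length or non-hex characters.
    """
    s = hex_string.strip().lower()
    if len(s) != FP2_HEX_LENGTH:
        raise FingerprintFormatError(
            f"drug {drug_id!r}: fingerprint must be {FP2_HEX_LENGTH} hex "
            f"characters, got {len(s)}")
    for pos, ch in enumerate(s):
        if ch not in _HEX_DIGITS:
            raise FingerprintFormatError(
                f"drug {drug_id!r}: non-hexadecimal character {ch!r} at position {pos}")
    return FingerprintVector(drug_id, np.fromiter((int(c, 16) for c in s), dtype=np.int64))


def read_fingerprint_table(path: str | Path) -> list[FingerprintVector]:
    """Read a TSV of (drug_id, hex_string) rows; duplicate ids are an error."""
    path = Path(path)
    out: list[FingerprintVector] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FingerprintFormatError(f"{path}: row with fewer than 2 columns: {row}")
            drug_id, hex_string = row[0], row[1]
            if drug_id in seen:
                raise FingerprintFormatError(f"{path}: duplicate drug id {drug_id!r}")
            seen.add(drug_id)
            out.append(parse_fp2_hex(drug_id, hex_string))
    return out


def write_fingerprint_table(fps: list[FingerprintVector], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for fp in fps:
            writer.writerow([fp.drug_id, fp.to_hex()])
    return path


def fingerprint_feature_names() -> list[str]:
    return [f"fp2_{i:03d}" for i in range(FP2_HEX_LENGTH)]
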