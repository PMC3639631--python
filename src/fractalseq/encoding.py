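"""Atomic-number encoding of nucleotide sequences.

A DNA string becomes a numeric series by mapping each base to the sum of
the atomic numbers of the atoms in its nucleobase:

====  =========  ================================  =====
base  molecule   atomic-number sum                 value
====  =========  ================================  =====
A     C5H5N5     5*6 + 5*1 + 5*7                   70
C     C4H5N3O    4*6 + 5*1 + 3*7 + 8               58
G     C5H5N5O    5*6 + 5*1 + 5*7 + 8               78
T     C5H6N2O2   5*6 + 6*1 + 2*7 + 2*8             66
====  =========  ================================  =====

Uracil (C4H4N2O2) sums to 58 — the same value as cytosine — which is why
RNA input is folded to the DNA alphabet upstream rather than encoded
directly.  The fractal-dimension estimator downstream is invariant to
affine re-mappings of these four values, so any alternative scalar
encoding can be swapped in through :class:`EncodingMap` without changing
the fitted dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .seq_io import NucleotideSequence

BASES = "ACGT"


@dataclass(frozen=True)
class EncodingMap:
    """A scalar value per base, e.g. the atomic-number sums."""

    values: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [b for b in BASES if b not in self.values]
        if missing:
            raise ValueError(f"encoding map {self.name!r} missing bases {missing}")
        for b in BASES:
            if not math.isfinite(float(self.values[b])):
                raise ValueError(f"encoding map {self.name!r}: non-finite value for {b}")

    def as_array(self) -> np.ndarray:
        """Values in A, C, G, T order."""
        return np.array([float(self.values[b]) for b in BASES])


#: default map: per-base sums of constituent atoms' atomic numbers
ATOMIC_NUMBER = EncodingMap(
    values={"A": 70.0, "C": 58.0, "G": 78.0, "T": 66.0},
    name="atomic-number",
)


@dataclass(frozen=True)
class NumericSeries:
    """An ordered real-valued series Int(1..N) derived from a sequence."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError(f"series {self.source_id!r}: need a non-empty 1-D series")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"series {self.source_id!r}: non-finite values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


def encode_atomic(
    seq: Union[NucleotideSequence, str],
    mapping: EncodingMap = ATOMIC_NUMBER,
) -> NumericSeries:
    """Encode a validated sequence as its numeric series.

    Length is preserved and encoding is position-wise, so encoding a
    concatenation equals concatenating the encodings.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence(id="<anonymous>", residues=seq)
    # map bases through a 4-entry lookup table via byte values
    lut = np.zeros(128, dtype=float)
    for b, v in zip(BASES, mapping.as_array()):
        lut[ord(b)] = v
    codes = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    return NumericSeries(values=lut[codes], source_id=seq.id)


def load_encoding_map(path: str | Path, name: str | None = None) -> EncodingMap:
    """Read a ``base=value`` config file (one entry per line, # comments)."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            key, val = line.split("=", 1)
            values[key.strip().upper()] = float(val)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'BASE=value', got {line!r}") from exc
    return EncodingMap(values=values, name=name or path.stem)
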