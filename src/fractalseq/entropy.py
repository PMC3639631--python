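"""Shannon entropy of base and adjacent-pair compositions, in bits.

The mononucleotide entropy is -sum p_b log2 p_b over the four base states
(maximum 2 bits); the dinucleotide entropy is the same functional over the
16 adjacent-pair states (maximum 4 bits).  Pairs are taken overlapping by
default — positions (i, i+1) for i = 1..N-1 — which maximizes counts on
short coding sequences; a step of 2 gives the non-overlapping reading.
Plug-in estimates with the 0*log 0 = 0 convention, no pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats as sps

from .seq_io import NucleotideSequence
from .stats import RegressionResult, ols_fit

MONO_STATES = tuple("ACGT")
DI_STATES = tuple(a + b for a, b in product("ACGT", repeat=2))


@dataclass(frozen=True)
class EntropyResult:
    """Mono- and dinucleotide entropies with their raw count histograms."""

    mono_bits: float
    di_bits: float
    counts_mono: Mapping[str, int]
    counts_di: Mapping[str, int]


def _residues(seq: Union[NucleotideSequence, str]) -> str:
    if isinstance(seq, NucleotideSequence):
        return seq.residues
    return str(seq)


def _entropy_bits(counts: np.ndarray) -> float:
    return float(sps.entropy(counts[counts > 0], base=2))


def mono_counts(seq: Union[NucleotideSequence, str]) -> dict[str, int]:
    r = _residues(seq)
    return {b: r.count(b) for b in MONO_STATES}


def di_counts(seq: Union[NucleotideSequence, str], step: int = 1) -> dict[str, int]:
    r = _residues(seq)
    counts = dict.fromkeys(DI_STATES, 0)
    for i in range(0, len(r) - 1, step):
        counts[r[i : i + 2]] += 1
    return counts


def mono_entropy(seq: Union[NucleotideSequence, str]) -> float:
    """Base-composition entropy in bits, in [0, 2]."""
    r = _residues(seq)
    if len(r) < 1:
        raise ValueError("empty sequence: entropy undefined")
    counts = np.array(list(mono_counts(r).values()), dtype=float)
    return _entropy_bits(counts)


def di_entropy(seq: Union[NucleotideSequence, str], step: int = 1) -> float:
    """Adjacent-pair entropy in bits, in [0, 4]; needs length >= 2."""
    r = _residues(seq)
    if len(r) < 2:
        raise ValueError("need at least 2 residues for dinucleotide entropy")
    if step not in (1, 2):
        raise ValueError(f"di-nucleotide step must be 1 or 2, got {step}")
    counts = np.array(list(di_counts(r, step).values()), dtype=float)
    return _entropy_bits(counts)


def entropy_profile(seq: Union[NucleotideSequence, str], di_step: int = 1) -> EntropyResult:
    """Both entropies plus the 4 + 16 raw counts for one sequence."""
    r = _residues(seq)
    return EntropyResult(
        mono_bits=mono_entropy(r),
        di_bits=di_entropy(r, step=di_step),
        counts_mono=mono_counts(r),
        counts_di=di_counts(r, step=di_step),
    )


def mono_di_correlation(profiles: Sequence[EntropyResult]) -> RegressionResult:
    """Regression of mononucleotide on dinucleotide entropy across sequences.

    Quantifies how tightly the two composition summaries track each other
    over a panel (proportional composition gives R^2 near 1).
    """
    if len(profiles) < 3:
        raise ValueError(f"need at least 3 sequences, got {len(profiles)}")
    di = [p.di_bits for p in profiles]
    mono = [p.mono_bits for p in profiles]
    return ols_fit(di, mono)
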