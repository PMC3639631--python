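"""Composed analyses over the sequence primitives.

Stages:

* per-sequence metric profiling (fractal dimension, mono- and
  dinucleotide entropy, length) for the mRNA, CDS and concatenated
  noncoding roles of each pair;
* the coding-versus-transcript comparison: per-gene dimension deltas,
  CDS/mRNA length ratios, and the panel regression of CDS dimension on
  mRNA dimension (x = mRNA FD, y = CDS FD throughout);
* inclusion/exclusion regressions over named gene subsets, quantifying
  how adding or deleting a group of sequences moves the panel R^2;
* fractal-dimension-versus-entropy maps with explicitly designated
  regression subsets (points left out are reported with their residual
  from the fitted line — outliers are never auto-detected);
* per-gene skewness of expression-level distributions across brain
  regions.

Per-sequence failures (e.g. a degenerate homopolymer) are recorded on
their row and do not abort a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .encoding import ATOMIC_NUMBER, EncodingMap, encode_atomic
from .entropy import di_entropy, mono_entropy
from .fractal import DEFAULT_MAX_K, DegenerateSeriesError, higuchi_fd
from .seq_io import MrnaCdsPair, NucleotideSequence
from .stats import RegressionResult, SkewnessResult, ols_fit, skewness

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceMetrics:
    """Per-sequence summary: length, fractal dimension, entropies."""

    id: str
    group: str
    role: str
    length: int
    fd: Optional[float]
    mono_bits: Optional[float]
    di_bits: Optional[float]
    error: Optional[str] = None


@dataclass(frozen=True)
class ComparisonRow:
    """One gene's mRNA/CDS comparison (delta = fd_cds - fd_mrna)."""

    gene: str
    fd_mrna: Optional[float]
    fd_cds: Optional[float]
    delta: Optional[float]
    len_ratio: float
    mrna: SequenceMetrics
    cds: SequenceMetrics
    noncoding: Optional[SequenceMetrics]
    error: Optional[str] = None


def sequence_metrics(
    seq: NucleotideSequence,
    group: str = "",
    max_k: int = DEFAULT_MAX_K,
    encoding: EncodingMap = ATOMIC_NUMBER,
    di_step: int = 1,
) -> SequenceMetrics:
    """Profile one sequence; degenerate series yield fd=None plus a message."""
    fd: Optional[float] = None
    mono: Optional[float] = None
    di: Optional[float] = None
    error: Optional[str] = None
    try:
        mono = mono_entropy(seq)
        di = di_entropy(seq, step=di_step)
        fd = higuchi_fd(encode_atomic(seq, encoding), max_k=max_k).fd
    except (DegenerateSeriesError, ValueError) as exc:
        error = str(exc)
        logger.warning("sequence %r: %s", seq.id, error)
    return SequenceMetrics(
        id=seq.id, group=group or seq.id, role=seq.role, length=len(seq),
        fd=fd, mono_bits=mono, di_bits=di, error=error,
    )


def compare_fd(
    pairs: Sequence[MrnaCdsPair],
    max_k: int = DEFAULT_MAX_K,
    encoding: EncodingMap = ATOMIC_NUMBER,
    di_step: int = 1,
) -> list[ComparisonRow]:
    """Profile every pair; one row per pair, failures recorded per row."""
    if not pairs:
        raise ValueError("need at least one mRNA/CDS pair")
    rows: list[ComparisonRow] = []
    for pair in pairs:
        m = sequence_metrics(pair.mrna, pair.gene, max_k, encoding, di_step)
        c = sequence_metrics(pair.cds, pair.gene, max_k, encoding, di_step)
        nc: Optional[SequenceMetrics] = None
        if pair.noncoding is not None and len(pair.noncoding) > 0:
            nc = sequence_metrics(pair.noncoding, pair.gene, max_k, encoding, di_step)
        error = m.error or c.error
        delta = None
        if m.fd is not None and c.fd is not None:
            delta = c.fd - m.fd
        rows.append(
            ComparisonRow(
                gene=pair.gene, fd_mrna=m.fd, fd_cds=c.fd, delta=delta,
                len_ratio=pair.len_ratio, mrna=m, cds=c, noncoding=nc, error=error,
            )
        )
    return rows


def _valid_rows(rows: Iterable[ComparisonRow]) -> list[ComparisonRow]:
    return [r for r in rows if r.fd_mrna is not None and r.fd_cds is not None]


def fd_regression(rows: Sequence[ComparisonRow]) -> RegressionResult:
    """Panel regression of CDS dimension on mRNA dimension."""
    ok = _valid_rows(rows)
    return ols_fit([r.fd_mrna for r in ok], [r.fd_cds for r in ok])


def fd_vs_ratio(rows: Sequence[ComparisonRow], which: str = "mrna") -> RegressionResult:
    """Regression of fractal dimension on the CDS/mRNA length ratio."""
    if which not in ("mrna", "cds"):
        raise ValueError(f"which must be 'mrna' or 'cds', got {which!r}")
    ok = _valid_rows(rows)
    fd = [r.fd_mrna if which == "mrna" else r.fd_cds for r in ok]
    return ols_fit([r.len_ratio for r in ok], fd)


def inclusion_study(
    rows: Sequence[ComparisonRow],
    subsets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One CDS-on-mRNA regression per named gene subset.

    Output rows follow the mapping's order; an undersized or otherwise
    degenerate subset contributes an error entry instead of aborting the
    batch.  n always equals the size of the requested selection that
    carried usable dimensions.
    """
    by_gene: dict[str, list[ComparisonRow]] = {}
    for r in rows:
        by_gene.setdefault(r.gene, []).append(r)
    records = []
    for name, genes in subsets.items():
        selected = [r for g in genes for r in by_gene.get(g, [])]
        ok = _valid_rows(selected)
        rec: dict[str, object] = {"subset": name, "n": len(ok)}
        try:
            missing = [g for g in genes if g not in by_gene]
            if missing:
                raise ValueError(f"unknown genes {missing}")
            fit = ols_fit([r.fd_mrna for r in ok], [r.fd_cds for r in ok])
            rec.update(
                r2=fit.r2, adjusted_r2=fit.adjusted_r2,
                slope=fit.slope, intercept=fit.intercept, error="",
            )
        except ValueError as exc:
            rec.update(
                r2=np.nan, adjusted_r2=np.nan, slope=np.nan, intercept=np.nan,
                error=str(exc),
            )
            logger.warning("subset %r: %s", name, exc)
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["subset", "n", "r2", "adjusted_r2", "slope", "intercept", "error"],
    )


def fd_entropy_map(
    metrics: Sequence[SequenceMetrics],
    entropy_kind: str = "di",
    regress_on: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, RegressionResult]:
    """Entropy against fractal dimension across sequences.

    ``regress_on`` designates, by group label, the points that define the
    fitted line (all points when omitted); the remaining points are kept
    in the table with ``in_fit=False`` and their residual from the line.
    Exclusion is always explicit — the function never decides for itself
    that a point is an outlier.
    """
    if entropy_kind not in ("mono", "di"):
        raise ValueError(f"entropy_kind must be 'mono' or 'di', got {entropy_kind!r}")
    usable = [
        m for m in metrics
        if m.fd is not None and (m.mono_bits if entropy_kind == "mono" else m.di_bits) is not None
    ]
    if regress_on is None:
        fit_set = list(usable)
    else:
        wanted = set(regress_on)
        fit_set = [m for m in usable if m.group in wanted]
    def _y(m: SequenceMetrics) -> float:
        return m.mono_bits if entropy_kind == "mono" else m.di_bits  # type: ignore[return-value]
    fit = ols_fit([m.fd for m in fit_set], [_y(m) for m in fit_set])
    records = []
    for m in usable:
        resid = _y(m) - (fit.slope * m.fd + fit.intercept)  # type: ignore[operator]
        records.append(
            {
                "id": m.id, "group": m.group, "role": m.role,
                "fd": m.fd, "entropy_bits": _y(m),
                "in_fit": m in fit_set, "residual": resid,
            }
        )
    points = pd.DataFrame.from_records(
        records, columns=["id", "group", "role", "fd", "entropy_bits", "in_fit", "residual"],
    )
    return points, fit


def expression_skewness(
    table: pd.DataFrame,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Per-gene skewness of expression values, ranked most-skewed first.

    ``table`` is gene-by-region (rows genes, columns region samples).
    Non-finite cells abort with their coordinates; a constant gene row
    becomes an error entry while the rest of the table is processed.
    """
    values = table.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        coords = [f"({table.index[i]}, {table.columns[j]})" for i, j in bad[:10]]
        raise ValueError(f"non-finite expression values at {', '.join(coords)}")
    records = []
    for gene in table.index:
        row = table.loc[gene].to_numpy(dtype=float)
        try:
            res: SkewnessResult = skewness(row, adjusted=adjusted)
            records.append(
                {"gene": gene, "n": res.n, "skewness": res.skewness,
                 "mean": res.mean, "sd": res.sd, "error": ""}
            )
        except ValueError as exc:
            records.append(
                {"gene": gene, "n": len(row), "skewness": np.nan,
                 "mean": np.nan, "sd": np.nan, "error": str(exc)}
            )
            logger.warning("gene %r: %s", gene, exc)
    frame = pd.DataFrame.from_records(
        records, columns=["gene", "n", "skewness", "mean", "sd", "error"],
    )
    frame = frame.sort_values("skewness", ascending=False, kind="stable").reset_index(drop=True)
    return frame


def skewness_ratio(skew_table: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Ratio of two genes' skewness values (the "factor difference")."""
    s = skew_table.set_index("gene")["skewness"]
    for g in (gene_a, gene_b):
        if g not in s.index or not np.isfinite(s[g]):
            raise ValueError(f"no skewness available for gene {g!r}")
    if s[gene_b] == 0:
        raise ValueError(f"gene {gene_b!r} has zero skewness; ratio undefined")
    return float(s[gene_a] / s[gene_b])


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Flatten comparison rows into a table (one row per gene)."""
    records = []
    for r in rows:
        records.append(
            {
                "gene": r.gene,
                "fd_mrna": r.fd_mrna, "fd_cds": r.fd_cds, "delta": r.delta,
                "len_ratio": r.len_ratio,
                "mrna_length": r.mrna.length, "cds_length": r.cds.length,
                "mono_bits_mrna": r.mrna.mono_bits, "mono_bits_cds": r.cds.mono_bits,
                "di_bits_mrna": r.mrna.di_bits, "di_bits_cds": r.cds.di_bits,
                "fd_noncoding": r.noncoding.fd if r.noncoding else np.nan,
                "error": r.error or "",
            }
        )
    return pd.DataFrame.from_records(records)


def metrics_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Long-format per-sequence metrics for all roles of all pairs."""
    records = []
    for r in rows:
        for m in (r.mrna, r.cds, r.noncoding):
            if m is None:
                continue
            records.append(
                {
                    "id": m.id, "gene": m.group, "role": m.role, "length": m.length,
                    "fd": m.fd, "mono_bits": m.mono_bits, "di_bits": m.di_bits,
                    "error": m.error or "",
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["id", "gene", "role", "length", "fd", "mono_bits", "di_bits", "error"],
    )
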