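"""Synthetic data with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed.  The module provides:

* i.i.d. and first-order-Markov nucleotide sequences with controlled
  composition (null models for the entropy and fractal estimators);
* fractional Brownian motion paths of known Hurst exponent H, whose
  theoretical fractal dimension 2 - H calibrates the Higuchi estimator;
* mRNA/CDS pairs whose fractal dimensions are *planted* on a chosen
  linear relation, emulating the shape of real coding-versus-transcript
  panels (a near-collinear majority with CDS dimension above the mRNA's,
  plus a minority of off-line pairs whose CDS dimension falls below);
* gene-by-region expression tables with controlled skewness, emulating
  brain-wide expression z-score distributions (168 regions per donor,
  4 donors by default).

Fractal-dimension planting works by bisection on a single fluctuation
parameter ``theta`` of a Markov family: ``theta`` near +1 gives persistent
(smooth, low-dimension) sequences, 0 gives i.i.d. (dimension ~2), and
negative values give anti-persistent alternation pushing the dimension
slightly above 2.  No closed form links transition matrices to Higuchi
dimensions, so targets are hit by search, to a declared tolerance, with an
explicit error when a target lies outside the attainable band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .encoding import NumericSeries, encode_atomic
from .fractal import DEFAULT_MAX_K, higuchi_fd
from .seq_io import MrnaCdsPair, NucleotideSequence, build_pair

BASES = "ACGT"

# partner map for the anti-persistent regime: preferring a high-contrast
# partner of the current base makes lag-1 jumps large relative to lag-2,
# lifting the fractal dimension above 2
_PARTNER = {"A": "G", "G": "C", "C": "G", "T": "C"}

#: theta interval on which the fluctuation family's dimension is monotone
THETA_RANGE = (-0.6, 0.95)


def gen_iid_sequence(
    n: int,
    probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    id: str = "iid",
) -> NucleotideSequence:
    """Length-n i.i.d. draw over A, C, G, T with the given probabilities."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError(f"probabilities must be 4 nonnegative values summing to 1, got {probs}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=n, p=p / p.sum())
    residues = "".join(BASES[i] for i in idx)
    return NucleotideSequence(id=id, residues=residues)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state row-stochastic matrix."""
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_markov_sequence(
    n: int,
    transition: np.ndarray,
    seed: int = 0,
    id: str = "markov",
) -> NucleotideSequence:
    """First-order Markov chain over A, C, G, T, started from stationarity.

    Sampling uses one uniform per step through the row's inverse CDF, so
    two calls with the same seed but nearby transition matrices produce
    strongly coupled sequences — which is what makes bisection on a chain
    parameter behave smoothly.
    """
    P = np.asarray(transition, dtype=float)
    if P.shape != (4, 4) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition must be a 4x4 row-stochastic matrix")
    if n < 1:
        raise ValueError("sequence length must be positive")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    pi_cum = np.cumsum(stationary_distribution(P))
    state = int(np.searchsorted(pi_cum, u[0] * pi_cum[-1]))
    out = [state]
    for i in range(1, n):
        state = int(np.searchsorted(cum[state], u[i] * cum[state, -1]))
        out.append(state)
    residues = "".join(BASES[s] for s in out)
    return NucleotideSequence(id=id, residues=residues)


def fluctuation_transition(theta: float) -> np.ndarray:
    """One-parameter Markov family interpolating smooth to rough series.

    ``theta >= 0``: repeat the current base with probability
    0.25 + 0.75*theta, otherwise move uniformly to one of the other three
    (theta = 0 is i.i.d. uniform, theta -> 1 near-homopolymer).
    ``theta < 0``: move to a fixed high-contrast partner base with
    probability 0.25 + 0.75*|theta|, otherwise uniformly to one of the
    remaining three — an anti-persistent regime whose encoded series has
    large lag-1 fluctuations.
    """
    if not -1.0 < theta < 1.0:
        raise ValueError(f"theta must be in (-1, 1), got {theta}")
    p = 0.25 + 0.75 * abs(theta)
    P = np.zeros((4, 4))
    for i, b in enumerate(BASES):
        pref = b if theta >= 0 else _PARTNER[b]
        j = BASES.index(pref)
        P[i, :] = (1.0 - p) / 3.0
        P[i, j] = p
    return P


def gen_fbm_series(
    n: int,
    hurst: float,
    seed: int = 0,
    id: Optional[str] = None,
) -> NumericSeries:
    """Fractional Brownian motion path of length n via circulant embedding.

    Fractional Gaussian noise with the exact autocovariance
    ``0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)`` is synthesized spectrally
    (Davies-Harte) and cumulated.  The path's theoretical fractal
    dimension is 2 - H.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError("need n >= 2 for an fBm path")
    rng = np.random.default_rng(seed)
    m = 2 * n
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # clip tiny negative rounding errors
    z = rng.standard_normal(2 * n)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * z[0]
    w[n] = np.sqrt(lam[n] / m) * z[1]
    i = np.arange(1, n)
    w[i] = np.sqrt(lam[i] / (2 * m)) * (z[2 : n + 1] + 1j * z[n + 1 : 2 * n])
    w[m - i] = np.conj(w[i])
    noise = np.fft.fft(w).real[:n]
    path = np.cumsum(noise)
    return NumericSeries(values=path, source_id=id or f"fbm_H{hurst:g}")


class UnattainableTargetError(ValueError):
    """A planted fractal dimension outside the generator's attainable band."""


def _fd_of(seq: NucleotideSequence, max_k: int) -> float:
    return higuchi_fd(encode_atomic(seq), max_k=max_k).fd


def _bisect_theta(
    target_fd: float,
    build: Callable[[float], NucleotideSequence],
    max_k: int,
    tol: float,
    max_iter: int,
    label: str,
) -> tuple[NucleotideSequence, float]:
    """Find theta whose generated sequence has the target dimension.

    ``build`` must reuse a fixed seed so the dimension is a near-monotone
    (decreasing) function of theta.  Returns the sequence and achieved fd.
    """
    lo, hi = THETA_RANGE
    f_lo = _fd_of(build(lo), max_k)   # roughest end, highest fd
    f_hi = _fd_of(build(hi), max_k)   # smoothest end, lowest fd
    if not (f_hi - tol <= target_fd <= f_lo + tol):
        raise UnattainableTargetError(
            f"{label}: planted fd {target_fd:.4f} outside attainable band "
            f"[{f_hi:.4f}, {f_lo:.4f}]"
        )
    best_seq, best_err = None, np.inf
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        seq = build(mid)
        fd = _fd_of(seq, max_k)
        err = abs(fd - target_fd)
        if err < best_err:
            best_seq, best_err, best_fd = seq, err, fd
        if err <= 0.25 * tol:
            break
        if fd > target_fd:
            lo = mid
        else:
            hi = mid
    if best_err > tol:
        raise UnattainableTargetError(
            f"{label}: bisection missed planted fd {target_fd:.4f} "
            f"(best error {best_err:.4f} > tolerance {tol})"
        )
    return best_seq, best_fd


@dataclass(frozen=True)
class PairPanel:
    """A planted panel: the pairs plus a table of targets and achieved values."""

    pairs: list[MrnaCdsPair]
    planted: pd.DataFrame


def gen_pair_panel(
    n_pairs: int = 15,
    slope: float = 1.2,
    intercept: float = -0.4,
    noise_sd: float = 0.002,
    n_offline: int = 2,
    offline_residual: float = -0.020,
    fd_mrna_range: tuple[float, float] = (2.025, 2.075),
    cds_length: int = 1200,
    len_ratio_range: tuple[float, float] = (0.35, 0.65),
    max_k: int = DEFAULT_MAX_K,
    tol: float = 0.003,
    max_iter: int = 40,
    seed: int = 0,
) -> PairPanel:
    """mRNA/CDS pairs with fractal dimensions planted on a linear relation.

    The majority ("core") pairs have mRNA dimensions evenly spaced over
    ``fd_mrna_range`` and CDS dimensions on the line
    ``slope * fd_mrna + intercept`` plus Gaussian noise of ``noise_sd``;
    with the defaults the line lies above the diagonal over the range, so
    core CDS dimensions exceed their mRNA's.  ``n_offline`` additional
    pairs sit in the lower part of the range with CDS dimensions displaced
    ``offline_residual`` below the line, giving them *negative* CDS-minus-
    mRNA deltas — the shape that degrades the panel regression when they
    are included.

    Each pair is built in two stages: the CDS is generated by bisection on
    the fluctuation parameter until its dimension hits the planted CDS
    value, then flanking noncoding regions are generated (one shared
    parameter for both flanks) by bisection until the concatenated mRNA
    hits the planted mRNA value.  Achieved dimensions are within ``tol``
    of planted ones or generation fails loudly.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if not 0 <= n_offline <= n_pairs:
        raise ValueError("n_offline must be between 0 and n_pairs")
    rng = np.random.default_rng(seed)
    n_core = n_pairs - n_offline

    lo, hi = fd_mrna_range
    targets: list[tuple[str, float, float, bool]] = []
    core_x = np.linspace(lo, hi, n_core) if n_core > 1 else np.array([0.5 * (lo + hi)])
    noise = rng.normal(0.0, noise_sd, size=n_core)
    if n_core >= 3 and noise_sd > 0:
        # orthogonalize the scatter against the planted x so the core
        # panel's sample regression line is the planted line exactly;
        # per-point deviations keep standard deviation noise_sd
        design = np.column_stack([np.ones(n_core), core_x])
        coef, *_ = np.linalg.lstsq(design, noise, rcond=None)
        noise = noise - design @ coef
        noise *= noise_sd / noise.std(ddof=1)
    for j, x in enumerate(core_x[:n_core]):
        y = slope * x + intercept + noise[j]
        targets.append((f"gene{j + 1:02d}", float(x), float(y), True))
    span = hi - lo
    for j in range(n_offline):
        # interior placement: leverage stays modest, so the off-line
        # residual reliably degrades the all-pairs regression
        x = lo + span * (0.15 + 0.15 * j)
        y = slope * x + intercept + offline_residual
        targets.append((f"gene{n_core + j + 1:02d}", float(x), float(y), False))

    pairs: list[MrnaCdsPair] = []
    records = []
    for gene, fd_m_target, fd_c_target, is_core in targets:
        pair_seed = int(rng.integers(0, 2**31 - 1))
        ratio = float(rng.uniform(*len_ratio_range))
        mrna_len = int(round(cds_length / ratio))
        flank5_len = (mrna_len - cds_length) // 2
        flank3_len = mrna_len - cds_length - flank5_len

        def build_cds(theta: float) -> NucleotideSequence:
            return gen_markov_sequence(
                cds_length, fluctuation_transition(theta),
                seed=pair_seed, id=f"{gene}_cds",
            )

        cds, fd_c = _bisect_theta(
            fd_c_target, build_cds, max_k, tol, max_iter, f"{gene} CDS",
        )

        def build_mrna(theta: float) -> NucleotideSequence:
            P = fluctuation_transition(theta)
            f5 = gen_markov_sequence(flank5_len, P, seed=pair_seed + 1, id="f5")
            f3 = gen_markov_sequence(flank3_len, P, seed=pair_seed + 2, id="f3")
            return NucleotideSequence(
                id=f"{gene}_mrna",
                residues=f5.residues + cds.residues + f3.residues,
            )

        mrna, fd_m = _bisect_theta(
            fd_m_target, build_mrna, max_k, tol, max_iter, f"{gene} mRNA",
        )
        mrna = NucleotideSequence(mrna.id, mrna.residues, role="mrna")
        cds_rec = NucleotideSequence(cds.id, cds.residues, role="cds")
        pairs.append(
            build_pair(gene, mrna, cds_rec, flank5_len + 1, flank5_len + cds_length)
        )
        records.append(
            {
                "gene": gene,
                "core": is_core,
                "fd_mrna_planted": fd_m_target,
                "fd_cds_planted": fd_c_target,
                "fd_mrna_achieved": fd_m,
                "fd_cds_achieved": fd_c,
                "mrna_length": mrna_len,
                "cds_length": cds_length,
            }
        )
    return PairPanel(pairs=pairs, planted=pd.DataFrame.from_records(records))


#: the four planted expression distributions, keyed by a descriptive gene
#: label, with target skewness of the region-wise z-score distribution
DEFAULT_GENE_SKEWS: Mapping[str, float] = {
    "HCRTR2": 0.91,
    "EPOR": 0.04,
    "HCRT": 2.2,
    "EPO": 1.1,
}


def _lognormal_sigma_for_skew(target: float) -> float:
    """Shape parameter of a lognormal with the given (positive) skewness."""

    def skew_of(s: float) -> float:
        w = np.exp(s * s)
        return (w + 2.0) * np.sqrt(w - 1.0)

    return float(brentq(lambda s: skew_of(s) - target, 1e-9, 3.0))


def gen_expression_table(
    genes: Mapping[str, float] = DEFAULT_GENE_SKEWS,
    n_regions: int = 168,
    n_patients: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-by-region expression z-score table with planted skewness.

    Rows are genes, columns region/donor samples (``n_regions`` regions
    for each of ``n_patients`` donors).  A gene with target skew 0 draws
    from a normal; nonzero targets draw from a standardized lognormal
    whose shape parameter is solved to give that population skewness
    (negated for negative targets).  Each row is standardized to mean 0,
    standard deviation 1 (a location/scale change, which leaves skewness
    untouched).
    """
    if n_regions < 3:
        raise ValueError("need at least 3 regions per donor")
    if n_patients < 1:
        raise ValueError("need at least one donor")
    for g, s in genes.items():
        if not np.isfinite(s):
            raise ValueError(f"gene {g!r}: skew target must be finite")
    rng = np.random.default_rng(seed)
    n = n_regions * n_patients
    columns = [
        f"R{r + 1:03d}_P{p + 1}" for p in range(n_patients) for r in range(n_regions)
    ]
    rows = {}
    for gene, target in genes.items():
        if target == 0.0:
            v = rng.standard_normal(n)
        else:
            sigma = _lognormal_sigma_for_skew(abs(target))
            v = rng.lognormal(mean=0.0, sigma=sigma, size=n)
            if target < 0:
                v = -v
        v = (v - v.mean()) / v.std(ddof=1)
        rows[gene] = v
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
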