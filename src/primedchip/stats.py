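"""Normalisations and statistical primitives.

Two test primitives carry the analysis:

* a paired count test that compares two conditions replicate by replicate —
  each replicate's counts (a_k, b_k) are tested against the library-size null
  proportion with an exact upper-tail binomial, the per-replicate evidence is
  converted to signed normal scores and Stouffer-combined, and a two-sided p
  is taken from the combined Z.  It replaces a negative-binomial differential
  caller while staying exact at small counts and respecting pairing.
* an exact Wilcoxon signed-rank test whose null distribution is the full
  2^n sign-flip distribution (computed by shift-convolution) up to n = 25,
  with a tie-corrected, continuity-corrected normal approximation beyond
  that.

Everything operates on plain numpy arrays / pandas objects; matrix-level
helpers vectorise the per-gene tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormalizedMatrix

Z_CLAMP = 8.0  # per-replicate normal scores are clamped to +/- this

EXACT_WILCOXON_MAX_N = 25


@dataclass
class TestResult:
    """One test outcome (Wilcoxon W or Stouffer-combined Z)."""

    statistic: float
    p_value: float
    effect: float = np.nan
    direction: str = "none"  # {up, down, none}
    q_value: float = np.nan
    z_scores: np.ndarray | None = None  # per-replicate signed normal scores
    null_proportions: np.ndarray | None = None  # per-replicate binomial null pi_k


@dataclass
class CorrelationResult:
    r: float
    n: int
    transform: str  # {sqrtRPM, log2ratio, identity}


# ---------------------------------------------------------------------------
# Normalisations
# ---------------------------------------------------------------------------

def rpm(counts: np.ndarray | pd.Series, library_size: float) -> np.ndarray | pd.Series:
    """Reads per million mapped reads: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return counts * (1e6 / library_size)


def rpkm(
    counts: np.ndarray | pd.Series,
    unit_lengths: np.ndarray | pd.Series,
    library_size: float,
) -> np.ndarray | pd.Series:
    """Reads per kilobase per million: count * 1e9 / (length * library_size)."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    lengths = np.asarray(unit_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("unit lengths must be > 0")
    return counts * (1e9 / library_size) / unit_lengths


def rpm_matrix(cm: CountMatrix) -> NormalizedMatrix:
    vals = cm.counts / cm.library_sizes * 1e6
    return NormalizedMatrix(vals, scale="RPM", samples=cm.samples)


def rpkm_matrix(cm: CountMatrix) -> NormalizedMatrix:
    vals = (cm.counts / cm.library_sizes * 1e9).div(cm.unit_lengths, axis=0)
    return NormalizedMatrix(vals, scale="RPKM", samples=cm.samples)


def add_half_min_pseudocount(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Add half of the smallest strictly positive value to every entry.

    Half of the minimum of a matrix that contains zeros can only usefully mean
    half of the positive minimum; the offset is recorded on the result.
    """
    vals = matrix.values.to_numpy()
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("cannot pseudocount an all-zero matrix")
    offset = positive.min() / 2.0
    return NormalizedMatrix(
        matrix.values + offset, scale=matrix.scale,
        pseudocount=matrix.pseudocount + offset, samples=matrix.samples,
    )


def average_replicates(values: pd.DataFrame, columns: list[str]) -> pd.Series:
    """Arithmetic mean of the given replicate columns."""
    return values[columns].mean(axis=1)


def log2_ratio(
    numerator: pd.DataFrame | pd.Series, denominator: pd.DataFrame | pd.Series
) -> pd.Series:
    """Per-gene log2(num/den); replicate columns are averaged before the ratio."""
    num = numerator.mean(axis=1) if isinstance(numerator, pd.DataFrame) else numerator
    den = denominator.mean(axis=1) if isinstance(denominator, pd.DataFrame) else denominator
    if (num <= 0).any() or (den <= 0).any():
        raise ValueError("log2_ratio requires strictly positive inputs; pseudocount first")
    return np.log2(num / den)


def zscore_rows(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Row z-scores with population (divisor-n) sd; constant rows map to zero."""
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("zscore_rows requires >= 2 columns")
    centred = vals.sub(vals.mean(axis=1), axis=0)
    sd = vals.std(axis=1, ddof=0)
    z = centred.div(sd.replace(0.0, np.inf), axis=0)
    return NormalizedMatrix(z, scale="zscore", samples=matrix.samples)


def sqrt_pearson(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> CorrelationResult:
    """Pearson correlation of (sqrt x, sqrt y) for non-negative RPM vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("sqrt_pearson requires paired vectors of length >= 3")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("sqrt_pearson requires non-negative inputs")
    sx, sy = np.sqrt(x), np.sqrt(y)
    if sx.std() == 0 or sy.std() == 0:
        raise ValueError("zero variance after sqrt transform")
    r = sps.pearsonr(sx, sy).statistic
    return CorrelationResult(r=float(r), n=len(x), transform="sqrtRPM")


def pearson(x, y, transform: str = "identity") -> CorrelationResult:
    r = sps.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic
    return CorrelationResult(r=float(r), n=len(x), transform=transform)


# ---------------------------------------------------------------------------
# Paired count test (binomial per replicate + Stouffer combination)
# ---------------------------------------------------------------------------

def binomial_upper_tail(a, n, pi):
    """P(X >= a) for X ~ Binomial(n, pi); vectorised."""
    return sps.binom.sf(np.asarray(a) - 1, n, pi)


def _stouffer_from_counts(
    a: np.ndarray, b: np.ndarray, a_libs: np.ndarray, b_libs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Combined Z and two-sided p per gene from (genes x replicates) counts."""
    a = np.atleast_2d(np.asarray(a, dtype=np.int64))
    b = np.atleast_2d(np.asarray(b, dtype=np.int64))
    a_libs = np.asarray(a_libs, dtype=float)
    b_libs = np.asarray(b_libs, dtype=float)
    if (a_libs <= 0).any() or (b_libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    n = a + b
    pi = a_libs / (a_libs + b_libs)  # per-replicate null proportion
    with np.errstate(divide="ignore"):
        p_upper = binomial_upper_tail(a, n, pi)
        z = -ndtri(p_upper)  # == ndtri(1 - p_upper), accurate for small tails
    z = np.clip(z, -Z_CLAMP, Z_CLAMP)
    informative = n > 0  # replicates with no counts at all carry no evidence
    z = np.where(informative, z, 0.0)
    k = informative.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = z.sum(axis=1) / np.sqrt(k)
    Z = np.where(k > 0, Z, 0.0)
    p = np.where(k > 0, 2.0 * ndtr(-np.abs(Z)), 1.0)
    return Z, p


def paired_count_test_matrix(
    a_counts: np.ndarray | pd.DataFrame,
    b_counts: np.ndarray | pd.DataFrame,
    a_libsizes: np.ndarray,
    b_libsizes: np.ndarray,
) -> pd.DataFrame:
    """Vectorised paired count test over a genes x replicates count pair.

    Returns a DataFrame with Z, two-sided p, BH q, the pseudocounted mean-RPM
    fold change a/b, and a direction label per gene.
    """
    index = a_counts.index if isinstance(a_counts, pd.DataFrame) else None
    A = np.asarray(a_counts, dtype=np.int64)
    B = np.asarray(b_counts, dtype=np.int64)
    if A.shape != B.shape:
        raise ValueError("a_counts and b_counts must have the same shape")
    Z, p = _stouffer_from_counts(A, B, a_libsizes, b_libsizes)
    # effect: fold change of pseudocounted mean RPM (a over b)
    a_rpm = (A / np.asarray(a_libsizes, float) * 1e6).mean(axis=1)
    b_rpm = (B / np.asarray(b_libsizes, float) * 1e6).mean(axis=1)
    both = np.concatenate([a_rpm, b_rpm])
    positive = both[both > 0]
    offset = positive.min() / 2.0 if positive.size else 0.5
    fc = (a_rpm + offset) / (b_rpm + offset)
    direction = np.where(Z > 0, "up", np.where(Z < 0, "down", "none"))
    out = pd.DataFrame(
        {
            "statistic": Z,
            "p_value": p,
            "q_value": bh_adjust(p),
            "effect": fc,
            "direction": direction,
        }
    )
    if index is not None:
        out.index = index
    return out


def paired_count_test(
    a_counts, b_counts, a_libsizes, b_libsizes
) -> TestResult:
    """Single-gene paired count test; see :func:`paired_count_test_matrix`."""
    a = np.asarray(a_counts, dtype=np.int64).reshape(1, -1)
    b = np.asarray(b_counts, dtype=np.int64).reshape(1, -1)
    res = paired_count_test_matrix(a, b, np.asarray(a_libsizes), np.asarray(b_libsizes))
    row = res.iloc[0]
    n = (a + b)[0]
    pi = np.asarray(a_libsizes, float) / (np.asarray(a_libsizes, float) + np.asarray(b_libsizes, float))
    with np.errstate(divide="ignore"):
        z = np.clip(-ndtri(sps.binom.sf(a[0] - 1, n, pi)), -Z_CLAMP, Z_CLAMP)
    z = np.where(n > 0, z, 0.0)
    direction = "none" if (n == 0).all() else str(row["direction"])
    return TestResult(
        statistic=float(row["statistic"]),
        p_value=float(row["p_value"]),
        effect=float(row["effect"]),
        direction=direction,
        z_scores=z,
        null_proportions=pi,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(d))  # midranks
    w_pos = float(ranks[d > 0].sum())
    return w_pos, ranks


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Two-sided exact p over the 2^n sign-flip distribution.

    The distribution of W+ is computed by shift-convolution, which enumerates
    the same 2^n sign assignments without materialising them.  Midranks from
    tied |d| are half-integers, so the convolution runs on doubled ranks.
    """
    ranks2 = np.round(ranks * 2).astype(np.int64)  # midranks doubled -> integers
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_pos * 2))
    p_ge = counts[w2:].sum()
    p_le = counts[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Paired Wilcoxon signed-rank test of x vs y (or one-sample vs 0).

    Zero differences are dropped; exact two-sided p for n <= 25 by sign-flip
    enumeration (midranks for ties), tie-corrected normal approximation with
    continuity correction for larger n.  All-zero differences give W = 0,
    p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if y is not None and len(x) != len(d):
        raise ValueError("x and y must have equal length")
    if len(d) < 1:
        raise ValueError("empty sample")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, effect=0.0, direction="none")
    w_pos, ranks = _signed_rank_stat(d)
    if n <= EXACT_WILCOXON_MAX_N:
        # sign-flip enumeration conditions on |d|, so midranks from ties are
        # handled exactly too
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            p = 1.0
        else:
            diff = w_pos - mean
            cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
            z = (diff - cc) / np.sqrt(var)
            p = float(min(1.0, 2.0 * ndtr(-abs(z))))
    med = float(np.median(d))
    direction = "up" if med > 0 else ("down" if med < 0 else "none")
    return TestResult(statistic=w_pos, p_value=p, effect=med, direction=direction)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
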