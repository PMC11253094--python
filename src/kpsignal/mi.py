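"""Histogram (plug-in) mutual information between voltage channels.

MI between two channels X and Y is estimated by binning both series on
equal-width grids over their observed ranges, normalizing the joint
histogram into p(x, y), forming marginals by summation, and evaluating

    I(X; Y) = sum_xy p(x,y) log2[ p(x,y) / (p(x) p(y)) ]      (bits)

with the 0*log 0 := 0 convention.  The channel-by-channel MI matrix puts
the marginal entropy H(X) = I(X; X) on the diagonal, so diagonal entries
bound the off-diagonal shared information.  The plug-in estimator is
biased upward by roughly (B-1)^2 / (2 N ln 2) for B bins and N samples;
no correction is applied by default (Miller-Madow is available behind a
flag) so values are directly comparable with plain histogram estimates.

Binning defaults to B = 10 equal-width bins per axis.  A rank mode bins
the rank-transformed series instead, making MI invariant under strictly
monotone rescaling of either channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, rankdata

from .recording import VoltageRecording

__all__ = [
    "JointHistogram",
    "MIMatrix",
    "joint_histogram",
    "joint_probability",
    "entropy",
    "mutual_information",
    "mi_matrix",
    "max_cross_correlation",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 10


@dataclass
class JointHistogram:
    """B x B joint counts with bin edges; counts sum to n."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n: int


@dataclass
class MIMatrix:
    """Symmetric channel x channel MI (bits); diagonal = marginal entropy."""

    values: np.ndarray
    channels: list[str]
    bins: int


def _prepare(x, y, bins):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    for name, s in (("x", x), ("y", y)):
        if np.min(s) == np.max(s):
            logger.warning("constant %s series: single occupied bin, entropy 0", name)
    return x, y


def _edges(s: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(np.min(s)), float(np.max(s))
    if lo == hi:  # degenerate span: one occupied bin on a token interval
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(x, y, bins: int = DEFAULT_BINS,
                    rank: bool = False) -> JointHistogram:
    """Equal-width joint histogram over the observed [min, max] spans."""
    x, y = _prepare(x, y, bins)
    if rank:
        x, y = rankdata(x), rankdata(y)
    xe, ye = _edges(x, bins), _edges(y, bins)
    counts, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    return JointHistogram(counts=counts.astype(int), x_edges=xe, y_edges=ye,
                          n=x.size)


def joint_probability(x, y, bins: int = DEFAULT_BINS, rank: bool = False
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint distribution p(x, y) plus marginals (normalized histogram).

    p sums to 1; p(x) and p(y) are its row and column sums.
    """
    h = joint_histogram(x, y, bins=bins, rank=rank)
    p = h.counts / h.n
    return p, p.sum(axis=1), p.sum(axis=0)


def _plugin_mi_bits(p: np.ndarray) -> float:
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = p[mask] / (px @ py)[mask]
    return float(np.sum(p[mask] * np.log2(ratio)))


def entropy(x, bins: int = DEFAULT_BINS, rank: bool = False) -> float:
    """Marginal (Shannon) entropy of the binned series, in bits."""
    x = np.asarray(x, dtype=float).ravel()
    if rank:
        x = rankdata(x)
    counts, _ = np.histogram(x, bins=_edges(x, bins))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def mutual_information(x, y, bins: int = DEFAULT_BINS, rank: bool = False,
                       miller_madow: bool = False) -> float:
    """Plug-in MI estimate in bits; symmetric and >= 0 up to rounding.

    ``miller_madow`` applies the first-order occupied-cell bias correction
    to each entropy term; the default is the uncorrected plug-in value.
    """
    p, px, py = joint_probability(x, y, bins=bins, rank=rank)
    mi = _plugin_mi_bits(p)
    if miller_madow:
        n = np.asarray(x).size
        kx, ky, kxy = np.count_nonzero(px), np.count_nonzero(py), np.count_nonzero(p)
        mi += ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n * np.log(2.0))
    return mi


def mi_matrix(recording: VoltageRecording, bins: int = DEFAULT_BINS,
              rank: bool = False) -> MIMatrix:
    """All-pairs MI matrix with marginal entropies on the diagonal.

    Each unordered pair is computed once and mirrored, so the matrix is
    exactly symmetric.
    """
    if recording.n_channels < 2:
        raise ValueError("need at least 2 channels for an MI matrix")
    c = recording.n_channels
    m = np.zeros((c, c))
    for i in range(c):
        m[i, i] = entropy(recording.values[:, i], bins=bins, rank=rank)
        for j in range(i + 1, c):
            v = mutual_information(recording.values[:, i], recording.values[:, j],
                                   bins=bins, rank=rank)
            m[i, j] = m[j, i] = v
    return MIMatrix(values=m, channels=list(recording.channels), bins=bins)


def max_cross_correlation(x, y, max_lag: int) -> tuple[float, int]:
    """Maximum lagged Pearson correlation and the lag achieving it.

    The correlation at lag L compares ``x[t]`` with ``y[t + L]``, so a
    positive returned lag means features in ``y`` trail those in ``x``.
    Ties prefer the smallest |lag|.  Raises on zero-variance overlaps
    (undefined correlation).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if not (0 <= max_lag < x.size):
        raise ValueError("need 0 <= max_lag < len(x)")

    best = (-np.inf, 0)
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            a, b = x[: x.size - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: y.size + lag]
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError(f"zero-variance overlap at lag {lag}")
        r = float(pearsonr(a, b).statistic)
        if r > best[0]:
            best = (r, lag)
    return best
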