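"""Spectrum-spectrum similarity measures on pairs of binned, L2-normalized
spectra.

The primary ranking score is the dot product (cosine similarity of unit
vectors). The remaining measures feed the validation feature vector:

* ``libc_cos_sim`` — library-centric cosine similarity: cosine computed with
  the query norm *reduced* to the bins matched by the library spectrum, so a
  query containing the whole library spectrum plus extra (e.g. chimeric)
  signal is not punished for the extra signal.
* ``xcorr`` — cross-correlation: aligned dot product minus the mean dot
  product over +-75-bin shifts of the library spectrum.
* ``pcc`` / ``kendall_tau`` — Pearson and Kendall tau-b correlation of the
  two intensity profiles.
* ``hgt`` — hypergeometric tail score: -log10 of the probability of seeing
  at least the observed number of matched bins by chance.
* ``dot_bias`` / ``penalty`` / ``delta_d`` / ``fval`` — concentration of the
  dot product on few bins, the piecewise penalty it incurs, the relative
  drop to the runner-up candidate, and their linear combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

from .preprocess import BinnedSpectrum

XCORR_WINDOW = 75  # +- shift range in 1-Th bins


@dataclass(frozen=True)
class ScoreSet:
    """All pairwise similarity scores for one spectrum-spectrum match."""

    dot: float
    libc_cosSim: float
    xcorr: float
    pcc: float
    kt: float
    hgt: float
    dotBias: float
    deltaD: float
    penalty: float
    fval: float


def _require_normalized(*spectra: BinnedSpectrum) -> None:
    for s in spectra:
        if not s.normalized:
            raise ValueError("similarity measures require L2-normalized spectra")


def dot_product(q: BinnedSpectrum, l: BinnedSpectrum) -> float:
    """Cosine similarity: sum of products over shared bins; in [0, 1]."""
    _require_normalized(q, l)
    small, large = (q.bins, l.bins) if len(q.bins) <= len(l.bins) else (l.bins, q.bins)
    return sum(v * large[k] for k, v in small.items() if k in large)


def libc_cos_sim(q: BinnedSpectrum, l: BinnedSpectrum) -> float:
    """Library-centric cosine similarity.

    Only query bins matched by the library spectrum enter the query norm:
    (sum_M q_i * l_i) / (||q|_M|| * ||l||), where M is the set of bins
    positive in both spectra; 0 when M is empty. Always >= dot_product.
    """
    _require_normalized(q, l)
    num = 0.0
    q_norm_sq = 0.0
    for k, qv in q.bins.items():
        lv = l.bins.get(k)
        if lv is not None and qv > 0 and lv > 0:
            num += qv * lv
            q_norm_sq += qv * qv
    if q_norm_sq == 0:
        return 0.0
    return num / sqrt(q_norm_sq)  # ||l|| = 1


def xcorr(q: BinnedSpectrum, l: BinnedSpectrum, window: int = XCORR_WINDOW) -> float:
    """Aligned dot minus the mean dot over library shifts tau in [-w, w], tau != 0."""
    _require_normalized(q, l)
    if window < 1:
        raise ValueError("xcorr window must be >= 1")
    aligned = dot_product(q, l)
    # background: for each query bin, sum library mass landing on it under
    # each shift; accumulate over the offset differences directly.
    background = 0.0
    for kq, qv in q.bins.items():
        for kl, lv in l.bins.items():
            tau = kq - kl  # library shifted by tau aligns bin kl onto kq
            if tau != 0 and -window <= tau <= window:
                background += qv * lv
    return aligned - background / (2 * window)


def pcc(q: BinnedSpectrum, l: BinnedSpectrum) -> float:
    """Pearson correlation over the union of the non-zero bins; 0 if constant."""
    support = sorted(set(q.bins) | set(l.bins))
    if len(support) < 2:
        return 0.0
    x = np.array([q.bins.get(k, 0.0) for k in support])
    y = np.array([l.bins.get(k, 0.0) for k in support])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def kendall_tau(q: BinnedSpectrum, l: BinnedSpectrum) -> float:
    """Kendall tau-b of intensities over matched bins; 0 when < 2 matches."""
    matched = [k for k in q.bins if k in l.bins
               and q.bins[k] > 0 and l.bins[k] > 0]
    if len(matched) < 2:
        return 0.0
    x = [q.bins[k] for k in matched]
    y = [l.bins[k] for k in matched]
    tau = stats.kendalltau(x, y).statistic
    return 0.0 if np.isnan(tau) else float(tau)


def hgt(q: BinnedSpectrum, l: BinnedSpectrum,
        n_bins_population: int | None = None) -> float:
    """Hypergeometric tail score -log10 P(X >= k), clipped at 0.

    N is the population of bins (by default the span of the union of the two
    binned m/z ranges), K the library's positive bins, n the query's
    positive bins, and k the number of matched bins.
    """
    q_support = {k for k, v in q.bins.items() if v > 0}
    l_support = {k for k, v in l.bins.items() if v > 0}
    if not q_support or not l_support:
        return 0.0
    if n_bins_population is None:
        union = q_support | l_support
        n_bins_population = max(union) - min(union) + 1
    N = int(n_bins_population)
    K = len(l_support)
    n = len(q_support)
    k = len(q_support & l_support)
    if N < max(K, n):
        raise ValueError(f"population N={N} smaller than support sizes "
                         f"(K={K}, n={n})")
    if k > min(K, n):
        raise ValueError("matched bins exceed the smaller support")
    if k == 0:
        return 0.0
    p_tail = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_tail = min(max(p_tail, 1e-300), 1.0)
    return max(0.0, -np.log10(p_tail))


def dot_bias(q: BinnedSpectrum, l: BinnedSpectrum) -> float:
    """Concentration of the dot product: sqrt(sum (q_i l_i)^2) / dot; 0 if dot=0."""
    _require_normalized(q, l)
    d = 0.0
    sq = 0.0
    small, large = (q.bins, l.bins) if len(q.bins) <= len(l.bins) else (l.bins, q.bins)
    for k, v in small.items():
        w = large.get(k)
        if w is not None:
            prod = v * w
            d += prod
            sq += prod * prod
    if d == 0:
        return 0.0
    return sqrt(sq) / d


def delta_d(best_dot: float, second_dot: float) -> float:
    """Relative drop from the best to the second-best dot product.

    1.0 when there is no runner-up (second = 0); 0 when best = 0.
    """
    if best_dot < second_dot:
        raise ValueError("best dot must be >= second dot")
    if second_dot < 0:
        raise ValueError("second dot must be >= 0")
    if best_dot == 0:
        return 0.0
    return (best_dot - second_dot) / best_dot


def penalty(dot_bias_value: float) -> float:
    """Piecewise-constant penalty on extreme dot-bias values.

    Very low bias (the dot spread thinly over many tiny products) or high
    bias (dominated by one or two peaks) are both suspicious and penalized.
    """
    if dot_bias_value < 0:
        raise ValueError("dot bias must be >= 0")
    b = dot_bias_value
    if b < 0.09:
        return 0.12
    if b > 0.45:
        return 0.24
    if b > 0.40:
        return 0.18
    if b > 0.35:
        return 0.12
    return 0.0


def fval(dot: float, deltaD: float, penalty_value: float) -> float:
    """Discriminant combination 0.6*dot + 0.4*deltaD - penalty."""
    return 0.6 * dot + 0.4 * deltaD - penalty_value


def score_pair(q: BinnedSpectrum, l: BinnedSpectrum,
               best_dot: float, second_dot: float) -> ScoreSet:
    """Compute the full score set for a query against its best candidate."""
    d = dot_product(q, l)
    dd = delta_d(best_dot, second_dot)
    db = dot_bias(q, l)
    pen = penalty(db)
    return ScoreSet(
        dot=d,
        libc_cosSim=libc_cos_sim(q, l),
        xcorr=xcorr(q, l),
        pcc=pcc(q, l),
        kt=kendall_tau(q, l),
        hgt=hgt(q, l),
        dotBias=db,
        deltaD=dd,
        penalty=pen,
        fval=fval(d, dd, pen),
    )
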