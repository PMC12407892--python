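"""Spike-count autocorrelation.

The autocorrelogram of binned spike counts ``A(t'_i)`` at lag ``t_j = j*dt``
is estimated as

    AC(t_j) = 1 / (sigma2 * (N - j)) * sum_{i=1}^{N-j}
              (A(t'_i) - mu1(j)) * (A(t'_{i+j}) - mu2(j)),

with the single global sample variance

    sigma2 = 1/(N-1) * [ sum A_i^2 - (1/N) (sum A_i)^2 ],

and the two windowed means mu1(j) (first N-j bins) and mu2(j) (last N-j
bins). At lag 0 this estimator equals (N-1)/N exactly for any non-constant
series, so the zero-lag value carries no information about dynamics; fits
start at the first lag or later (see :func:`find_fit_start`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .spikes import BinnedCounts

__all__ = [
    "Autocorrelogram",
    "DegenerateSeriesError",
    "compute_autocorrelogram",
    "autocorrelation_bruteforce",
    "find_fit_start",
    "DEFAULT_MAX_LAG",
]

#: Default maximum fitted lag in seconds.
DEFAULT_MAX_LAG = 5.0


class DegenerateSeriesError(ValueError):
    """Raised when the count series is constant (zero sample variance)."""


@dataclass(frozen=True)
class Autocorrelogram:
    """Lagged correlation estimates of a binned count series.

    ``lags`` are in seconds starting at 0; ``ac[j]`` is the estimate at lag
    ``lags[j]``. ``sample_variance`` is the global normalizer; ``mean_head``
    and ``mean_tail`` hold the per-lag windowed means of the original and
    shifted series.
    """

    lags: np.ndarray
    ac: np.ndarray
    sample_variance: float
    mean_head: np.ndarray
    mean_tail: np.ndarray
    bin_width: float
    n_bins: int
    unit_id: object = None

    @property
    def max_lag(self) -> float:
        return float(self.lags[-1])


def compute_autocorrelogram(counts: BinnedCounts,
                            max_lag: float = DEFAULT_MAX_LAG) -> Autocorrelogram:
    """Autocorrelation of binned counts up to ``max_lag`` seconds.

    Cross-products over all lags are accumulated with a single FFT
    correlation; the windowed means come from cumulative sums, so the
    whole autocorrelogram is O(N log N).
    """
    a = np.asarray(counts.counts, dtype=float)
    n = a.size
    dt = counts.bin_width
    max_j = int(round(max_lag / dt))
    if max_j < 1:
        raise ValueError("max_lag must cover at least one bin")
    if n <= max_j + 1:
        raise ValueError("series too short for requested max_lag")

    total = a.sum()
    sq = np.dot(a, a)
    sigma2 = (sq - total * total / n) / (n - 1)
    if sigma2 <= 0:
        raise DegenerateSeriesError(
            "constant count series: sample variance is zero")

    # cross(j) = sum_i a_i * a_{i+j}; full autocorrelation via FFT.
    m = max_j + 1
    cross = fftconvolve(a, a[::-1], mode="full")[n - 1:n - 1 + m]
    # enforce exactness at lag 0 against FFT round-off
    cross[0] = sq

    csum = np.concatenate(([0.0], np.cumsum(a)))
    j = np.arange(m)
    win = n - j
    head = csum[n - j] - csum[0]        # sum of first N-j entries
    tail = csum[n] - csum[j]            # sum of last N-j entries
    mu1 = head / win
    mu2 = tail / win
    ac = (cross - win * mu1 * mu2) / (sigma2 * win)
    return Autocorrelogram(
        lags=j * dt, ac=ac, sample_variance=float(sigma2),
        mean_head=mu1, mean_tail=mu2, bin_width=dt, n_bins=n,
        unit_id=counts.unit_id)


def autocorrelation_bruteforce(a: np.ndarray, max_j: int) -> np.ndarray:
    """Literal double-loop evaluation of the lagged-correlation estimator.

    Independent oracle for :func:`compute_autocorrelogram`; O(N*max_j),
    intended for short series only.
    """
    a = np.asarray(a, dtype=float)
    n = a.size
    sigma2 = (np.sum(a ** 2) - np.sum(a) ** 2 / n) / (n - 1)
    out = np.empty(max_j + 1)
    for j in range(max_j + 1):
        mu1 = np.mean(a[:n - j])
        mu2 = np.mean(a[j:])
        s = 0.0
        for i in range(n - j):
            s += (a[i] - mu1) * (a[i + j] - mu2)
        out[j] = s / (sigma2 * (n - j))
    return out


def find_fit_start(ac: Autocorrelogram, search_horizon: int = 20) -> int:
    """Earliest lag at which the autocorrelation begins to decay.

    Some units show refractory-like dips at the first lags before the
    autocorrelation peaks and decays; fitting starts at the peak. The rule
    is the argmax of AC over lags ``1..search_horizon`` (ties broken toward
    the earliest lag), so monotonically decaying units return 1.
    """
    if search_horizon < 1:
        raise ValueError("search_horizon must be >= 1")
    hi = min(search_horizon, len(ac.ac) - 1)
    window = ac.ac[1:hi + 1]
    return int(np.argmax(window)) + 1
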