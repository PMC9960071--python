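"""Single-channel amplitude analysis.

All-point histograms over baseline-subtracted sweeps, Gaussian-mixture
peak fitting (the dominant non-baseline peak gives the open-channel
amplitude at each voltage), linear conductance regression, slope-equality
testing between two conductance lines, and the percent reduction of GHK
absolute permeability between external-K+ conditions.

The analyzer takes pre-filtered data as given; the acquisition low-pass
(200 Hz digital filter) is modelled in the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "AmplitudeHistogram",
    "GaussianPeaks",
    "all_point_histogram",
    "baseline_subtract",
    "fit_gaussian_peaks",
    "conductance_from_iv",
    "compare_slopes",
    "permeability_reduction",
]

DEFAULT_BIN_WIDTH_PA = 0.01


@dataclass
class AmplitudeHistogram:
    """All-point amplitude histogram of single-channel sweeps."""

    bin_edges: np.ndarray      # pA, len = n_bins + 1
    counts: np.ndarray         # integer counts
    n_sweeps: int
    voltage_mV: float | None = None
    flags: list[str] = field(default_factory=list)
    _samples: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def baseline_subtract(sweep, closed_mask=None, offset: float | None = None):
    """Subtract the closed-state baseline from one sweep.

    Default baseline is the median of the closed-state segment (or of the
    whole sweep when ``closed_mask`` is None — adequate when the channel is
    closed most of the time); a constant ``offset`` overrides.
    """
    y = np.asarray(sweep, dtype=float)
    if offset is None:
        ref = y[np.asarray(closed_mask, bool)] if closed_mask is not None else y
        offset = float(np.median(ref))
    return y - offset


def all_point_histogram(sweeps, bin_width: float = DEFAULT_BIN_WIDTH_PA,
                        voltage_mV: float | None = None) -> AmplitudeHistogram:
    """All-point histogram over baseline-subtracted sweeps.

    Every sample is binned exactly once; total count equals the number of
    included samples.  A bin width larger than the signal range collapses
    the histogram to a single bin, which is flagged.
    """
    arrs = [np.asarray(s, dtype=float).ravel() for s in sweeps]
    if not arrs or sum(a.size for a in arrs) == 0:
        raise ValueError("no samples supplied")
    data = np.concatenate(arrs)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(data.min() / bin_width) * bin_width
    hi = np.ceil(data.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(data, bins=edges)
    flags = ["single_bin"] if n_bins == 1 else []
    return AmplitudeHistogram(edges, counts, n_sweeps=len(arrs),
                              voltage_mV=voltage_mV, flags=flags,
                              _samples=data)


@dataclass
class GaussianPeaks:
    """Gaussian mixture decomposition of an amplitude histogram.

    ``peaks`` are (mean pA, sd pA, weight) sorted by descending weight.
    The baseline (closed) component is the one nearest 0 pA; components
    whose means are not resolved from the baseline (within 2 sd — e.g.
    fragments of a heavy-tailed closed level) count as baseline-like.
    The largest peak is the highest-weight resolved component (mixture
    weight, i.e. area, is bin-width invariant unlike peak height).
    """

    peaks: list[tuple[float, float, float]]
    baseline_index: int
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.peaks)

    @property
    def baseline(self) -> tuple[float, float, float]:
        return self.peaks[self.baseline_index]

    def _baseline_like(self, i: int) -> bool:
        mu_b = self.peaks[self.baseline_index][0]
        mu, sd, _ = self.peaks[i]
        return abs(mu - mu_b) < 2.0 * max(sd, self.peaks[self.baseline_index][1])

    @property
    def largest_peak(self) -> float:
        """Mean (pA) of the dominant open-level (non-baseline) component."""
        for i, (mu, _sd, _w) in enumerate(self.peaks):
            if i != self.baseline_index and not self._baseline_like(i):
                return mu
        return self.peaks[self.baseline_index][0]


def fit_gaussian_peaks(hist: AmplitudeHistogram, k_max: int = 3,
                       random_state: int = 0,
                       max_fit_samples: int = 200_000) -> GaussianPeaks:
    """Fit a Gaussian mixture to an all-point histogram.

    The component count is selected by BIC over k = 1..k_max.  Fitting uses
    the underlying samples when available (subsampled deterministically
    above ``max_fit_samples``), otherwise bin centers repeated by count
    (histogram-resolution quantization).
    """
    if np.count_nonzero(hist.counts) < 2 * k_max:
        raise ValueError("histogram has fewer occupied bins than 2*k_max")
    if hist._samples is not None:
        data = hist._samples
    else:
        data = np.repeat(hist.bin_centers, hist.counts)
    if data.size > max_fit_samples:
        rng = np.random.default_rng(random_state)
        data = rng.choice(data, size=max_fit_samples, replace=False)
    X = data.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, n_init=3,
                             random_state=random_state)
        gm.fit(X)
        bic = gm.bic(X)
        if gm.converged_ and bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    if best is None:
        return GaussianPeaks([(float(data.mean()), float(data.std()), 1.0)],
                             0, converged=False)
    mus = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    ws = best.weights_.ravel()
    order = np.argsort(ws)[::-1]
    peaks = [(float(mus[i]), float(sds[i]), float(ws[i])) for i in order]
    baseline = int(np.argmin([abs(p[0]) for p in peaks]))
    return GaussianPeaks(peaks, baseline, converged=True)


def conductance_from_iv(voltage_mV, amplitude_pA):
    """Single-channel chord conductance by linear regression.

    Returns (slope_pS, intercept_pA, slope_stderr_pS, reversal_mV).
    Slope in pS = (pA/mV) * 1000; the reversal potential is the x-intercept
    of the fitted line (nan for a zero-slope line, which is degenerate).
    """
    v = np.asarray(voltage_mV, dtype=float)
    i = np.asarray(amplitude_pA, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 voltages")
    res = stats.linregress(v, i)
    slope_pS = res.slope * 1000.0
    rev = -res.intercept / res.slope if res.slope != 0.0 else float("nan")
    return (float(slope_pS), float(res.intercept),
            float(res.stderr * 1000.0), float(rev))


def compare_slopes(x1, y1, x2, y2):
    """Test for equality of two regression slopes (common-slope ANCOVA F).

    Fits an OLS model with a group indicator and group-by-x interaction;
    the F test on the interaction term tests slope equality.  Returns
    (F, p).  Identical data give F = 0, p = 1.
    """
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    n1, n2 = x1.size, x2.size
    if n1 < 3 or n2 < 3:
        raise ValueError("each line needs >= 3 points")
    if np.ptp(x1) == 0.0 or np.ptp(x2) == 0.0:
        raise ValueError("degenerate predictor variance")
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(n1), np.ones(n2)])
    X = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, X).fit()
    # contrast selecting the interaction coefficient
    contrast = np.zeros(X.shape[1])
    contrast[3] = 1.0
    test = fit.f_test(contrast)
    f_val = float(np.squeeze(test.fvalue))
    p_val = float(test.pvalue)
    if not np.isfinite(f_val):  # exactly collinear residual-free case
        f_val, p_val = 0.0, 1.0
    return f_val, p_val


def permeability_reduction(p_low: float, p_high: float) -> float:
    """Percent reduction of absolute permeability from low to high K+o.

    100 * (1 - P_high / P_low); requires P_low > 0.
    """
    if p_low <= 0:
        raise ValueError("P_low must be positive")
    return 100.0 * (1.0 - p_high / p_low)
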