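"""Episodic voltage-clamp traces and trace-level statistics.

Covers the recording container, peak extraction, unspecific-current
subtraction, multi-exponential tail fitting with extrapolation, the
fractional fast-inactivation statistic of hooked tail currents,
reversal-potential estimation, and the relative-inhibition difference
statistic used to compare mutant and wild-type K+o sensitivity.

Sign convention: currents are stored as recorded (outward positive).  The
inactivation statistic works in fitted model space so it applies equally to
inward tails; the ratio X/Y is sign-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "Segment",
    "Recording",
    "TailFitResults",
    "RelativeInhibition",
    "peak_current",
    "subtract_unspecific",
    "fit_tail_multiexp",
    "fractional_inactivation",
    "inactivation_series",
    "delta_I_rel",
    "estimate_reversal",
    "linear_fit_with_correlation",
]

# default analysis cursors within a tail segment: start 7.5 ms after the
# segment start (midpoint of the usual 5-10 ms post-transient placement),
# end at 97% of the segment duration
DEFAULT_CURSOR_START_S = 7.5e-3
DEFAULT_CURSOR_END_FRAC = 0.97


@dataclass(frozen=True)
class Segment:
    """One protocol segment: [t_start, t_end) at a command voltage."""

    label: str
    t_start: float
    t_end: float
    voltage_mV: float

    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Recording:
    """An episodic recording: sweeps sharing one protocol.

    ``sweeps`` is a DataFrame with columns ``sweep`` (int), ``time_s`` and
    ``current``; time is strictly increasing within a sweep and every
    sample falls in exactly one protocol segment.
    """

    sweeps: pd.DataFrame
    protocol: list[Segment]
    sample_rate: float
    solution: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"sweep", "time_s", "current"}
        if not req.issubset(self.sweeps.columns):
            missing = sorted(req - set(self.sweeps.columns))
            raise ValueError(f"sweeps table missing column(s): {missing}")
        for sw, grp in self.sweeps.groupby("sweep"):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"time not strictly increasing in sweep {sw}")
        labels = [s.label for s in self.protocol]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate protocol segment labels")

    def segment(self, label: str) -> Segment:
        for s in self.protocol:
            if s.label == label:
                return s
        raise KeyError(f"no protocol segment {label!r}")

    def segment_data(self, label: str, sweep: int | None = None) -> pd.DataFrame:
        seg = self.segment(label)
        df = self.sweeps
        if sweep is not None:
            df = df[df["sweep"] == sweep]
        out = df[(df["time_s"] >= seg.t_start) & (df["time_s"] < seg.t_end)]
        if out.empty:
            raise ValueError(f"segment {label!r} contains no samples")
        return out

    @property
    def sweep_ids(self) -> list[int]:
        return sorted(self.sweeps["sweep"].unique().tolist())


def peak_current(rec: Recording, segment: str, sweep: int | None = None,
                 direction: str = "auto") -> float:
    """Peak current over an entire protocol segment.

    ``direction``: 'outward' takes the maximum, 'inward' the minimum,
    'auto' takes the outward maximum for depolarizing segments (command
    voltage above the first protocol segment) and the largest-magnitude
    signed excursion otherwise.
    """
    data = rec.segment_data(segment, sweep)["current"].to_numpy()
    if direction == "outward":
        return float(np.max(data))
    if direction == "inward":
        return float(np.min(data))
    if direction != "auto":
        raise ValueError("direction must be 'auto', 'outward' or 'inward'")
    seg = rec.segment(segment)
    if seg.voltage_mV > rec.protocol[0].voltage_mV:
        return float(np.max(data))
    return float(data[np.argmax(np.abs(data))])


def subtract_unspecific(series, blank_mean, n_blanks: int | None = None):
    """Subtract mean unspecific (water-injected oocyte) current point-wise.

    Both arguments are amplitudes taken at identical cursor positions.
    Returns the corrected series; ``n_blanks`` is echoed through for
    book-keeping in reports.
    """
    s = np.asarray(series, dtype=float)
    b = np.asarray(blank_mean, dtype=float)
    if b.ndim == 0:
        b = np.full_like(s, float(b))
    if s.shape != b.shape:
        raise ValueError("series and blank_mean lengths differ")
    return s - b


class TailFitResults:
    """Multi-exponential tail fit with extrapolated amplitudes.

    Model (t relative to the tail-segment start):

        I(t) = a0 + sum_i a_i exp(-t / tau_i)

    fitted between two cursors inside the segment.  Components are sorted
    by time constant.  ``Y`` is the extrapolation of a0 plus all
    deactivating components to the segment start (the total current had no
    channel inactivated); ``X`` the extrapolation of the full model (the
    actual initial open-channel current); the hook (recovery) component is
    the one whose amplitude opposes the deactivation direction.
    """

    def __init__(self, a0, amplitudes, taus, window, t_data, y_data, cov,
                 converged):
        order = np.argsort(taus)
        self.a0 = float(a0)
        self.amplitudes = np.asarray(amplitudes, dtype=float)[order]
        self.taus = np.asarray(taus, dtype=float)[order]
        self.window = tuple(window)
        self.t_data = t_data
        self.y_data = y_data
        self.cov = cov
        self.converged = bool(converged)
        k = len(self.taus)
        if cov is not None:
            bse = np.sqrt(np.abs(np.diag(cov)))
            self.a0_stderr = float(bse[0])
            # parameter order in cov: a0, a1..ak, tau1..tauk (pre-sort)
            amp_se = bse[1:1 + k][order]
            tau_se = bse[1 + k:1 + 2 * k][order]
            self.amplitude_stderr = amp_se
            self.tau_stderr = tau_se
        else:
            self.a0_stderr = np.inf
            self.amplitude_stderr = np.full(k, np.inf)
            self.tau_stderr = np.full(k, np.inf)

    @property
    def n_components(self) -> int:
        return len(self.taus)

    @property
    def components(self) -> list[tuple[float, float]]:
        return list(zip(self.amplitudes.tolist(), self.taus.tolist()))

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.a0)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-t / tau)
        return out

    @property
    def resid(self):
        return self.y_data - self.predict(self.t_data)

    def _polarity(self) -> float:
        """Sign of the net tail deflection relative to a0."""
        return float(np.sign(np.sum(self.amplitudes)))

    def deactivating_mask(self, rel_tol: float = 5e-3) -> np.ndarray:
        """True for components decaying in the tail direction.

        Components with magnitude below ``rel_tol`` of the total amplitude
        are treated as deactivating (numerically absent hooks).
        """
        s = self._polarity()
        total = np.abs(self.amplitudes).sum()
        tiny = np.abs(self.amplitudes) < rel_tol * max(total, 1e-30)
        return (np.sign(self.amplitudes) == s) | tiny

    @property
    def Y(self) -> float:
        """Extrapolated no-inactivation amplitude at the segment start."""
        return self.a0 + float(self.amplitudes[self.deactivating_mask()].sum())

    def X(self, eval_mode: str = "model_t0") -> float:
        """Initial open-channel current.

        'model_t0' extrapolates the full fitted model to the segment start;
        'model_cursor' evaluates it at the first cursor; 'raw_cursor' reads
        the raw sample nearest the first cursor.
        """
        if eval_mode == "model_t0":
            return self.a0 + float(self.amplitudes.sum())
        if eval_mode == "model_cursor":
            return float(self.predict(np.array([self.window[0]]))[0])
        if eval_mode == "raw_cursor":
            idx = int(np.argmin(np.abs(self.t_data - self.window[0])))
            return float(self.y_data[idx])
        raise ValueError("eval_mode must be 'model_t0', 'model_cursor' or "
                         "'raw_cursor'")

    def plot(self, ax=None):
        """Plot the windowed tail data with the fit and its extrapolation
        to the segment start (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t_data, self.y_data, ".", ms=2, label="data")
        grid = np.linspace(0.0, self.t_data.max(), 400)
        ax.plot(grid, self.predict(grid), "-", label="fit (extrapolated)")
        ax.axhline(self.Y, ls="--", lw=0.8, label="Y")
        ax.legend()
        ax.set_xlabel("time from segment start (s)")
        return ax

    def summary(self) -> str:
        lines = [f"tail fit: {self.n_components} components, "
                 f"window [{self.window[0]:.4g}, {self.window[1]:.4g}] s, "
                 f"converged={self.converged}",
                 f"  a0 = {self.a0:.6g} ± {self.a0_stderr:.3g}"]
        for i, (a, tau) in enumerate(self.components, start=1):
            lines.append(f"  a{i} = {a:.6g} ± {self.amplitude_stderr[i-1]:.3g}"
                         f"  tau{i} = {tau:.6g} ± {self.tau_stderr[i-1]:.3g} s")
        lines.append(f"  X = {self.X():.6g}  Y = {self.Y:.6g}")
        return "\n".join(lines)


def _multiexp(t, *params):
    k = (len(params) - 1) // 2
    a0 = params[0]
    out = np.full_like(np.asarray(t, dtype=float), a0)
    for i in range(k):
        out = out + params[1 + i] * np.exp(-t / params[1 + k + i])
    return out


_TAU_START_SCALES = {
    2: [(20.0, 3.0), (50.0, 5.0), (8.0, 1.5)],
    3: [(50.0, 10.0, 2.0), (120.0, 20.0, 4.0), (250.0, 25.0, 2.5)],
}


def _is_degenerate(popt, k, ptp):
    """Detect the classic multi-exponential failure modes: amplitude pairs
    cancelling at nearly coincident time constants, or amplitudes far
    beyond the data range."""
    amps = np.abs(popt[1:1 + k])
    taus = np.sort(popt[1 + k:])
    if np.any(amps > 8.0 * ptp):
        return True
    return bool(np.any(taus[1:] / taus[:-1] < 1.3))


def _fit_multiexp_window(t, y, n_components: int):
    """Fit a0 + sum a_i exp(-t/tau_i) on (t, y); t relative to segment start.

    Multi-start over log-spaced time-constant ladders with linear
    least-squares amplitude initialization; amplitudes are bounded by a
    multiple of the data range and time constants by the window span to
    exclude degenerate optima.  Returns the lowest-SSR non-degenerate
    converged solution (or the best degenerate one, flagged unconverged).
    """
    k = n_components
    span = t[-1] - t[0]
    ptp = float(np.ptp(y)) or 1.0
    lo = np.concatenate([[y.min() - ptp], np.full(k, -10.0 * ptp),
                         np.full(k, max(span * 1e-4, 1e-6))])
    hi = np.concatenate([[y.max() + ptp], np.full(k, 10.0 * ptp),
                         np.full(k, 5.0 * span)])
    best = None
    for scales in _TAU_START_SCALES[k]:
        taus0 = span / np.asarray(scales)
        basis = np.column_stack([np.ones_like(t)] +
                                [np.exp(-t / tau) for tau in taus0])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        p0 = np.clip(np.concatenate([coef, taus0]), lo, hi)
        try:
            popt, pcov = curve_fit(_multiexp, t, y, p0=p0, bounds=(lo, hi),
                                   maxfev=20000, method="trf")
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _multiexp(t, *popt)) ** 2))
        degen = _is_degenerate(popt, k, ptp)
        cand = (degen, ssr, popt, pcov)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        taus0 = span / np.asarray(_TAU_START_SCALES[k][0])
        p0 = np.concatenate([[y.mean()], np.zeros(k), taus0])
        return p0, None, False
    degen, _ssr, popt, pcov = best
    return popt, pcov, not degen


def fit_tail_multiexp(rec: Recording, tail_segment: str,
                      n_components: int = 3,
                      cursors: tuple[float, float] | None = None,
                      sweep: int | None = None,
                      auto_fallback: bool = True) -> TailFitResults:
    """Fit a tail-current segment with 2 or 3 exponentials.

    ``cursors`` are (start, end) in seconds relative to the segment start;
    the default places the first cursor 7.5 ms after the segment start
    (past the capacitive transient) and the second at 97% of the segment.
    With ``auto_fallback`` a 3-component fit whose smallest-|a| component is
    indistinguishable from zero (stderr exceeding |a|) is refit with 2.
    """
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    seg = rec.segment(tail_segment)
    data = rec.segment_data(tail_segment, sweep)
    t = data["time_s"].to_numpy() - seg.t_start
    y = data["current"].to_numpy()
    if sweep is None and len(rec.sweep_ids) > 1:
        # average across sweeps on the common time base
        piv = data.pivot_table(index="time_s", values="current", aggfunc="mean")
        t = piv.index.to_numpy() - seg.t_start
        y = piv["current"].to_numpy()
    if cursors is None:
        cursors = (DEFAULT_CURSOR_START_S,
                   DEFAULT_CURSOR_END_FRAC * seg.duration())
    c0, c1 = cursors
    mask = (t >= c0) & (t <= c1)
    tw, yw = t[mask], y[mask]
    if tw.size < 2 * n_components + 2:
        raise ValueError("fewer points in the cursor window than parameters")
    popt, pcov, converged = _fit_multiexp_window(tw, yw, n_components)
    k = n_components
    fit = TailFitResults(popt[0], popt[1:1 + k], popt[1 + k:], (c0, c1),
                         tw, yw, pcov, converged)
    if auto_fallback and n_components == 3:
        i_min = int(np.argmin(np.abs(fit.amplitudes)))
        undetermined = (fit.amplitude_stderr[i_min]
                        > abs(fit.amplitudes[i_min]))
        if not fit.converged or undetermined:
            fit2 = fit_tail_multiexp(rec, tail_segment, 2, cursors, sweep,
                                     auto_fallback=False)
            if fit2.converged:
                fit = fit2
    return fit


def fractional_inactivation(fit: TailFitResults,
                            x_eval: str = "model_t0") -> float:
    """Fractional fast inactivation 1 - X/Y from a fitted tail.

    X is the initial open-channel current, Y the no-inactivation total
    obtained by extrapolating the constant plus all deactivating
    components to the segment start.  A tail with no recovering (hook)
    component gives 0.  Values outside [0, 1) are clipped with a warning.
    Undefined (raises) when Y = 0.
    """
    y_tot = fit.Y
    if y_tot == 0.0:
        raise ZeroDivisionError("extrapolated total amplitude Y is zero; "
                                "fractional inactivation undefined")
    if bool(np.all(fit.deactivating_mask())):
        return 0.0
    frac = 1.0 - fit.X(x_eval) / y_tot
    if not 0.0 <= frac < 1.0:
        warnings.warn(f"fractional inactivation {frac:.3g} outside [0, 1); "
                      "clipping", stacklevel=2)
        frac = float(np.clip(frac, 0.0, 1.0 - 1e-12))
    return float(frac)


def inactivation_series(fractions_by_axis, axis: str = "prepulse_voltage"
                        ) -> pd.DataFrame:
    """Aggregate per-cell inactivation fractions along a protocol axis.

    ``fractions_by_axis`` is an iterable of (axis_value, fraction) pairs,
    one per recording; duplicates of an axis value are treated as cells and
    aggregated as mean ± SEM.
    """
    rows = list(fractions_by_axis)
    if not rows:
        raise ValueError("no tagged recordings supplied")
    for r in rows:
        if len(r) != 2:
            raise ValueError("expected (axis_value, fraction) pairs")
    df = pd.DataFrame(rows, columns=[axis, "fraction"])
    g = df.groupby(axis)["fraction"]
    out = pd.DataFrame({
        axis: g.mean().index,
        "fraction_mean": g.mean().to_numpy(),
        "fraction_sem": g.sem(ddof=1).to_numpy(),
        "n": g.count().to_numpy(),
    })
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class RelativeInhibition:
    """Mutant-vs-wild-type difference of K+o inhibition.

    delta_I_rel = [1 - I_high(Mut)/I_low(Mut)] - [1 - I_high(WT)/I_low(WT)]

    Negative values mean the mutant is less inhibited (or potentiated)
    relative to wild type.
    """

    ratio_mut: float
    ratio_wt: float
    delta_I_rel: float


def delta_I_rel(mut_low: float, mut_high: float, wt_low: float,
                wt_high: float) -> RelativeInhibition:
    """Relative-inhibition difference between mutant and wild type."""
    if mut_low == 0.0 or wt_low == 0.0:
        raise ZeroDivisionError("reference (low-K+o) amplitude is zero")
    rm = mut_high / mut_low
    rw = wt_high / wt_low
    return RelativeInhibition(rm, rw, (1.0 - rm) - (1.0 - rw))


def estimate_reversal(vm_mV, current) -> float:
    """Reversal potential (mV) by linear interpolation of the zero crossing.

    Requires the instantaneous currents to change sign across the voltage
    range; uses the first bracketing pair in voltage order.
    """
    v = np.asarray(vm_mV, dtype=float)
    i = np.asarray(current, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    exact = np.flatnonzero(i == 0.0)
    if exact.size:
        return float(v[exact[0]])
    sign_change = np.flatnonzero(np.sign(i[:-1]) * np.sign(i[1:]) < 0)
    if sign_change.size == 0:
        raise ValueError("currents do not change sign; reversal not bracketed")
    k = sign_change[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


def linear_fit_with_correlation(x, y):
    """Least-squares line plus the Pearson correlation coefficient.

    Returns (slope, intercept, r).  ``r`` is nan (degenerate, flagged by
    value) when y has zero variance; zero variance in x raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
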