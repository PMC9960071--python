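"""Concentration–response pipeline for external-K+ inhibition.

From per-pulse peak amplitudes recorded under a stepped perfusion protocol
(default 0.2, 2, 5, 20, 100 mM K+o) this module detects stabilization,
retains three points per concentration, subtracts blank (water-injected
oocyte) currents, normalizes to the lowest concentration, applies the GHK
driving-force correction, and fits the Hill inhibition equation per cell
with Table-style aggregate reporting (mean ± SEM over cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophys import ghk_current_ratio
from .constants import T_DEFAULT
from .fitting import CurveFitResults, HillModel

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "StabilizationError",
    "ConcentrationSeries",
    "CorrectedDoseResponse",
    "detect_stabilization",
    "build_series",
    "ghk_correct",
    "two_point_inhibition",
    "DoseResponseExperiment",
    "DoseResponsePooledResults",
    "fit_series",
    "two_sample_ttest",
]

DEFAULT_CONCENTRATIONS = (0.2, 2.0, 5.0, 20.0, 100.0)
DEFAULT_KIN_MM = 108.0  # oocyte internal K+
DEFAULT_VM_MV = 60.0    # depolarizing test potential


class StabilizationError(ValueError):
    """Raised when a pulse series never stabilizes (series excluded)."""


def detect_stabilization(amplitudes, tol: float = 0.05,
                         window: int = 3) -> int:
    """Index of the first stabilized pulse in a pulse-by-pulse series.

    The series is stabilized at index i when the spread (max - min) of the
    ``window`` consecutive pulses starting at i is below ``tol`` of their
    mean.  Raises :class:`StabilizationError` if no window qualifies.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < max(window, 4):
        raise ValueError("need at least 4 pulses")
    for i in range(a.size - window + 1):
        w = a[i:i + window]
        mean = np.abs(w).mean()
        if mean == 0.0 or np.ptp(w) / mean < tol:
            return i
    raise StabilizationError("pulse amplitudes never stabilized")


@dataclass
class ConcentrationSeries:
    """Blank-corrected, stabilized triplets for one cell.

    ``points`` maps concentration (mM) to exactly three retained peak
    amplitudes.  ``reference`` is the mean of the triplet at the lowest
    concentration, used for normalization.
    """

    cell_id: str
    points: dict[float, np.ndarray]
    blank_corrected: bool = False
    n_blanks: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for c, trip in self.points.items():
            trip = np.asarray(trip, dtype=float)
            if trip.size != 3:
                raise ValueError(f"concentration {c} mM: expected exactly "
                                 f"three retained points, got {trip.size}")
            self.points[c] = trip

    @property
    def concentrations(self) -> np.ndarray:
        return np.array(sorted(self.points))

    @property
    def reference(self) -> float:
        return float(self.points[self.concentrations[0]].mean())

    def normalized(self) -> pd.DataFrame:
        """Triplet means normalized to the lowest-concentration mean."""
        ref = self.reference
        if ref == 0.0:
            raise ZeroDivisionError("zero reference amplitude")
        rows = []
        for c in self.concentrations:
            trip = self.points[c] / ref
            rows.append((float(c), trip.mean(),
                         trip.std(ddof=1) / np.sqrt(3)))
        return pd.DataFrame(rows, columns=["conc_mM", "observed_norm",
                                           "observed_sem"])


def build_series(cell_id: str, pulses_by_conc: dict[float, np.ndarray],
                 blanks_by_conc: dict[float, np.ndarray] | None = None,
                 required_max_mM: float = 100.0, tol: float = 0.05,
                 n_blanks: int = 0) -> ConcentrationSeries:
    """Assemble a :class:`ConcentrationSeries` from per-pulse amplitudes.

    ``pulses_by_conc`` maps each concentration to the chronological peak
    amplitudes recorded in that solution; ``blanks_by_conc`` maps to the
    per-pulse blank means (averaged over 3-4 water-injected oocytes at
    identical cursors), subtracted point-wise.  The three points retained
    per concentration start at the stabilization index.  A series that
    never reached ``required_max_mM`` is rejected, mirroring the exclusion
    of recordings that did not reach the 100 mM perfusion step.
    """
    if required_max_mM not in pulses_by_conc:
        raise ValueError(f"series excluded: never reached "
                         f"{required_max_mM} mM perfusion step")
    points: dict[float, np.ndarray] = {}
    for conc, amps in pulses_by_conc.items():
        amps = np.asarray(amps, dtype=float)
        if blanks_by_conc is not None:
            blank = np.asarray(blanks_by_conc[conc], dtype=float)
            if blank.ndim == 0:
                blank = np.full_like(amps, float(blank))
            if blank.shape != amps.shape:
                raise ValueError(f"blank series length mismatch at {conc} mM")
            amps = amps - blank
        idx = detect_stabilization(amps, tol=tol) if amps.size >= 4 else 0
        if idx + 3 > amps.size:
            raise ValueError(f"fewer than three stabilized points at {conc} mM")
        points[float(conc)] = amps[idx:idx + 3]
    return ConcentrationSeries(cell_id, points,
                               blank_corrected=blanks_by_conc is not None,
                               n_blanks=n_blanks)


@dataclass(frozen=True)
class CorrectedDoseResponse:
    """One concentration after GHK driving-force correction."""

    conc_mM: float
    observed_norm: float
    observed_sem: float
    ith: float
    corrected: float


def ghk_correct(norm_table: pd.DataFrame, vm_mV: float = DEFAULT_VM_MV,
                kin_mM: float = DEFAULT_KIN_MM, T: float = T_DEFAULT,
                mode: str = "additive") -> list[CorrectedDoseResponse]:
    """Correct normalized means for the theoretical GHK current reduction.

    The theoretical value Ith(C) is the GHK current ratio between
    concentration C and the reference (lowest) concentration at equal
    internal K+.  'additive' (default) removes the theoretical *reduction*:
    corrected = observed + (1 - Ith); 'multiplicative' divides:
    corrected = observed / Ith.  Both give corrected(reference) = observed.
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError("mode must be 'additive' or 'multiplicative'")
    concs = norm_table["conc_mM"].to_numpy()
    c_ref = concs.min()
    out = []
    for _, row in norm_table.iterrows():
        ith = ghk_current_ratio(kin_mM, row["conc_mM"], kin_mM, c_ref,
                                vm_mV, T)
        obs = row["observed_norm"]
        corr = obs + (1.0 - ith) if mode == "additive" else obs / ith
        out.append(CorrectedDoseResponse(
            float(row["conc_mM"]), float(obs),
            float(row.get("observed_sem", np.nan)), float(ith), float(corr)))
    return out


def two_point_inhibition(series_norm: pd.DataFrame,
                         low_mM: float = 0.2, high_mM: float = 100.0) -> float:
    """Simplified inhibition 1 - I(high)/I(low) from endpoint currents.

    Negative values indicate potentiation by high K+o (the phenotype of
    the F339A/F340A/V310A mutants).
    """
    tab = series_norm.set_index("conc_mM")["observed_norm"]
    for c in (low_mM, high_mM):
        if c not in tab.index:
            raise ValueError(f"endpoint concentration {c} mM missing")
    low = float(tab[low_mM])
    if low == 0.0:
        raise ZeroDivisionError("zero current at the low-K+o endpoint")
    return 1.0 - float(tab[high_mM]) / low


class DoseResponsePooledResults:
    """Per-cell Hill fits and Table-style aggregates.

    ``params_table`` has one row per cell (ic50_mM, imax, nh, converged);
    ``mean``/``sem`` aggregate over cells, matching per-cell mean ± SEM
    reporting.
    """

    def __init__(self, cell_results: dict[str, CurveFitResults],
                 pooled: CurveFitResults | None = None):
        self.cell_results = cell_results
        self.pooled = pooled
        rows = []
        for cid, res in cell_results.items():
            rows.append({"cell": cid, "ic50_mM": res["ic50"],
                         "imax": res["imax"], "nh": res["nh"],
                         "converged": res.converged})
        self.params_table = pd.DataFrame(rows)

    @property
    def n_cells(self) -> int:
        return len(self.cell_results)

    @property
    def converged_table(self) -> pd.DataFrame:
        return self.params_table[self.params_table["converged"]]

    def _agg(self, stat: str) -> pd.Series:
        tab = self.converged_table[["ic50_mM", "imax", "nh"]]
        return tab.mean() if stat == "mean" else tab.sem(ddof=1)

    @property
    def mean(self) -> pd.Series:
        return self._agg("mean")

    @property
    def sem(self) -> pd.Series:
        return self._agg("sem")

    def to_dict(self) -> dict:
        m, s = self.mean, self.sem
        return {
            "ic50_mM": float(m["ic50_mM"]), "ic50_mM_sem": float(s["ic50_mM"]),
            "imax": float(m["imax"]), "imax_sem": float(s["imax"]),
            "nh": float(m["nh"]), "nh_sem": float(s["nh"]),
            "n": int(self.converged_table.shape[0]),
        }

    def summary(self) -> str:
        d = self.to_dict()
        return (f"Hill inhibition, {d['n']} cells (mean ± SEM)\n"
                f"  IC50 = {d['ic50_mM']:.3g} ± {d['ic50_mM_sem']:.2g} mM\n"
                f"  Imax = {d['imax']:.3g} ± {d['imax_sem']:.2g}\n"
                f"  nH   = {d['nh']:.3g} ± {d['nh_sem']:.2g}")


class DoseResponseExperiment:
    """A set of cells measured over the same concentration ladder.

    Built from per-cell corrected dose-response tables (lists of
    :class:`CorrectedDoseResponse` or (conc, corrected) DataFrames);
    ``fit()`` fits each cell with the Hill model and aggregates.
    """

    def __init__(self, cells: dict[str, list[CorrectedDoseResponse]]):
        if not cells:
            raise ValueError("no cells supplied")
        self.cells = cells

    @classmethod
    def from_normalized(cls, norm_tables: dict[str, pd.DataFrame],
                        vm_mV: float = DEFAULT_VM_MV,
                        kin_mM: float = DEFAULT_KIN_MM,
                        T: float = T_DEFAULT, mode: str = "additive"):
        return cls({cid: ghk_correct(tab, vm_mV, kin_mM, T, mode)
                    for cid, tab in norm_tables.items()})

    def fit(self, pooled: bool = False) -> DoseResponsePooledResults:
        per_cell = {}
        all_c, all_y = [], []
        for cid, rows in self.cells.items():
            c = np.array([r.conc_mM for r in rows])
            y = np.array([r.corrected for r in rows])
            per_cell[cid] = HillModel(c, y).fit()
            all_c.append(c)
            all_y.append(y)
        pooled_res = None
        if pooled:
            pooled_res = HillModel(np.concatenate(all_c),
                                   np.concatenate(all_y)).fit()
        return DoseResponsePooledResults(per_cell, pooled_res)


def fit_series(cells: dict[str, list[CorrectedDoseResponse]],
               pooled: bool = False) -> DoseResponsePooledResults:
    """Fit corrected dose-response data per cell and aggregate."""
    return DoseResponseExperiment(cells).fit(pooled=pooled)


def two_sample_ttest(a, b):
    """Plain Welch two-sample t test (t, p) — reporting plumbing."""
    from scipy import stats
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)
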