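"""Selectivity-filter ion-permeation analysis of MD-style z trajectories.

Inputs are per-frame z coordinates (Å) of K+ ions along the pore axis,
relative to a fixed filter reference (by convention the center of mass of
the four G314 carbonyl carbons, z = 0).  The module classifies per-frame
filter occupancy substates (Scav, S4..S0), detects complete permeation
events via an exit-distance criterion, classifies each outward event as
canonical (knock-on: a cavity ion newly binds Scav and triggers the S0
release) or spontaneous-S0 release, measures S0 occupancy split by ion
origin, computes axial density profiles, converts event counts to current,
and summarizes aromatic side-chain dihedral flipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import E_CHARGE

__all__ = [
    "SITE_ORDER",
    "SiteMap",
    "OccupancyFrame",
    "PermeationEvent",
    "classify_substates",
    "detect_permeations",
    "classify_modes",
    "s0_occupancy_by_origin",
    "density_profile",
    "current_from_flux",
    "dihedral_flip_stats",
]

# filter sites ordered internal -> external
SITE_ORDER = ("Scav", "S4", "S3", "S2", "S1", "S0")

DEFAULT_BAND_WIDTH_A = 3.1
DEFAULT_EXIT_OFFSET_A = 6.0   # exit reference above the substate reference
DEFAULT_EXIT_THRESHOLD_A = 4.0
DEFAULT_DEBOUNCE_FRAMES = 2


@dataclass(frozen=True)
class SiteMap:
    """Axial band definition of the filter sites.

    ``bands`` maps each site name to (lower, upper) z in Å; bands are
    non-overlapping and ordered internal -> external.  z below the lowest
    band is 'internal', z at or above the top band's upper edge is
    'external'.  Permeation completes when an ion passes
    ``exit_reference + exit_threshold``.

    The band boundaries are package defaults (canonical K+-channel site
    spacing), not literature values, and are fully configurable.
    """

    bands: dict[str, tuple[float, float]]
    exit_reference: float = DEFAULT_EXIT_OFFSET_A
    exit_threshold: float = DEFAULT_EXIT_THRESHOLD_A

    def __post_init__(self):
        prev_upper = -np.inf
        for name in SITE_ORDER:
            if name not in self.bands:
                raise ValueError(f"missing band for site {name}")
            lo, hi = self.bands[name]
            if not lo < hi:
                raise ValueError(f"band {name} has non-positive width")
            if lo < prev_upper:
                raise ValueError(f"band {name} overlaps its inner neighbour")
            prev_upper = hi

    @classmethod
    def default(cls, band_width: float = DEFAULT_BAND_WIDTH_A,
                s2_center: float = 0.0,
                exit_reference: float = DEFAULT_EXIT_OFFSET_A,
                exit_threshold: float = DEFAULT_EXIT_THRESHOLD_A) -> "SiteMap":
        """Evenly spaced bands with S2 centered near the filter reference."""
        half = band_width / 2.0
        centers = {name: s2_center + band_width * (i - SITE_ORDER.index("S2"))
                   for i, name in enumerate(SITE_ORDER)}
        bands = {n: (c - half, c + half) for n, c in centers.items()}
        return cls(bands, exit_reference, exit_threshold)

    @property
    def internal_boundary(self) -> float:
        return self.bands[SITE_ORDER[0]][0]

    @property
    def external_boundary(self) -> float:
        return self.bands[SITE_ORDER[-1]][1]

    @property
    def exit_z(self) -> float:
        return self.exit_reference + self.exit_threshold

    def site_of(self, z: float) -> str:
        """Site label for one z ('internal'/'external' outside the filter)."""
        if z < self.internal_boundary:
            return "internal"
        for name in SITE_ORDER:
            lo, hi = self.bands[name]
            if lo <= z < hi:
                return name
        return "external"

    def site_codes(self, z: np.ndarray) -> np.ndarray:
        """Vectorized site classification: -1 internal, 0..5 filter sites
        (SITE_ORDER index), 6 external.  z falling in a gap between two
        bands maps to the band with the nearest center."""
        z = np.asarray(z, dtype=float)
        out = np.full(z.shape, -1, dtype=int)
        for i, name in enumerate(SITE_ORDER):
            lo, hi = self.bands[name]
            out[(z >= lo) & (z < hi)] = i
        out[z < self.internal_boundary] = -1
        out[z >= self.external_boundary] = len(SITE_ORDER)
        # gap frames: assign to nearest band edge
        gap = (out == -1) & (z >= self.internal_boundary)
        if np.any(gap):
            centers = np.array([(self.bands[n][0] + self.bands[n][1]) / 2.0
                                for n in SITE_ORDER])
            out[gap] = np.argmin(np.abs(z[gap, None] - centers[None, :]),
                                 axis=1)
        return out

    def to_dict(self) -> dict:
        return {"bands": {k: list(v) for k, v in self.bands.items()},
                "exit_reference_A": self.exit_reference,
                "exit_threshold_A": self.exit_threshold}

    @classmethod
    def from_dict(cls, d: dict) -> "SiteMap":
        return cls({k: tuple(v) for k, v in d["bands"].items()},
                   d.get("exit_reference_A", DEFAULT_EXIT_OFFSET_A),
                   d.get("exit_threshold_A", DEFAULT_EXIT_THRESHOLD_A))


@dataclass(frozen=True)
class OccupancyFrame:
    """Occupied-site tuple of one frame, rendered internal -> external."""

    time_ns: float
    sites: tuple[str, ...]
    flagged: bool = False

    @property
    def label(self) -> str:
        return "-".join(self.sites) if self.sites else "empty"


@dataclass(frozen=True)
class PermeationEvent:
    """One complete pore passage."""

    ion_id: int
    time_ns: float              # completion time (exit-threshold crossing)
    direction: str              # 'outward' | 'inward'
    mode: str = "unassigned"    # 'canonical' | 'spontaneous_S0' | 'other'


def _tracks_to_frames(tracks: pd.DataFrame):
    """Validate the shared time base and pivot to (times, ions, Z matrix)."""
    req = {"time_ns", "ion_id", "z_A"}
    if not req.issubset(tracks.columns):
        missing = sorted(req - set(tracks.columns))
        raise ValueError(f"trajectory table missing column(s): {missing}")
    piv = tracks.pivot_table(index="time_ns", columns="ion_id", values="z_A")
    times = piv.index.to_numpy(dtype=float)
    if times.size > 2:
        steps = np.diff(times)
        if steps.max() - steps.min() > 1e-6 * max(steps.mean(), 1e-12):
            warnings.warn("non-uniform frame step detected", stacklevel=3)
    return times, piv.columns.to_numpy(), piv.to_numpy()


def classify_substates(tracks: pd.DataFrame, sites: SiteMap
                       ) -> list[OccupancyFrame]:
    """Per-frame filter occupancy labels.

    Each frame reports the tuple of occupied filter sites in
    internal -> external order (ions in bulk are ignored).  Two ions in
    one band violate single-file occupancy: the frame is kept but flagged
    and a warning is issued.
    """
    times, ions, Z = _tracks_to_frames(tracks)
    out = []
    n_flagged = 0
    for fi, t in enumerate(times):
        z = Z[fi]
        codes = sites.site_codes(z[np.isfinite(z)])
        in_filter = codes[(codes >= 0) & (codes < len(SITE_ORDER))]
        uniq, counts = np.unique(in_filter, return_counts=True)
        flagged = bool(np.any(counts > 1))
        if flagged:
            n_flagged += 1
        occupied = tuple(SITE_ORDER[i] for i in sorted(uniq))
        out.append(OccupancyFrame(float(t), occupied, flagged))
    if n_flagged:
        warnings.warn(f"{n_flagged} frame(s) with two ions in one band "
                      "(retained, flagged)", stacklevel=2)
    return out


def substate_distribution(frames: list[OccupancyFrame],
                          exclude_flagged: bool = True) -> pd.Series:
    """Occupancy-substate probabilities over frames."""
    labels = [f.label for f in frames if not (exclude_flagged and f.flagged)]
    s = pd.Series(labels).value_counts(normalize=True)
    s.name = "probability"
    return s


def _debounced_zones(z: np.ndarray, lo: float, hi: float,
                     debounce: int) -> np.ndarray:
    """Zone sequence (-1 below lo, +1 at/above hi, 0 between) requiring a
    zone to persist ``debounce`` frames before it registers."""
    raw = np.zeros(z.size, dtype=int)
    raw[z < lo] = -1
    raw[z >= hi] = 1
    if debounce <= 1:
        return raw
    out = np.empty_like(raw)
    current = raw[0]
    run_val, run_len = raw[0], 1
    out[0] = current
    for i in range(1, raw.size):
        if raw[i] == run_val:
            run_len += 1
        else:
            run_val, run_len = raw[i], 1
        if run_val != current and run_len >= debounce:
            current = run_val
        out[i] = current
    return out


def detect_permeations(tracks: pd.DataFrame, sites: SiteMap,
                       debounce: int = DEFAULT_DEBOUNCE_FRAMES
                       ) -> list[PermeationEvent]:
    """Detect complete pore passages from the ion z tracks.

    An outward event completes when an ion last seen on the internal side
    (below the lowest filter band) reaches beyond
    ``exit_reference + exit_threshold``; inward events are the reverse.
    An ion that re-enters and exits again yields multiple events.  A short
    debounce (in frames) suppresses boundary chatter.
    """
    times, ions, Z = _tracks_to_frames(tracks)
    lo = sites.internal_boundary
    hi = sites.exit_z
    events: list[PermeationEvent] = []
    for ci, ion in enumerate(ions):
        z = Z[:, ci]
        valid = np.isfinite(z)
        t_i = times[valid]
        zones = _debounced_zones(z[valid], lo, hi, debounce)
        side = 0
        for k in range(zones.size):
            zk = zones[k]
            if zk == 0:
                continue
            if side != 0 and zk != side:
                direction = "outward" if zk > side else "inward"
                events.append(PermeationEvent(int(ion), float(t_i[k]),
                                              direction))
            side = zk
    events.sort(key=lambda e: e.time_ns)
    return events


def _site_intervals(in_site: np.ndarray):
    """Contiguous True runs as (start_idx, end_idx_exclusive) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], in_site.view(np.int8),
                                                 [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def classify_modes(events: list[PermeationEvent], tracks: pd.DataFrame,
                   sites: SiteMap, window_ns: float = 1.0
                   ) -> list[PermeationEvent]:
    """Assign a conduction mode to each outward permeation event.

    For each event the S0-release time is the last frame the permeating
    ion occupied the filter (S0 band) before completion.  Within the
    ``window_ns`` preceding the release:

    * canonical       — Scav became *newly* occupied (a Scav entry by any
      other ion falls inside the window), the knock-on trigger;
    * spontaneous_S0  — Scav was unoccupied throughout the window;
    * other           — Scav was occupied but not newly (resident there
      since before the window), or no release frame is resolvable.

    Inward events keep mode 'other'.  Events outside the occupancy time
    range are rejected.
    """
    times, ions, Z = _tracks_to_frames(tracks)
    if not events:
        return []
    t0, t1 = times[0], times[-1]
    for e in events:
        if not (t0 <= e.time_ns <= t1):
            raise ValueError(f"event at {e.time_ns} ns outside the "
                             "trajectory time range")
    codes = np.full(Z.shape, -99, dtype=int)
    for ci in range(Z.shape[1]):
        valid = np.isfinite(Z[:, ci])
        codes[valid, ci] = sites.site_codes(Z[valid, ci])
    scav_code = 0  # SITE_ORDER.index("Scav")
    s0_code = SITE_ORDER.index("S0")
    scav_occ = np.any(codes == scav_code, axis=1)
    # per-ion Scav entry times (rising edges)
    entry = np.zeros_like(scav_occ)
    per_ion_scav = codes == scav_code
    rising = np.zeros_like(per_ion_scav)
    rising[1:] = per_ion_scav[1:] & ~per_ion_scav[:-1]
    rising[0] = per_ion_scav[0]
    ion_index = {int(i): k for k, i in enumerate(ions)}
    out = []
    for e in events:
        if e.direction != "outward":
            out.append(PermeationEvent(e.ion_id, e.time_ns, e.direction,
                                       "other"))
            continue
        ci = ion_index[e.ion_id]
        before = times <= e.time_ns
        in_s0 = (codes[:, ci] == s0_code) & before
        if not np.any(in_s0):
            out.append(PermeationEvent(e.ion_id, e.time_ns, e.direction,
                                       "other"))
            continue
        t_release = times[np.flatnonzero(in_s0)[-1]]
        win = (times >= t_release - window_ns) & (times <= t_release)
        # exclude the permeating ion itself from trigger bookkeeping
        others = np.ones(len(ions), dtype=bool)
        others[ci] = False
        scav_occ_others = np.any(codes[:, others] == scav_code, axis=1)
        new_entry_others = np.any(rising[:, others], axis=1)
        if np.any(new_entry_others & win):
            mode = "canonical"
        elif not np.any(scav_occ_others & win):
            mode = "spontaneous_S0"
        else:
            mode = "other"
        out.append(PermeationEvent(e.ion_id, e.time_ns, e.direction, mode))
    return out


def mode_fractions(events: list[PermeationEvent]) -> dict[str, float]:
    """Percentages of outward events per mode (sum to 100)."""
    outward = [e for e in events if e.direction == "outward"]
    if not outward:
        return {"canonical": 0.0, "spontaneous_S0": 0.0, "other": 0.0}
    n = len(outward)
    out = {}
    for m in ("canonical", "spontaneous_S0", "other"):
        out[m] = 100.0 * sum(e.mode == m for e in outward) / n
    return out


def s0_occupancy_by_origin(tracks: pd.DataFrame, sites: SiteMap,
                           min_dwell_ns: float = 0.4) -> dict[str, float]:
    """Occupied-time fractions of the S0 site split by ion origin.

    A dwell counts only if it lasts at least ``min_dwell_ns``.  Origin is
    'from_external' when the ion entered S0 from above (external side),
    'from_SF' when it arrived from S1 below.  Returned probabilities are
    qualifying occupied time divided by the trajectory duration.
    """
    times, ions, Z = _tracks_to_frames(tracks)
    if times.size < 2:
        return {"from_SF": 0.0, "from_external": 0.0}
    dt = float(np.median(np.diff(times)))
    duration = times[-1] - times[0] + dt
    s0_code = SITE_ORDER.index("S0")
    occupied = {"from_SF": 0.0, "from_external": 0.0}
    for ci in range(Z.shape[1]):
        z = Z[:, ci]
        valid = np.isfinite(z)
        codes = np.full(times.size, -99, dtype=int)
        codes[valid] = sites.site_codes(z[valid])
        in_s0 = codes == s0_code
        for start, stop in _site_intervals(in_s0):
            dwell = (stop - start) * dt
            if dwell < min_dwell_ns:
                continue
            prev = codes[start - 1] if start > 0 else -99
            if prev >= len(SITE_ORDER):          # external
                origin = "from_external"
            elif prev == s0_code - 1:            # S1 below
                origin = "from_SF"
            elif prev == -99:                    # starts trajectory in S0
                origin = "from_SF"
            else:
                origin = "from_SF" if prev < s0_code else "from_external"
            occupied[origin] += dwell
    return {k: v / duration for k, v in occupied.items()}


def density_profile(tracks: pd.DataFrame, z_bins,
                    z_range: tuple[float, float] | None = None
                    ) -> pd.DataFrame:
    """Mean axial ion density versus z.

    Density has units ions/Å; its integral over the binned range equals
    the mean number of ions in range per frame (conservation identity,
    exact up to floating-point rounding).
    """
    times, ions, Z = _tracks_to_frames(tracks)
    z = Z[np.isfinite(Z)]
    if np.isscalar(z_bins):
        if z_range is None:
            z_range = (float(z.min()), float(z.max()) + 1e-9)
        edges = np.linspace(z_range[0], z_range[1], int(z_bins) + 1)
    else:
        edges = np.asarray(z_bins, dtype=float)
    counts, edges = np.histogram(z, bins=edges)
    widths = np.diff(edges)
    density = counts / (times.size * widths)
    return pd.DataFrame({"z_A": 0.5 * (edges[:-1] + edges[1:]),
                         "density_per_A": density,
                         "bin_width_A": widths})


def current_from_flux(n_outward: int, duration_ns: float,
                      n_inward: int = 0) -> float:
    """Single-channel current (pA) from net permeation counts.

    I = (n_out - n_in) e / duration; 10 outward events in 100 ns give
    16.02 pA.
    """
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    return (n_outward - n_inward) * E_CHARGE / (duration_ns * 1e-9) * 1e12


def dihedral_flip_stats(times_ns, chi_deg, boundary_deg: float = 110.0,
                        hysteresis_deg: float = 10.0) -> dict:
    """Two-state statistics of an aromatic ring dihedral time series.

    The chi1-like C-Ca-Cb-Cg angle of F339/F340 occupies two configurations
    (~55 deg and ~160 deg); ``boundary_deg`` separates them.  States are
    tracked with a hysteresis band of +/- ``hysteresis_deg`` around the
    boundary so noise does not register as flips.  Returns state
    probabilities (summing to 1), the flip count, and a 5-degree histogram.
    """
    t = np.asarray(times_ns, dtype=float)
    chi = np.asarray(chi_deg, dtype=float)
    if np.any(chi < -180.0) or np.any(chi >= 360.0):
        raise ValueError("dihedral angles expected in degrees, [-180, 360)")
    hi_thresh = boundary_deg + hysteresis_deg
    lo_thresh = boundary_deg - hysteresis_deg
    state = 1 if chi[0] > boundary_deg else 0   # 1 = high (~160), 0 = low
    states = np.empty(chi.size, dtype=int)
    flips = 0
    for i, c in enumerate(chi):
        if state == 0 and c > hi_thresh:
            state = 1
            if i > 0:
                flips += 1
        elif state == 1 and c < lo_thresh:
            state = 0
            if i > 0:
                flips += 1
        states[i] = state
    p_high = float(states.mean())
    counts, edges = np.histogram(chi, bins=np.arange(-180.0, 360.1, 5.0))
    return {
        "p_low": 1.0 - p_high,
        "p_high": p_high,
        "n_flips": int(flips),
        "histogram": pd.DataFrame({
            "chi_deg": 0.5 * (edges[:-1] + edges[1:]),
            "count": counts,
        }),
    }
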