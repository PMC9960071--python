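"""Seeded synthetic-data generators with ground-truth logs.

Every generator emulates one input class of the analysis pipeline —
dose-response triplets, two-electrode voltage-clamp traces with hooked
tails, single-channel sweeps, GHK current–voltage tables, reversal-shift
samples, conductance–voltage tables, ion z-trajectories of the
selectivity filter, and side-chain dihedral tracks — and emits the
programmed ground truth alongside, so analyzers can be tested for exact
and statistical recovery.

All generators are deterministic given (config, seed).  The trajectory
generator is a validation instrument, not a physical model: its site
anchors and the analyzer's :class:`~kflux.permeation.SiteMap` come from
one shared definition so classification tests are well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal

from . import biophys
from .constants import CONST, T_DEFAULT
from .permeation import SITE_ORDER, SiteMap
from .traces import Recording, Segment

__all__ = [
    "TraceModelConfig",
    "HopModelConfig",
    "gen_dose_response",
    "gen_tevc_trace",
    "default_protocol",
    "gen_single_channel",
    "gen_iv_ghk",
    "gen_reversal_shifts",
    "gen_gv_data",
    "gen_ion_trajectory",
    "gen_dihedral_tracks",
]


# ---------------------------------------------------------------------------
# dose-response ensembles

def gen_dose_response(imax: float, ic50_mM: float, nh: float,
                      concs=(0.2, 2.0, 5.0, 20.0, 100.0),
                      noise_sd: float = 0.02, n_cells: int = 8,
                      seed: int = 0, with_ghk_effect: bool = False,
                      vm_mV: float = 60.0, kin_mM: float = 108.0,
                      T: float = T_DEFAULT):
    """Normalized dose-response triplets for ``n_cells`` synthetic cells.

    Each cell yields three points per concentration: Hill-model value plus
    i.i.d. Gaussian noise.  With ``with_ghk_effect`` the driving-force
    reduction is superimposed in the additive first-order form
    observed = I_Hill(C) - (1 - Ith(C)), so the full pipeline including
    the GHK correction can be exercised end to end.

    Returns (cells, truth): ``cells`` maps cell id to a DataFrame with
    columns conc_mM, point_index, observed_norm; ``truth`` echoes the
    programmed parameters.
    """
    rng = np.random.default_rng(seed)
    concs = np.asarray(concs, dtype=float)
    cells = {}
    for ci in range(n_cells):
        rows = []
        for c in concs:
            base = biophys.hill_inhibition(c, imax, ic50_mM, nh)
            if with_ghk_effect:
                ith = biophys.ghk_current_ratio(kin_mM, c, kin_mM,
                                                concs.min(), vm_mV, T)
                base = base - (1.0 - ith)
            for k in range(3):
                rows.append((float(c), k,
                             base + rng.normal(0.0, noise_sd)))
        cells[f"cell{ci:02d}"] = pd.DataFrame(
            rows, columns=["conc_mM", "point_index", "observed_norm"])
    truth = {"imax": imax, "ic50_mM": ic50_mM, "nh": nh,
             "noise_sd": noise_sd, "n_cells": n_cells, "seed": seed,
             "with_ghk_effect": with_ghk_effect, "vm_mV": vm_mV,
             "kin_mM": kin_mM}
    return cells, truth


# ---------------------------------------------------------------------------
# TEVC traces with hooked tails

@dataclass
class TraceModelConfig:
    """Parameters of the synthetic whole-cell trace model.

    The tail is a constant plus a capacitive spike, one recovering (hook)
    component and two deactivating components.  The recovery amplitude is
    solved so that the extrapolated statistic 1 - X/Y equals
    ``inactivation_fraction`` exactly (X, Y extrapolated to the tail
    start), and both are logged.
    """

    activation_tau_s: float = 0.2
    inactivation_fraction: float = 0.35     # in [0, 0.6]
    inactivation_tau_s: float = 0.05
    deactivation_taus_s: tuple[float, float] = (0.15, 0.5)
    deactivation_split: float = 0.6         # weight of the faster component
    recovery_tau_s: float = 0.03
    peak_current: float = 2.0               # depolarized peak, uA
    tail_amplitude: float = -2.0            # no-inactivation tail total, uA
    leak_current: float = 0.0               # constant offset a0, uA
    capacitive_amplitude: float = 1.0       # uA, sign follows voltage step
    capacitive_tau_s: float = 1e-3
    noise_sd: float = 0.0
    sample_rate_hz: float = 5000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.inactivation_fraction <= 0.6:
            raise ValueError("inactivation fraction must lie in [0, 0.6]")
        for tau in (self.activation_tau_s, self.inactivation_tau_s,
                    self.recovery_tau_s, self.capacitive_tau_s,
                    *self.deactivation_taus_s):
            if tau <= 0:
                raise ValueError("all time constants must be positive")


def default_protocol(hold_s: float = 0.05, depol_s: float = 2.0,
                     tail_s: float = 2.0, v_hold: float = -100.0,
                     v_depol: float = 60.0, v_tail: float = -100.0
                     ) -> list[Segment]:
    """Hold / depolarize / tail protocol used by the trace generator."""
    return [
        Segment("hold", 0.0, hold_s, v_hold),
        Segment("depol", hold_s, hold_s + depol_s, v_depol),
        Segment("tail", hold_s + depol_s, hold_s + depol_s + tail_s, v_tail),
    ]


def gen_tevc_trace(cfg: TraceModelConfig,
                   protocol: list[Segment] | None = None):
    """One synthetic sweep with a hooked tail current.

    Returns (Recording, truth).  The truth log carries the programmed
    inactivation fraction together with the exact X (initial open-channel
    current) and Y (no-inactivation total) of the clean tail model, and
    the clean depolarized peak.
    """
    if protocol is None:
        protocol = default_protocol()
    rng = np.random.default_rng(cfg.seed)
    labels = {s.label for s in protocol}
    if not {"depol", "tail"}.issubset(labels):
        raise ValueError("protocol must contain 'depol' and 'tail' segments")
    dt = 1.0 / cfg.sample_rate_hz
    t_end = protocol[-1].t_end
    t = np.arange(0.0, t_end, dt)
    i_clean = np.zeros_like(t)  # channel current; leak added at the end

    seg_depol = next(s for s in protocol if s.label == "depol")
    seg_tail = next(s for s in protocol if s.label == "tail")

    # depolarizing segment: activation with a partial sag to the
    # inactivated steady state
    md = (t >= seg_depol.t_start) & (t < seg_depol.t_end)
    td = t[md] - seg_depol.t_start
    f = cfg.inactivation_fraction
    act = (1.0 - np.exp(-td / cfg.activation_tau_s))
    sag = 1.0 - f * (1.0 - np.exp(-td / cfg.inactivation_tau_s))
    depol_wave = cfg.peak_current * act * sag
    cap_d = cfg.capacitive_amplitude * np.exp(-td / cfg.capacitive_tau_s)
    i_clean[md] += depol_wave + cap_d

    # tail segment: recovery (hook) + two deactivating exponentials; the
    # leak is a constant added to the whole trace afterwards (analysis
    # removes it by unspecific-current subtraction before tail fitting)
    mt = (t >= seg_tail.t_start) & (t < seg_tail.t_end)
    tt = t[mt] - seg_tail.t_start
    y_total = cfg.tail_amplitude                  # a1 + a2 by design
    a1 = cfg.deactivation_split * y_total
    a2 = (1.0 - cfg.deactivation_split) * y_total
    a_r = -f * y_total                            # hook amplitude: 1-X/Y = f
    tail_wave = (a_r * np.exp(-tt / cfg.recovery_tau_s)
                 + a1 * np.exp(-tt / cfg.deactivation_taus_s[0])
                 + a2 * np.exp(-tt / cfg.deactivation_taus_s[1]))
    cap_t = -cfg.capacitive_amplitude * np.exp(-tt / cfg.capacitive_tau_s)
    i_clean[mt] = tail_wave + cap_t

    peak_clean = float(depol_wave.max())
    i_clean = i_clean + cfg.leak_current
    i_noisy = i_clean + rng.normal(0.0, cfg.noise_sd, size=t.size)
    rec = Recording(
        sweeps=pd.DataFrame({"sweep": 0, "time_s": t, "current": i_noisy}),
        protocol=list(protocol),
        sample_rate=cfg.sample_rate_hz,
        metadata={"generator": "gen_tevc_trace", "seed": cfg.seed},
    )
    truth = {"inactivation_fraction": f, "X": (1.0 - f) * y_total,
             "Y": y_total, "tail_components": [
                 (a_r, cfg.recovery_tau_s),
                 (a1, cfg.deactivation_taus_s[0]),
                 (a2, cfg.deactivation_taus_s[1])],
             "leak": cfg.leak_current, "peak_depol": peak_clean,
             "config": asdict(cfg)}
    return rec, truth


# ---------------------------------------------------------------------------
# single-channel sweeps

def gen_single_channel(levels_pA=(0.0, 0.5), weights=(0.7, 0.3),
                       n_sweeps: int = 11, duration_s: float = 4.0,
                       sample_rate_hz: float = 10_000.0,
                       filter_hz: float = 200.0,
                       mean_dwell_s: float = 0.05,
                       noise_sd_pA: float = 0.05, seed: int = 0):
    """Telegraph-signal single-channel sweeps, low-pass filtered.

    Levels (baseline 0 required) are visited in segments with exponential
    dwells; segment levels are drawn i.i.d. with the given weights, so the
    stationary occupancy matches the weights.  The signal is filtered with
    a 4-pole low-pass Bessel filter (the digital 200 Hz analysis filter of
    the acquisition chain) before Gaussian noise of ``noise_sd_pA`` is
    added.  Returns (list of sweep arrays, truth).
    """
    levels = np.asarray(levels_pA, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if 0.0 not in levels:
        raise ValueError("levels must include the 0 pA baseline")
    if levels.size != weights.size:
        raise ValueError("levels and weights must have equal length")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    sos = signal.bessel(4, filter_hz, fs=sample_rate_hz, output="sos")
    sweeps = []
    for _ in range(n_sweeps):
        ideal = np.empty(n)
        pos = 0
        while pos < n:
            lv = levels[rng.choice(levels.size, p=weights)]
            dwell = max(int(rng.exponential(mean_dwell_s) * sample_rate_hz), 1)
            ideal[pos:pos + dwell] = lv
            pos += dwell
        filtered = signal.sosfilt(sos, ideal)
        sweeps.append(filtered + rng.normal(0.0, noise_sd_pA, size=n))
    truth = {"levels_pA": levels.tolist(), "weights": weights.tolist(),
             "noise_sd_pA": noise_sd_pA, "filter_hz": filter_hz,
             "filter_family": "4-pole Bessel low-pass (scipy.signal.bessel)",
             "mean_dwell_s": mean_dwell_s, "seed": seed}
    return sweeps, truth


# ---------------------------------------------------------------------------
# GHK current-voltage and reversal-shift samples

def gen_iv_ghk(p_cm_s: float, ki_mM: float, ko_mM: float, voltages_mV,
               noise_sd: float = 0.05, seed: int = 0,
               noise_mode: str = "multiplicative", scale: float = 1.0,
               T: float = T_DEFAULT):
    """Current–voltage table from the GHK flux equation plus noise.

    'multiplicative' noise perturbs each current by (1 + sd*eps);
    'additive' adds sd (in current units) directly.  ``scale`` converts
    the GHK current density to the recording's units (e.g. an effective
    area to yield pA) and must be passed identically to the fit.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(voltages_mV, dtype=float)
    i_clean = scale * np.asarray(biophys.ghk_flux(p_cm_s, ki_mM, ko_mM, v, T))
    if noise_mode == "multiplicative":
        i_noisy = i_clean * (1.0 + rng.normal(0.0, noise_sd, size=v.size))
    elif noise_mode == "additive":
        i_noisy = i_clean + rng.normal(0.0, noise_sd, size=v.size)
    else:
        raise ValueError("noise_mode must be 'multiplicative' or 'additive'")
    table = pd.DataFrame({"vm_mV": v, "current": i_noisy})
    truth = {"p_cm_per_s": p_cm_s, "ki_mM": ki_mM, "ko_mM": ko_mM,
             "noise_sd": noise_sd, "noise_mode": noise_mode,
             "scale": scale, "T_K": T, "seed": seed}
    return table, truth


def gen_reversal_shifts(true_ratio: float, z: float = 1.0,
                        T: float = T_DEFAULT, noise_sd_mV: float = 0.5,
                        n: int = 5, seed: int = 0):
    """Reversal-potential shift samples for a programmed P_X/P_K ratio.

    dErev = (RT/zF) ln(ratio) + Gaussian noise, in mV.  The default noise
    (0.5 mV) is the typical reading precision of a TEVC reversal
    potential; n defaults to 5 cells.
    """
    if true_ratio <= 0:
        raise ValueError("permeability ratio must be positive")
    rng = np.random.default_rng(seed)
    mean_shift = 1e3 * CONST.vt(T) / z * np.log(true_ratio)
    shifts = mean_shift + rng.normal(0.0, noise_sd_mV, size=n)
    truth = {"ratio": true_ratio, "mean_shift_mV": float(mean_shift),
             "z": z, "noise_sd_mV": noise_sd_mV, "seed": seed}
    return shifts, truth


def gen_gv_data(vhalf_mV: float, z: float, gmin: float, voltages_mV,
                noise_sd: float = 0.03, n: int = 1, seed: int = 0,
                T: float = T_DEFAULT):
    """Conductance–voltage tables from the Boltzmann-with-offset curve.

    Returns (DataFrame with columns replicate, v_mV, g_norm; truth).
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(voltages_mV, dtype=float)
    rows = []
    for r in range(n):
        g = biophys.boltzmann_offset(v, vhalf_mV, z, gmin, T)
        g = g + rng.normal(0.0, noise_sd, size=v.size)
        for vv, gg in zip(v, g):
            rows.append((r, vv, gg))
    table = pd.DataFrame(rows, columns=["replicate", "v_mV", "g_norm"])
    truth = {"vhalf_mV": vhalf_mV, "z": z, "gmin": gmin,
             "noise_sd": noise_sd, "n": n, "seed": seed}
    return table, truth


# ---------------------------------------------------------------------------
# ion-hopping trajectories

@dataclass
class HopModelConfig:
    """Configuration of the stochastic ion-hopping trajectory generator.

    Permeating ions enter from the internal bulk, traverse the site ladder
    (Scav, S4, S3, S2, S1, S0) with exponential per-site dwells, wait at
    S0 as the resident ion and are released according to a programmed
    conduction-mode mixture:

    * canonical — the next incoming ion newly binds Scav and the resident
      is released ``coupling_delay_ns`` later (knock-on trigger);
    * spontaneous_S0 — the resident leaves after an exponential dwell with
      the Scav site guaranteed vacant throughout the preceding
      ``mode_window_ns``;
    * other — the next ion binds Scav *earlier* than the classification
      window before release, so Scav is occupied but not newly.

    External ions bind the vacant S0 site at a rate proportional to the
    external K+ concentration.  Every permeation (with mode), S0 external
    binding interval and transit dwell is logged.
    """

    duration_ns: float = 250.0
    frame_ns: float = 0.05
    mode_probs: tuple[float, float, float] = (0.5, 0.4, 0.1)  # canon/spont/other
    event_mean_ns: float = 6.0        # mean extra spacing between releases
    hop_dwell_ns: float = 0.3         # mean per-site transit dwell
    coupling_delay_ns: float = 0.3    # Scav arrival -> release (canonical)
    mode_window_ns: float = 1.0       # classification window the modes target
    spontaneous_guard_ns: float = 1.3 # enforced Scav-free lead (spontaneous)
    ko_mM: float = 5.0
    s0_binding_rate_per_ns_per_mM: float = 1e-3
    ext_dwell_mean_ns: float = 0.8    # external ion dwell at S0
    jitter_sd_A: float = 0.25
    internal_z_A: float = -14.0
    external_z_A: float = 12.0
    background: str = "none"          # 'none' | 'S3-S2' | 'full-cycle'
    background_switch_mean_ns: float = 4.0
    include_permeation: bool = True   # False: background/binder ions only
    seed: int = 0

    def __post_init__(self):
        if self.frame_ns <= 0 or self.duration_ns <= 0:
            raise ValueError("duration and frame step must be positive")
        if self.hop_dwell_ns / 5.0 < self.frame_ns:
            raise ValueError("frame step too coarse: must be below the "
                             "shortest mean dwell / 5")
        if abs(sum(self.mode_probs) - 1.0) > 1e-9:
            raise ValueError("mode probabilities must sum to 1")
        if self.background not in ("none", "S3-S2", "full-cycle"):
            raise ValueError("unknown background mode")

    def sitemap(self) -> SiteMap:
        return SiteMap.default()


def _schedule_add(schedule, ion, z, t_start, t_end):
    if t_end > t_start:
        schedule.append((ion, z, t_start, t_end))


def gen_ion_trajectory(cfg: HopModelConfig):
    """Simulate ion z-tracks through the filter with truth-logged events.

    Returns (tracks, truth): ``tracks`` is a DataFrame with columns
    time_ns, ion_id, z_A on a uniform frame grid; ``truth`` holds the
    permeation events (ion, completion time, mode), external S0 binding
    intervals, transit dwell draws, and the echoed config.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = cfg.sitemap()
    centers = {n: 0.5 * (sites.bands[n][0] + sites.bands[n][1])
               for n in SITE_ORDER}
    ladder = list(SITE_ORDER)  # Scav..S0
    exit_clear_z = sites.exit_z + 2.0

    duration = cfg.duration_ns
    schedule: list[tuple[int, float, float, float]] = []  # ion, z, t0, t1
    events: list[dict] = []
    hop_dwells: list[float] = []
    s0_vacant_from = 0.0
    s0_vacancies: list[tuple[float, float]] = []

    def draw_dwell() -> float:
        d = float(rng.exponential(cfg.hop_dwell_ns))
        hop_dwells.append(d)
        return max(d, cfg.frame_ns)  # keep dwells resolvable on the grid

    ion_id = 0

    def traverse(ion, t_from, first_site_idx):
        """Walk the ladder from ``first_site_idx`` up to S0; return arrival."""
        t = t_from
        for si in range(first_site_idx, len(ladder)):
            dwell = draw_dwell()
            if si == len(ladder) - 1:
                return t  # arrival at S0; resident dwell handled by caller
            _schedule_add(schedule, ion, centers[ladder[si]], t, t + dwell)
            t += dwell
        return t

    # --- permeating ions -------------------------------------------------
    if cfg.include_permeation:
        # first resident
        t_entry = 1.0
        _schedule_add(schedule, ion_id, cfg.internal_z_A, 0.0, t_entry)
        arr_scav = t_entry + draw_dwell()
        _schedule_add(schedule, ion_id, centers["Scav"], t_entry, arr_scav)
        resident = ion_id
        resident_since = traverse(ion_id, arr_scav, 1)
        ion_id += 1

    min_sep = 0.15
    while cfg.include_permeation:
        mode = ("canonical", "spontaneous_S0", "other")[
            int(rng.choice(3, p=np.asarray(cfg.mode_probs)))]
        incomer = ion_id
        if mode == "canonical":
            t_release = (resident_since + cfg.coupling_delay_ns
                         + float(rng.exponential(cfg.event_mean_ns)) + min_sep)
            arr_scav = t_release - cfg.coupling_delay_ns
            scav_leave = t_release + min_sep
        elif mode == "spontaneous_S0":
            t_release = (resident_since + cfg.spontaneous_guard_ns
                         + float(rng.exponential(cfg.event_mean_ns)))
            arr_scav = t_release + min_sep
            scav_leave = arr_scav + draw_dwell()
        else:  # other: Scav occupied since before the window
            arr_scav = resident_since + min_sep
            t_release = (arr_scav + cfg.mode_window_ns
                         + cfg.spontaneous_guard_ns
                         + float(rng.exponential(cfg.event_mean_ns)))
            scav_leave = t_release + min_sep
        if t_release + 3.0 > duration:
            # last resident never releases: hold at S0 to the end
            _schedule_add(schedule, resident, centers["S0"],
                          resident_since, duration)
            break
        # incoming ion: internal bulk, then Scav
        _schedule_add(schedule, incomer, cfg.internal_z_A, 0.0, arr_scav)
        _schedule_add(schedule, incomer, centers["Scav"], arr_scav, scav_leave)
        # resident release and exit
        _schedule_add(schedule, resident, centers["S0"], resident_since,
                      t_release)
        t_exit = t_release + cfg.frame_ns * 3
        _schedule_add(schedule, resident, exit_clear_z, t_release, t_exit)
        _schedule_add(schedule, resident, cfg.external_z_A, t_exit, duration)
        events.append({"ion_id": int(resident),
                       "time_ns": float(t_release),
                       "direction": "outward", "mode": mode})
        # incoming becomes the next resident
        new_since = traverse(incomer, scav_leave, 1)
        s0_vacancies.append((t_release, new_since))
        resident, resident_since = incomer, new_since
        ion_id += 1

    # --- external S0 binders ---------------------------------------------
    bindings: list[dict] = []
    rate = cfg.s0_binding_rate_per_ns_per_mM * cfg.ko_mM
    if rate > 0:
        for v0, v1 in s0_vacancies:
            t = v0
            while True:
                t += float(rng.exponential(1.0 / rate))
                if t >= v1:
                    break
                dwell = float(rng.exponential(cfg.ext_dwell_mean_ns))
                t_out = min(t + dwell, v1)
                ion = ion_id
                ion_id += 1
                _schedule_add(schedule, ion, cfg.external_z_A, 0.0, t)
                _schedule_add(schedule, ion, centers["S0"], t, t_out)
                _schedule_add(schedule, ion, cfg.external_z_A, t_out, duration)
                bindings.append({"ion_id": int(ion), "t_in_ns": float(t),
                                 "t_out_ns": float(t_out),
                                 "origin": "external"})
                t = t_out

    # --- background substate ions ----------------------------------------
    def telegraph(ion, z_a, z_b, sync_times=None):
        """Alternate between two anchors; returns the switch times used."""
        t, state = 0.0, 0
        switches = []
        if sync_times is None:
            while t < duration:
                dwell = float(rng.exponential(cfg.background_switch_mean_ns))
                t_next = min(t + dwell, duration)
                _schedule_add(schedule, ion, z_a if state == 0 else z_b,
                              t, t_next)
                switches.append(t_next)
                t, state = t_next, 1 - state
        else:
            bounds = [0.0] + list(sync_times) + [duration]
            for k in range(len(bounds) - 1):
                _schedule_add(schedule, ion,
                              z_a if k % 2 == 0 else z_b,
                              bounds[k], bounds[k + 1])
        return switches

    background_states = None
    if cfg.background == "S3-S2":
        telegraph(ion_id, centers["S3"], centers["S2"])
        ion_id += 1
    elif cfg.background == "full-cycle":
        # three dedicated ions realizing Scav-S3-S2 <-> S4-S3-S1
        switches = telegraph(ion_id, centers["Scav"], centers["S4"])
        _schedule_add(schedule, ion_id + 1, centers["S3"], 0.0, duration)
        telegraph(ion_id + 2, centers["S2"], centers["S1"],
                  sync_times=switches)
        background_states = ("Scav-S3-S2", "S4-S3-S1")
        ion_id += 3

    # --- sample onto frames ----------------------------------------------
    times = np.arange(0.0, duration, cfg.frame_ns)
    frames = {i: np.full(times.size, np.nan) for i in range(ion_id)}
    for ion, z, t0, t1 in schedule:
        i0 = int(np.ceil(t0 / cfg.frame_ns - 1e-9))
        i1 = min(int(np.ceil(t1 / cfg.frame_ns - 1e-9)), times.size)
        if i1 > i0:
            frames[ion][i0:i1] = z
    rows = []
    for ion, z in frames.items():
        filled = pd.Series(z).ffill().bfill().to_numpy()
        jitter = rng.normal(0.0, cfg.jitter_sd_A, size=times.size)
        rows.append(pd.DataFrame({"time_ns": times, "ion_id": ion,
                                  "z_A": filled + jitter}))
    tracks = pd.concat(rows, ignore_index=True)

    truth = {"events": events, "s0_ext_bindings": bindings,
             "hop_dwells_ns": hop_dwells,
             "background_states": background_states,
             "config": asdict(cfg), "sitemap": sites.to_dict(),
             "n_ions": ion_id, "duration_ns": duration}
    return tracks, truth


# ---------------------------------------------------------------------------
# dihedral tracks

def gen_dihedral_tracks(p_high_by_subunit=(0.8, 0.3, 0.5, 0.6),
                        low_deg: float = 55.0, high_deg: float = 160.0,
                        switch_mean_ns: float = 5.0,
                        duration_ns: float = 500.0, frame_ns: float = 0.1,
                        noise_sd_deg: float = 8.0, seed: int = 0):
    """Two-state dihedral telegraph tracks for four subunits.

    Each subunit alternates between configurations near ``low_deg`` and
    ``high_deg`` with the programmed stationary probability of the high
    state; segment states are drawn i.i.d. so occupancy matches the
    program.  Returns (DataFrame time_ns/subunit/chi_deg, truth).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_ns, frame_ns)
    rows = []
    for su, p_high in enumerate(p_high_by_subunit):
        chi = np.empty(times.size)
        pos = 0
        while pos < times.size:
            state_high = rng.random() < p_high
            dwell = max(int(rng.exponential(switch_mean_ns) / frame_ns), 1)
            chi[pos:pos + dwell] = high_deg if state_high else low_deg
            pos += dwell
        chi = chi + rng.normal(0.0, noise_sd_deg, size=times.size)
        rows.append(pd.DataFrame({"time_ns": times, "subunit": su,
                                  "chi_deg": chi}))
    truth = {"p_high_by_subunit": list(p_high_by_subunit),
             "low_deg": low_deg, "high_deg": high_deg, "seed": seed}
    return pd.concat(rows, ignore_index=True), truth
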