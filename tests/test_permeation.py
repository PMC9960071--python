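"""Selectivity-filter trajectory analysis: substates, permeation events,
conduction modes, S0 occupancy, densities, flux-to-current, dihedrals."""

import numpy as np
import pandas as pd
import pytest

from kflux import permeation as perm
from kflux.permeation import SITE_ORDER, SiteMap
from kflux.simulate import HopModelConfig, gen_ion_trajectory

SM = SiteMap.default()


def _center(site):
    lo, hi = SM.bands[site]
    return 0.5 * (lo + hi)


def _tracks(rows):
    return pd.DataFrame(rows, columns=["time_ns", "ion_id", "z_A"])


class TestSiteMap:
    def test_bands_ordered_and_contiguous_lookup(self):
        assert SM.site_of(_center("S2")) == "S2"
        assert SM.site_of(-20.0) == "internal"
        assert SM.site_of(+20.0) == "external"

    def test_json_round_trip(self):
        sm2 = SiteMap.from_dict(SM.to_dict())
        assert sm2.bands == SM.bands
        assert sm2.exit_z == SM.exit_z

    def test_overlapping_bands_rejected(self):
        bands = {n: list(SM.bands[n]) for n in SITE_ORDER}
        bands["S3"] = (bands["S3"][0], bands["S2"][0] + 1.0)
        with pytest.raises(ValueError):
            SiteMap({k: tuple(v) for k, v in bands.items()})


class TestClassifySubstates:
    def test_single_ion_constant_site(self):
        tr = _tracks([(t, 0, _center("S2")) for t in np.arange(0, 1, 0.1)])
        frames = perm.classify_substates(tr, SM)
        assert all(f.label == "S2" for f in frames)

    def test_two_ion_frame_label_order(self):
        tr = _tracks([(0.0, 0, _center("S3")), (0.0, 1, _center("S1"))])
        frames = perm.classify_substates(tr, SM)
        assert frames[0].label == "S3-S1"

    def test_double_occupancy_flagged(self):
        tr = _tracks([(0.0, 0, _center("S2")), (0.0, 1, _center("S2"))])
        with pytest.warns(UserWarning, match="two ions"):
            frames = perm.classify_substates(tr, SM)
        assert frames[0].flagged

    def test_generator_substate_cycle_recovered(self):
        cfg = HopModelConfig(duration_ns=200.0, background="full-cycle",
                             include_permeation=False, seed=2)
        tracks, truth = gen_ion_trajectory(cfg)
        frames = perm.classify_substates(tracks, SM)
        dist = perm.substate_distribution(frames)
        # the two programmed states dominate; equal mean dwells -> ~50/50
        top = dist.index[:2].tolist()
        assert set(top) == set(truth["background_states"])
        assert dist.iloc[:2].sum() > 0.95
        assert abs(dist[top[0]] - 0.5) < 0.15


class TestDetectPermeations:
    def test_bulk_resident_ion_no_events(self):
        tr = _tracks([(t, 0, 15.0) for t in np.arange(0, 1, 0.1)])
        assert perm.detect_permeations(tr, SM) == []

    def test_hand_built_outward_passage(self):
        path = [-14.0, _center("Scav"), _center("S4"), _center("S3"),
                _center("S2"), _center("S1"), _center("S0"), 11.0, 12.0,
                12.0]
        tr = _tracks([(0.1 * k, 0, z) for k, z in enumerate(path)])
        ev = perm.detect_permeations(tr, SM, debounce=1)
        assert len(ev) == 1
        assert ev[0].direction == "outward"

    def test_generator_counts_exact(self, hop_trajectory):
        cfg, tracks, truth = hop_trajectory
        ev = perm.detect_permeations(tracks, cfg.sitemap())
        assert len(ev) == len(truth["events"])
        assert sorted(e.ion_id for e in ev) == sorted(
            e["ion_id"] for e in truth["events"])

    def test_translation_invariance(self, hop_trajectory):
        cfg, tracks, _ = hop_trajectory
        sm = cfg.sitemap()
        ev0 = perm.detect_permeations(tracks, sm)
        shifted = tracks.copy()
        shifted["z_A"] = shifted["z_A"] + 5.0
        shifted["time_ns"] = shifted["time_ns"] + 100.0
        bands = {k: (v[0] + 5.0, v[1] + 5.0) for k, v in sm.bands.items()}
        sm5 = SiteMap(bands, sm.exit_reference + 5.0, sm.exit_threshold)
        ev5 = perm.detect_permeations(shifted, sm5)
        assert len(ev5) == len(ev0)
        assert [e.ion_id for e in ev5] == [e.ion_id for e in ev0]

    def test_per_ion_flux_conservation(self, hop_trajectory):
        # outward - inward per ion equals its net side change
        cfg, tracks, _ = hop_trajectory
        sm = cfg.sitemap()
        ev = perm.detect_permeations(tracks, sm)
        for ion, grp in tracks.groupby("ion_id"):
            z = grp.sort_values("time_ns")["z_A"].to_numpy()
            sides = np.where(z < sm.internal_boundary, -1,
                             np.where(z >= sm.exit_z, 1, 0))
            nz = sides[sides != 0]
            net = (nz[-1] - nz[0]) // 2 if nz.size else 0
            n_out = sum(e.ion_id == ion and e.direction == "outward"
                        for e in ev)
            n_in = sum(e.ion_id == ion and e.direction == "inward"
                       for e in ev)
            assert n_out - n_in == net


class TestClassifyModes:
    def test_generator_modes_recovered_exactly(self, hop_trajectory):
        cfg, tracks, truth = hop_trajectory
        sm = cfg.sitemap()
        ev = perm.detect_permeations(tracks, sm)
        ev = perm.classify_modes(ev, tracks, sm,
                                 window_ns=cfg.mode_window_ns)
        got = {e.ion_id: e.mode for e in ev}
        want = {e["ion_id"]: e["mode"] for e in truth["events"]}
        agree = sum(got[i] == want[i] for i in want) / len(want)
        assert agree >= 0.99

    def test_fractions_sum_to_one(self, hop_trajectory):
        cfg, tracks, _ = hop_trajectory
        sm = cfg.sitemap()
        ev = perm.classify_modes(perm.detect_permeations(tracks, sm),
                                 tracks, sm)
        fr = perm.mode_fractions(ev)
        assert sum(fr.values()) == pytest.approx(100.0)

    def test_event_outside_time_range_rejected(self, hop_trajectory):
        cfg, tracks, _ = hop_trajectory
        bad = [perm.PermeationEvent(0, 1e9, "outward")]
        with pytest.raises(ValueError):
            perm.classify_modes(bad, tracks, cfg.sitemap())


class TestS0Occupancy:
    def test_no_s0_visits(self):
        tr = _tracks([(t, 0, _center("S3")) for t in np.arange(0, 1, 0.1)])
        occ = perm.s0_occupancy_by_origin(tr, SM)
        assert occ == {"from_SF": 0.0, "from_external": 0.0}

    def test_external_dwell_fraction(self):
        # external ion dwells 1 ns in S0 within a 10 ns track -> 0.1
        times = np.arange(0.0, 10.0, 0.1)
        z = np.where((times >= 4.0) & (times < 5.0), _center("S0"), 12.0)
        tr = _tracks(list(zip(times, np.zeros_like(times, dtype=int), z)))
        occ = perm.s0_occupancy_by_origin(tr, SM, min_dwell_ns=0.4)
        assert occ["from_external"] == pytest.approx(0.1, abs=0.011)
        assert occ["from_SF"] == 0.0

    def test_short_dwell_ignored(self):
        times = np.arange(0.0, 10.0, 0.1)
        z = np.where((times >= 4.0) & (times < 4.3), _center("S0"), 12.0)
        tr = _tracks(list(zip(times, np.zeros_like(times, dtype=int), z)))
        occ = perm.s0_occupancy_by_origin(tr, SM, min_dwell_ns=0.4)
        assert occ["from_external"] == 0.0

    def test_sf_origin_detected(self):
        times = np.arange(0.0, 10.0, 0.1)
        z = np.where(times < 5.0, _center("S1"), _center("S0"))
        tr = _tracks(list(zip(times, np.zeros_like(times, dtype=int), z)))
        occ = perm.s0_occupancy_by_origin(tr, SM, min_dwell_ns=0.4)
        assert occ["from_SF"] == pytest.approx(0.5, abs=0.02)
        assert occ["from_external"] == 0.0


class TestDensityProfile:
    def test_stationary_ion_delta_peak(self):
        tr = _tracks([(t, 0, 0.0) for t in np.arange(0, 1, 0.1)])
        prof = perm.density_profile(tr, 20, z_range=(-10.0, 10.0))
        integral = (prof["density_per_A"] * prof["bin_width_A"]).sum()
        assert integral == pytest.approx(1.0, rel=1e-12)
        assert prof.loc[prof["density_per_A"].idxmax(), "z_A"] == \
            pytest.approx(0.0, abs=0.5)

    def test_uniform_walk_flat_profile(self):
        rng = np.random.default_rng(0)
        times = np.arange(0.0, 100.0, 0.1)
        tr = _tracks(list(zip(times, np.zeros_like(times, dtype=int),
                              rng.uniform(-10, 10, times.size))))
        prof = perm.density_profile(tr, 10, z_range=(-10.0, 10.0))
        dens = prof["density_per_A"].to_numpy()
        assert dens.std() / dens.mean() < 0.2

    def test_integral_conservation_on_generator(self, hop_trajectory):
        _, tracks, truth = hop_trajectory
        prof = perm.density_profile(tracks, 60)
        integral = (prof["density_per_A"] * prof["bin_width_A"]).sum()
        n_frames = tracks["time_ns"].nunique()
        mean_count = len(tracks) / n_frames
        assert integral == pytest.approx(mean_count, rel=1e-9)


class TestCurrentFromFlux:
    def test_values(self):
        assert perm.current_from_flux(0, 100.0) == 0.0
        assert perm.current_from_flux(10, 100.0) == pytest.approx(16.02,
                                                                  abs=0.01)
        assert perm.current_from_flux(5, 100.0, n_inward=5) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            perm.current_from_flux(1, 0.0)


class TestDihedralFlips:
    def test_constant_high_state(self):
        t = np.arange(0.0, 10.0, 0.1)
        st = perm.dihedral_flip_stats(t, np.full(t.size, 160.0))
        assert st["p_high"] == 1.0 and st["n_flips"] == 0

    def test_square_wave_flip_count(self):
        t = np.arange(0.0, 10.0, 0.1)
        chi = np.where((t // 2).astype(int) % 2 == 0, 55.0, 160.0)
        st = perm.dihedral_flip_stats(t, chi)
        assert st["n_flips"] == 4

    def test_noise_within_hysteresis_not_counted(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 50.0, 0.1)
        chi = 160.0 + rng.normal(0, 8.0, t.size)
        st = perm.dihedral_flip_stats(t, chi, hysteresis_deg=30.0)
        assert st["n_flips"] == 0

    def test_generator_probabilities_recovered(self):
        from kflux.simulate import gen_dihedral_tracks
        tracks, truth = gen_dihedral_tracks(seed=4)
        for su, p_true in enumerate(truth["p_high_by_subunit"]):
            grp = tracks[tracks["subunit"] == su]
            st = perm.dihedral_flip_stats(grp["time_ns"], grp["chi_deg"])
            # binomial CI over effective independent dwell segments
            n_eff = 500.0 / 5.0
            ci = 1.96 * np.sqrt(p_true * (1 - p_true) / n_eff)
            assert abs(st["p_high"] - p_true) < max(ci * 2, 0.1)
            assert st["p_low"] + st["p_high"] == pytest.approx(1.0)
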