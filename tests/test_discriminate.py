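"""Prediction tests and the aggregate model call."""

import numpy as np
import pandas as pd
import pytest

from conftest import dna_polyline_px
from loopblock import discriminate as disc
from loopblock import mechanics as mech
from loopblock import quantify as q
from loopblock import synthetic as syn
from loopblock.errors import InsufficientDataError, InvalidArgumentError


def _levels_and_loop_profile(kin, stack, frame, optics):
    poly = dna_polyline_px(kin, optics)
    prof = q.extract_profile(stack.dna[frame], poly, 11, optics.pixel_size_um)
    a1 = np.asarray(kin.geometry["anchor1_um"])
    stem = np.asarray(kin.geometry["stem_um"])
    arm = float(np.hypot(*(stem - a1)))
    rel = (prof.arc_position_um - arm) / optics.pixel_size_um
    tether = float(np.median(prof.intensity[(rel < -8) & (rel > -14)]))
    sel = rel > 2.0
    loop_prof = q.IntensityProfile(prof.arc_position_um[sel], prof.intensity[sel])
    return tether, loop_prof


class TestLoopMultiplicity:
    def test_single_loop_supports_nontopological(self, nontopo_kin, nontopo_noiseless, optics):
        tether, loop_prof = _levels_and_loop_profile(
            nontopo_kin, nontopo_noiseless, len(nontopo_kin) - 1, optics
        )
        v = disc.classify_loop_multiplicity(loop_prof, 2.0 * tether, tether)
        assert v.outcome == disc.SUPPORTS_NONTOPO
        assert v.statistics["peak_ratio"] == pytest.approx(2.0, abs=0.3)

    def test_double_loop_supports_pseudotopological(self, pseudo_kin, pseudo_noiseless, optics):
        tether, loop_prof = _levels_and_loop_profile(
            pseudo_kin, pseudo_noiseless, len(pseudo_kin) - 1, optics
        )
        v = disc.classify_loop_multiplicity(loop_prof, 2.0 * tether, tether)
        assert v.outcome == disc.SUPPORTS_PSEUDO
        assert v.statistics["peak_ratio"] > 3.0

    def test_flat_profile_is_inconclusive(self):
        rng = np.random.default_rng(0)
        prof = q.IntensityProfile(np.arange(30) * 0.108, 10.0 + rng.normal(0, 0.3, 30))
        v = disc.classify_loop_multiplicity(prof, 20.0, 10.0)
        assert v.outcome == disc.INCONCLUSIVE

    def test_scale_invariance(self, pseudo_kin, pseudo_noiseless, optics):
        tether, loop_prof = _levels_and_loop_profile(
            pseudo_kin, pseudo_noiseless, len(pseudo_kin) - 1, optics
        )
        for scale in (0.1, 1.0, 250.0):
            scaled = q.IntensityProfile(loop_prof.arc_position_um, loop_prof.intensity * scale)
            v = disc.classify_loop_multiplicity(scaled, 2.0 * tether * scale, tether * scale)
            assert v.outcome == disc.SUPPORTS_PSEUDO

    def test_bad_single_loop_baseline_rejected(self):
        prof = q.IntensityProfile(np.arange(10.0), np.full(10, 20.0))
        with pytest.raises(InvalidArgumentError):
            disc.classify_loop_multiplicity(prof, 5.0, 10.0)


class TestStemResidence:
    def test_groundtruth_nontopological_series(self, optics):
        kin = syn.simulate_kinematics(
            syn.SimulationConfig(model="nontopological", encounter_loop_kb=24.0,
                                 post_encounter_kb=6.0),
            optics,
        )
        v = disc.test_stem_residence(kin.measurement_series(), kin.encounter_frame)
        assert v.outcome == disc.SUPPORTS_NONTOPO
        # departure at the extrusion speed, ~0.07 µm/s for 0.5 kb/s
        assert v.statistics["departure_speed_um_s"] == pytest.approx(0.07, abs=0.005)
        assert 0.8 < v.statistics["speed_ratio"] < 1.25
        # noise-free final distance equals the continuous-extrusion expectation
        assert v.statistics["final_distance_um"] == pytest.approx(
            v.statistics["expected_final_distance_um"], rel=1e-6
        )
        assert v.statistics["final_distance_um"] == pytest.approx(0.84, abs=0.005)

    def test_groundtruth_pseudotopological_series(self, pseudo_kin):
        v = disc.test_stem_residence(
            pseudo_kin.measurement_series(), pseudo_kin.encounter_frame
        )
        assert v.outcome == disc.SUPPORTS_PSEUDO
        assert v.statistics["max_distance_um"] == 0.0

    def test_expected_position_consistency_with_mechanics(self, optics):
        kin = syn.simulate_kinematics(
            syn.SimulationConfig(model="nontopological", encounter_loop_kb=24.0,
                                 post_encounter_kb=6.0),
            optics,
        )
        v = disc.test_stem_residence(kin.measurement_series(), kin.encounter_frame)
        direct = mech.expected_roadblock_position(6.0, 15.0, 2.1012)
        assert v.statistics["expected_final_distance_um"] == pytest.approx(direct, rel=1e-6)

    def test_too_few_post_frames_rejected(self, nontopo_kin):
        series = nontopo_kin.measurement_series()
        with pytest.raises(InsufficientDataError):
            disc.test_stem_residence(series, len(series) - 2)


class TestMsdLoopCoupling:
    @staticmethod
    def _series(loop, msd, dt=1.0):
        t = np.arange(len(loop)) * dt
        return (pd.DataFrame({"time_s": t, "loop_kb": loop}),
                pd.DataFrame({"time_s": t, "msd_um2": msd}))

    def test_flat_msd_flat_loop_counts_stall_without_growth(self):
        loop, msd = self._series(np.full(40, 12.0), np.full(40, 0.2))
        v = disc.test_msd_loop_coupling(loop, msd)
        assert v.outcome == disc.SUPPORTS_NONTOPO
        assert v.statistics["n_stalls"] >= 1
        assert v.statistics["n_stalls_with_loop_growth"] == 0

    def test_flat_msd_growing_loop_supports_pseudotopological(self):
        loop, msd = self._series(12.0 + 0.5 * np.arange(40), np.full(40, 0.2))
        v = disc.test_msd_loop_coupling(loop, msd)
        assert v.outcome == disc.SUPPORTS_PSEUDO
        assert v.statistics["n_stalls_with_loop_growth"] >= 1

    def test_no_plateau_is_inconclusive(self):
        t = np.arange(40)
        loop, msd = self._series(12.0 + 0.5 * t, 0.05 * (1.1 ** t))
        v = disc.test_msd_loop_coupling(loop, msd)
        assert v.outcome == disc.INCONCLUSIVE
        assert v.statistics["n_stalls"] == 0

    def test_misaligned_time_bases_rejected(self):
        loop, _ = self._series(np.full(40, 12.0), np.full(40, 0.2))
        _, msd = self._series(np.full(40, 12.0), np.full(40, 0.2), dt=0.5)
        with pytest.raises(InvalidArgumentError):
            disc.test_msd_loop_coupling(loop, msd)

    def test_fifteen_nontopological_stall_events_show_no_growth(self):
        n_growth = 0
        n_stalls = 0
        for seed in range(15):
            ev = syn.simulate_stall_event("nontopological", seed=seed)
            v = disc.test_msd_loop_coupling(
                ev[["time_s", "loop_kb"]], ev[["time_s", "msd_um2"]]
            )
            n_stalls += v.statistics["n_stalls"]
            n_growth += v.statistics["n_stalls_with_loop_growth"]
        assert n_stalls >= 15
        assert n_growth == 0


class TestAggregateAndPurity:
    def test_unanimous_call(self):
        vs = [disc.PredictionVerdict(f"P{i}", disc.SUPPORTS_NONTOPO) for i in (1, 2, 3)]
        assert disc.aggregate_verdict(vs).call == "nontopological"

    def test_tie_is_inconclusive(self):
        vs = [
            disc.PredictionVerdict("P1", disc.SUPPORTS_NONTOPO),
            disc.PredictionVerdict("P2", disc.SUPPORTS_PSEUDO),
            disc.PredictionVerdict("P3", disc.INCONCLUSIVE),
        ]
        assert disc.aggregate_verdict(vs).call == disc.INCONCLUSIVE

    def test_all_inconclusive(self):
        vs = [disc.PredictionVerdict("P1", disc.INCONCLUSIVE)]
        assert disc.aggregate_verdict(vs).call == disc.INCONCLUSIVE

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            disc.aggregate_verdict([])

    def test_outcomes_are_pure_functions_of_statistics(self, optics):
        # re-applying each decision rule to the reported statistics must
        # reproduce the stored outcome
        kin = syn.simulate_kinematics(
            syn.SimulationConfig(model="nontopological", encounter_loop_kb=24.0,
                                 post_encounter_kb=6.0),
            optics,
        )
        v2 = disc.test_stem_residence(kin.measurement_series(), kin.encounter_frame)
        s = v2.statistics
        assert disc.p2_outcome(
            s["frac_below_threshold"], s["speed_ratio"], s["monotonicity"]
        ) == v2.outcome
        for seed in range(3):
            ev = syn.simulate_stall_event("pseudotopological", seed=seed)
            v3 = disc.test_msd_loop_coupling(
                ev[["time_s", "loop_kb"]], ev[["time_s", "msd_um2"]]
            )
            assert disc.p3_outcome(
                v3.statistics["n_stalls"], v3.statistics["n_stalls_with_loop_growth"]
            ) == v3.outcome


class TestDetectEncounter:
    def test_first_sustained_colocalization(self):
        d = np.array([1.0, 0.8, 0.5, 0.1, 0.05, 0.04, 0.5, 0.9])
        assert disc.detect_encounter(d) == 3

    def test_single_frame_dip_ignored(self):
        d = np.array([1.0, 0.1, 1.0, 1.0, 1.0])
        assert disc.detect_encounter(d) is None
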