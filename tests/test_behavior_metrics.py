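"""Fixation metrics, perturbation responses, correction fractions."""

import numpy as np
import pytest

from windcompass import behavior_metrics as bm
from windcompass import closed_loop_sim as cl


class TestFixationMetrics:
    def test_perfect_downwind_fixation(self):
        fm = bm.fixation_metrics(np.full(1000, 180.0))
        assert fm.mean_orientation == pytest.approx(180.0)
        assert fm.fixation_strength == pytest.approx(1.0)
        assert fm.toward_fraction == 0.0

    def test_eight_point_symmetric_distribution(self):
        angles = np.repeat(np.arange(-135.0, 181.0, 45.0), 10)
        fm = bm.fixation_metrics(angles)
        assert fm.fixation_strength == pytest.approx(0.0, abs=1e-12)
        assert fm.toward_fraction == pytest.approx(0.25)

    def test_two_flanking_angles(self):
        angles = np.array([45.0] * 50 + [-45.0] * 50)
        fm = bm.fixation_metrics(angles)
        assert fm.mean_orientation == pytest.approx(0.0, abs=1e-9)
        assert fm.fixation_strength == pytest.approx(np.cos(np.deg2rad(45.0)))

    def test_uniform_null(self):
        """Uniform orienting: toward fraction 0.25, strength near 0."""
        rng = np.random.default_rng(0)
        fm = bm.fixation_metrics(rng.uniform(-180.0, 180.0, 60_000))
        assert fm.toward_fraction == pytest.approx(0.25, abs=0.02)
        assert fm.fixation_strength < 0.02

    def test_strength_bounds_and_equality_condition(self):
        rng = np.random.default_rng(1)
        mixed = rng.uniform(-180, 180, 500)
        assert 0.0 <= bm.fixation_metrics(mixed).fixation_strength < 1.0
        assert bm.fixation_metrics(np.full(5, 33.0)).fixation_strength == \
            pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bm.fixation_metrics(np.array([]))


def _session(agent, seed=0, reps=2, arena=None, orientation0=0.0):
    arena = arena or cl.ArenaConfig()
    sched = cl.make_schedule(reps, seed=seed)
    return cl.run_session(agent, arena, sched, seed=seed,
                          orientation0=orientation0)


class TestSlipResponses:
    def test_zero_response_agent(self, still_agent):
        rec = _session(still_agent)
        for r in bm.slip_responses(rec).values():
            assert np.allclose(r.integrated, 0.0)
            assert r.timecourses.shape[1] == 301  # 6 s at 50 Hz + 1

    def test_constant_turn_integral(self, still_agent, default_arena):
        """dWBA = -1 throughout integrates to -5 deg*s over the 5 s window."""
        rec = _session(still_agent)
        rec.dwba = np.full_like(rec.dwba, -1.0)
        for r in bm.slip_responses(rec).values():
            assert np.allclose(r.integrated, -5.0, atol=0.05)

    def test_corrective_agent_opposes_both_slip_directions(self):
        agent = cl.FlyAgent(theta_goal=180.0, k=0.5, noise_sd=0.5)
        rec = _session(agent, seed=3, reps=3, orientation0=180.0)
        resp = bm.slip_responses(rec)
        for typ, r in resp.items():
            sign = cl.SLIP_SIGNS[typ]
            assert np.sign(r.integrated.mean()) == -sign

    def test_slip_geometry_for_non_responder(self, still_agent, default_arena):
        """Without a response, post-slip orientation differs from pre-slip
        by exactly the slip displacement."""
        rec = _session(still_agent, seed=4, reps=1)
        fs = rec.fs
        for typ, onset in rec.schedule.entries:
            if typ not in cl.SLIP_SAMPLES:
                continue
            i_on = int(round(onset * fs))
            i_end = i_on + cl.SLIP_SAMPLES[typ]
            slip = cl.apply_slip(cl.SLIP_SAMPLES[typ], cl.SLIP_SIGNS[typ],
                                 default_arena)
            from windcompass._angles import wrap_deg
            delta = wrap_deg(rec.orientation[i_end + 5] - rec.orientation[i_on - 1])
            assert float(delta) == pytest.approx(slip, abs=1e-9)


class TestCorrectionFraction:
    def test_perfect_corrector_scores_one(self, default_arena):
        """An agent that fully restores its orientation after every slip
        has correction fraction 1 for both slip sizes.

        The agent reacts after the slip ends (0.5 s latency) and steers
        gently enough to stay under the motor cap, so its recorded wing
        commands all translate into actual rotation.
        """
        agent = cl.FlyAgent(theta_goal=180.0, k=0.8, noise_sd=0.0, latency=25)
        sched = cl.make_schedule(2, seed=5)
        rec = cl.run_session(agent, default_arena, sched, seed=5,
                             orientation0=180.0)
        for typ, cf in bm.correction_fractions(rec).items():
            assert cf == pytest.approx(1.0, abs=0.05)

    def test_zero_response_scores_zero(self, still_agent):
        rec = _session(still_agent)
        for cf in bm.correction_fractions(rec).values():
            assert cf == pytest.approx(0.0, abs=1e-12)

    def test_anti_corrective_scores_minus_one(self, still_agent, default_arena):
        rec = _session(still_agent, seed=6, reps=1)
        resp = bm.slip_responses(rec)
        for typ, r in resp.items():
            slip = cl.apply_slip(cl.SLIP_SAMPLES[typ], cl.SLIP_SIGNS[typ],
                                 default_arena)
            # a response whose orientation-equivalent equals the slip itself
            fake = np.full_like(r.integrated,
                                slip / (default_arena.gain * default_arena.fs))
            assert bm.correction_fraction(fake, slip, rec) == pytest.approx(-1.0)

    def test_zero_slip_rejected(self, still_agent):
        rec = _session(still_agent)
        with pytest.raises(ValueError):
            bm.correction_fraction(np.array([1.0]), 0.0, rec)


class TestPauseResponses:
    def test_bias_toward_source_is_positive_on_both_sides(self):
        """Sign adjustment makes toward-source turning positive no matter
        which side the fly is on."""
        agent = cl.FlyAgent(k=0.0, noise_sd=0.0, pause_bias=2.0)
        for theta0 in (120.0, -120.0):
            sched = cl.PerturbationSchedule(entries=(("pause_long", 1.0),),
                                            trial_len=20.0)
            rec = cl.run_session(agent, cl.ArenaConfig(), sched, seed=0,
                                 orientation0=theta0)
            r = bm.pause_responses(rec)["pause_long"]
            assert r.integrated.mean() > 0

    def test_zero_dwba_gives_zero(self, still_agent):
        rec = _session(still_agent)
        for r in bm.pause_responses(rec).values():
            assert np.allclose(r.integrated, 0.0)

    def test_mirror_sessions_have_identical_adjusted_timecourses(self):
        """A session and its mirror image (all orientations negated) give
        the same toward/away timecourse."""
        agent = cl.FlyAgent(k=0.0, noise_sd=0.0, pause_bias=2.0)
        sched = cl.PerturbationSchedule(entries=(("pause_long", 1.0),),
                                        trial_len=20.0)
        rec = cl.run_session(agent, cl.ArenaConfig(), sched, seed=0,
                             orientation0=90.0)
        mirrored = cl.run_session(agent, cl.ArenaConfig(), sched, seed=0,
                                  orientation0=-90.0)
        a = bm.pause_responses(rec)["pause_long"].mean_timecourse
        b = bm.pause_responses(mirrored)["pause_long"].mean_timecourse
        assert np.allclose(a, b)


class TestResponseHistogram:
    def test_collapse_pools_mirror_responses(self):
        values = np.array([30.0, -30.0])
        signs = np.array([+1.0, -1.0])
        edges, probs = bm.response_histogram(values, slip_signs=signs)
        nonzero = np.flatnonzero(probs)
        assert len(nonzero) == 1
        assert probs[nonzero[0]] == 1.0

    def test_all_zero_single_central_bin(self):
        edges, probs = bm.response_histogram(np.zeros(10))
        k = np.flatnonzero(probs)
        assert len(k) == 1
        assert probs[k[0]] == 1.0
        assert edges[k[0]] < 0 < edges[k[0] + 1]

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        _, probs = bm.response_histogram(rng.normal(0, 50, 200))
        assert probs.sum() == pytest.approx(1.0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            bm.response_histogram(np.array([1.0]), bin_width=0.0)


class TestFlySummary:
    def test_summary_table_columns(self, still_agent):
        rec = _session(still_agent)
        table = bm.fly_summary([rec])
        assert len(table) == 1
        assert {"fly_id", "genotype", "mean_orientation_deg",
                "fixation_strength", "toward_fraction"} <= set(table.columns)
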