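"""Generator ground truth: graphs, signals, cohorts, behavior."""

import numpy as np
import pytest

from swnf import feedback, netbuild, swmetrics, synthgen
from swnf.preprocess import PreprocessConfig, intensity_to_od, od_to_conc


def _center(x):
    return x - x.mean(axis=-1, keepdims=True)


class TestMakeWSGraph:
    @pytest.mark.parametrize("p", [0.0, 0.05, 0.3, 1.0])
    def test_edge_count_conserved(self, p):
        net = synthgen.make_ws_graph(35, 10, p, seed=7)
        assert net.adjacency.sum() // 2 == 35 * 10 // 2
        assert not net.adjacency.diagonal().any()
        assert (net.adjacency == net.adjacency.T).all()

    def test_lattice_is_regular_with_closed_form_clustering(self):
        net = synthgen.make_ws_graph(35, 10, 0.0, seed=0)
        assert (net.adjacency.sum(axis=1) == 10).all()
        # ring-lattice closed form C = 3(k-2)/(4(k-1))
        k = 4
        small = synthgen.make_ws_graph(12, k, 0.0, seed=0)
        expected = 3 * (k - 2) / (4 * (k - 1))
        assert swmetrics.clustering_coefficient(small.adjacency) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("bad", [dict(neighbor_k=7),
                                     dict(neighbor_k=36),
                                     dict(rewiring_p=1.5)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            synthgen.make_ws_graph(35, **{"neighbor_k": 10, **bad})

    def test_clustering_nonincreasing_in_p(self):
        ps = [0.0, 0.05, 0.1, 0.3, 1.0]
        means = []
        for p in ps:
            cs = [swmetrics.clustering_coefficient(
                synthgen.make_ws_graph(35, 10, p, seed=s).adjacency)
                for s in range(100)]
            means.append(np.mean(cs))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_intermediate_p_brackets_lattice_and_random(self):
        cs = [swmetrics.clustering_coefficient(
            synthgen.make_ws_graph(35, 10, 0.1, seed=s).adjacency)
            for s in range(100)]
        c_lattice = swmetrics.clustering_coefficient(
            synthgen.make_ws_graph(35, 10, 0.0, seed=0).adjacency)
        c_random = np.mean([swmetrics.clustering_coefficient(
            synthgen.make_ws_graph(35, 10, 1.0, seed=s).adjacency)
            for s in range(100)])
        assert c_random < np.mean(cs) < c_lattice


class TestGenOxyhb:
    def test_deterministic_under_fixed_seed(self):
        net = synthgen.make_ws_graph(seed=1)
        cfg = synthgen.SignalGenConfig(seed=9)
        a = synthgen.gen_oxyhb(net, cfg, 10.0)
        b = synthgen.gen_oxyhb(net, cfg, 10.0)
        assert np.array_equal(a.data, b.data)

    def test_zero_coupling_gives_uncorrelated_channels(self):
        net = synthgen.make_ws_graph(seed=2)
        cfg = synthgen.SignalGenConfig(coupling_strength=0.0, seed=0).clean()
        vals = []
        for s in range(50):
            rec = synthgen.gen_oxyhb(net, cfg, 25.0,
                                     rng=np.random.default_rng(s))
            r = np.corrcoef(rec.data)
            iu = np.triu_indices(35, 1)
            vals.append(np.abs(r[iu]).mean())
        assert np.mean(vals) < 0.15

    def test_coupled_pairs_correlate_more(self):
        net = synthgen.make_ws_graph(seed=3)
        cfg = synthgen.SignalGenConfig(coupling_strength=0.6, seed=0).clean()
        adj = net.adjacency
        iu = np.triu_indices(35, 1)
        on, off = [], []
        for s in range(10):
            rec = synthgen.gen_oxyhb(net, cfg, 25.0,
                                     rng=np.random.default_rng(100 + s))
            r = np.corrcoef(rec.data)
            on.append(r[iu][adj[iu]].mean())
            off.append(r[iu][~adj[iu]].mean())
        assert np.mean(on) > np.mean(off)

    def test_too_short_duration_rejected(self):
        net = synthgen.make_ws_graph(seed=1)
        with pytest.raises(ValueError):
            synthgen.gen_oxyhb(net, synthgen.SignalGenConfig(), 2.0)


class TestGenRawIntensity:
    def test_zero_concentration_gives_constant_intensity(self):
        out = synthgen.gen_raw_intensity(np.zeros((3, 50)), np.zeros((3, 50)))
        assert np.allclose(out, out[..., :1])

    def test_round_trip_identity(self, rng):
        hbo = rng.standard_normal((4, 100))
        hbr = rng.standard_normal((4, 100))
        cfg = PreprocessConfig()
        rec_hbo, rec_hbr = od_to_conc(
            intensity_to_od(synthgen.gen_raw_intensity(hbo, hbr, cfg)), cfg)
        assert np.abs(_center(rec_hbo.data) - _center(hbo)).max() < 1e-9
        assert np.abs(_center(rec_hbr.data) - _center(hbr)).max() < 1e-9

    def test_doubling_dpf_in_generation_halves_recovery(self, rng):
        hbo = rng.standard_normal((2, 80))
        hbr = rng.standard_normal((2, 80))
        gen_cfg = PreprocessConfig(dpf=(12.0, 12.0, 12.0))
        rec_cfg = PreprocessConfig()
        rec, _ = od_to_conc(
            intensity_to_od(synthgen.gen_raw_intensity(hbo, hbr, gen_cfg)),
            rec_cfg)
        assert np.allclose(_center(rec.data), 2 * _center(hbo), atol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        cfg = PreprocessConfig(baseline_intensity=0.0)
        with pytest.raises(ValueError):
            synthgen.gen_raw_intensity(np.zeros((1, 10)), np.zeros((1, 10)),
                                       cfg)


class TestTrainingCohort:
    def test_session_layout(self):
        cohort = synthgen.CohortConfig(n_subjects=1, seed=4)
        cfg = synthgen.SignalGenConfig(seed=4).clean()
        ses = synthgen.gen_subject_day(cohort, cfg, 0, 1)
        assert len(ses.blocks) == 18
        first = ses.blocks[0]
        assert first.baseline.start == 3072            # 120 s rest
        assert first.baseline.stop - first.baseline.start == 384
        assert first.regulation.stop - first.regulation.start == 640
        total = ses.blocks[-1].regulation.stop
        assert ses.recording.n_samples == total

    def test_up_schedule_monotone_per_subject(self):
        cohort = synthgen.CohortConfig(n_subjects=5, seed=5,
                                       subject_p_sd=0.002)
        cfg = synthgen.SignalGenConfig(seed=5).clean()
        for subj in range(5):
            p1 = synthgen.gen_subject_day(cohort, cfg, subj, 1,
                                          include_rest=False).p_regulation
            p5 = synthgen.gen_subject_day(cohort, cfg, subj, 5,
                                          include_rest=False).p_regulation
            assert p5 < p1

    def test_invalid_day_rejected(self):
        cohort = synthgen.CohortConfig(seed=0)
        with pytest.raises(ValueError):
            synthgen.gen_subject_day(cohort, synthgen.SignalGenConfig(),
                                     0, 6)

    def test_recovered_sigma_orders_with_rewiring_p(self):
        """netbuild+swmetrics on generated signals recover the p ordering."""
        cfg = synthgen.SignalGenConfig(seed=0).clean()
        means = []
        for p in (0.05, 0.5, 1.0):
            sigs = []
            for s in range(20):
                net = synthgen.make_ws_graph(35, 10, p, seed=s)
                rec = synthgen.gen_oxyhb(net, cfg, 5.0,
                                         rng=np.random.default_rng(50 + s))
                sigs.append(feedback.sigma_online(rec.data[:, :128],
                                                  n_nulls=10, seed=s))
            means.append(np.mean(sigs))
        assert means[0] > means[1] > means[2]


class TestGenBehavior:
    def test_deterministic(self):
        cohort = synthgen.CohortConfig(seed=11)
        a = synthgen.gen_behavior(cohort)
        b = synthgen.gen_behavior(cohort)
        assert a.equals(b)

    def test_table_shape_and_columns(self):
        cohort = synthgen.CohortConfig(n_subjects=3, seed=1)
        df = synthgen.gen_behavior(cohort)
        assert len(df) == 3 * 3 * 90
        assert set(df.columns) >= {"subject", "group", "day", "condition",
                                   "rt_ms", "correct"}

    def test_zero_effect_config_recovers_zero(self):
        eff = synthgen.BehaviorEffects(
            stroop_delta={"posttest": (0.0, 45.0), "followup": (0.0, 45.0)})
        cohort = synthgen.CohortConfig(behavior=eff, seed=0)
        from swnf.experiments import behavior_recovery
        grand = behavior_recovery(cohort, "posttest", "delta_stroop_ms",
                                  n_cohorts=150, seed=21)
        assert abs(grand) < 3.0
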