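"""First-passage metrics, ensemble profiles and variant ranking."""

import math

import numpy as np
import pytest

from arrestkin.core import AP_RESIDUES, AnalysisConfig, Entity, EventTable
from arrestkin.kinetics import (
    VariantKinetics,
    covered_distance,
    cv_series,
    delta_profile,
    ensemble_profile,
    extraction_time,
    first_displacement_time,
    leu259_release_time,
    ptc_detach_time,
    rank_variants,
)
from arrestkin.synth import (
    default_tunnel,
    render_trajectory,
    sample_ensemble,
    sample_event_table,
)

from conftest import make_topology, make_trajectory


def _linear_motion_traj(speed=0.7, n_frames=11, dt=1.0):
    """Single AP bead moving at `speed` Å/ns along x; one far wall atom."""
    topo = make_topology([(0, 0, 0)], [(50, 0, 0)])
    frames = [[(speed * k * dt, 0, 0), (50, 0, 0)] for k in range(n_frames)]
    return make_trajectory(frames, topo, dt=dt)


class TestFirstPassage:
    def test_linear_motion_crossing_time(self):
        """0.7 Å/ns crosses 3.5 Å strictly only at 4.2 Å, i.e. t = 6 ns."""
        traj = _linear_motion_traj()
        assert first_displacement_time(traj, 237, threshold=3.5) == 6.0

    def test_stationary_residue_censored(self):
        traj = _linear_motion_traj(speed=0.0)
        assert first_displacement_time(traj, 237) is None

    def test_detach_threshold_monotonicity(self):
        traj = _linear_motion_traj()
        t35 = first_displacement_time(traj, 237, threshold=3.5)
        t38 = first_displacement_time(traj, 237, threshold=3.8)
        assert t38 >= t35

    def test_missing_calpha_rejected(self):
        traj = _linear_motion_traj()
        traj.topology.is_calpha[:] = False
        with pytest.raises(ValueError, match="C-alpha"):
            first_displacement_time(traj, 237, mode="CALPHA")


class TestEventTableMetrics:
    def test_extraction_is_difference_per_metric_definition(self):
        """Full solvation at 60 ns with detach at 13 ns gives T = 47 ns."""
        table = EventTable(variant="x", replica=0,
                           t_release={237: 1.0, 259: 12.0, 260: 13.0},
                           t_detach_M260=13.0, extraction_time_T=47.0,
                           exited=True)
        assert extraction_time(table) == 47.0
        assert ptc_detach_time(table) == 13.0

    def test_censored_detach_censors_extraction(self, configs):
        table = sample_event_table(configs["C247K/S255A"], 1)
        assert ptc_detach_time(table) is None
        assert extraction_time(table) is None


class TestTrajectoryMetrics:
    def test_leu259_release_from_rendered_fixture(self, configs, analysis):
        events = sample_event_table(configs["W256A"], seed=9)
        dt = 0.5
        traj = render_trajectory(events, default_tunnel(), dt=dt,
                                 analysis=analysis)
        t = leu259_release_time(traj, cutoff=analysis.contact_cutoff)
        truth = events.t_release[259]
        assert truth <= t <= truth + dt + 1e-9

    def test_unbroken_contact_censored(self, configs, analysis):
        events = sample_event_table(configs["C247K/S255A"], seed=9)
        traj = render_trajectory(events, default_tunnel(), dt=1.0,
                                 analysis=analysis, horizon=10.0)
        assert leu259_release_time(traj) is None

    def test_leu259_equals_brute_force_crossing(self, configs, analysis):
        events = sample_event_table(configs["WT"], seed=2)
        traj = render_trajectory(events, default_tunnel(), dt=0.5,
                                 analysis=analysis)
        topo = traj.topology
        a = np.flatnonzero(topo.ap_mask & (topo.residue_seq == 259))
        b = np.flatnonzero(topo.entity_mask(Entity.P_TRNA))
        expected = None
        for k in range(traj.n_frames):
            d = min(np.linalg.norm(traj.coords[k, i] - traj.coords[k, j])
                    for i in a for j in b)
            if d > analysis.contact_cutoff:
                expected = traj.times[k]
                break
        assert leu259_release_time(traj) == expected

    def test_covered_distance_zero_without_motion(self, configs):
        events = sample_event_table(configs["C247K/S255A"], seed=0)
        # censor everything: no bead moves at all
        frozen = EventTable(variant="x", replica=0,
                            t_release={r: None for r in AP_RESIDUES})
        tunnel = default_tunnel()
        traj = render_trajectory(frozen, tunnel, dt=1.0, horizon=3.0)
        point = tunnel.virtual_point(12.5)
        assert covered_distance(traj, point) == pytest.approx(0.0)

    def test_covered_distance_bounded_by_initial_cv(self, configs):
        events = sample_event_table(configs["WT"], seed=5)
        tunnel = default_tunnel()
        traj = render_trajectory(events, tunnel, dt=0.5)
        point = tunnel.virtual_point(12.5)
        cv = cv_series(traj, point)
        assert covered_distance(traj, point) <= cv[0] + 1e-12


class TestEnsembles:
    def test_delta_profile_single_replica(self):
        table = EventTable(variant="x", replica=0,
                           t_release={237: 2.0, 238: 5.0, 239: 9.0})
        assert delta_profile(table) == {237: 2.0, 238: 3.0, 239: 4.0}

    def test_delta_sums_to_final_release(self, configs):
        table = sample_event_table(configs["WT"], seed=8)
        deltas = delta_profile(table)
        assert sum(deltas.values()) == pytest.approx(table.t_release[260])

    def test_negative_delta_warned_not_clipped(self):
        table = EventTable(variant="x", replica=0,
                           t_release={237: 5.0, 238: 4.0})
        with pytest.warns(RuntimeWarning, match="inversion"):
            deltas = delta_profile(table)
        assert deltas[238] == -1.0

    def test_wt_ensemble_recovers_config_mean(self, configs):
        tables = sample_ensemble(configs["WT"], master_seed=7)
        vk = ensemble_profile(tables, f_L=1.0)
        mean, se = vk.t_M260
        assert vk.n_detached == 20
        assert mean == pytest.approx(13.2, abs=3 * se)

    def test_all_censored_variant(self, configs):
        tables = sample_ensemble(configs["C247K/S255A"], master_seed=7)
        vk = ensemble_profile(tables)
        assert vk.n_detached == 0
        assert vk.t_M260 == (None, None)
        assert vk.t_profile[250][2] == 0  # zero contributing replicas

    def test_censored_values_never_enter_means(self, configs):
        tables = sample_ensemble(configs["C247S/P254C/S255A"], master_seed=3)
        vk = ensemble_profile(tables)
        for res in AP_RESIDUES:
            mean, se, n = vk.t_profile[res]
            uncensored = [t.t_release[res] for t in tables
                          if t.t_release[res] is not None]
            assert n == len(uncensored)
            if n:
                assert mean == pytest.approx(np.mean(uncensored))
            else:
                assert mean is None

    def test_parameter_recovery_over_master_seeds(self, configs):
        """20-replica estimates of the detach and extraction means land
        within 3 SE of the config values in at least 99% of 50 independent
        master seeds, for every variant whose chain is never censored
        (censoring biases the naive config-mean reference)."""
        for name in ("WT", "S255A", "W256A"):
            config = configs[name]
            target_detach = sum(config.residence_mean.values())
            trials, hits = 0, 0
            for seed in range(50):
                tables = sample_ensemble(config, master_seed=seed)
                vk = ensemble_profile(tables)
                mean, se = vk.t_M260
                trials += 1
                hits += abs(mean - target_detach) <= 3 * se
                mT, seT = vk.T_extraction
                if vk.n_exited >= 2:
                    trials += 1
                    hits += abs(mT - config.extraction_mean) <= 3 * seT
            assert hits / trials >= 0.99, f"{name}: {hits}/{trials}"


class TestRanking:
    @staticmethod
    def _vk(name, mean, se, n_detached=20, f_L=None):
        return VariantKinetics(
            variant=name, n_replicas=20, t_profile={}, dt_profile={},
            t_M260=(mean, se), t_L259=(mean, se), T_extraction=(None, None),
            n_detached=n_detached, n_exited=0, D_mean=(None, None), f_L=f_L)

    def test_identical_kinetics_tie_flagged(self):
        ranking = rank_variants([self._vk("a", 10.0, 0.5),
                                 self._vk("b", 10.0, 0.5)])
        assert ("a", "b") in ranking.ties or ("b", "a") in ranking.ties

    def test_fully_censored_variant_ranks_strongest(self):
        ranking = rank_variants([
            self._vk("weak", 10.0, 0.5),
            self._vk("stalled", None, None, n_detached=0),
            self._vk("mid", 25.0, 0.5),
        ])
        assert ranking.order == ["stalled", "mid", "weak"]

    def test_perfect_concordance_gives_spearman_one(self):
        ranking = rank_variants([
            self._vk("s1", 30.0, 0.1, f_L=0.1),
            self._vk("s2", 20.0, 0.1, f_L=0.5),
            self._vk("s3", 10.0, 0.1, f_L=0.9),
        ])
        assert ranking.spearman == pytest.approx(1.0)

    def test_needs_two_variants(self):
        with pytest.raises(ValueError):
            rank_variants([self._vk("a", 1.0, 0.1)])
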