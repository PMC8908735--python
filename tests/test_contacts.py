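"""Contact detection, persistence, networks and RMSD."""

import math

import numpy as np
import pytest

from arrestkin.contacts import (
    CONTACT_NETWORKS,
    contacts_in_frame,
    filter_persistent,
    kabsch_rmsd,
    min_heavy_distance,
    network_timeseries,
    persistence_table,
    persistent_counts_by_residue,
    rmsd_to_reference,
)
from arrestkin.core import AP_RESIDUES, Entity, EventTable, RegionMap
from arrestkin.synth import default_tunnel, render_trajectory

from conftest import make_topology, make_trajectory


def _random_mixed_topology(n_atoms, rng):
    """Half AP / half ribosome atoms with spread residue numbers."""
    n_ap = n_atoms // 2
    ap_pos = [(0, 0, 0)] * n_ap
    other = [(0, 0, 0)] * (n_atoms - n_ap)
    topo = make_topology(ap_pos, other)
    # spread AP beads over the 24 residues so INTRA exclusion matters
    topo.residue_seq[:n_ap] = rng.integers(237, 261, size=n_ap)
    return topo


class TestMinDistance:
    def test_two_atoms(self):
        frame = np.array([[0.0, 0, 0], [3.4, 0, 0]])
        assert min_heavy_distance(frame, [0], [1]) == pytest.approx(3.4)

    def test_empty_group_rejected(self):
        frame = np.zeros((2, 3))
        with pytest.raises(ValueError, match="empty"):
            min_heavy_distance(frame, [], [1])

    def test_overlapping_groups_rejected(self):
        frame = np.zeros((2, 3))
        with pytest.raises(ValueError, match="disjoint"):
            min_heavy_distance(frame, [0, 1], [1])


class TestContactsInFrame:
    def test_inter_pair_within_cutoff(self):
        topo = make_topology([(0, 0, 0)], [(3.2, 0, 0)])
        frame = np.array([[0.0, 0, 0], [3.2, 0, 0]])
        pairs = contacts_in_frame(frame, topo, cutoff=3.5)
        assert len(pairs) == 1
        kind, res, partner = next(iter(pairs))
        assert kind == "INTER" and res == 237
        assert partner[0] == Entity.RIBOSOME.value

    def test_adjacent_residues_excluded_from_intra(self):
        topo = make_topology([(0, 0, 0), (2.0, 0, 0)])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert contacts_in_frame(frame, topo, cutoff=3.5) == set()

    def test_separated_residues_make_intra(self):
        topo = make_topology([(0, 0, 0), (50, 0, 0), (2.0, 0, 0)])
        frame = np.array([[0.0, 0, 0], [50, 0, 0], [2.0, 0, 0]])
        pairs = contacts_in_frame(frame, topo, cutoff=3.5)
        assert pairs == {("INTRA", 237, (Entity.AP.value, 239, "UNK"))}

    def test_tiny_cutoff_empty(self):
        topo = make_topology([(0, 0, 0)], [(3.2, 0, 0)])
        frame = np.array([[0.0, 0, 0], [3.2, 0, 0]])
        assert contacts_in_frame(frame, topo, cutoff=1e-9) == set()

    def test_tie_at_cutoff_counts_as_contact(self):
        topo = make_topology([(0, 0, 0)], [(3.5, 0, 0)])
        frame = np.array([[0.0, 0, 0], [3.5, 0, 0]])
        assert len(contacts_in_frame(frame, topo, cutoff=3.5)) == 1

    def test_tree_equals_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            topo = _random_mixed_topology(100, rng)
            frame = rng.uniform(0, 30, size=(100, 3))
            fast = contacts_in_frame(frame, topo, cutoff=3.5)
            slow = contacts_in_frame(frame, topo, cutoff=3.5,
                                     brute_force=True)
            assert fast == slow


class TestPersistence:
    def _blinking_traj(self):
        """AP bead in contact with the wall atom in frames 1-3 of 4."""
        topo = make_topology([(0, 0, 0)], [(3.0, 0, 0)])
        frames = [
            [(0, 0, 0), (30, 0, 0)],
            [(27, 0, 0), (30, 0, 0)],
            [(27, 0, 0), (30, 0, 0)],
            [(27, 0, 0), (30, 0, 0)],
        ]
        return make_trajectory(frames, topo)

    def test_persistence_fraction(self):
        records = persistence_table(self._blinking_traj(), cutoff=3.5)
        assert len(records) == 1
        assert records[0].persistence == pytest.approx(0.75)

    def test_threshold_filter_monotone(self):
        records = persistence_table(self._blinking_traj(), cutoff=3.5)
        strict = set((r.ap_residue, r.partner) for r in
                     filter_persistent(records, 0.75))
        loose = set((r.ap_residue, r.partner) for r in
                    filter_persistent(records, 0.50))
        assert strict <= loose

    def test_counts_monotone_in_threshold(self, configs):
        from arrestkin.synth import sample_event_table

        events = EventTable(variant="stall", replica=0,
                            t_release={r: None for r in AP_RESIDUES})
        traj = render_trajectory(events, default_tunnel(), dt=1.0,
                                 horizon=4.0)
        records = persistence_table(traj, cutoff=3.5)
        counts = persistent_counts_by_residue(records, RegionMap())
        for kind in ("inter", "intra"):
            assert (counts[f"{kind}_75"] <= counts[f"{kind}_50"]).all()

    def test_empty_records_all_zero(self):
        counts = persistent_counts_by_residue([], RegionMap())
        assert (counts[["inter_50", "inter_75", "intra_50", "intra_75"]]
                .to_numpy() == 0).all()

    def test_stalled_fixture_ct_exceeds_nt(self):
        """A fully stalled chain keeps every anchor contact with persistence
        1.0, and the C-terminal region has more persistent intermolecular
        contacts than the N-terminal one (site density encodes this)."""
        events = EventTable(variant="stall", replica=0,
                            t_release={r: None for r in AP_RESIDUES})
        traj = render_trajectory(events, default_tunnel(), dt=1.0,
                                 horizon=4.0)
        records = persistence_table(traj, cutoff=3.5)
        inter = [r for r in records if r.kind == "INTER"]
        by_res = {}
        for r in inter:
            by_res.setdefault(r.ap_residue, []).append(r)
        for res in AP_RESIDUES:
            assert any(rec.persistence == 1.0 for rec in by_res[res])
        counts = persistent_counts_by_residue(inter, RegionMap())
        ct = counts[counts.region == "CT"]["inter_75"].sum()
        nt = counts[counts.region == "NT"]["inter_75"].sum()
        assert ct > nt


class TestNetworks:
    def _cluster_topology(self):
        members = sorted(CONTACT_NETWORKS["CN3"] | CONTACT_NETWORKS["CN1"])
        positions = [(0, 0, 0)] * len(members)
        topo = make_topology(positions, [])
        topo.residue_seq[:] = members
        return topo, members

    def test_clustered_members_intact(self):
        topo, members = self._cluster_topology()
        # CN3 members clustered within 3 Å; CN1 members far apart
        frame = []
        for res in members:
            if res in CONTACT_NETWORKS["CN3"]:
                frame.append((0.0, 1.0 * (res - 250), 0.0))
            else:
                frame.append((50.0 + 20 * (res - 247), 0, 0))
        traj = make_trajectory([frame, frame], topo)
        nets = {k: CONTACT_NETWORKS[k] for k in ("CN1", "CN3")}
        ts = network_timeseries(traj, networks=nets, cutoff=3.5)
        assert ts["CN3"].all()
        assert not ts["CN1"].any()

    def test_displaced_member_breaks_network(self):
        topo, members = self._cluster_topology()
        frame = [(0.0, 1.0 * (res - 250), 0.0) if res in
                 CONTACT_NETWORKS["CN3"] else (50, 0, 0) for res in members]
        broken = list(frame)
        broken[members.index(256)] = (0.0, 20.0, 0.0)
        traj = make_trajectory([frame, broken], topo)
        ts = network_timeseries(traj, networks={"CN3": CONTACT_NETWORKS["CN3"]},
                                cutoff=3.5)
        assert bool(ts["CN3"].iloc[0]) and not bool(ts["CN3"].iloc[1])

    def test_cn3_at_least_as_stable_as_cn1_on_encoded_fixture(self):
        """Fixture built so CN3 stays clustered while CN1 breaks halfway."""
        topo, members = self._cluster_topology()
        def frame(cn1_intact):
            out = []
            for res in members:
                if res in CONTACT_NETWORKS["CN3"]:
                    out.append((0.0, 1.2 * (res - 250), 0.0))
                elif cn1_intact:
                    out.append((50.0, 1.2 * (res - 248), 0.0))
                else:
                    out.append((50.0 + 20 * (res - 247), 0.0, 0.0))
            return out
        frames = [frame(True), frame(True), frame(False), frame(False)]
        nets = {k: CONTACT_NETWORKS[k] for k in ("CN1", "CN3")}
        ts = network_timeseries(make_trajectory(frames, topo), networks=nets,
                                cutoff=3.5)
        assert ts["CN3"].mean() >= ts["CN1"].mean()


class TestRMSD:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(5, 3))
        assert kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(6, 3))
        moved = ref + np.array([1.0, 2.0, 2.0])
        assert kabsch_rmsd(moved, ref) == pytest.approx(0.0, abs=1e-10)
        # arbitrary proper rotation
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        assert kabsch_rmsd(ref @ rot.T + 3.0, ref) == pytest.approx(
            0.0, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a))

    def test_small_case_matches_independent_superposition(self):
        """Cross-check the Kabsch implementation against MDAnalysis on a
        3-atom toy with fixed printed coordinates."""
        rms = pytest.importorskip("MDAnalysis.analysis.rms")
        a = np.array([[0.0, 0.0, 0.0], [1.5, 0.2, 0.0], [0.3, 1.8, 0.4]])
        b = np.array([[0.1, -0.1, 0.0], [1.4, 0.4, 0.1], [0.5, 1.6, 0.2]])
        expected = rms.rmsd(a, b, superposition=True)
        assert kabsch_rmsd(a, b) == pytest.approx(expected, abs=1e-6)

    def test_trajectory_rmsd_selection(self):
        topo = make_topology([(0, 0, 0), (3.8, 0, 0)])
        frames = [[(0, 0, 0), (3.8, 0, 0)],
                  [(1, 2, 2), (4.8, 2, 2)],     # pure translation
                  [(0, 0, 0), (5.8, 0, 0)]]     # stretched
        traj = make_trajectory(frames, topo)
        out = rmsd_to_reference(traj, traj.coords[0], [0, 1])
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(0.0, abs=1e-10)
        assert out[2] > 0.5

    def test_empty_selection_rejected(self):
        topo = make_topology([(0, 0, 0)])
        traj = make_trajectory([[(0, 0, 0)]], topo)
        with pytest.raises(ValueError, match="empty"):
            rmsd_to_reference(traj, traj.coords[0], [])
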