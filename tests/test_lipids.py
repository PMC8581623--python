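"""Dual-cutoff contacts, interaction graphs, binding sites, g(r)."""

import networkx as nx
import numpy as np
import pytest

from oligokin.lipids import (
    build_interaction_graph,
    contact_intervals,
    detect_binding_sites,
    detect_contacts_dual_cutoff,
    radial_distribution,
    residue_residence_times,
    site_kinetics,
)
from oligokin.synthetic import LipidContactData, generate_lipid_distance_series


def make_data(segments, n_frames=100, frame_dt=1.0, far=3.0, n_residues=10):
    return LipidContactData(
        n_frames=n_frames,
        frame_dt=frame_dt,
        n_residues=n_residues,
        segments={
            k: (start, np.asarray(vals, dtype=float))
            for k, (start, vals) in segments.items()
        },
        far_distance=far,
        true_site_members=[],
        true_durations=np.array([]),
        true_koff=np.nan,
    )


class TestDualCutoff:
    def test_always_far_yields_nothing(self):
        assert contact_intervals(np.full(50, 2.0)) == []

    def test_hand_traced_hysteresis(self):
        # enter at frame 1 (<0.55), survive 0.8/0.9 (<=1.0), exit at 1.2,
        # re-enter at frame 5, exit at 2.0
        series = [2.0, 0.5, 0.8, 0.9, 1.2, 0.5, 2.0]
        ivals = contact_intervals(np.array(series), frame_dt=1.0)
        assert ivals == [(1.0, 4.0), (5.0, 6.0)]

    def test_never_entering_stays_out(self):
        series = np.array([2.0, 0.7, 0.7, 0.9, 2.0])
        assert contact_intervals(series) == []

    def test_truncated_at_series_end(self):
        ivals = contact_intervals(np.array([2.0, 0.4, 0.6]), frame_dt=1.0)
        assert ivals == [(1.0, 3.0)]

    def test_idempotent_on_own_frames(self):
        rng = np.random.default_rng(0)
        series = np.concatenate(
            [[2.0], rng.uniform(0.3, 0.5, 20), [2.0]]
        )
        (a, b), = contact_intervals(series, frame_dt=1.0)
        inner = series[int(a) : int(b)]
        again = contact_intervals(inner, frame_dt=1.0, start_frame=int(a))
        assert again == [(a, b)]

    def test_rejects_inverted_cutoffs(self):
        with pytest.raises(ValueError):
            contact_intervals(np.zeros(5), lower=1.0, upper=0.5)


class TestResidueProfiles:
    def test_site_member_residence_matches_truth(self):
        data = generate_lipid_distance_series(
            0.1, n_residues=6, site_members={0, 1, 2}, n_frames=60_000, seed=1
        )
        contacts = detect_contacts_dual_cutoff(data)
        profiles = {p.residue: p for p in residue_residence_times(contacts)}
        assert set(profiles) == {0, 1, 2}
        for res in (0, 1, 2):
            assert abs(profiles[res].residence_time - 10.0) / 10.0 < 0.15

    def test_nonmember_absent_and_occupancy_bounds(self):
        data = generate_lipid_distance_series(
            0.1, n_residues=6, site_members={0}, n_frames=5000, seed=2
        )
        contacts = detect_contacts_dual_cutoff(data)
        profiles = residue_residence_times(contacts)
        assert all(p.residue == 0 for p in profiles)
        assert all(0 <= p.occupancy <= 1 for p in profiles)

    def test_always_bound_residue_has_unit_occupancy(self):
        data = make_data({(0, 0): (0, [0.4] * 100)}, n_frames=100)
        contacts = detect_contacts_dual_cutoff(data)
        (p,) = residue_residence_times(contacts)
        assert p.occupancy == pytest.approx(1.0)


class TestInteractionGraph:
    def test_no_shared_lipid_no_edge(self):
        data = make_data(
            {(0, 0): (0, [0.4] * 50), (1, 1): (0, [0.4] * 50)}, n_frames=100
        )
        G = build_interaction_graph(detect_contacts_dual_cutoff(data))
        assert not G.has_edge(0, 1)

    def test_half_time_co_contact_weight(self):
        data = make_data(
            {(0, 5): (0, [0.4] * 100), (1, 5): (0, [0.4] * 50)}, n_frames=100
        )
        G = build_interaction_graph(detect_contacts_dual_cutoff(data))
        assert G[0][1]["weight"] == pytest.approx(0.5)

    def test_graph_symmetric(self):
        data = generate_lipid_distance_series(
            0.1, n_residues=8, site_members={0, 1, 2, 3}, n_frames=5000, seed=3
        )
        G = build_interaction_graph(detect_contacts_dual_cutoff(data))
        for i, j, w in G.edges(data="weight"):
            assert G[j][i]["weight"] == w


class TestBindingSites:
    def test_disconnected_cliques_are_two_sites(self):
        G = nx.Graph()
        for base in (0, 10):
            for i in range(5):
                for j in range(i + 1, 5):
                    G.add_edge(base + i, base + j, weight=1.0)
        sites = detect_binding_sites(G, seed=0)
        assert len(sites) == 2
        assert {frozenset(range(5)), frozenset(range(10, 15))} == {
            s.residues for s in sites
        }

    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(4)
        G = nx.Graph()
        groups = [list(range(10)), list(range(10, 20)), list(range(20, 30))]
        nodes = [n for g in groups for n in g]
        for a_idx in range(len(nodes)):
            for b_idx in range(a_idx + 1, len(nodes)):
                a, b = nodes[a_idx], nodes[b_idx]
                same = a // 10 == b // 10
                p = 0.9 if same else 0.05
                if rng.random() < p:
                    G.add_edge(a, b, weight=1.0)
        sites = detect_binding_sites(G, seed=0)
        # assignment accuracy vs planted labels (best matching)
        correct = 0
        for s in sites:
            votes = [sum(1 for r in s.residues if r // 10 == g) for g in range(3)]
            correct += max(votes)
        assert correct / 30 >= 0.95

    def test_single_edge_graph(self):
        G = nx.Graph()
        G.add_edge(3, 7, weight=1.0)
        sites = detect_binding_sites(G, seed=0)
        assert len(sites) == 1 and sites[0].residues == frozenset({3, 7})

    def test_empty_graph_no_sites(self):
        assert detect_binding_sites(nx.Graph(), seed=0) == []

    def test_deterministic_under_seed(self):
        data = generate_lipid_distance_series(
            0.1,
            n_residues=12,
            site_members=[{0, 1, 2}, {6, 7, 8}],
            n_frames=20_000,
            seed=5,
        )
        G = build_interaction_graph(detect_contacts_dual_cutoff(data))
        a = detect_binding_sites(G, seed=9)
        b = detect_binding_sites(G, seed=9)
        assert [s.residues for s in a] == [s.residues for s in b]


class TestSiteKinetics:
    def test_single_residue_site_reduces_to_residue_profile(self):
        data = generate_lipid_distance_series(
            0.1, n_residues=4, site_members={2}, n_frames=30_000, seed=6
        )
        contacts = detect_contacts_dual_cutoff(data)
        (profile,) = residue_residence_times(contacts)
        from oligokin.lipids import BindingSite

        site = site_kinetics(BindingSite(1, frozenset({2})), data)
        assert site.site_residence_time == pytest.approx(profile.residence_time)
        assert site.n_events == profile.n_events

    def test_alternating_residues_give_one_long_interval(self):
        # lipid 0 alternates between residues 0 and 1 without ever leaving
        a = np.array(([0.4] * 5 + [2.0] * 5) * 4, dtype=float)
        b = np.array(([2.0] * 5 + [0.4] * 5) * 4, dtype=float)
        data = make_data({(0, 0): (0, a), (1, 0): (0, b)}, n_frames=40)
        from oligokin.lipids import BindingSite

        site = site_kinetics(BindingSite(1, frozenset({0, 1})), data)
        assert site.n_events == 1
        contacts = detect_contacts_dual_cutoff(data)
        per_res = residue_residence_times(contacts)
        assert site.site_residence_time > max(
            p.residence_time for p in per_res
        )

    def test_three_concurrent_lipids(self):
        segs = {(0, lip): (0, [0.4] * 100) for lip in range(3)}
        data = make_data(segs, n_frames=100)
        from oligokin.lipids import BindingSite

        site = site_kinetics(BindingSite(1, frozenset({0})), data)
        assert site.mean_lipid_count == pytest.approx(3.0)

    def test_site_residence_at_least_member_max(self):
        data = generate_lipid_distance_series(
            0.05, n_residues=8, site_members={0, 1, 2, 3}, n_frames=50_000, seed=7
        )
        contacts = detect_contacts_dual_cutoff(data)
        per_res = residue_residence_times(contacts)
        from oligokin.lipids import BindingSite

        site = site_kinetics(BindingSite(1, frozenset({0, 1, 2, 3})), data)
        assert site.site_residence_time >= max(
            p.residence_time for p in per_res
        ) * (1 - 1e-9)


class TestRadialDistribution:
    BOX = np.array([30.0, 30.0])

    def test_uniform_lipids_are_flat(self):
        rng = np.random.default_rng(8)
        lipids = rng.uniform(0, 30, size=(20_000, 2))
        ref = np.array([[15.0, 15.0]])
        rd = radial_distribution(lipids, ref, self.BOX, bins=15, r_max=12.0)
        # Poisson standard error per bin
        se = 1.0 / np.sqrt(np.maximum(rd.counts, 1))
        ok = np.abs(rd.g - 1.0) <= 3 * np.maximum(se, 0.05)
        assert ok[rd.counts > 50].all()

    def test_pinned_lipids_make_a_spike(self):
        ref = np.array([[15.0, 15.0]])
        lipids = np.tile([16.0, 15.0], (500, 1))  # all at distance 1
        rd = radial_distribution(lipids, ref, self.BOX, bins=20, r_max=10.0)
        assert np.nanargmax(rd.g) == 2  # bin [1.0, 1.5)
        assert rd.counts[2] == 500

    def test_density_normalization_cancels_count(self):
        rng = np.random.default_rng(9)
        lipids = rng.uniform(0, 30, size=(5000, 2))
        ref = np.array([[10.0, 10.0], [20.0, 20.0]])
        g1 = radial_distribution(lipids, ref, self.BOX, bins=10, r_max=8).g
        g2 = radial_distribution(
            np.vstack([lipids, lipids]), ref, self.BOX, bins=10, r_max=8
        ).g
        assert np.allclose(g1, g2, equal_nan=True)
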