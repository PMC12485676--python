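"""Salt-bridge detection, site assignment and occupancy statistics."""

import numpy as np
import pytest

import cttaccess as ct
from cttaccess.contacts import (
    ContactTimeline,
    SaltBridgeCriterion,
    default_site_registry,
)
from cttaccess.structio import BoxGeometry, ChainLabels, LatticeModel

from conftest import brute_force_salt_bridges


def _two_residue_model(distance):
    """A glutamate (chain T) and an arginine (chain B) with OE1-NH1 at
    the requested distance."""
    names = ["OE1", "OE2", "NH1", "NE", "NH2"]
    elements = ["O", "O", "N", "N", "N"]
    res_names = ["GLU", "GLU", "ARG", "ARG", "ARG"]
    res_ids = [445, 445, 390, 390, 390]
    chains = ["T", "T", "B", "B", "B"]
    coord = np.array([
        [0, 0, 0], [1.0, 1.0, 0],
        [distance, 0, 0], [distance + 1.2, 0.5, 0], [distance + 1.0, -1.0, 0],
    ], dtype=float)
    # the tail chain sits one ring above the body chain, so chain B is
    # its trans (minus-end) neighbour
    return LatticeModel(
        names, elements, res_names, res_ids, chains, coord,
        {"T": ChainLabels("alpha", 0, 1, 1), "B": ChainLabels("beta", 0, 0, 0)},
    )


class TestDetect:
    def test_contact_within_cutoff(self):
        m = _two_residue_model(3.2)
        got = ct.detect_salt_bridges(
            m.coord, m, SaltBridgeCriterion(), np.array([0, 1]),
            np.array([2, 3, 4]),
        )
        assert got == {("T", 445, "B", 390)}

    def test_no_contact_beyond_cutoff(self):
        m = _two_residue_model(6.0)
        got = ct.detect_salt_bridges(
            m.coord, m, SaltBridgeCriterion(), np.array([0, 1]),
            np.array([2, 3, 4]),
        )
        assert got == set()

    def test_residue_level_deduplication(self):
        m = _two_residue_model(2.8)  # several atom pairs within cutoff
        got = ct.detect_salt_bridges(
            m.coord, m, SaltBridgeCriterion(), np.array([0, 1]),
            np.array([2, 3, 4]),
        )
        assert len(got) == 1

    def test_matches_brute_force_on_random_frames(self):
        """Neighbour-list detection equals the all-pairs oracle on random
        coordinate sets, including periodic straddles (small version of
        the acceptance check)."""
        rng = np.random.default_rng(21)
        n = 120
        names, elements, res_names, res_ids, chains = [], [], [], [], []
        for i in range(n // 2):
            names += ["OE1", "OE2"]
            elements += ["O", "O"]
            res_names += ["GLU", "GLU"]
            res_ids += [500 + i, 500 + i]
            chains += ["T", "T"]
        for i in range(n // 4):
            names += ["NZ"]
            elements += ["N"]
            res_names += ["LYS"]
            res_ids += [100 + i]
            chains += ["B"]
        m = LatticeModel(
            names, elements, res_names, res_ids, chains,
            np.zeros((len(names), 3)),
            {"T": ChainLabels("alpha", 0, 0, 0),
             "B": ChainLabels("beta", 0, 0, 0)},
        )
        tail_sel = np.nonzero(m.chain_id == "T")[0]
        body_sel = np.nonzero(m.chain_id == "B")[0]
        box = BoxGeometry(mode="axial_periodic", axial_length=30.0)
        crit = SaltBridgeCriterion()
        for trial in range(20):
            frame = rng.uniform(0, 30, size=(m.n_atoms, 3))
            got = ct.detect_salt_bridges(
                frame, m, crit, tail_sel, body_sel, box
            )
            expected = brute_force_salt_bridges(
                frame, m, crit, tail_sel, body_sel, box
            )
            assert got == expected

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(4)
        m = _two_residue_model(3.9)
        frame = m.coord + rng.normal(0, 0.05, m.coord.shape)
        small = ct.detect_salt_bridges(
            frame, m, SaltBridgeCriterion(cutoff=3.0),
            np.array([0, 1]), np.array([2, 3, 4]),
        )
        large = ct.detect_salt_bridges(
            frame, m, SaltBridgeCriterion(cutoff=5.0),
            np.array([0, 1]), np.array([2, 3, 4]),
        )
        assert small <= large


class TestAssignSites:
    def test_site1_on_trans_minus_neighbor(self, periodic_tailed_lattice):
        tailed, _ = periodic_tailed_lattice
        # tail on the ring-1 dimer of protofilament 0
        tail_chain = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "alpha"
            and tailed.labels[c].ring_index == 1
            and tailed.labels[c].protofilament_index == 0
        )
        beta_minus = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "beta"
            and tailed.labels[c].ring_index == 0
            and tailed.labels[c].protofilament_index == 0
        )
        labeled = ct.assign_sites(
            [(tail_chain, 441, beta_minus, 390)],
            default_site_registry(), tailed,
        )
        assert labeled[0].site == 1

    def test_wrong_protofilament_is_other(self, periodic_tailed_lattice):
        tailed, _ = periodic_tailed_lattice
        tail_chain = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "alpha"
            and tailed.labels[c].ring_index == 1
            and tailed.labels[c].protofilament_index == 0
        )
        wrong_beta = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "beta"
            and tailed.labels[c].ring_index == 0
            and tailed.labels[c].protofilament_index == 2
        )
        labeled = ct.assign_sites(
            [(tail_chain, 441, wrong_beta, 390)],
            default_site_registry(), tailed,
        )
        assert labeled[0].site == "other"

    def test_periodic_wrap_to_top_ring(self, periodic_tailed_lattice):
        """The ring-0 tail's minus neighbour is the top ring's β across
        the periodic boundary."""
        tailed, _ = periodic_tailed_lattice
        n_rings = max(
            tailed.labels[c].ring_index or 0 for c in tailed.chains()
        ) + 1
        tail_chain = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "alpha"
            and tailed.labels[c].ring_index == 0
            and tailed.labels[c].protofilament_index == 0
        )
        top_beta = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "beta"
            and tailed.labels[c].ring_index == n_rings - 1
            and tailed.labels[c].protofilament_index == 0
        )
        labeled = ct.assign_sites(
            [(tail_chain, 445, top_beta, 174)],
            default_site_registry(), tailed,
        )
        assert labeled[0].site == 2

    def test_no_wrap_without_periodicity(self, small_lattice):
        lattice, _ = small_lattice
        tailed = ct.append_tail(
            lattice, ct.TailSpec(target_role="alpha", seed=1)
        )
        tail_chain = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "alpha"
            and tailed.labels[c].ring_index == 0
            and tailed.labels[c].protofilament_index == 0
        )
        top_beta = next(
            c for c in tailed.chains()
            if tailed.labels[c].subunit_role == "beta"
            and tailed.labels[c].ring_index == 1
            and tailed.labels[c].protofilament_index == 0
        )
        labeled = ct.assign_sites(
            [(tail_chain, 445, top_beta, 174)],
            default_site_registry(), tailed,
        )
        assert labeled[0].site == "other"

    def test_cis_site_on_own_chain_only(self, periodic_tailed_lattice):
        tailed, _ = periodic_tailed_lattice
        alphas = [c for c in tailed.chains()
                  if tailed.labels[c].subunit_role == "alpha"]
        own, foreign = alphas[0], alphas[1]
        got = ct.assign_sites(
            [(own, 449, own, 112), (own, 449, foreign, 112)],
            default_site_registry(), tailed,
        )
        assert got[0].site == 4
        assert got[1].site == "other"

    def test_partition_into_sites_or_other(self, periodic_tailed_lattice):
        tailed, _ = periodic_tailed_lattice
        alphas = [c for c in tailed.chains()
                  if tailed.labels[c].subunit_role == "alpha"]
        betas = [c for c in tailed.chains()
                 if tailed.labels[c].subunit_role == "beta"]
        registry = default_site_registry()
        contacts = [
            (alphas[0], 445, b, num)
            for b in betas
            for s in registry
            for num, _ in s.residues
        ]
        labeled = ct.assign_sites(contacts, registry, tailed)
        assert all(lc.site in (1, 2, 3, 4, "other") for lc in labeled)
        assert len(labeled) == len(contacts)  # every contact retained


def _random_timeline(rng, p, n_tails=5, n_frames=4000):
    residues = list(ct.GLUTAMATE_RESIDUES)
    occ = rng.random((n_tails, len(residues), 4, n_frames)) < p
    return ContactTimeline(
        [f"T{i}" for i in range(n_tails)], residues, [1, 2, 3, 4], occ, 0.1
    )


class TestStatistics:
    def test_zero_timeline_gives_zero_matrix(self):
        tl = _random_timeline(np.random.default_rng(0), p=0.0, n_frames=50)
        m = ct.interaction_rates(tl)
        assert (m.values == 0).all()

    def test_always_bound_cell_is_one(self):
        rng = np.random.default_rng(0)
        tl = _random_timeline(rng, p=0.0, n_frames=50)
        tl.occupancy[:, 0, 0, :] = True  # (E441, site 1) in every frame
        m = ct.interaction_rates(tl)
        assert m.cell(441, 1) == 1.0
        assert m.cell(443, 1) == 0.0

    def test_bernoulli_rate_recovery(self):
        p = 0.3
        n_tails, n_frames = 5, 10_000
        tl = _random_timeline(np.random.default_rng(0), p, n_tails, n_frames)
        m = ct.interaction_rates(tl)
        se = np.sqrt(p * (1 - p) / (n_tails * n_frames))
        assert np.abs(m.values - p).max() < 3 * se

    def test_rates_averaged_over_trajectories(self):
        rng = np.random.default_rng(1)
        a = _random_timeline(rng, 0.0, n_frames=10)
        b = _random_timeline(rng, 0.0, n_frames=10)
        a.occupancy[:, 0, 0, :] = True
        m = ct.interaction_rates([a, b])
        assert m.cell(441, 1) == pytest.approx(0.5)

    def test_invalid_cells_excluded_from_denominator(self):
        tl = _random_timeline(np.random.default_rng(2), 0.0, n_tails=4,
                              n_frames=20)
        tl.occupancy[0, 0, 0, :] = True  # tail 0 bound at site 1 always
        tl.valid[1:, 0] = False  # only tail 0 has a site-1 partner
        m = ct.interaction_rates(tl)
        assert m.cell(441, 1) == pytest.approx(1.0)

    def test_trace_all_false_and_all_true(self):
        tl = _random_timeline(np.random.default_rng(0), 0.0, n_frames=30)
        assert (ct.inaccessibility_trace(tl).fraction_inaccessible == 0).all()
        tl.occupancy[:] = True
        assert (ct.inaccessibility_trace(tl).fraction_inaccessible == 1).all()

    def test_trace_independence_closed_form(self):
        """With independent stationary per-(residue, site) occupancies q,
        the per-tail inaccessibility expectation is 1 - prod(1 - q)."""
        q = 0.05
        rng = np.random.default_rng(31)
        tl = _random_timeline(rng, q, n_tails=8, n_frames=10_000)
        trace = ct.inaccessibility_trace(tl)
        cells = len(ct.INACCESSIBLE_RESIDUES) * 4
        expected = 1 - (1 - q) ** cells
        se = np.sqrt(expected * (1 - expected) / (8 * 10_000))
        assert abs(trace.time_average() - expected) < 3 * se

    def test_per_residue_mode(self):
        tl = _random_timeline(np.random.default_rng(0), 0.0, n_frames=10)
        tl.occupancy[:, tl.tail_residues.index(445), 0, :] = True
        trace = ct.inaccessibility_trace(tl, mode="per_residue")
        assert trace.fraction_inaccessible == pytest.approx(
            np.full(10, 1 / len(ct.INACCESSIBLE_RESIDUES))
        )

    def test_smoothing_window(self):
        tl = _random_timeline(np.random.default_rng(0), 0.0, n_frames=4)
        tl.occupancy[:, 2, 0, 1] = True  # one fully bound frame
        raw = ct.inaccessibility_trace(tl).fraction_inaccessible
        smooth = ct.inaccessibility_trace(
            tl, smoothing_window=2
        ).fraction_inaccessible
        assert raw.tolist() == [0, 1, 0, 0]
        assert smooth.tolist() == [0, 0.5, 0.5, 0]

    def test_empty_residue_set_errors(self):
        tl = _random_timeline(np.random.default_rng(0), 0.0, n_frames=5)
        with pytest.raises(ValueError, match="empty"):
            ct.inaccessibility_trace(tl, residues=[])

    def test_trace_monotone_in_cutoff_framewise(self):
        """Enlarging the cutoff can only add contacts, so the per-frame
        inaccessibility is monotone non-decreasing in the cutoff."""
        m = _two_residue_model(3.9)
        frames = [m.coord + d for d in np.zeros((6, 3))]
        traj = ct.Trajectory(m, frames, 0.1)
        vals = []
        for cutoff in (3.0, 4.0, 5.0):
            tl = ct.build_timeline(
                traj, criterion=SaltBridgeCriterion(cutoff=cutoff),
                tail_residues=[445],
            )
            tr = ct.inaccessibility_trace(tl, residues=[445])
            vals.append(tr.fraction_inaccessible)
        assert (vals[0] <= vals[1]).all() and (vals[1] <= vals[2]).all()


class TestTimeline:
    def test_contacts_only_in_planted_frame(self):
        m = _two_residue_model(20.0)
        close = m.coord.copy()
        close[0] = close[2] + np.array([3.0, 0, 0])  # OE1 near NH1
        frames = [m.coord, close, m.coord]
        tl = ct.build_timeline(
            ct.Trajectory(m, frames, 0.1), tail_residues=[445]
        )
        bound = tl.occupancy.any(axis=(0, 1, 2))
        assert bound.tolist() == [False, True, False]

    def test_concatenation(self):
        m = _two_residue_model(3.0)
        t1 = ct.build_timeline(
            ct.Trajectory(m, [m.coord], 0.1), tail_residues=[445]
        )
        t2 = ct.build_timeline(
            ct.Trajectory(m, [m.coord + 50.0], 0.1), tail_residues=[445]
        )
        both = ct.build_timeline(
            ct.Trajectory(m, [m.coord, m.coord + 50.0], 0.1),
            tail_residues=[445],
        )
        assert (t1.concat(t2).occupancy == both.occupancy).all()

    def test_streaming_equals_eager(self, tmp_path, periodic_tailed_lattice):
        tailed, _ = periodic_tailed_lattice
        kin = ct.preset("gdp_like", n_frames=20, seed=9)
        traj, _ = ct.simulate_binding(kin, tailed)
        eager = ct.Trajectory(tailed, [f.copy() for f in traj],
                              traj.frame_interval_ns)
        a = ct.build_timeline(traj)
        b = ct.build_timeline(eager)
        assert (a.occupancy == b.occupancy).all()


class TestRegistryAndExport:
    def test_default_registry_shape(self):
        reg = default_site_registry()
        assert len(reg) == 4
        assert len(reg.by_id(2).residues) == 5
        assert {s.host for s in reg} == {"trans_beta_minus", "cis_alpha"}
        assert [n for n, _ in reg.by_id(1).residues] == [390, 391, 392]

    def test_registry_tsv_round_trip(self, tmp_path):
        reg = default_site_registry()
        p = tmp_path / "sites.tsv"
        reg.to_table(p)
        back = ct.SiteRegistry.from_table(p)
        assert back == reg

    def test_export_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        m = ct.InteractionRateMatrix(
            list(ct.GLUTAMATE_RESIDUES), [1, 2, 3, 4],
            rng.random((7, 4)),
        )
        tr = ct.AccessibilityTrace(
            np.arange(1, 11) * 0.1, rng.random(10)
        )
        paths = ct.export_results(m, tr, tmp_path / "out")
        m2 = ct.read_rate_matrix(paths["rates"])
        tr2 = ct.read_trace(paths["trace"])
        assert np.allclose(m2.values, m.values, atol=1e-9)
        assert np.allclose(tr2.fraction_inaccessible,
                           tr.fraction_inaccessible, atol=1e-9)

    def test_matrix_tsv_shape(self, tmp_path):
        m = ct.InteractionRateMatrix(
            list(ct.GLUTAMATE_RESIDUES), [1, 2, 3, 4], np.zeros((7, 4))
        )
        paths = ct.export_results(m, None, tmp_path / "zero")
        lines = paths["rates"].read_text().splitlines()
        assert len(lines) == 8  # header + 7 glutamate rows
        assert lines[0].split("\t")[1:] == [
            "site_1", "site_2", "site_3", "site_4"
        ]
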