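"""Origin/inversion registration, distances, clustering and consensus."""

import numpy as np
import pytest

import dmphase as dp
from dmphase import registration_clustering as rc
from dmphase.crystal_core import get_spacegroup


@pytest.fixture(scope="module")
def p21_toy():
    return dp.generate_toy_crystal(dp.UnitCell(20, 24, 22), "P21",
                                   solvent_fraction=0.72, seed=5)


def shifted_phase_set(p, tau_frac, invert=False):
    ph = -p.phase_deg if invert else p.phase_deg
    ph = np.mod(ph + 360.0 * (p.refl.hkl @ np.asarray(tau_frac)), 360.0)
    return dp.PhaseSet(p.refl, ph, p.weight)


def shifted_envelope(env, shift_idx, invert=False):
    m = rc.invert_grid(env.mask) if invert else env.mask
    return dp.BinaryEnvelope(rc.apply_shift(m, shift_idx),
                             env.solvent_fraction, env.cell, env.spacegroup)


class TestEnvelopeCC:
    def test_identical_masks(self, toy):
        assert dp.envelope_cc(toy.envelope, toy.envelope) == pytest.approx(1.0)

    def test_complement_at_half_fraction(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(10, 10, 10)) < 0.5
        e1 = dp.BinaryEnvelope(mask, 0.5)
        e2 = dp.BinaryEnvelope(~mask, 0.5)
        assert dp.envelope_cc(e1, e2) == pytest.approx(-1.0, abs=0.01)

    def test_independent_masks_near_zero(self):
        rng = np.random.default_rng(1)
        shape = (47, 47, 47)  # ~1e5 points
        e1 = dp.BinaryEnvelope(rng.uniform(size=shape) < 0.3, 0.7)
        e2 = dp.BinaryEnvelope(rng.uniform(size=shape) < 0.3, 0.7)
        assert abs(dp.envelope_cc(e1, e2)) < 0.02

    def test_single_class_undefined(self):
        e1 = dp.BinaryEnvelope(np.ones((4, 4, 4), bool), 0.5)
        with pytest.raises(ValueError, match="undefined"):
            dp.envelope_cc(e1, e1)

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(6, 6, 6)) < 0.4
        b = rng.uniform(size=(6, 6, 6)) < 0.4
        n = a.size
        f11 = np.sum(a & b) / n
        f00 = np.sum(~a & ~b) / n
        f10 = np.sum(a & ~b) / n
        f01 = np.sum(~a & b) / n
        expected = (f11 * f00 - f01 * f10) / np.sqrt(
            (f11 + f10) * (f01 + f00) * (f11 + f01) * (f10 + f00))
        got = dp.envelope_cc(dp.BinaryEnvelope(a, 0.6), dp.BinaryEnvelope(b, 0.6))
        assert got == pytest.approx(expected, rel=1e-10)


class TestEnvelopeRegistration:
    def test_identity(self, toy):
        reg = dp.best_registration(toy.envelope, toy.envelope, toy.spacegroup)
        assert reg.shift == (0.0, 0.0, 0.0)
        assert not reg.inverted
        assert reg.score == pytest.approx(1.0)

    def test_planted_shift_recovered_continuous_origin(self, toy):
        shape = np.array(toy.envelope.mask.shape)
        t = np.array([3, 7, 11])
        moved = shifted_envelope(toy.envelope, t)
        reg = dp.best_registration(toy.envelope, moved, toy.spacegroup)
        assert reg.score == pytest.approx(1.0)
        # applying the recovered shift to the moved envelope restores it
        back = rc.apply_shift(moved.mask, reg.shift_idx(shape))
        assert np.array_equal(back, toy.envelope.mask)

    def test_planted_allowed_shift_discrete_group(self, p21_toy):
        env = p21_toy.envelope
        shape = np.array(env.mask.shape)
        tau = np.array([0.5, 0.25, 0.0])  # (1/2, y, 0) is an allowed origin
        moved = shifted_envelope(env, np.round(tau * shape).astype(int))
        reg = dp.best_registration(env, moved, p21_toy.spacegroup)
        assert reg.score == pytest.approx(1.0)
        assert reg.shift[0] == pytest.approx(0.5)
        assert reg.shift[2] == pytest.approx(0.0)

    def test_inversion_recovered(self, toy):
        inv = shifted_envelope(toy.envelope, (0, 0, 0), invert=True)
        reg = dp.best_registration(toy.envelope, inv, toy.spacegroup)
        assert reg.inverted
        assert reg.score == pytest.approx(1.0)

    def test_scores_invariant_under_common_shift(self, toy):
        rngl = np.random.default_rng(3)
        other = dp.BinaryEnvelope(
            rngl.uniform(size=toy.envelope.mask.shape) < 0.2, 0.8,
            toy.cell, toy.spacegroup)
        d0 = dp.envelope_distance(toy.envelope, other, toy.spacegroup)
        t = (5, 2, 9)
        d1 = dp.envelope_distance(shifted_envelope(toy.envelope, t),
                                  shifted_envelope(other, t), toy.spacegroup)
        assert d0 == pytest.approx(d1, abs=1e-9)


class TestPhaseDistances:
    def test_identical_zero(self, toy):
        assert dp.phase_distance(toy.phases, toy.phases, toy.spacegroup) \
            == pytest.approx(0.0, abs=1e-9)

    def test_allowed_origin_shift_gives_zero(self, toy):
        shape = toy.density.values.shape
        tau = np.array([4, 9, 14]) / np.array(shape)
        moved = shifted_phase_set(toy.phases, tau)
        d = dp.phase_distance(toy.phases, moved, toy.spacegroup,
                              grid_shape=shape)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_inversion_gives_zero_when_ambiguous(self, toy):
        inv = shifted_phase_set(toy.phases, (0, 0, 0), invert=True)
        d = dp.phase_distance(toy.phases, inv, toy.spacegroup,
                              grid_shape=toy.density.values.shape)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_independent_uniform_pairs_near_90(self):
        rng = np.random.default_rng(4)
        cell = dp.UnitCell(10, 10, 10)
        from dmphase.crystal_core import ReflectionData, generate_unique_reflections
        hkl = generate_unique_reflections(cell, cell and dp.get_spacegroup("P1"), 1.1)
        n = len(hkl)
        assert n > 1500
        refl = ReflectionData(hkl, np.ones(n), np.zeros(n), np.zeros(n, bool),
                              cell, dp.get_spacegroup("P1"))
        p1 = dp.PhaseSet(refl, rng.uniform(0, 360, n))
        p2 = dp.PhaseSet(refl, rng.uniform(0, 360, n))
        d = dp.weighted_mean_abs_phase_diff(p1, p2, register=False)
        assert d == pytest.approx(90.0, abs=2.0)

    def test_symmetry_of_distance(self, toy):
        rng = np.random.default_rng(5)
        p2 = dp.PhaseSet(toy.refl, rng.uniform(0, 360, len(toy.refl)))
        shape = toy.density.values.shape
        d12 = dp.phase_distance(toy.phases, p2, toy.spacegroup, shape)
        d21 = dp.phase_distance(p2, toy.phases, toy.spacegroup, shape)
        assert d12 == pytest.approx(d21, abs=0.5)

    def test_triangle_inequality_on_registered_classes(self, toy):
        rng = np.random.default_rng(6)
        shape = toy.density.values.shape
        ps = [dp.PhaseSet(toy.refl, rng.uniform(0, 360, len(toy.refl)))
              for _ in range(3)]
        d01 = dp.phase_distance(ps[0], ps[1], toy.spacegroup, shape)
        d12 = dp.phase_distance(ps[1], ps[2], toy.spacegroup, shape)
        d02 = dp.phase_distance(ps[0], ps[2], toy.spacegroup, shape)
        assert d02 <= d01 + d12 + 1e-6

    def test_weighted_difference_hand_computation(self):
        cell = dp.UnitCell(10, 10, 10)
        from dmphase.crystal_core import ReflectionData
        hkl = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [2, 1, 1]])
        refl = ReflectionData(hkl, np.ones(5), np.zeros(5), np.zeros(5, bool),
                              cell, get_spacegroup("P1"))
        p = dp.PhaseSet(refl, np.array([10.0, 350.0, 90.0, 180.0, 30.0]),
                        np.array([1.0, 0.5, 0.25, 1.0, 0.1]))
        model = dp.PhaseSet(refl, np.array([40.0, 10.0, 80.0, 150.0, 300.0]))
        diffs = np.array([30.0, 20.0, 10.0, 30.0, 90.0])
        expected = np.sum(p.weight * diffs) / np.sum(p.weight)
        got = dp.weighted_mean_abs_phase_diff(p, model, register=False)
        assert got == pytest.approx(expected, rel=1e-12)


class TestDBSCAN:
    def test_two_tight_groups(self):
        n = 12
        d = np.full((n, n), 0.9)
        np.fill_diagonal(d, 0.0)
        d[:6, :6] = 0.01
        d[6:, 6:] = 0.01
        np.fill_diagonal(d, 0.0)
        cs = dp.dbscan(d, min_points=5, eps=0.1)
        assert cs.n_clusters == 2
        assert set(cs.members(0)) == set(range(6))

    def test_all_distant_is_noise(self):
        d = np.full((8, 8), 0.9)
        np.fill_diagonal(d, 0.0)
        cs = dp.dbscan(d, min_points=3, eps=0.1)
        assert cs.n_clusters == 0
        assert np.all(cs.labels == -1)

    def test_group_below_min_points_is_noise(self):
        n = 4
        d = np.full((n, n), 0.01)
        np.fill_diagonal(d, 0.0)
        cs = dp.dbscan(d, min_points=5, eps=0.1)
        assert cs.n_clusters == 0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            dp.dbscan(np.array([[0.0, np.nan], [np.nan, 0.0]]), 2, 0.5)
        with pytest.raises(ValueError):
            dp.dbscan(np.array([[0.0, 1.0], [2.0, 0.0]]), 2, 0.5)


class TestChooseEps:
    def test_constant_distances(self):
        d = np.full((6, 6), 0.3)
        np.fill_diagonal(d, 0.0)
        assert dp.choose_eps_envelopes(d) == pytest.approx(0.3)

    def test_uniform_grid_gives_fourth_percentile(self):
        n = 60
        iu = np.triu_indices(n, k=1)
        vals = np.linspace(0, 1, len(iu[0]))
        d = np.zeros((n, n))
        d[iu] = vals
        d += d.T
        assert dp.choose_eps_envelopes(d) == pytest.approx(0.04, abs=0.002)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        n = 20
        d = rng.uniform(size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = rng.permutation(n)
        assert dp.choose_eps_envelopes(d) == pytest.approx(
            dp.choose_eps_envelopes(d[np.ix_(perm, perm)]))


class TestConsensusEnvelope:
    def test_identical_members_unchanged(self, toy):
        cons = dp.consensus_envelope([toy.envelope] * 3, toy.spacegroup,
                                     connectivity_edit=False)
        assert np.array_equal(cons.mask, toy.envelope.mask)

    def test_majority_vote(self, toy):
        m2 = toy.envelope.mask.copy()
        voxel = tuple(np.argwhere(m2)[0])
        m2[voxel] = False  # one member disagrees on one voxel
        e2 = dp.BinaryEnvelope(m2, 0.8, toy.cell, toy.spacegroup)
        cons = dp.consensus_envelope([toy.envelope, toy.envelope, e2],
                                     toy.spacegroup, connectivity_edit=False)
        assert cons.mask[voxel]

    def test_small_island_erased_and_void_filled(self, toy):
        mask = toy.envelope.mask.copy()
        # plant a 5-voxel island deep in the solvent and a small void
        solvent = np.argwhere(~mask)
        far = solvent[-1]
        island = [tuple((far + [0, 0, k]) % mask.shape) for k in range(5)]
        for v in island:
            mask[v] = True
        planted = dp.BinaryEnvelope(mask, 0.8, toy.cell, toy.spacegroup)
        cons = dp.consensus_envelope([planted, planted], toy.spacegroup,
                                     min_component_fraction=0.01)
        assert not any(cons.mask[v] for v in island)

    def test_members_on_different_grids_rejected(self, toy):
        other = dp.BinaryEnvelope(np.zeros((4, 4, 4), bool), 0.8)
        with pytest.raises(ValueError):
            dp.consensus_envelope([toy.envelope, other], toy.spacegroup)


class TestConsensusPhases:
    def test_identical_members(self, toy):
        cons, cv, defined = dp.consensus_phases([toy.phases, toy.phases],
                                                toy.spacegroup,
                                                toy.density.values.shape)
        assert np.allclose(rc.wrap_abs_deg(cons.phase_deg - toy.phases.phase_deg),
                           0.0, atol=1e-6)
        assert cv == pytest.approx(0.0, abs=1e-9)

    def test_unit_vector_mean(self):
        cell = dp.UnitCell(10, 10, 10)
        from dmphase.crystal_core import ReflectionData
        hkl = np.array([[1, 0, 0], [0, 1, 0], [2, 1, 0], [1, 1, 1],
                        [2, 0, 1], [1, 2, 0], [0, 2, 1], [2, 2, 1],
                        [1, 0, 2], [0, 1, 2]])
        refl = ReflectionData(hkl, np.ones(10), np.zeros(10),
                              np.zeros(10, bool), cell, get_spacegroup("P1"))
        p1 = dp.PhaseSet(refl, np.full(10, 10.0))
        p2 = dp.PhaseSet(refl, np.full(10, 50.0))
        # a coarse registration grid keeps the zero shift optimal, so the
        # per-reflection circular mean is what is being exercised
        cons, cv, defined = dp.consensus_phases([p1, p2], get_spacegroup("P1"),
                                                (2, 2, 2))
        assert np.allclose(cons.phase_deg, 30.0, atol=1e-6)
        assert cv == pytest.approx(1 - np.cos(np.deg2rad(20.0)), rel=1e-6)

    def test_antipodal_pair_flagged_undefined(self):
        cell = dp.UnitCell(10, 10, 10)
        from dmphase.crystal_core import ReflectionData
        hkl = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]])
        refl = ReflectionData(hkl, np.ones(4), np.zeros(4), np.zeros(4, bool),
                              cell, get_spacegroup("P1"))
        # shift-free framing: both sets identical except one antipodal pair
        base = np.array([0.0, 90.0, 45.0, 120.0])
        other = base.copy()
        other[0] = 180.0
        p1 = dp.PhaseSet(refl, base)
        p2 = dp.PhaseSet(refl, other)
        cons, cv, defined = dp.consensus_phases(
            [p1, p2], get_spacegroup("P1"), (8, 8, 8))
        # registration may compensate; verify via the unregistered route
        z = (np.exp(1j * np.deg2rad(base)) + np.exp(1j * np.deg2rad(other))) / 2
        assert abs(z[0]) < 1e-12


class TestNullCalibration:
    def test_random_envelopes_high_distance(self, toy):
        rng = np.random.default_rng(8)
        shape = toy.envelope.mask.shape
        es = [dp.BinaryEnvelope(rng.uniform(size=shape) < 0.2, 0.8,
                                toy.cell, toy.spacegroup) for _ in range(2)]
        d = dp.envelope_distance(es[0], es[1], toy.spacegroup)
        assert d > 0.95  # independent envelopes: CC ~ 0 even after search
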