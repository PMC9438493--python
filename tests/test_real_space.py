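"""Triweight filtering, variance envelopes, the real-space projection and
the Wasserstein metric."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import dmphase as dp
from dmphase.real_space import ReferenceHistogram, TriweightKernel, triweight


@pytest.fixture
def cell():
    return dp.UnitCell(16.0, 16.0, 16.0)


@pytest.fixture
def random_map(cell, rng):
    return dp.DensityMap(rng.normal(size=(16, 16, 16)), cell)


def make_envelope(mask, fraction=None, cell=None):
    frac = 1.0 - mask.mean() if fraction is None else fraction
    return dp.BinaryEnvelope(mask, frac, cell)


class TestTriweight:
    def test_closed_forms(self):
        assert triweight(0.0, 5.0) == 1.0
        assert triweight(5.0, 5.0) == 0.0
        assert triweight(2.5, 5.0) == pytest.approx((3 / 4) ** 3)
        assert triweight(7.0, 5.0) == 0.0

    def test_monotone_on_support(self):
        r = np.linspace(0, 5, 50)
        w = triweight(r, 5.0)
        assert np.all(np.diff(w) <= 0)


class TestLocalVariance:
    def test_constant_map_zero_variance(self, cell):
        m = dp.DensityMap(np.full((16, 16, 16), 3.0), cell)
        var = dp.local_variance_map(m, 4.0)
        assert np.abs(var.values).max() < 1e-12

    def test_shift_invariance(self, random_map):
        v1 = dp.local_variance_map(random_map, 4.0).values
        shifted = random_map.with_values(random_map.values + 7.5)
        v2 = dp.local_variance_map(shifted, 4.0).values
        assert np.allclose(v1, v2, atol=1e-8)

    def test_matches_direct_windowed_computation(self, cell, rng):
        # brute-force weighted variance with explicit periodic windows
        values = np.zeros((16, 16, 16))
        values[:8] = 1.0  # two-level block: variance peaks at the interface
        r0 = 3.0
        var = dp.local_variance_map(dp.DensityMap(values, cell), r0).values
        kern = TriweightKernel(r0, (16, 16, 16), cell).kernel
        offsets = np.array(np.nonzero(kern > 0)).T
        weights = kern[tuple(offsets.T)]
        for point in [(0, 4, 4), (8, 3, 3), (4, 8, 8), (15, 1, 2)]:
            idx = (offsets + np.array(point)) % 16
            vals = values[tuple(idx.T)]
            mean = np.sum(weights * vals)
            expected = np.sum(weights * vals ** 2) - mean ** 2
            assert var[point] == pytest.approx(max(expected, 0.0), abs=1e-10)
        interface = var[8, :, :].mean()
        interior = var[4, :, :].mean()
        assert interface > 10 * interior

    def test_kernel_too_large_rejected(self, random_map):
        with pytest.raises(ValueError, match="half the cell"):
            dp.local_variance_map(random_map, 9.0)

    def test_radius_below_grid_spacing_rejected(self, random_map):
        with pytest.raises(ValueError):
            dp.local_variance_map(random_map, 1.0)


class TestEnvelopeFromVariance:
    def test_exact_protein_count(self, cell, rng):
        var = dp.DensityMap(rng.uniform(size=(4, 4, 4)), cell)
        env = dp.envelope_from_variance(var, 0.75)
        assert env.protein_count == 16

    def test_threshold_equals_quantile(self, cell):
        # monotone field: the mask is exactly the top (1 - fraction) block
        field = np.arange(16 ** 3, dtype=float).reshape(16, 16, 16)
        env = dp.envelope_from_variance(dp.DensityMap(field, cell), 0.6)
        n_protein = round(0.4 * 16 ** 3)
        cut = np.sort(field.ravel())[-n_protein]
        assert env.protein_count == n_protein
        assert np.array_equal(env.mask, field >= cut)

    def test_realized_fraction_close(self, cell, rng):
        for frac in (0.6, 0.75, 0.85):
            var = dp.DensityMap(rng.uniform(size=(16, 16, 16)), cell)
            env = dp.envelope_from_variance(var, frac)
            assert abs(env.realized_solvent_fraction - frac) <= 1.0 / 16 ** 3 + 1e-12

    def test_affine_rescaling_invariance(self, cell, rng):
        var = dp.DensityMap(rng.uniform(size=(8, 8, 8)), cell)
        e1 = dp.envelope_from_variance(var, 0.7)
        e2 = dp.envelope_from_variance(var.with_values(3.0 * var.values + 11.0), 0.7)
        assert np.array_equal(e1.mask, e2.mask)

    def test_constant_variance_rejected(self, cell):
        with pytest.raises(ValueError, match="constant"):
            dp.envelope_from_variance(dp.DensityMap(np.ones((8, 8, 8)), cell), 0.7)


class TestFlattenSolvent:
    def test_mean_imposed(self, cell):
        v = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[:2] = True
        v[~mask] = np.resize([1.0, 2.0, 3.0], int((~mask).sum()))
        out = dp.flatten_solvent(dp.DensityMap(v, cell), make_envelope(mask))
        assert np.allclose(out.values[~mask], 2.0)
        assert np.array_equal(out.values[mask], v[mask])

    def test_idempotent(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = rng.uniform(size=(8, 8, 8)) < 0.3
        env = make_envelope(mask)
        once = dp.flatten_solvent(m, env)
        twice = dp.flatten_solvent(once, env)
        assert np.array_equal(once.values, twice.values)

    def test_empty_solvent_rejected(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        env = make_envelope(np.ones((8, 8, 8), bool), fraction=0.5)
        with pytest.raises(ValueError):
            dp.flatten_solvent(m, env)


class TestHistogramMatch:
    def test_self_match_is_identity(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = rng.uniform(size=(8, 8, 8)) < 0.4
        ref = ReferenceHistogram(m.values[mask])
        out = dp.histogram_match_protein(m, make_envelope(mask), ref)
        assert np.allclose(out.values[mask], m.values[mask], atol=1e-9)

    def test_two_point_reference_reached(self, cell):
        # uniform input values mapped onto a two-point reference
        v = np.linspace(0, 1, 512).reshape(8, 8, 8)
        mask = np.ones((8, 8, 8), bool)
        ref = ReferenceHistogram(np.repeat([0.0, 10.0], 256))
        out = dp.histogram_match_protein(dp.DensityMap(v, cell),
                                         make_envelope(mask, fraction=0.01), ref)
        got = np.sort(out.values[mask])
        w1 = dp.wasserstein_1_samples(got, ref.values)
        assert w1 < 1e-6 * 10.0

    def test_rank_order_preserved(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = rng.uniform(size=(8, 8, 8)) < 0.5
        ref = ReferenceHistogram(rng.gamma(2.0, size=1000))
        out = dp.histogram_match_protein(m, make_envelope(mask), ref)
        before = np.argsort(m.values[mask], kind="stable")
        after = out.values[mask]
        assert np.all(np.diff(after[before]) >= -1e-12)

    def test_tied_values_stay_tied(self, cell, rng):
        v = rng.normal(size=(8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        mask[0] = False
        v[mask][:]  # no-op; make a flat block inside the region
        v[4:] = -1.25
        ref = ReferenceHistogram(rng.normal(size=2000))
        out = dp.histogram_match_protein(dp.DensityMap(v, cell),
                                         make_envelope(mask), ref)
        block = out.values[4:][mask[4:]]
        assert np.ptp(block) < 1e-12

    def test_too_few_protein_points(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, :5] = True
        with pytest.raises(ValueError, match="10"):
            dp.histogram_match_protein(m, make_envelope(mask),
                                       ReferenceHistogram(rng.normal(size=100)))


class TestProjectReal:
    @pytest.mark.parametrize("mode", ["moment", "histogram"])
    def test_idempotent(self, cell, rng, mode):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = rng.uniform(size=(8, 8, 8)) < 0.25
        env = make_envelope(mask)
        ref = ReferenceHistogram(rng.normal(size=500))
        once = dp.project_real(m, env, ref, protein_transform=mode)
        twice = dp.project_real(once, env, ref, protein_transform=mode)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_regions_independent_and_solvent_flat(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = rng.uniform(size=(8, 8, 8)) < 0.25
        env = make_envelope(mask)
        ref = ReferenceHistogram(rng.normal(size=500))
        out = dp.project_real(m, env, ref)
        assert dp.solvent_variance(out, env) < 1e-24
        # protein region depends only on the protein input values
        m2 = m.copy()
        m2.values[~mask] += 5.0
        out2 = dp.project_real(m2, env, ref)
        assert np.allclose(out.values[mask], out2.values[mask])

    def test_moment_mode_preserves_variance_and_sets_mean(self, cell, rng):
        m = dp.DensityMap(rng.normal(size=(8, 8, 8)), cell)
        mask = rng.uniform(size=(8, 8, 8)) < 0.3
        env = make_envelope(mask)
        ref = ReferenceHistogram(rng.normal(loc=2.0, size=500))
        out = dp.project_real(m, env, ref, protein_transform="moment")
        assert out.values[mask].mean() == pytest.approx(ref.mean)
        assert out.values[mask].var() == pytest.approx(m.values[mask].var())

    def test_least_squares_among_assignments_of_reference_values(self, cell, rng):
        # rearrangement inequality: the sorted-to-sorted assignment of the
        # reference values is the least-squares one; the quantile map must
        # realize it and beat random permutations
        m = 12
        vals = rng.normal(size=m)
        ref_vals = np.sort(rng.normal(size=m))
        v = np.zeros(27)
        v[:m] = vals
        mask = np.zeros(27, bool)
        mask[:m] = True
        out = dp.histogram_match_protein(
            dp.DensityMap(v.reshape(3, 3, 3), cell),
            make_envelope(mask.reshape(3, 3, 3)),
            ReferenceHistogram(ref_vals))
        got = out.values.ravel()[:m]
        cost = np.sum((got - vals) ** 2)
        optimal = np.empty(m)
        optimal[np.argsort(vals, kind="stable")] = ref_vals
        assert cost == pytest.approx(np.sum((optimal - vals) ** 2), rel=1e-9)
        for _ in range(300):
            perm = rng.permutation(m)
            assert cost <= np.sum((ref_vals[perm] - vals) ** 2) + 1e-12


class TestSolventVariance:
    def test_flat_and_two_level(self, cell):
        v = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[0] = True
        env = make_envelope(mask)
        assert dp.solvent_variance(dp.DensityMap(v, cell), env) == 0.0
        v[~mask] = np.resize([0.0, 2.0], 48)
        assert dp.solvent_variance(dp.DensityMap(v, cell), env) == pytest.approx(1.0)

    def test_matches_direct_formula(self, cell, rng):
        v = rng.normal(size=(8, 8, 8))
        mask = rng.uniform(size=(8, 8, 8)) < 0.3
        env = make_envelope(mask)
        assert dp.solvent_variance(dp.DensityMap(v, cell), env) == pytest.approx(
            np.var(v[~mask]))


class TestWasserstein:
    def test_identical_zero(self):
        x = np.linspace(0, 1, 11)
        F = np.linspace(0, 1, 11)
        assert dp.wasserstein_1(x, F, x, F) == 0.0

    def test_translated_point_masses(self):
        # step CDFs for point masses at a and a + delta
        a, delta = 1.0, 0.35
        sp = np.array([a - 1e-12, a])
        sq = np.array([a + delta - 1e-12, a + delta])
        F = np.array([0.0, 1.0])
        assert dp.wasserstein_1(sp, F, sq, F) == pytest.approx(delta, rel=1e-6)

    def test_translated_uniforms(self):
        x = np.linspace(0, 1, 200)
        got = dp.wasserstein_1(x, x, x + 0.2, x)
        assert got == pytest.approx(0.2, rel=1e-6)

    def test_sample_version_matches_scipy(self, rng):
        a = rng.normal(size=300)
        b = rng.gamma(2.0, size=400)
        mine = dp.wasserstein_1_samples(a, b)
        theirs = scipy.stats.wasserstein_distance(a, b)
        assert mine == pytest.approx(theirs, rel=1e-9)

    def test_unbounded_support_rejected(self):
        with pytest.raises(ValueError):
            dp.wasserstein_1([0.0, np.inf], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = (r.normal(size=50) for _ in range(3))
        dab = dp.wasserstein_1_samples(a, b)
        dbc = dp.wasserstein_1_samples(b, c)
        dac = dp.wasserstein_1_samples(a, c)
        assert dac <= dab + dbc + 1e-10


class TestReferenceHistogram:
    def test_text_round_trip(self, tmp_path, rng):
        ref = ReferenceHistogram(rng.normal(size=200), provenance={
            "b_factor": 20.0, "resolution": 3.0, "sigma": None})
        path = tmp_path / "ref.txt"
        ref.to_text(path)
        back = ReferenceHistogram.from_text(path)
        assert np.allclose(np.sort(back.values), np.sort(ref.values), rtol=1e-6)

    def test_cdf_monotone(self, rng):
        ref = ReferenceHistogram(rng.normal(size=500))
        x = np.linspace(-4, 4, 100)
        assert np.all(np.diff(ref.cdf(x)) >= 0)
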