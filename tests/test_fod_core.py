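"""Core statistics: T/O/R/M profiles, divergences, RD, K fitting.

Independent oracles: a naive double-loop observed profile, a one-line KL
summation, and hand-evaluated values of the Levitt polynomial.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fodm.fod_core import (
    DegenerateGeometryError,
    Profile,
    SupportError,
    UndefinedRDError,
    fit_gaussian_field,
    fit_k,
    kl_divergence,
    levitt_weight,
    m_profile,
    observed_profile,
    rd,
    score_chain,
    theoretical_profile,
    uniform_profile,
)
from fodm.structure_io import EffectiveAtomChain
from fodm.synthetic_data import SyntheticSpec, make_profile_pair, make_structure

from conftest import random_rotation


def chain_from(positions, h, name="toy"):
    positions = np.asarray(positions, dtype=float)
    h = np.asarray(h, dtype=float)
    n = len(positions)
    return EffectiveAtomChain(
        unit_name=name,
        keys=tuple(("A", i + 1, "") for i in range(n)),
        labels=tuple(f"A:RES{i + 1}" for i in range(n)),
        positions=positions,
        h=h,
    )


def random_chain(n, seed):
    rng = np.random.default_rng(seed)
    return chain_from(rng.normal(0, 10, size=(n, 3)), rng.uniform(0.05, 1.0, size=n))


# --------------------------------------------------------------------------
# oracles

def observed_brute_force(positions, h, cutoff=9.0, include_self=True):
    """Naive O(N^2) double loop over Levitt-weighted pair interactions."""
    n = len(positions)
    raw = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j and not include_self:
                continue
            r = np.linalg.norm(positions[i] - positions[j])
            if r <= cutoff:
                x = r / cutoff
                w = 1.0 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8)
                raw[i] += (h[i] + h[j]) * w
    return raw / raw.sum()


def kl_oracle(p, q):
    return sum(pi * np.log2(pi / qi) for pi, qi in zip(p, q) if pi > 0)


# --------------------------------------------------------------------------
# Gaussian field


class TestGaussianField:
    def test_three_sigma_rule(self):
        # axis-symmetric points with max |x| = 9 -> sigma_x = 3
        pts = [(-9, 0, 0), (9, 0, 0), (0, 2, 0), (0, -2, 0), (0, 0, 1), (0, 0, -1)]
        field = fit_gaussian_field(chain_from(pts, np.ones(6)))
        assert max(field.sigmas) == pytest.approx(3.0, rel=1e-6)

    def test_all_atoms_within_three_sigma(self):
        chain = random_chain(60, 2)
        field = fit_gaussian_field(chain)
        aligned = field.align(chain.positions)
        assert np.all(np.abs(aligned) <= 3 * np.asarray(field.sigmas) + 1e-9)

    def test_rotation_invariant_sigmas(self):
        chain = random_chain(40, 3)
        R = random_rotation(7)
        rotated = chain_from(chain.positions @ R.T, chain.h)
        s1 = sorted(fit_gaussian_field(chain).sigmas)
        s2 = sorted(fit_gaussian_field(rotated).sigmas)
        np.testing.assert_allclose(s1, s2, rtol=1e-8)

    def test_cube_corners_isotropic(self):
        corners = [(x, y, z) for x in (-3, 3) for y in (-3, 3) for z in (-3, 3)]
        field = fit_gaussian_field(chain_from(corners, np.ones(8)))
        assert field.sigmas[0] == pytest.approx(field.sigmas[1], rel=1e-6)
        assert field.sigmas[1] == pytest.approx(field.sigmas[2], rel=1e-6)

    def test_collinear_rejected(self):
        pts = [(float(i), 0.0, 0.0) for i in range(10)]
        with pytest.raises(DegenerateGeometryError):
            fit_gaussian_field(chain_from(pts, np.ones(10)))

    def test_sigma_floor(self):
        # a nearly flat sheet still gets a 1 Å floor on the thin axis
        rng = np.random.default_rng(0)
        pts = np.c_[rng.normal(0, 8, 30), rng.normal(0, 8, 30), rng.normal(0, 1e-4, 30)]
        field = fit_gaussian_field(chain_from(pts, np.ones(30)))
        assert min(field.sigmas) == pytest.approx(1.0)


class TestTheoreticalProfile:
    def test_center_residue_is_mode(self):
        chain = random_chain(50, 5)
        field = fit_gaussian_field(chain)
        # append a residue exactly at the centre
        pts = np.vstack([chain.positions, field.center])
        aug = chain_from(pts, np.ones(len(pts)))
        t = theoretical_profile(aug, field)
        assert np.argmax(t.values) == len(pts) - 1

    def test_equidistant_residues_equal(self):
        pts = [(5, 0, 0), (-5, 0, 0), (0, 3, 0), (0, -3, 0), (0, 0, 1)]
        chain = chain_from(pts, np.ones(5))
        from fodm.fod_core import GaussianField

        field = GaussianField(center=np.zeros(3), sigmas=(4.0, 3.0, 2.0), rotation=np.eye(3))
        t = theoretical_profile(chain, field)
        assert t.values[0] == pytest.approx(t.values[1], rel=1e-12)
        assert t.values[2] == pytest.approx(t.values[3], rel=1e-12)

    def test_hand_evaluated_gaussian_product(self):
        # five-point layout, axis-aligned field: compare to explicit arithmetic
        from fodm.fod_core import GaussianField

        pts = np.array([(0, 0, 0), (2, 0, 0), (0, 3, 0), (0, 0, 4), (1, 1, 1)], dtype=float)
        sx, sy, sz = 2.0, 3.0, 4.0
        field = GaussianField(center=np.zeros(3), sigmas=(sx, sy, sz), rotation=np.eye(3))
        raw = np.array([
            np.exp(-x**2 / (2 * sx**2)) * np.exp(-y**2 / (2 * sy**2)) * np.exp(-z**2 / (2 * sz**2))
            for x, y, z in pts
        ])
        expected = raw / raw.sum()
        t = theoretical_profile(chain_from(pts, np.ones(5)), field)
        np.testing.assert_allclose(t.values, expected, rtol=1e-12)

    def test_strictly_positive(self):
        chain = random_chain(80, 6)
        t = theoretical_profile(chain, fit_gaussian_field(chain))
        assert np.all(t.values > 0)

    def test_rigid_motion_invariant(self):
        chain = random_chain(60, 8)
        R = random_rotation(21)
        moved = chain_from(chain.positions @ R.T + np.array([3.0, -7.0, 1.0]), chain.h)
        t1 = theoretical_profile(chain, fit_gaussian_field(chain))
        t2 = theoretical_profile(moved, fit_gaussian_field(moved))
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)


class TestObservedProfile:
    def test_levitt_weight_hand_values(self):
        # w(x) = 1 - (7x^2 - 9x^4 + 5x^6 - x^8)/2
        assert levitt_weight(0.0) == pytest.approx(1.0)
        assert levitt_weight(1.0) == pytest.approx(0.0, abs=1e-15)  # 1 - (7-9+5-1)/2
        assert levitt_weight(0.5) == pytest.approx(0.369140625)  # hand-evaluated
        assert levitt_weight(2.0) == 0.0

    def test_pair_at_cutoff_sees_self_only(self):
        h = np.array([0.3, 0.9])
        chain = chain_from([(0, 0, 0), (9, 0, 0)], h)
        o = observed_profile(chain, cutoff=9.0)
        np.testing.assert_allclose(o.values, h / h.sum(), rtol=1e-12)

    def test_coincident_pair_full_weight(self):
        h = np.array([0.4, 0.6])
        chain = chain_from([(0, 0, 0), (0, 0, 0)], h)
        o = observed_profile(chain)
        # raw_i = 2 h_i + (h_i + h_j): both terms at w = 1
        raw = 2 * h + h.sum()
        np.testing.assert_allclose(o.values, raw / raw.sum(), rtol=1e-12)

    @pytest.mark.parametrize("n,seed", [(4, 0), (20, 1), (50, 2)])
    def test_matches_brute_force(self, n, seed):
        chain = random_chain(n, seed)
        o = observed_profile(chain)
        expected = observed_brute_force(chain.positions, chain.h)
        np.testing.assert_allclose(o.values, expected, atol=1e-12)

    def test_self_term_excluded_matches_brute_force(self):
        chain = random_chain(25, 3)
        o = observed_profile(chain, include_self=False)
        expected = observed_brute_force(chain.positions, chain.h, include_self=False)
        np.testing.assert_allclose(o.values, expected, atol=1e-12)

    def test_rigid_motion_invariant(self):
        chain = random_chain(40, 4)
        R = random_rotation(9)
        moved = chain_from(chain.positions @ R.T + 11.0, chain.h)
        np.testing.assert_allclose(
            observed_profile(chain).values, observed_profile(moved).values, atol=1e-10
        )


class TestUniformProfile:
    def test_values(self):
        np.testing.assert_allclose(uniform_profile(4).values, [0.25] * 4)
        np.testing.assert_allclose(uniform_profile(1).values, [1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uniform_profile(0)


# --------------------------------------------------------------------------
# divergences, RD, M, K


simplex = st.integers(2, 30).flatmap(
    lambda n: st.lists(st.floats(1e-3, 1.0), min_size=n, max_size=n)
)


class TestKLDivergence:
    def test_identity_is_zero(self):
        p = Profile.from_raw("O", np.array([0.2, 0.5, 0.3]))
        assert kl_divergence(p, p) == 0.0

    def test_one_bit_example(self):
        p = Profile.from_raw("O", np.array([1.0, 0.0]) + 0.0)
        q = Profile.from_raw("T", np.array([0.5, 0.5]))
        assert kl_divergence(p, q) == pytest.approx(1.0)  # log2(1/0.5)

    @settings(derandomize=True, max_examples=60)
    @given(raw_p=simplex, raw_q=simplex)
    def test_matches_summation_oracle_and_nonnegative(self, raw_p, raw_q):
        n = min(len(raw_p), len(raw_q))
        p = Profile.from_raw("O", np.array(raw_p[:n]))
        q = Profile.from_raw("T", np.array(raw_q[:n]))
        d = kl_divergence(p, q)
        assert d == pytest.approx(kl_oracle(p.values, q.values), abs=1e-12)
        assert d >= 0.0

    def test_support_error(self):
        p = Profile.from_raw("O", np.array([0.5, 0.5]))
        q = Profile(role="T", values=np.array([1.0, 0.0]), normalizer=1.0)
        with pytest.raises(SupportError):
            kl_divergence(p, q)

    def test_length_mismatch(self):
        p = Profile.from_raw("O", np.ones(3))
        q = Profile.from_raw("T", np.ones(4))
        with pytest.raises(ValueError):
            kl_divergence(p, q)


class TestRD:
    def test_o_equals_t_gives_zero(self):
        t = Profile.from_raw("T", np.array([0.5, 0.3, 0.2]))
        o = Profile(role="O", values=t.values, normalizer=1.0)
        r = uniform_profile(3)
        assert rd(o, t, r) == 0.0

    def test_o_equals_r_gives_one(self):
        t = Profile.from_raw("T", np.array([0.5, 0.3, 0.2]))
        r = uniform_profile(3)
        o = Profile(role="O", values=r.values, normalizer=1.0)
        assert rd(o, t, r) == 1.0

    def test_undefined_when_all_equal(self):
        r = uniform_profile(4)
        o = Profile(role="O", values=r.values, normalizer=1.0)
        t = Profile(role="T", values=r.values, normalizer=1.0)
        with pytest.raises(UndefinedRDError):
            rd(o, t, r)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        t = Profile.from_raw("T", rng.uniform(0.01, 1, 20))
        o = Profile.from_raw("O", rng.uniform(0.01, 1, 20))
        r = uniform_profile(20)
        assert 0.0 <= rd(o, t, r) <= 1.0


class TestMProfile:
    def test_k_zero_returns_t_exactly(self):
        t = Profile.from_raw("T", np.array([0.1, 0.6, 0.3]))
        m = m_profile(t, 0.0)
        np.testing.assert_array_equal(m.values, t.values)

    def test_k_one_is_uniform_exactly(self):
        rng = np.random.default_rng(1)
        t = Profile.from_raw("T", rng.uniform(0.01, 1, 25))
        m = m_profile(t, 1.0)
        np.testing.assert_allclose(m.values, np.full(25, 1 / 25), rtol=1e-12)

    def test_large_k_approaches_inverted_profile(self):
        rng = np.random.default_rng(2)
        t = Profile.from_raw("T", rng.uniform(0.01, 1, 30))
        inv = t.values.max() - t.values
        inv = inv / inv.sum()
        m = m_profile(t, 1e3)
        np.testing.assert_allclose(m.values, inv, atol=2e-3)

    def test_dkl_r_to_m_decreasing_on_unit_interval(self):
        rng = np.random.default_rng(3)
        t = Profile.from_raw("T", rng.uniform(0.01, 1, 40))
        r = uniform_profile(40)
        ks = np.linspace(0, 1, 11)
        ds = [kl_divergence(r, m_profile(t, k)) for k in ks]
        assert all(a >= b - 1e-12 for a, b in zip(ds, ds[1:]))
        assert ds[-1] == pytest.approx(0.0, abs=1e-12)

    def test_negative_k_rejected(self):
        t = Profile.from_raw("T", np.ones(3))
        with pytest.raises(ValueError):
            m_profile(t, -0.1)


class TestFitK:
    def test_o_equals_t_gives_zero(self):
        rng = np.random.default_rng(4)
        t = Profile.from_raw("T", rng.uniform(0.01, 1, 50))
        o = Profile(role="O", values=t.values, normalizer=1.0)
        k, d = fit_k(t, o)
        assert k == pytest.approx(0.0, abs=1e-3)
        assert d == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("k_true", [0.2, 0.7, 1.3, 2.1, 3.5])
    @pytest.mark.parametrize("n", [50, 300, 900])
    def test_recovers_known_k(self, k_true, n):
        t, o = make_profile_pair(n, k_true, seed=int(n + 10 * k_true))
        k, d = fit_k(t, o)
        assert k == pytest.approx(k_true, abs=0.05)
        assert d <= 1e-8

    def test_uniform_o_fits_k_one(self):
        rng = np.random.default_rng(5)
        t = Profile.from_raw("T", rng.uniform(0.01, 1, 60))
        o = Profile(role="O", values=uniform_profile(60).values, normalizer=1.0)
        k, _ = fit_k(t, o)
        assert k == pytest.approx(1.0, abs=1e-3)

    def test_fitted_divergence_never_exceeds_k_zero(self):
        # K = 0 is in the search set, so D_KL(O|M(k)) <= D_KL(O|T)
        chain = make_structure(SyntheticSpec(n_residues=120, mode="uniform", seed=6))
        res, _ = score_chain(chain)
        assert res.dkl_om_at_k <= res.dkl_ot + 1e-12


class TestScoreChain:
    def test_result_identity_holds(self):
        chain = make_structure(SyntheticSpec(n_residues=150, seed=7))
        res, profs = score_chain(chain)
        assert res.rd == pytest.approx(res.dkl_ot / (res.dkl_ot + res.dkl_or), rel=1e-12)
        for p in (profs.t, profs.o, profs.m_at_k):
            assert p.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_in_complex_requires_parent(self):
        chain = make_structure(SyntheticSpec(n_residues=30, seed=8))
        with pytest.raises(ValueError):
            score_chain(chain, context="in_complex")

    def test_in_complex_restriction_renormalises(self):
        parent = make_structure(SyntheticSpec(n_residues=100, seed=9))
        sub = parent.subset(range(40), name="sub")
        res, profs = score_chain(sub, context="in_complex", parent=parent, indices=list(range(40)))
        assert res.n_residues == 40
        assert profs.t.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert profs.o.values.sum() == pytest.approx(1.0, abs=1e-9)
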