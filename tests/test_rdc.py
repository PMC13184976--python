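"""Saupe tensor SVD fit, Q factor, alternating tensor/population fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairpinxb.errors import (
    ConfigError,
    DegenerateGeometryError,
    DomainError,
    InsufficientDataError,
    LabelingError,
    SingularFitError,
)
from hairpinxb.observables import RdcRestraint
from hairpinxb.rdc import (
    RdcFit,
    SaupeTensor,
    conformer_design,
    fit_tensor_and_populations,
    predict_rdc,
    q_factor,
    rdc_design_row,
    svd_fit_tensor,
    xb_population,
)
from hairpinxb.structures import Atom, Conformer, ConformerPool
from hairpinxb.synthetic import standard_rdc_pairs


def bond_pool(bonds, ids=None):
    """One conformer per call: a fan of unit C-H bonds from the origin."""
    atoms = []
    for i, b in enumerate(bonds, start=1):
        atoms.append(Atom(f"C{i}", "C", i, "TOY", [0.0, 0.0, 0.0]))
        atoms.append(Atom(f"H{i}", "H", i, "TOY", np.asarray(b, float)))
    return Conformer(ids or "bonds", atoms)


def fan_pairs(n):
    return [((i, f"C{i}"), (i, f"H{i}")) for i in range(1, n + 1)]


class TestDesignRow:
    def test_axial_tensor_bond_along_z(self):
        # S_zz = 2 Da: a bond along z predicts D = 2 Da
        da = 3.7
        tensor = SaupeTensor([-da, 2 * da, 0.0, 0.0, 0.0])  # Syy=-Da, Szz=2Da
        row = rdc_design_row([0.0, 0.0, 1.0])
        assert row @ tensor.s == pytest.approx(2 * da)

    def test_magic_angle_gives_zero(self):
        da = 2.2
        tensor = SaupeTensor([-da, 2 * da, 0.0, 0.0, 0.0])
        theta = np.arccos(np.sqrt(1.0 / 3.0))  # 3 cos^2 - 1 = 0
        bond = [np.sin(theta), 0.0, np.cos(theta)]
        assert rdc_design_row(bond) @ tensor.s == pytest.approx(0.0, abs=1e-12)

    def test_even_in_bond_direction(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=3)
        np.testing.assert_allclose(rdc_design_row(b), rdc_design_row(-b))

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            rdc_design_row([0.0, 0.0, 0.0])


class TestSaupeTensor:
    def test_matrix_is_traceless_symmetric(self):
        t = SaupeTensor([1.0, -2.0, 0.3, -0.7, 0.2])
        S = t.to_matrix()
        assert abs(np.trace(S)) < 1e-12
        np.testing.assert_allclose(S, S.T)

    def test_matrix_round_trip(self):
        t = SaupeTensor(np.random.default_rng(1).normal(size=5))
        np.testing.assert_allclose(
            SaupeTensor.from_matrix(t.to_matrix()).s, t.s
        )

    def test_row_contraction_equals_matrix_form(self):
        # independent oracle: D = b^T S b for the full 3x3 matrix
        rng = np.random.default_rng(2)
        t = SaupeTensor(rng.normal(size=5))
        S = t.to_matrix()
        for _ in range(5):
            b = rng.normal(size=3)
            b /= np.linalg.norm(b)
            assert rdc_design_row(b) @ t.s == pytest.approx(b @ S @ b)


class TestSvdFit:
    @given(seed=st.integers(0, 200))
    @settings(max_examples=25, deadline=None)
    def test_noiseless_recovery_from_generic_bonds(self, seed):
        rng = np.random.default_rng(seed)
        bonds = rng.normal(size=(8, 3))
        bonds /= np.linalg.norm(bonds, axis=1, keepdims=True)
        c = bond_pool(bonds)
        pool = ConformerPool([c])
        s_true = rng.normal(size=5)
        d = conformer_design(c, fan_pairs(8)) @ s_true
        rdcs = [RdcRestraint(p, float(v), 0.3) for p, v in zip(fan_pairs(8), d)]
        tensor, cn = svd_fit_tensor(pool, np.array([1.0]), rdcs)
        rel = np.linalg.norm(tensor.s - s_true) / np.linalg.norm(s_true)
        assert rel < 1e-10
        assert cn >= 1.0

    def test_parallel_bonds_are_singular(self):
        c = bond_pool([[0, 0, 1]] * 5)
        rdcs = [RdcRestraint(p, 1.0, 0.3) for p in fan_pairs(5)]
        with pytest.raises(SingularFitError):
            svd_fit_tensor(ConformerPool([c]), np.array([1.0]), rdcs)

    def test_four_rdcs_insufficient(self):
        c = bond_pool(np.eye(3).tolist() + [[0.5, 0.5, 0.707]])
        rdcs = [RdcRestraint(p, 1.0, 0.3) for p in fan_pairs(4)]
        with pytest.raises(InsufficientDataError):
            svd_fit_tensor(ConformerPool([c]), np.array([1.0]), rdcs)


class TestQFactor:
    def test_perfect_fit_is_zero(self):
        d = np.array([3.0, -5.0, 1.0])
        assert q_factor(d, d) == 0.0

    def test_zero_calculation_is_one(self):
        d = np.array([3.0, -5.0, 1.0])
        assert q_factor(d, np.zeros(3)) == pytest.approx(1.0)

    def test_worked_example(self):
        assert q_factor(np.array([4.0, 3.0]), np.array([4.0, 0.0])) == pytest.approx(0.6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        d_obs = rng.normal(size=10)
        d_calc = d_obs + rng.normal(0, 0.1, size=10)
        q1 = q_factor(d_obs, d_calc)
        q2 = q_factor(7.3 * d_obs, 7.3 * d_calc)
        assert q1 == pytest.approx(q2)

    def test_all_zero_observations_undefined(self):
        with pytest.raises(DomainError):
            q_factor(np.zeros(4), np.ones(4))


class TestJointFit:
    def test_noiseless_three_conformer_mixture(self, pool_and_truth):
        pool, _ = pool_and_truth
        sub = ConformerPool([pool[0], pool[4], pool[11]])
        w_true = np.array([0.5, 0.3, 0.2])
        pairs = standard_rdc_pairs(sub[0])
        assert len(pairs) == 15
        s_true = np.random.default_rng(5).normal(size=5)
        G = np.zeros((len(pairs), 5))
        for w, c in zip(w_true, sub):
            G += w * conformer_design(c, pairs)
        rdcs = [
            RdcRestraint(p, float(v), 0.3) for p, v in zip(pairs, G @ s_true)
        ]
        fit = fit_tensor_and_populations(sub, rdcs)
        assert fit.q < 1e-8
        np.testing.assert_allclose(fit.populations, w_true, atol=1e-4)
        # tensor matrix invariants hold after the fit
        S = fit.tensor.to_matrix()
        assert abs(np.trace(S)) < 1e-12 * max(np.linalg.norm(S), 1.0)
        np.testing.assert_allclose(S, S.T)

    def test_single_conformer_reduces_to_svd(self, pool_and_truth):
        pool, _ = pool_and_truth
        sub = ConformerPool([pool[2]])
        pairs = standard_rdc_pairs(sub[0])
        s_true = np.random.default_rng(6).normal(size=5)
        d = conformer_design(sub[0], pairs) @ s_true
        rdcs = [RdcRestraint(p, float(v), 0.3) for p, v in zip(pairs, d)]
        fit = fit_tensor_and_populations(sub, rdcs)
        assert fit.populations == pytest.approx([1.0])
        tensor, _ = svd_fit_tensor(sub, np.array([1.0]), rdcs)
        np.testing.assert_allclose(fit.tensor.s, tensor.s, atol=1e-8)

    def test_q_classification_thresholds(self):
        fit = lambda q: RdcFit(  # noqa: E731
            SaupeTensor(np.zeros(5) + 0.1), np.array([1.0]), q, 5.0,
            np.zeros(3), True, "", 1
        )
        from hairpinxb.rdc import _q_class

        assert _q_class(0.005) == "good"
        assert _q_class(0.219) == "good"
        assert _q_class(0.322) == "acceptable"
        assert _q_class(0.376) == "acceptable"
        assert _q_class(0.41) == "poor"

    def test_q_trace_monotone_over_accepted_iterations(self, pool_and_truth):
        pool, truth = pool_and_truth
        sub = ConformerPool([pool[0], pool[4], pool[11], pool[15]])
        pairs = standard_rdc_pairs(sub[0])
        rng = np.random.default_rng(8)
        s_true = rng.normal(size=5)
        w_true = np.array([0.4, 0.3, 0.2, 0.1])
        G = np.zeros((len(pairs), 5))
        for w, c in zip(w_true, sub):
            G += w * conformer_design(c, pairs)
        d = G @ s_true + rng.normal(0, 0.3, size=len(pairs))
        rdcs = [RdcRestraint(p, float(v), 0.3) for p, v in zip(pairs, d)]
        from hairpinxb.rdc import _alternate

        blocks = np.stack([conformer_design(c, pairs) for c in sub])
        fit = _alternate(
            blocks, np.array([r.d_obs for r in rdcs]),
            np.array([1 / r.error for r in rdcs]),
            np.full(4, 0.25), 100, 1e-12, 10.0 / 0.3,
        )
        assert fit.q <= q_factor(
            np.array([r.d_obs for r in rdcs]),
            predict_rdc(sub, np.full(4, 0.25), fit.tensor, pairs),
        ) + 1e-12

    def test_cn_flag(self):
        t = SaupeTensor(np.zeros(5) + 0.1)
        good = RdcFit(t, np.array([1.0]), 0.1, 5.5, np.zeros(3), 5.5 < 30, "good", 1)
        bad = RdcFit(t, np.array([1.0]), 0.1, 31.0, np.zeros(3), 31.0 < 30, "good", 1)
        assert good.reliable and not bad.reliable
        assert bad.unreliable


class TestPredictAndXb:
    def test_zero_tensor_predicts_zero(self, pool_and_truth):
        pool, truth = pool_and_truth
        pairs = standard_rdc_pairs(pool[0])
        d = predict_rdc(pool, truth.populations, SaupeTensor(np.zeros(5)), pairs)
        np.testing.assert_allclose(d, 0.0)

    def test_two_conformer_average_is_linear(self, pool_and_truth):
        pool, _ = pool_and_truth
        pairs = standard_rdc_pairs(pool[0])[:6]
        t = SaupeTensor(np.random.default_rng(9).normal(size=5))
        a = ConformerPool([pool[0]])
        b = ConformerPool([pool[1]])
        both = ConformerPool([pool[0], pool[1]])
        da = predict_rdc(a, np.array([1.0]), t, pairs)
        db = predict_rdc(b, np.array([1.0]), t, pairs)
        dmix = predict_rdc(both, np.array([0.5, 0.5]), t, pairs)
        np.testing.assert_allclose(dmix, 0.5 * (da + db), atol=1e-12)

    def test_xb_population_examples(self):
        t = SaupeTensor(np.zeros(5) + 0.1)
        fit = RdcFit(t, np.array([0.3, 0.7]), 0.1, 5.0, np.zeros(3), True, "good", 1)
        assert xb_population(fit, [True, False]) == pytest.approx(30.0)
        all_fit = RdcFit(t, np.array([0.6, 0.4]), 0.1, 5.0, np.zeros(3), True, "good", 1)
        assert xb_population(all_fit, [True, True]) == pytest.approx(100.0)
        with pytest.raises(LabelingError):
            xb_population(fit, [True])

    def test_noiseless_xb_share_recovered_exactly(self, pool_and_truth, gen_cfg):
        """Truth XB share 40% on a 5-conformer pool, noiseless RDCs."""
        from hairpinxb.synthetic import enrich_with_xb_conformers, _xb_label

        pool, _ = pool_and_truth
        enriched = enrich_with_xb_conformers(pool, gen_cfg, 2, seed=31)
        chosen = [0, 4, 11, len(enriched) - 2, len(enriched) - 1]
        sub = ConformerPool([enriched[i] for i in chosen])
        xb = np.array([_xb_label(c, gen_cfg) for c in sub])
        assert xb.sum() == 2
        w_true = np.where(xb, 0.20, 0.20)  # XB share exactly 40%
        pairs = standard_rdc_pairs(sub[0])
        s_true = np.random.default_rng(12).normal(size=5)
        G = np.zeros((len(pairs), 5))
        for w, c in zip(w_true, sub):
            G += w * conformer_design(c, pairs)
        rdcs = [RdcRestraint(p, float(v), 0.3) for p, v in zip(pairs, G @ s_true)]
        fit = fit_tensor_and_populations(sub, rdcs)
        assert xb_population(fit, xb) == pytest.approx(40.0, abs=0.1)

    def test_population_validation(self, pool_and_truth):
        pool, _ = pool_and_truth
        pairs = standard_rdc_pairs(pool[0])[:5]
        t = SaupeTensor(np.zeros(5) + 0.1)
        with pytest.raises(ConfigError):
            predict_rdc(pool, np.ones(len(pool)), t, pairs)  # sums to n
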