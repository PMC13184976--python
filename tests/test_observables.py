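"""NOE buildup reduction, Karplus couplings, RDC extraction, forward models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairpinxb.errors import (
    CalibrationError,
    ConfigError,
    DegenerateGeometryError,
    InsufficientDataError,
)
from hairpinxb.observables import (
    CouplingPair,
    JRestraint,
    KarplusCoefficients,
    MixingSeries,
    NoeDistanceRestraint,
    RdcRestraint,
    distance_to_rate,
    fit_buildup,
    karplus_j,
    predict_j,
    predict_noe_distance,
    rate_to_distance,
    rdc_from_couplings,
    read_j_csv,
    read_noe_series_csv,
    read_rdc_csv,
    reduce_noe_series,
    write_j_csv,
    write_noe_series_csv,
    write_rdc_csv,
)
from hairpinxb.structures import ConformerPool, backbone_phi

PAIR = ((1, "H"), (1, "HA"))
TIMES = np.arange(0.1, 0.71, 0.1)


class TestBuildup:
    def test_exact_line_slope(self):
        s = MixingSeries(PAIR, TIMES, 2.0 * TIMES)
        assert fit_buildup(s) == pytest.approx(2.0)

    def test_constant_intensities(self):
        s = MixingSeries(PAIR, TIMES, np.full_like(TIMES, 3.3))
        assert fit_buildup(s) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_matches_closed_form_ols(self):
        rng = np.random.default_rng(12)
        y = 1.7 * TIMES + 0.2 + rng.normal(0, 0.05, size=len(TIMES))
        s = MixingSeries(PAIR, TIMES, y)
        # closed-form OLS oracle
        t_c = TIMES - TIMES.mean()
        expected = float(np.dot(t_c, y - y.mean()) / np.dot(t_c, t_c))
        assert fit_buildup(s) == pytest.approx(expected, rel=1e-12)

    def test_through_origin_flag(self):
        y = 2.0 * TIMES + 1.0
        s = MixingSeries(PAIR, TIMES, y)
        expected = float(np.dot(TIMES, y) / np.dot(TIMES, TIMES))
        assert fit_buildup(s, through_origin=True) == pytest.approx(expected)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            MixingSeries(PAIR, [0.1, 0.2], [1.0, 2.0])

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ConfigError):
            MixingSeries(PAIR, [0.1, 0.3, 0.2], [1, 2, 3])


class TestRateToDistance:
    def test_reference_rate_gives_reference_distance(self):
        assert rate_to_distance(1.0, 1.0) == pytest.approx(1.78)

    def test_sixty_four_fold_weaker_doubles_distance(self):
        assert rate_to_distance(1.0 / 64.0, 1.0) == pytest.approx(3.56)

    def test_729_fold_stronger_is_third(self):
        assert rate_to_distance(729.0, 1.0) == pytest.approx(1.78 / 3.0)

    def test_nonpositive_rate_raises(self):
        with pytest.raises(CalibrationError):
            rate_to_distance(-0.1, 1.0)
        with pytest.raises(CalibrationError):
            rate_to_distance(1.0, 0.0)

    @given(
        r=st.floats(1.8, 8.0),
        sigma_ref=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_encode_decode_round_trip(self, r, sigma_ref):
        sigma = distance_to_rate(r, sigma_ref)
        assert rate_to_distance(sigma, sigma_ref) == pytest.approx(r, rel=1e-12)


class TestKarplus:
    @pytest.mark.parametrize(
        "phi,expected",
        [(-120.0, 9.87), (60.0, 6.35), (-60.0, 4.1075)],
    )
    def test_default_coefficients(self, phi, expected):
        assert karplus_j(phi) == pytest.approx(expected, abs=5e-3)

    def test_periodicity(self):
        k = KarplusCoefficients()
        for phi in (-170.0, -60.0, 33.0, 121.0):
            assert karplus_j(phi, k) == pytest.approx(karplus_j(phi + 360.0, k))

    def test_extrema_match_dense_grid(self):
        # brute-force oracle on a dense grid vs the quadratic-in-cos form
        k = KarplusCoefficients()
        grid = np.arange(-180.0, 180.0, 0.01)
        vals = np.array([karplus_j(p, k) for p in grid])
        # analytic extrema of A c^2 + B c + C over c in [-1, 1]
        candidates = [k.A + k.B + k.C, k.A - k.B + k.C]
        c_star = -k.B / (2 * k.A)
        if -1 <= c_star <= 1:
            candidates.append(k.A * c_star**2 + k.B * c_star + k.C)
        assert vals.max() == pytest.approx(max(candidates), abs=1e-4)
        assert vals.min() == pytest.approx(min(candidates), abs=1e-4)


class TestForwardModels:
    def test_single_conformer_noe_is_plain_distance(self, pool_and_truth):
        pool, _ = pool_and_truth
        sub = ConformerPool([pool[0]])
        pair = ((1, "H"), (1, "HA"))
        from hairpinxb.structures import distance

        assert predict_noe_distance(sub, np.array([1.0]), pair) == pytest.approx(
            distance(pool[0], *pair)
        )

    def test_equal_mix_of_2_and_4_angstrom(self, toy_factory):
        c1 = toy_factory([[0, 0, 0], [2, 0, 0]])
        c2 = toy_factory([[0, 0, 0], [4, 0, 0]], id="toy2")
        pool = ConformerPool([c1, c2])
        expected = (0.5 * 2.0**-6 + 0.5 * 4.0**-6) ** (-1.0 / 6.0)
        r = predict_noe_distance(pool, np.array([0.5, 0.5]), ((1, "A1"), (1, "A2")))
        assert r == pytest.approx(expected)
        assert r == pytest.approx(2.239, abs=1e-3)

    def test_effective_distance_bounds_and_convexity(self, pool_and_truth):
        pool, truth = pool_and_truth
        pair = ((3, "HA"), (10, "HA"))
        from hairpinxb.structures import distance

        r_each = np.array([distance(c, *pair) for c in pool])
        w = truth.populations
        r_eff = predict_noe_distance(pool, w, pair)
        assert r_each.min() - 1e-9 <= r_eff <= r_each.max() + 1e-9
        assert r_eff <= float(np.dot(w, r_each)) + 1e-9

    def test_zero_distance_raises(self, toy_factory):
        c = toy_factory([[0, 0, 0], [0, 0, 0]])
        pool = ConformerPool([c])
        with pytest.raises(DegenerateGeometryError):
            predict_noe_distance(pool, np.array([1.0]), ((1, "A1"), (1, "A2")))

    def test_predict_j_single_and_mixture(self, pool_and_truth):
        pool, _ = pool_and_truth
        sub = ConformerPool([pool[0]])
        expected = karplus_j(backbone_phi(pool[0], 3))
        assert predict_j(sub, np.array([1.0]), 3) == pytest.approx(expected)

        two = ConformerPool([pool[0], pool[1]])
        w = np.array([0.5, 0.5])
        mix = predict_j(two, w, 3)
        j0 = karplus_j(backbone_phi(pool[0], 3))
        j1 = karplus_j(backbone_phi(pool[1], 3))
        assert mix == pytest.approx(0.5 * (j0 + j1))

    def test_permutation_invariance(self, pool_and_truth):
        pool, truth = pool_and_truth
        order = np.random.default_rng(0).permutation(len(pool))
        permuted = ConformerPool([pool[int(i)] for i in order])
        w = truth.populations
        pair = ((5, "H"), (8, "H"))
        assert predict_noe_distance(permuted, w[order], pair) == pytest.approx(
            predict_noe_distance(pool, w, pair)
        )
        assert predict_j(permuted, w[order], 4) == pytest.approx(
            predict_j(pool, w, 4)
        )


class TestRdcExtraction:
    @pytest.mark.parametrize(
        "t_strong,t_weak,expected",
        [(150.0, 150.0, 0.0), (145.0, 152.3, -7.3)],
    )
    def test_difference(self, t_strong, t_weak, expected):
        cp = CouplingPair(((1, "CA"), (1, "HA")), t_strong, t_weak)
        assert rdc_from_couplings(cp).d_obs == pytest.approx(expected)

    def test_encoded_rdc_round_trip(self):
        # a gel pair constructed to encode D = +6 Hz
        cp = CouplingPair(((1, "CA"), (1, "HA")), 146.0, 140.0)
        assert rdc_from_couplings(cp).d_obs == pytest.approx(6.0)


class TestReduction:
    def _series(self, r_map, sigma_ref=1.0):
        ref = MixingSeries(((7, "HA1"), (7, "HA2")), TIMES, sigma_ref * TIMES, True)
        out = [ref]
        for pair, r in r_map.items():
            sigma = distance_to_rate(r, sigma_ref)
            out.append(MixingSeries(pair, TIMES, sigma * TIMES))
        return out

    def test_reduce_recovers_distances(self):
        r_map = {((1, "H"), (1, "HA")): 2.4, ((2, "H"), (3, "HA")): 3.7}
        restraints = reduce_noe_series(self._series(r_map))
        assert len(restraints) == 2
        for r in restraints:
            assert r.r_obs == pytest.approx(r_map[r.pair], rel=1e-10)

    def test_rate_rel_error_propagation(self):
        r_map = {((1, "H"), (1, "HA")): 3.0}
        (r,) = reduce_noe_series(self._series(r_map), rate_rel_error=0.06)
        assert r.error == pytest.approx(3.0 * 0.01)

    def test_requires_exactly_one_reference(self):
        series = self._series({((1, "H"), (1, "HA")): 2.4})
        with pytest.raises(CalibrationError):
            reduce_noe_series(series[1:])


class TestTableIO:
    def test_noe_series_round_trip(self, tmp_path):
        series = [
            MixingSeries(((7, "HA1"), (7, "HA2")), TIMES, 1.0 * TIMES, True),
            MixingSeries(((1, "H"), (1, "HA")), TIMES, 0.2 * TIMES),
        ]
        path = tmp_path / "noe.csv"
        write_noe_series_csv(series, path)
        back = read_noe_series_csv(path)
        assert len(back) == 2
        ref = [s for s in back if s.reference_flag]
        assert len(ref) == 1 and ref[0].pair == ((7, "HA1"), (7, "HA2"))
        np.testing.assert_allclose(back[1].intensities, series[1].intensities)

    def test_j_round_trip(self, tmp_path):
        restraints = [JRestraint(2, 8.1, 0.3), JRestraint(3, 4.9, 0.3)]
        path = tmp_path / "j.csv"
        write_j_csv(restraints, path)
        back = read_j_csv(path)
        assert [(r.residue, r.j_obs) for r in back] == [(2, 8.1), (3, 4.9)]

    def test_rdc_round_trip_and_coupling_pairs(self, tmp_path):
        restraints = [RdcRestraint(((1, "CA"), (1, "HA")), -7.3, 0.4)]
        path = tmp_path / "rdc.csv"
        write_rdc_csv(restraints, path)
        back = read_rdc_csv(path)
        assert back[0].d_obs == pytest.approx(-7.3)
        # the T_strong/T_weak form is accepted as well
        pair_table = tmp_path / "pairs.csv"
        pair_table.write_text(
            "res_c,atom_c,res_h,atom_h,t_strong,t_weak\n1,CA,1,HA,145.0,152.3\n"
        )
        pairs = read_rdc_csv(pair_table)
        assert pairs[0].d_obs == pytest.approx(-7.3)
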