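"""Calibrated lesion model: quadratics, decomposition, DSBs, thresholds."""

import numpy as np
import pytest
from scipy.optimize import brentq

from nanodamage.lesions import (
    calibrate_lambda,
    decompose_lesions,
    mean_dsb,
    mean_lesions,
    min_let_for,
    sample_voxel_damage,
)
from nanodamage._rng import substream

ANCHOR_SETS = {
    "alpha": ((162.4, 39.8), (103.4, 23.1), (11.5, 2.0)),
    "proton": ((41.3, 10.8), (26.1, 6.3), (9.4, 2.0)),
}


class TestCalibration:
    @pytest.mark.parametrize("pid", sorted(ANCHOR_SETS))
    def test_exact_solve_matches_polyfit_oracle(self, pid):
        anchors = ANCHOR_SETS[pid]
        a, b, c = calibrate_lambda(anchors)
        L = np.array([x for x, _ in anchors])
        y = np.array([v for _, v in anchors])
        oracle = np.polyfit(L, y, 2)
        assert (a, b, c) == pytest.approx(tuple(oracle), rel=1e-9)
        for let, lam in anchors:
            assert a * let * let + b * let + c == pytest.approx(lam, abs=1e-9)

    def test_frozen_coefficients(self, cal):
        assert cal.value("lesions.lambda_coeffs.alpha") == pytest.approx(
            (3.5423e-4, 0.188896, -0.219154), rel=1e-4)
        assert cal.value("lesions.lambda_coeffs.proton") == pytest.approx(
            (1.2090e-3, 0.214565, -0.123739), rel=1e-4)
        assert cal.value("lesions.lambda_coeffs.electron") == pytest.approx(
            (3.51817e-2, 3.05282e-2, 9.74218e-3), rel=1e-4)

    def test_electron_anchors_from_site_inversion(self, cal):
        # the low-LET anchors are lambdas solving the printed electron
        # damage-site counts 86.7 and 67.9
        anchors = dict(cal.value("lesions.lambda_anchors.electron"))
        assert anchors[0.2] == pytest.approx(0.0172551, rel=1e-5)
        assert anchors[0.4] == pytest.approx(0.0275825, rel=1e-5)
        assert anchors[7.1] == 2.0

    def test_anchors_reproduced(self, cal):
        for pid in ("alpha", "proton", "electron"):
            for let, lam in cal.value(f"lesions.lambda_anchors.{pid}"):
                assert mean_lesions(pid, let) == pytest.approx(lam, abs=1e-6)

    def test_duplicate_anchor_lets_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            calibrate_lambda(((10, 1.0), (10, 2.0), (20, 3.0)))

    def test_derived_constants(self, cal):
        assert cal.value("lesions.p_lee") == pytest.approx(0.4733, abs=1e-3)
        assert cal.value("lesions.sb_share") == pytest.approx(0.4419, abs=1e-4)
        assert cal.value("lesions.c_lin_per_kev_um") == pytest.approx(0.0769, abs=1e-4)


class TestMeanLesions:
    def test_non_anchor_table_checks(self):
        # remaining published cluster sizes act as independent checks
        assert mean_lesions("alpha", 15.2) == pytest.approx(2.8, rel=0.10)
        assert mean_lesions("alpha", 8.6) == pytest.approx(1.4, rel=0.10)

    def test_clamped_at_zero_below_quadratic_root(self):
        assert mean_lesions("alpha", 0.5) == 0.0
        assert mean_lesions("proton", 0.2) == 0.0

    @pytest.mark.parametrize(
        "pid, lo, hi",
        [("alpha", 1.2, 270.0), ("proton", 0.7, 85.0), ("electron", 0.2, 29.0)],
    )
    def test_strictly_increasing(self, pid, lo, hi):
        grid = np.linspace(lo, hi, 200)
        vals = [mean_lesions(pid, L) for L in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            mean_lesions("alpha", -1.0)
        with pytest.raises(ValueError):
            mean_lesions("alpha", 300.5)


class TestDecomposition:
    def test_alpha_max_let_breakdown(self):
        dec = decompose_lesions("alpha", 162.4)
        assert dec.linear_direct + dec.linear_indirect == pytest.approx(12.49, abs=0.01)
        assert dec.lee_part == pytest.approx(27.31, abs=0.01)
        assert dec.ssb_mean == pytest.approx(20.91, abs=0.01)
        assert dec.base_mean == pytest.approx(39.8 - 20.91, abs=0.01)

    def test_zero_let(self):
        dec = decompose_lesions("proton", 0.0)
        assert dec.total == 0.0
        assert dec.ssb_mean == 0.0 and dec.base_mean == 0.0

    def test_parts_sum_to_lambda(self):
        rng = np.random.default_rng(0)
        for pid, lo in (("alpha", 2.0), ("proton", 1.0)):
            for L in rng.uniform(lo, 80.0, 10):
                dec = decompose_lesions(pid, float(L))
                assert dec.total == pytest.approx(mean_lesions(pid, float(L)), rel=1e-12)
                assert dec.linear_direct >= 0
                assert dec.linear_indirect >= 0
                assert dec.lee_part >= 0

    @pytest.mark.parametrize(
        "pid, lo, hi", [("alpha", 2, 270), ("proton", 1, 85), ("electron", 1.1, 29)]
    )
    def test_direct_share_increases_with_let(self, pid, lo, hi):
        grid = np.linspace(lo, hi, 80)
        shares = []
        for L in grid:
            dec = decompose_lesions(pid, L)
            lam = mean_lesions(pid, L)
            shares.append((dec.linear_direct + dec.lee_part) / lam)
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))


class TestDSB:
    @pytest.mark.parametrize(
        "pid, lmin", [("electron", 9.0), ("proton", 11.8), ("alpha", 15.2)]
    )
    def test_unity_at_minimum_let(self, pid, lmin):
        assert mean_dsb(pid, lmin) == pytest.approx(1.0, abs=1e-6)

    def test_zero_at_zero_let(self):
        assert mean_dsb("alpha", 0.0) == 0.0
        assert mean_dsb("proton", 0.0) == 0.0
        # the electron quadratic keeps a tiny positive intercept from its
        # site-count anchors, so its DSB mean at zero LET is ~1e-5, not 0
        assert mean_dsb("electron", 0.0) < 1e-5

    def test_cap_at_half_total_high_let(self):
        # at the alpha maximum anchor the lambda/2 cap is active
        assert mean_dsb("alpha", 162.4) == pytest.approx(19.9, abs=1e-6)
        grid = np.linspace(1, 270, 100)
        for L in grid:
            assert mean_dsb("alpha", L) <= mean_lesions("alpha", L) / 2 + 1e-12

    def test_nondecreasing(self):
        grid = np.linspace(0.5, 270, 200)
        vals = [mean_dsb("alpha", L) for L in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestThresholds:
    def test_clustered_damage_minimum_lets(self):
        assert min_let_for("electron", "total_lesions", 2.0) == pytest.approx(7.1, abs=1e-2)
        assert min_let_for("proton", "total_lesions", 2.0) == pytest.approx(9.4, abs=1e-2)
        assert min_let_for("alpha", "total_lesions", 2.0) == pytest.approx(11.5, abs=1e-2)

    def test_dsb_minimum_lets(self):
        assert min_let_for("electron", "dsb", 1.0) == pytest.approx(9.0, abs=1e-2)
        assert min_let_for("proton", "dsb", 1.0) == pytest.approx(11.8, abs=1e-2)
        assert min_let_for("alpha", "dsb", 1.0) == pytest.approx(15.2, abs=1e-2)

    def test_bisection_agrees_with_brentq_oracle(self):
        root = min_let_for("alpha", "total_lesions", 5.0)
        oracle = brentq(lambda L: mean_lesions("alpha", L) - 5.0, 0.1, 300)
        assert root == pytest.approx(oracle, abs=2e-3)

    def test_unattainable_level(self):
        with pytest.raises(ValueError, match="not attainable"):
            min_let_for("alpha", "total_lesions", 1e6)
        with pytest.raises(KeyError):
            min_let_for("alpha", "ionizations", 1.0)


class TestSampling:
    def test_seed_determinism(self):
        a = sample_voxel_damage("alpha", 103.4, seed=21)
        b = sample_voxel_damage("alpha", 103.4, seed=21)
        assert a == b

    def test_strand_pairing_pigeonhole(self):
        rng = substream(4, "lesions")
        for _ in range(500):
            c = sample_voxel_damage("proton", 41.3, rng=rng)
            assert c.dsb <= c.ssb // 2
            assert c.dsb <= c.total / 2
            assert c.ssb + c.base == c.total

    def test_mean_total_matches_lambda(self):
        """Sampled voxel totals converge on the calibrated mean."""
        rng = substream(8, "lesions")
        cases = [("alpha", 103.4), ("proton", 26.1), ("electron", 7.1),
                 ("alpha", 15.2), ("proton", 41.3)]
        for pid, L in cases:
            n = 20_000
            tot = sum(sample_voxel_damage(pid, L, rng=rng).total for _ in range(n))
            lam = mean_lesions(pid, L)
            se = np.sqrt(lam / n)
            assert tot / n == pytest.approx(lam, abs=3 * se)

    def test_parts_scale_with_sampled_total(self):
        c = sample_voxel_damage("alpha", 162.4, seed=3)
        assert c.direct_part + c.indirect_part + c.lee_part == pytest.approx(
            c.total, rel=1e-9)
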