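"""Nucleus-scale scoring: tracks, damage sites, cluster size, simulation."""

import numpy as np
import pytest

from nanodamage.nucleus import (
    TABLE2_ROWS,
    cluster_size,
    damage_sites,
    n_tracks,
    simulate_nucleus,
    table2_report,
)
from nanodamage.lesions import mean_lesions


class TestTracks:
    @pytest.mark.parametrize(
        "let, expected", [(0.2, 325.0), (162.4, 0.40025), (8.6, 7.55814)]
    )
    def test_track_counts(self, let, expected):
        assert n_tracks(let) == pytest.approx(expected, rel=1e-4)

    def test_energy_bookkeeping_exact(self):
        for let in (0.2, 1.7, 26.1, 162.4, 262.2):
            assert n_tracks(let) * let * 4.0 == pytest.approx(260.0, rel=1e-9)

    def test_nonpositive_let(self):
        with pytest.raises(ValueError):
            n_tracks(0.0)


class TestDeterministicScoring:
    def test_compat_reproduces_published_cells(self):
        assert cluster_size("alpha", 162.4) == pytest.approx(39.8, abs=1e-6)
        assert cluster_size("alpha", 103.4) == pytest.approx(23.1, abs=1e-6)
        assert cluster_size("proton", 41.3) == pytest.approx(10.8, abs=1e-6)
        assert damage_sites("alpha", 162.4) == pytest.approx(1.6, rel=0.01)
        assert damage_sites("alpha", 103.4) == pytest.approx(2.5, rel=0.01)
        assert damage_sites("alpha", 8.6) == pytest.approx(30.3, rel=0.01)
        assert damage_sites("alpha", 15.2) == pytest.approx(17.3, rel=0.02)
        assert damage_sites("proton", 41.3) == pytest.approx(6.3, rel=0.01)
        assert damage_sites("proton", 26.1) == pytest.approx(10.1, rel=0.02)
        # electron rows are exact by construction of the lambda anchors
        assert damage_sites("electron", 0.2) == pytest.approx(86.7, abs=1e-6)
        assert damage_sites("electron", 0.4) == pytest.approx(67.9, abs=1e-6)

    def test_report_covers_all_rows_with_printed_lets(self):
        df = table2_report()
        assert len(df) == len(TABLE2_ROWS)
        assert list(df.columns) == [
            "particle", "energy_MeV", "LET", "range_um",
            "cluster_size", "damage_sites",
        ]
        # the proton 1 MeV row carries the printed 26.1 LET override
        row = df[(df.particle == "proton") & (df.energy_MeV == 1.0)].iloc[0]
        assert row.LET == 26.1
        # low-LET cluster sizes print as "<1"
        sub = df[df.LET < 2.0]
        assert (sub.cluster_size < 1.0).all()

    @pytest.mark.parametrize(
        "pid, let",
        [("alpha", 8.6), ("alpha", 162.4), ("proton", 5.0), ("electron", 0.2)],
    )
    def test_compat_sites_dominate_principled(self, pid, let):
        assert damage_sites(pid, let, "table2_compat") >= damage_sites(
            pid, let, "principled")

    def test_principled_cluster_size_low_lambda_limit(self):
        # lambda/(1 - e^-lambda) -> 1 as lambda -> 0
        assert cluster_size("electron", 0.2, "principled") == pytest.approx(1.0, abs=0.01)
        lam = mean_lesions("alpha", 162.4)
        assert cluster_size("alpha", 162.4, "principled") == pytest.approx(
            lam / -np.expm1(-lam), rel=1e-12)

    @pytest.mark.parametrize("pid, lo, hi", [("alpha", 9.0, 262.2), ("proton", 5.0, 81.5)])
    def test_cluster_grows_while_sites_shrink(self, pid, lo, hi):
        """Higher LET means fewer tracks per dose: larger clusters but
        fewer separate damage sites."""
        grid = np.linspace(lo, hi, 60)
        cs = [cluster_size(pid, L) for L in grid]
        ds = [damage_sites(pid, L) for L in grid]
        assert all(b > a for a, b in zip(cs, cs[1:]))
        assert all(b < a for a, b in zip(ds, ds[1:]))

    def test_mode_validation(self):
        with pytest.raises(ValueError, match="unknown mode"):
            damage_sites("alpha", 8.6, "exact")


class TestSimulation:
    def test_seed_determinism(self):
        a = simulate_nucleus("alpha", let=15.2, seed=5, reps=10)
        b = simulate_nucleus("alpha", let=15.2, seed=5, reps=10)
        assert a == b

    def test_energy_argument_uses_track_averaged_let(self):
        (rep,) = simulate_nucleus("alpha", energy=100.0, seed=1, reps=1)
        assert rep.let == 8.6

    def test_report_bookkeeping(self):
        (rep,) = simulate_nucleus("proton", let=41.3, seed=2, reps=1)
        assert rep.n_tracks * rep.let * 4.0 == pytest.approx(260.0, rel=1e-9)

    @pytest.mark.parametrize("mode", ["table2_compat", "principled"])
    def test_mean_converges_to_deterministic(self, mode):
        reps = simulate_nucleus("alpha", let=8.6, seed=13, reps=600, mode=mode)
        sites = np.array([r.damage_sites for r in reps])
        cs = np.array([r.cluster_size for r in reps])
        det_sites = damage_sites("alpha", 8.6, mode)
        det_cs = cluster_size("alpha", 8.6, mode)
        assert sites.mean() == pytest.approx(
            det_sites, abs=3 * sites.std(ddof=1) / np.sqrt(len(reps)))
        # principled cluster size is a ratio estimator; allow its small bias
        tol = 3 * cs.std(ddof=1) / np.sqrt(len(reps)) + (0.02 if mode == "principled" else 0)
        assert cs.mean() == pytest.approx(det_cs, abs=tol)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            simulate_nucleus("alpha", let=8.6, reps=0)
        with pytest.raises(ValueError):
            simulate_nucleus("alpha", energy=100.0, let=8.6)
        with pytest.raises(ValueError):
            simulate_nucleus("alpha")
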