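"""Partial-likelihood correctness, invariances, fitting and intervals."""

import numpy as np
import pandas as pd
import pytest

import flocknbda as fn
from flocknbda.networks import BIRD, FLOCK, FollowingNetwork
from flocknbda.oada import ModelSpec, OadaData, build_oada_data, marginal_negloglik

from oracles import enumeration_negloglik, random_instance


def three_naive_diffusion():
    return fn.Diffusion(
        flock="F1",
        patch_rank=1,
        acquisitions=[("B1", 100.0), ("B2", 200.0), ("B3", 300.0)],
        censored=frozenset(),
        demonstrators=frozenset(),
    )


def trivial_roster(birds, flock="F1"):
    return pd.DataFrame(
        {
            BIRD: birds,
            FLOCK: flock,
            "sex": "M",
            "age": 2.0,
            "informed": False,
            "feeding_activity": 1,
            "transmission_weight": 1.0,
        }
    )


def zero_networks(birds, flock="F1"):
    n = len(birds)
    return {"following": {flock: FollowingNetwork(flock, birds, np.zeros((n, n)), 1.0)}}


class TestSocialExposure:
    def test_single_informed_neighbour(self):
        net = FollowingNetwork(
            "F1", ["i", "j"], np.array([[0.0, 2.0], [0.0, 0.0]]), 1.0
        )
        T = fn.social_exposure(net, {"j": 1}, {"j": 1.0}, "i")
        assert T == 2.0

    def test_no_informed_no_exposure(self):
        net = FollowingNetwork("F1", ["i", "j"], np.ones((2, 2)) - np.eye(2), 1.0)
        assert fn.social_exposure(net, {}, {"j": 1.0}, "i") == 0.0

    def test_homogeneous_exposure_uniform(self, small_dataset):
        # under the homogeneous network every naive bird sees the same
        # exposure sum_j w_j z_j
        roster = small_dataset.roster
        flock = roster[FLOCK].iloc[0]
        sub = roster[roster[FLOCK] == flock]
        net = small_dataset.networks["homogeneous"][flock]
        informed = set(sub.loc[sub["informed"], BIRD])
        weights = dict(zip(sub[BIRD], sub["transmission_weight"]))
        status = {b: 1 for b in informed}
        expect = sum(weights[b] for b in informed)
        for b in sub[BIRD]:
            if b not in informed:
                assert fn.social_exposure(net, status, weights, b) == pytest.approx(
                    expect, abs=1e-12
                )


class TestNextAcquirerProbabilities:
    def test_uniform_when_asocial(self):
        p = fn.next_acquirer_probabilities(["a", "b", "c"], 0.0, {})
        np.testing.assert_allclose(p, [1 / 3] * 3)

    def test_two_to_one_odds(self):
        p = fn.next_acquirer_probabilities(["a", "b"], 1.0, {"a": 1.0, "b": 0.0})
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-15)

    def test_matches_hand_ratio(self):
        rng = np.random.default_rng(3)
        T = dict(zip("abcd", rng.uniform(0, 3, 4)))
        eta = dict(zip("abcd", rng.normal(size=4)))
        s = 0.7
        p = fn.next_acquirer_probabilities(list("abcd"), s, T, eta)
        lam = np.array([np.exp(eta[b]) * (1 + s * T[b]) for b in "abcd"])
        np.testing.assert_allclose(p, lam / lam.sum(), atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestNegLogLik:
    def test_asocial_three_birds_is_ln6(self):
        birds = ["B1", "B2", "B3"]
        spec = ModelSpec(network_type=None, scenario="asocial")
        nll = fn.oada_negloglik(
            np.empty(0), spec, [three_naive_diffusion()],
            zero_networks(birds), trivial_roster(birds),
        )
        assert nll == pytest.approx(np.log(6), abs=1e-12)

    def test_monotone_time_warp_invariance(self):
        birds = ["B1", "B2", "B3"]
        d = three_naive_diffusion()
        warped = fn.Diffusion(
            flock=d.flock,
            patch_rank=d.patch_rank,
            acquisitions=[(b, np.expm1(t / 100.0)) for b, t in d.acquisitions],
            censored=d.censored,
            demonstrators=d.demonstrators,
        )
        spec = ModelSpec(network_type=None, scenario="asocial")
        args = (zero_networks(birds), trivial_roster(birds))
        assert fn.oada_negloglik(np.empty(0), spec, [d], *args) == fn.oada_negloglik(
            np.empty(0), spec, [warped], *args
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        diff, nets, roster = random_instance(rng)
        spec = ModelSpec(scenario="separate_s", covariates=("sex", "age"))
        s_free = rng.uniform(0, 2, size=2)
        beta = rng.normal(0, 0.5, size=2)
        expected = enumeration_negloglik(diff, nets, roster, spec, s_free, beta)
        got = fn.oada_negloglik(
            np.concatenate([s_free, beta]), spec, [diff], nets, roster
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_network_equals_asocial(self):
        rng = np.random.default_rng(5)
        diff, _, roster = random_instance(rng, n_birds=5, n_events=3)
        nets = zero_networks([f"B{k}" for k in range(5)])
        spec_soc = ModelSpec(scenario="shared_s", covariates=("sex",))
        spec_aso = ModelSpec(network_type=None, scenario="asocial", covariates=("sex",))
        beta = np.array([0.3])
        nll_soc = fn.oada_negloglik(np.r_[2.0, beta], spec_soc, [diff], nets, roster)
        nll_aso = fn.oada_negloglik(beta, spec_aso, [diff], nets, roster)
        assert nll_soc == pytest.approx(nll_aso, abs=1e-12)

    def test_edge_scale_absorbed_by_s(self, small_dataset):
        """Multiplying all edge weights by c rescales s_hat by 1/c and
        leaves the maximized likelihood unchanged."""
        ds = small_dataset
        c = 3.7
        scaled = {
            fl: FollowingNetwork(fl, net.nodes, net.adjacency * c, net.observation_hours)
            for fl, net in ds.networks["following"].items()
        }
        spec = ModelSpec(scenario="s_patch1_only", covariates=("sex",))
        fit1 = fn.fit_oada(spec, ds.diffusions, ds.networks, ds.roster)
        fit2 = fn.fit_oada(spec, ds.diffusions, {"following": scaled}, ds.roster)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)
        assert fit2.s_hat[1] == pytest.approx(fit1.s_hat[1] / c, rel=1e-3)

    def test_negative_s_rejected(self):
        birds = ["B1", "B2", "B3"]
        spec = ModelSpec(scenario="shared_s")
        with pytest.raises(ValueError):
            fn.oada_negloglik(
                np.array([-1.0]), spec, [three_naive_diffusion()],
                zero_networks(birds), trivial_roster(birds),
            )


class TestAssignPatchStrata:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=[FLOCK, "patch_id", BIRD, "latency_s", "censored"]
        )

    def test_earlier_first_feed_gets_rank_one(self):
        roster = trivial_roster(["B1", "B2", "B3"])
        tab = self._table(
            [
                ("F1", "west", "B1", 13490.0, False),
                ("F1", "east", "B2", 6807.0, False),
            ]
        )
        diffs = fn.assign_patch_strata(tab, roster, 30420.0)
        ranks = {(d.patch_rank): d for d in diffs}
        assert ranks[1].acquisitions[0][0] == "B2"
        assert ranks[2].acquisitions[0][0] == "B1"

    def test_unexploited_patch_is_rank_two(self):
        roster = trivial_roster(["B1", "B2"])
        tab = self._table(
            [
                ("F1", "west", "B1", 100.0, False),
                ("F1", "east", "B2", 30420.0, True),
            ]
        )
        diffs = fn.assign_patch_strata(tab, roster, 30420.0)
        by_rank = {d.patch_rank: d for d in diffs}
        assert by_rank[2].acquisitions == []
        assert by_rank[2].censored == {"B1", "B2"}

    def test_relabeling_patches_keeps_ranks(self):
        roster = trivial_roster(["B1", "B2"])
        rows = [("F1", "west", "B1", 50.0, False), ("F1", "east", "B2", 99.0, False)]
        a = fn.assign_patch_strata(self._table(rows), roster, 30420.0)
        swapped = [(f, {"west": "Z", "east": "A"}[p], b, t, c) for f, p, b, t, c in rows]
        b = fn.assign_patch_strata(self._table(swapped), roster, 30420.0)
        for da, db in zip(a, b):
            assert da.patch_rank == db.patch_rank
            assert da.acquisitions == db.acquisitions

    def test_tied_first_latencies_need_tie_break(self):
        roster = trivial_roster(["B1", "B2"])
        rows = [("F1", "west", "B1", 50.0, False), ("F1", "east", "B2", 50.0, False)]
        with pytest.raises(ValueError, match="tie"):
            fn.assign_patch_strata(self._table(rows), roster, 30420.0)
        diffs = fn.assign_patch_strata(
            self._table(rows), roster, 30420.0, tie_break="patch_id"
        )
        assert {d.patch_rank for d in diffs} == {1, 2}


class TestFitting:
    def test_fixed_effects_reduction_of_mixed_model(self, small_dataset):
        """With the variance components pushed to the lower boundary the
        Laplace marginal equals the fixed-effects likelihood."""
        ds = small_dataset
        data = build_oada_data(ds.diffusions, ds.networks, ds.roster)
        spec_f = ModelSpec(scenario="s_patch1_only", covariates=("sex",))
        spec_m = ModelSpec(
            scenario="s_patch1_only", covariates=("sex",),
            random_effects="flock_plus_individual",
        )
        fit_f = fn.fit_oada(spec_f, data)
        theta = np.r_[fit_f.params, -16.0, -16.0]  # log-variances at the floor
        nll_m = marginal_negloglik(theta, spec_m, data)
        assert nll_m == pytest.approx(-fit_f.loglik, abs=1e-5)

    def test_boundary_estimate_flagged(self, small_dataset):
        # s at patch 2 was simulated at 0, so fitting patch-2-only social
        # transmission should end on (or extremely near) the boundary
        ds = small_dataset
        spec = ModelSpec(scenario="s_patch2_only", covariates=("sex",))
        fit = fn.fit_oada(spec, ds.diffusions, ds.networks, ds.roster)
        assert fit.s_hat[2] < 0.5
        if fit.s_hat[2] < 1e-6:
            assert fit.s_boundary[2]

    def test_mixed_model_recovers_flock_heterogeneity_direction(self):
        # strong flock frailty should push sigma2_flock well above zero
        sc = fn.SyntheticScenario(
            n_flocks=6, flock_size=8, s_true=(0.0, 0.0),
            sigma_flock2=1.0, seed=99,
        )
        ds = fn.generate_dataset(sc)
        data = build_oada_data(ds.diffusions, ds.networks, ds.roster)
        spec = ModelSpec(
            network_type=None, scenario="asocial", random_effects="flock"
        )
        fit = fn.fit_oada(spec, data)
        assert fit.converged


class TestProfileCI:
    def test_exact_quadratic_interval(self):
        # -logL = (theta-2)^2: the 95% bound solves 2*(theta-2)^2 = 3.8415
        lo, hi = fn.likelihood_interval(
            lambda th: (th - 2.0) ** 2, center=2.0, nll_min=0.0
        )
        half = np.sqrt(3.841458820694124 / 2.0)
        assert lo == pytest.approx(2.0 - half, abs=1e-5)
        assert hi == pytest.approx(2.0 + half, abs=1e-5)

    def test_boundary_lower_bound_is_zero(self, small_dataset):
        ds = small_dataset
        data = build_oada_data(ds.diffusions, ds.networks, ds.roster)
        spec = ModelSpec(scenario="s_patch2_only", covariates=("sex",))
        fit = fn.fit_oada(spec, data)
        lo, hi = fn.profile_ci(spec, data, fit, "s2")
        assert lo == 0.0
        assert hi > fit.s_hat[2]

    def test_interval_matches_dense_grid_oracle(self, default_dataset):
        ds = default_dataset
        data = build_oada_data(ds.diffusions, ds.networks, ds.roster)
        spec = ModelSpec(scenario="s_patch1_only", covariates=("sex",))
        fit = fn.fit_oada(spec, data)
        lo, hi = fn.profile_ci(spec, data, fit, "s1")
        assert np.isfinite(hi)  # well identified at full study size
        # dense-grid profile oracle
        from flocknbda.oada import _profile_nll

        grid = np.linspace(max(lo - 0.5, 1e-6), hi + 0.5, 400)
        step = grid[1] - grid[0]
        prof = np.array([_profile_nll(0, g, spec, data, fit.params) for g in grid])
        crit = -fit.loglik + 3.841458820694124 / 2.0
        inside = grid[prof <= crit]
        assert inside.min() == pytest.approx(lo, abs=1.5 * step)
        assert inside.max() == pytest.approx(hi, abs=1.5 * step)
        assert lo <= fit.s_hat[1] <= hi


class TestLRT:
    def test_identical_logliks(self, small_dataset):
        ds = small_dataset
        spec = ModelSpec(network_type=None, scenario="asocial", covariates=("sex",))
        fit = fn.fit_oada(spec, ds.diffusions, ds.networks, ds.roster)
        chi2, df, p = fn.lrt_vs_asocial(
            fn.fit_oada(
                ModelSpec(scenario="shared_s", covariates=("sex",)),
                ds.diffusions, ds.networks, ds.roster,
            ),
            fit,
        )
        assert df == 1 and chi2 >= 0.0

    def test_chi2_closed_form(self):
        from scipy import stats

        chi2 = 2 * (-500.0 - (-503.0))
        assert chi2 == 6.0
        assert stats.chi2.sf(chi2, 1) == pytest.approx(0.0143, abs=5e-4)

    def test_mismatched_covariates_rejected(self, small_dataset):
        ds = small_dataset
        f1 = fn.fit_oada(
            ModelSpec(scenario="shared_s", covariates=("sex",)),
            ds.diffusions, ds.networks, ds.roster,
        )
        f0 = fn.fit_oada(
            ModelSpec(network_type=None, scenario="asocial"),
            ds.diffusions, ds.networks, ds.roster,
        )
        with pytest.raises(ValueError):
            fn.lrt_vs_asocial(f1, f0)
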