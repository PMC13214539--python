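"""Resource states, utilization profiles, Levins breadth, Pianka overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ecozone.niche import (
    aggregate_niche,
    bin_resource_states,
    breadth_overlap_regression,
    levins_breadth,
    pianka_overlap,
    site_niche_features,
    utilization_profile,
)
from ecozone.synthetic import SyntheticConfig, generate_dataset

from conftest import make_states, random_profile_inputs


def profile_from_matrix(P: np.ndarray, R: int = 5):
    """Wrap a species x state share matrix as a one-gradient profile."""
    from ecozone.niche import UtilizationProfile

    P = np.asarray(P, dtype=float)[:, None, :]
    return UtilizationProfile(
        species=[f"sp{i+1}" for i in range(P.shape[0])],
        gradients=["g"], P=P, R=R,
    )


# ---------------------------------------------------------------------------
# brute-force oracles: literal loops over species x species x states
# ---------------------------------------------------------------------------

def brute_profile(community: pd.DataFrame, states, gradient: str, R: int):
    P = {}
    site_state = states.states[gradient]
    for sp in community.columns:
        total = community[sp].sum()
        row = []
        for j in range(1, R + 1):
            s = 0.0
            for site in community.index:
                if site_state[site] == j:
                    s += community.loc[site, sp]
            row.append(s / total if total > 0 else 0.0)
        P[sp] = row
    return P


def brute_levins(P: dict[str, list[float]]):
    return {sp: 1.0 / sum(p * p for p in row) for sp, row in P.items()}


def brute_pianka(P: dict[str, list[float]]):
    out = {}
    for i in P:
        for k in P:
            num = sum(pi * pk for pi, pk in zip(P[i], P[k]))
            den = (sum(p * p for p in P[i]) * sum(p * p for p in P[k])) ** 0.5
            out[(i, k)] = num / den
    return out


class TestResourceStates:
    def test_quintiles_of_one_to_ten(self):
        env = pd.DataFrame({"g": np.arange(1.0, 11.0)},
                           index=[f"s{i}" for i in range(10)])
        states = bin_resource_states(env, R=5)
        assert np.allclose(states.edges["g"], [2.8, 4.6, 6.4, 8.2])
        assert list(states.states["g"]) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_state_monotone_in_gradient(self):
        rng = np.random.default_rng(3)
        env = pd.DataFrame({"g": np.sort(rng.normal(size=17))},
                           index=[f"s{i}" for i in range(17)])
        st = bin_resource_states(env, R=5).states["g"]
        assert (np.diff(st) >= 0).all()

    def test_median_split(self):
        env = pd.DataFrame({"g": [0.0, 1.0]}, index=["a", "b"])
        st = bin_resource_states(env, R=2).states["g"]
        assert sorted(st) == [1, 2]

    def test_constant_gradient_named_in_error(self):
        env = pd.DataFrame({"DO": [1.0, 1.0, 1.0, 1.0, 1.0], "WT": range(5)},
                           index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="DO"):
            bin_resource_states(env, R=5)

    def test_too_few_sites_rejected(self):
        env = pd.DataFrame({"g": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="at least R"):
            bin_resource_states(env, R=5)


class TestUtilizationProfile:
    def test_hand_worked_shares(self):
        comm = pd.DataFrame({"sp": [2.0, 6.0]}, index=["s1", "s2"])
        states = make_states({"g": [1, 4]})
        prof = utilization_profile(comm, states)
        assert np.allclose(prof.frame("g").loc["sp"], [0.25, 0, 0, 0.75, 0])

    def test_point_and_uniform_support(self):
        comm = pd.DataFrame({"pt": [0, 5.0, 0, 0, 0], "uni": [2.0] * 5},
                            index=[f"s{i+1}" for i in range(5)])
        states = make_states({"g": [1, 3, 2, 4, 5]})
        prof = utilization_profile(comm, states)
        assert np.allclose(prof.frame("g").loc["pt"], [0, 0, 1, 0, 0])
        assert np.allclose(prof.frame("g").loc["uni"], [0.2] * 5)

    def test_zero_abundance_species_excluded(self):
        comm = pd.DataFrame({"a": [1.0, 2.0], "gone": [0.0, 0.0]}, index=["s1", "s2"])
        states = make_states({"g": [1, 2]})
        prof = utilization_profile(comm, states)
        assert prof.excluded == ["gone"]
        assert prof.active().species == ["a"]

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            community, states = random_profile_inputs(rng)
            prof = utilization_profile(community, states).active()
            assert np.allclose(prof.P.sum(axis=2), 1.0, atol=1e-12)


class TestLevinsAndPianka:
    def test_levins_analytic_values(self):
        prof = profile_from_matrix([
            [0.2, 0.2, 0.2, 0.2, 0.2],
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0, 0.0],
        ])
        B = levins_breadth(prof).B["g"]
        assert B.iloc[0] == pytest.approx(5.0, abs=1e-12)
        assert B.iloc[1] == pytest.approx(1.0, abs=1e-12)
        assert B.iloc[2] == pytest.approx(2.0, abs=1e-12)

    def test_pianka_analytic_values(self):
        prof = profile_from_matrix([
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.3, 0.7],
        ])
        O = pianka_overlap(prof).pairwise["g"]
        assert O.iloc[0, 1] == pytest.approx(0.5 / np.sqrt(0.5), abs=1e-6)
        assert O.iloc[0, 2] == pytest.approx(1.0, abs=1e-12)   # identical profiles
        assert O.iloc[0, 3] == pytest.approx(0.0, abs=1e-12)   # disjoint supports
        assert np.allclose(O, O.T)
        assert np.allclose(np.diag(O), 1.0)

    def test_single_species_overlap_rejected(self):
        prof = profile_from_matrix([[1.0, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="two species"):
            pianka_overlap(prof)

    def test_matches_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            community, states = random_profile_inputs(rng)
            prof = utilization_profile(community, states)
            breadth = levins_breadth(prof)
            overlap = pianka_overlap(prof)
            for g in ("g1", "g2"):
                P = brute_profile(community, states, g, R=5)
                bB = brute_levins(P)
                bO = brute_pianka(P)
                for sp in breadth.B.index:
                    assert breadth.B.loc[sp, g] == pytest.approx(bB[sp], abs=1e-12)
                for i in overlap.pairwise[g].index:
                    for k in overlap.pairwise[g].columns:
                        assert overlap.pairwise[g].loc[i, k] == pytest.approx(
                            bO[(i, k)], abs=1e-12
                        )

    def test_scale_invariance_of_one_species(self):
        rng = np.random.default_rng(5)
        community, states = random_profile_inputs(rng)
        base_b = levins_breadth(utilization_profile(community, states)).B
        base_o = pianka_overlap(utilization_profile(community, states)).pairwise["g1"]
        scaled = community.copy()
        scaled[scaled.columns[0]] *= 137.5
        b2 = levins_breadth(utilization_profile(scaled, states)).B
        o2 = pianka_overlap(utilization_profile(scaled, states)).pairwise["g1"]
        assert np.allclose(base_b, b2)
        assert np.allclose(base_o, o2)


class TestAggregation:
    def test_complete_overlap_totals(self):
        prof = profile_from_matrix([[0.5, 0.5, 0, 0, 0]] * 3)
        ov = pianka_overlap(prof)
        assert np.allclose(ov.totals["g"], 2.0)   # each overlaps 2 others fully
        assert ov.mean_r["g"] == pytest.approx(2.0)

    def test_constant_breadth_ranks_all_tied(self):
        prof = profile_from_matrix([[0.5, 0.5, 0, 0, 0]] * 4)
        br = levins_breadth(prof)
        assert (br.rank_s == 1).all()
        assert br.mean_s.unique() == pytest.approx(2.0)

    def test_toy_means(self):
        from ecozone.niche import NicheBreadthTable, _dense_rank_desc

        B = pd.DataFrame([[2.0, 4.0], [3.0, 1.0]], index=["a", "b"], columns=["g1", "g2"])
        br = NicheBreadthTable(
            B=B, mean_s=B.mean(axis=1), mean_r=B.mean(axis=0),
            rank_s=_dense_rank_desc(B.mean(axis=1)),
            rank_r=_dense_rank_desc(B.mean(axis=0)), R=5,
        )
        assert list(br.mean_s) == [3.0, 2.0]
        assert list(br.mean_r) == [2.5, 2.5]

    def test_report_layout(self):
        prof = profile_from_matrix([
            [0.2, 0.2, 0.2, 0.2, 0.2],
            [1.0, 0, 0, 0, 0],
            [0.5, 0.5, 0, 0, 0],
        ])
        rep_b, rep_o = aggregate_niche(levins_breadth(prof), pianka_overlap(prof))
        for rep in (rep_b, rep_o):
            assert "Mean-S" in rep.columns and "Rank" in rep.columns
            assert list(rep.index[-2:]) == ["MEAN-R", "RANK"]


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        res = breadth_overlap_regression(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_null_fit_constant_response(self):
        res = breadth_overlap_regression(np.arange(5.0), np.full(5, 2.0))
        assert res.slope == 0.0
        assert res.r2 == 0.0

    def test_three_point_closed_form(self):
        res = breadth_overlap_regression([1, 2, 3], [2, 3, 5])
        assert res.slope == pytest.approx(1.5, abs=1e-12)
        assert res.r2 == pytest.approx(27 / 28, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="[Zz]ero-variance"):
            breadth_overlap_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOnSyntheticData:
    def test_generalists_recover_larger_breadth(self):
        """Species planted with wider niches score higher Levins breadth."""
        rhos = []
        for seed in range(1, 21):
            ds = generate_dataset(SyntheticConfig(seed=seed))
            states = bin_resource_states(ds.environment)
            prof = utilization_profile(ds.community, states)
            br = levins_breadth(prof)
            true_width = ds.niche_truth["width"].loc[br.B.index].mean(axis=1)
            rhos.append(spearmanr(true_width, br.mean_s).statistic)
        assert np.mean(rhos) > 0
        assert min(rhos) > 0

    def test_site_features_cover_all_sites(self, default_dataset):
        ds = default_dataset
        states = bin_resource_states(ds.environment)
        prof = utilization_profile(ds.community, states)
        feats = site_niche_features(
            ds.community, levins_breadth(prof), pianka_overlap(prof)
        )
        assert list(feats.index) == list(ds.community.index)
        assert feats.notna().all().all()
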