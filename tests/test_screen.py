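import numpy as np
import pandas as pd
import pytest
from scipy import stats

from penescreen.cohort_io import Cohort

from penescreen.screen import (
    build_design, confirm_directions, empirical_q,
    match_controls, permutation_q, rank_normalize, run_step1, run_screen,
)
from conftest import make_null_traits


# ---------------------------------------------------------------------------
# rank-based inverse normal transform


class TestRankNormalize:
    def test_blom_offset_closed_form_n3(self):
        got = rank_normalize(np.array([1.0, 2.0, 3.0]))
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(got, expected)
        np.testing.assert_allclose(got, [-0.869424, 0.0, 0.869424], atol=1e-6)

    def test_moments_for_large_n(self, rng):
        out = rank_normalize(rng.exponential(size=1000))
        assert abs(out.mean()) < 0.01
        assert out.std() == pytest.approx(1.0, abs=0.05)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(rank_normalize(x),
                                   rank_normalize(np.exp(3 * x)))

    def test_ties_get_average_rank_and_missing_preserved(self):
        s = pd.Series([1.0, 1.0, 2.0, np.nan])
        out = rank_normalize(s)
        assert out.iloc[0] == out.iloc[1] < 0
        assert np.isnan(out.iloc[3])

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            rank_normalize(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError, match="2 non-missing"):
            rank_normalize(np.array([1.0, np.nan]))


# ---------------------------------------------------------------------------
# empirical q-values


class TestEmpiricalQ:
    def test_rank_one_with_clean_null_gives_one_over_b(self):
        p_obs = np.array([1e-6, 0.5, 0.9])
        pool = np.linspace(0.01, 1, 3000)  # no permuted p below 1e-6
        q = empirical_q(p_obs, pool, B=1000)
        assert q[0] == pytest.approx(1 / 1000)

    def test_all_observed_one_gives_q_one(self):
        q = empirical_q(np.ones(5), np.linspace(0.001, 1, 500), B=100)
        np.testing.assert_allclose(q, 1.0)

    def test_monotone_nondecreasing_in_p(self, rng):
        p_obs = rng.uniform(size=40)
        pool = rng.uniform(size=4000)
        q = empirical_q(p_obs, pool, B=100)
        order = np.argsort(p_obs)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


# ---------------------------------------------------------------------------
# step 1 + permutations


def _null_cohort_design(paper_like, rng, n_traits):
    res, groups, kin = paper_like
    cohort = res.cohort
    traits = make_null_traits(cohort, n_traits, rng)
    null_cohort = Cohort(participants=cohort.participants, traits=traits,
                         flags=cohort.flags, pedigree=cohort.pedigree)
    sel = groups["group"].isin(["asymptomatic_carrier",
                                "asymptomatic_noncarrier"])
    ids = groups.index[sel]
    part = cohort.participants.loc[ids]
    covars = pd.DataFrame({"age": part["age"], "age2": part["age"] ** 2,
                           "sex": (part["sex"] == "female").astype(float)},
                          index=ids)
    outcome = (groups.loc[ids, "group"] == "asymptomatic_carrier").astype(float)
    return null_cohort, build_design(covars, outcome, kin)


class TestStep1:
    def test_null_traits_give_uniform_p(self, paper_like, rng):
        cohort, design = _null_cohort_design(paper_like, rng, 500)
        mask = np.isfinite(design.X).all(axis=1)
        eig, Xm = design.eigen_for(mask)
        Y = cohort.traits.loc[design.ids].to_numpy()[mask]
        from penescreen.kinship import fit_lmm_batch
        _b, _s, p, _g = fit_lmm_batch(Y, Xm, eig)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_trait_equal_to_outcome_is_extreme(self, paper_like):
        res, groups, kin = paper_like
        cohort = res.cohort
        outcome01 = (groups["group"] == "asymptomatic_carrier").astype(float)
        traits = pd.DataFrame({"copy_v1": outcome01}, index=cohort.traits.index)
        c2 = Cohort(participants=cohort.participants, traits=traits,
                    flags=cohort.flags, pedigree=cohort.pedigree)
        out = run_step1(c2, groups, kin, traits=["copy"])
        assert out.loc["copy", "p"] < 1e-100

    def test_no_variance_trait_skipped(self, paper_like):
        res, groups, kin = paper_like
        cohort = res.cohort
        traits = pd.DataFrame({"flat_v1": np.ones(cohort.n()),
                               "ok_v1": np.arange(cohort.n(), dtype=float)},
                              index=cohort.traits.index)
        c2 = Cohort(participants=cohort.participants, traits=traits,
                    flags=cohort.flags, pedigree=cohort.pedigree)
        with pytest.warns(UserWarning, match="flat"):
            out = run_step1(c2, groups, kin, traits=["flat", "ok"])
        assert list(out.index) == ["ok"]


class TestPermutationQ:
    def test_bit_reproducible_and_order_invariant(self, paper_like, rng):
        cohort, design = _null_cohort_design(paper_like, rng, 6)
        traits = [c[:-3] for c in cohort.traits.columns]
        s1 = run_step1(cohort, None, None, traits=traits, design=design)
        q_a = permutation_q(cohort, design, traits, B=100, seed=5, step1=s1)
        q_b = permutation_q(cohort, design, traits, B=100, seed=5, step1=s1)
        pd.testing.assert_frame_equal(q_a, q_b)
        shuffled = traits[::-1]
        q_c = permutation_q(cohort, design, shuffled, B=100, seed=5,
                            step1=s1.loc[[t for t in s1.index]])
        np.testing.assert_allclose(q_a["q"].sort_index(),
                                   q_c["q"].sort_index())

    def test_requires_minimum_permutations(self, paper_like, rng):
        cohort, design = _null_cohort_design(paper_like, rng, 2)
        with pytest.raises(ValueError, match="at least 100"):
            permutation_q(cohort, design, ["null000"], B=10, seed=0)


# ---------------------------------------------------------------------------
# direction confirmation


class TestConfirmDirections:
    @staticmethod
    def _inject(paper_like, shift_groups, name="inj"):
        res, groups, kin = paper_like
        cohort = res.cohort
        rng = np.random.default_rng(99)
        vals = rng.normal(100, 10, cohort.n())
        for g, delta in shift_groups.items():
            vals[(groups["group"] == g).to_numpy()] += delta
        traits = pd.DataFrame({f"{name}_v1": vals}, index=cohort.traits.index)
        c2 = Cohort(participants=cohort.participants, traits=traits,
                    flags=cohort.flags, pedigree=cohort.pedigree)
        s1 = run_step1(c2, groups, kin, traits=[name])
        return confirm_directions(s1, c2, groups, kin)

    def test_protective_pattern_confirmed(self, paper_like):
        out = self._inject(paper_like, {"asymptomatic_carrier": -8.0})
        assert out.loc["inj", "verdict"] == "confirmed"

    def test_direct_variant_effect_not_confirmed(self, paper_like):
        out = self._inject(paper_like, {"asymptomatic_carrier": -8.0,
                                        "symptomatic_carrier": -8.0})
        assert out.loc["inj", "verdict"] == "not_confirmed"

    def test_zero_effect_never_confirmed_with_tiny_groups(self, paper_like):
        res, groups, kin = paper_like
        shrunk = groups.copy()
        sympt = shrunk.index[shrunk["group"] == "symptomatic_carrier"]
        shrunk.loc[sympt[1:], "group"] = "dropped"
        cohort = res.cohort
        s1 = run_step1(cohort, shrunk, kin, traits=["QRS"])
        out = confirm_directions(s1, cohort, shrunk, kin)
        assert out.loc["QRS", "verdict"] == "untestable"

    def test_no_hits_raises(self, paper_like):
        res, groups, kin = paper_like
        with pytest.raises(ValueError, match="no step-1 hits"):
            confirm_directions(pd.DataFrame(), res.cohort, groups, kin)


# ---------------------------------------------------------------------------
# matched controls


class TestMatchControls:
    @staticmethod
    def _frame(n, rng, sex=None):
        return pd.DataFrame({
            "age": rng.uniform(20, 70, n),
            "sex": sex if sex is not None
            else rng.choice(["male", "female"], n),
        }, index=pd.Index([f"x{i:04d}" for i in range(n)]))

    def test_48_cases_get_192_same_sex_controls(self, rng):
        cases = self._frame(48, rng)
        pool = self._frame(2000, rng)
        pool.index = "p" + pool.index
        chosen = match_controls(cases, pool, ratio=4)
        assert len(chosen) == 192 == len(set(chosen))
        counts = pool.loc[chosen, "sex"].value_counts()
        for sex, grp in cases.groupby("sex"):
            assert counts[sex] == 4 * len(grp)

    def test_exact_age_duplicates_preferred(self, rng):
        cases = pd.DataFrame({"age": [40.0], "sex": ["male"]}, index=["c1"])
        pool = pd.DataFrame({"age": [40.0, 40.0, 40.0, 40.0, 41.0, 39.0],
                             "sex": ["male"] * 6},
                            index=[f"p{i}" for i in range(6)])
        chosen = match_controls(cases, pool, ratio=4)
        assert set(chosen) == {"p0", "p1", "p2", "p3"}

    def test_matched_mean_age_close(self, rng):
        cases = self._frame(40, rng)
        pool = self._frame(4000, rng)
        pool.index = "p" + pool.index
        chosen = match_controls(cases, pool, ratio=4)
        assert abs(pool.loc[chosen, "age"].mean() - cases["age"].mean()) < 1.0

    def test_insufficient_pool_lists_shortfall(self, rng):
        cases = self._frame(10, rng, sex=["female"] * 10)
        pool = self._frame(20, rng, sex=["female"] * 20)
        with pytest.raises(ValueError, match="female: need 40, have 20"):
            match_controls(cases, pool, ratio=4)


def test_full_screen_recovers_and_confirms_injected_traits(paper_like):
    """End-to-end: the default generator injects HR +6.41, QRS −5.7 and
    lnSDNN −0.216 into asymptomatic carriers only; one screen run at B=200
    should flag them at q ≤ 0.05 and confirm the direction pattern."""
    res, groups, kin = paper_like
    out = run_screen(res.cohort, groups, kin, B=200, seed=42,
                     sensitivity=True)
    for t in ("HR", "QRS", "lnSDNN"):
        assert t in out.hits
        assert out.step2.loc[t, "verdict"] == "confirmed"
        # sensitivity betas agree in sign with the primary analysis
        assert (np.sign(out.sensitivity_rank.loc[t, "beta"])
                == np.sign(out.step1.loc[t, "beta"]))
        assert (np.sign(out.sensitivity_matched.loc[t, "beta"])
                == np.sign(out.step1.loc[t, "beta"]))
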