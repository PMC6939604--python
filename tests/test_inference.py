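"""Partial correlations, Fisher comparisons, MANCOVA and regressions."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cptddm import (
    fisher_compare,
    hierarchical_stepwise_regression,
    interaction_regression,
    mancova_pillai,
    partial_correlation,
)
from cptddm.inference import AnalysisError, age_adjusted_means


def _synthetic_analysis_frame(n=64, seed=0, coupled="v"):
    """Cohort-shaped frame whose inattention tracks one measure."""
    rng = np.random.default_rng(seed)
    group = np.repeat(["VP", "term"], [n - n // 2, n // 2])
    age = rng.normal(9.4, 1.0, n)
    frame = pd.DataFrame(
        {
            "group": group,
            "age_years": age,
            "hit_rate_pct": rng.normal(86, 8, n),
            "sdrt_ms": rng.normal(168, 40, n),
            "v": rng.normal(0.2, 0.09, n),
        }
    )
    signal = (frame[coupled] - frame[coupled].mean()) / frame[coupled].std()
    frame["swan_inattention"] = -6 * signal + rng.normal(0, 6, n)
    return frame


class TestPartialCorrelation:
    def test_no_controls_reduces_to_pearson(self, rng):
        x = rng.normal(size=50)
        y = x * 0.5 + rng.normal(size=50)
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.k == 0

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=30)
        assert partial_correlation(x, x).r == pytest.approx(1.0)

    def test_common_cause_partialed_out(self, rng):
        """x = z + e1, y = z + e2: controlling z leaves ~0 correlation,
        and the residual r matches the textbook recursion exactly."""
        n = 10_000
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = z + rng.normal(size=n)
        res = partial_correlation(x, y, z)
        assert abs(res.r) < 3 / math.sqrt(n)
        r_xy = sps.pearsonr(x, y)[0]
        r_xz = sps.pearsonr(x, z)[0]
        r_yz = sps.pearsonr(y, z)[0]
        closed = (r_xy - r_xz * r_yz) / math.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2)
        )
        assert res.r == pytest.approx(closed, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        frame = pd.DataFrame(
            {
                "x": rng.normal(size=40),
                "y": rng.normal(size=40),
                "z": rng.normal(size=40),
            }
        )
        frame["y"] += 0.6 * frame["x"] + 0.4 * frame["z"]
        res = partial_correlation(frame["x"], frame["y"], frame["z"])
        ref = pingouin.partial_corr(frame, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)
        assert res.n == int(ref["n"].iloc[0])

    def test_degenerate_inputs_rejected(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(AnalysisError):
            partial_correlation(z, np.zeros(20))
        with pytest.raises(AnalysisError):
            partial_correlation(z[:5], z[:5], np.column_stack([z[:5]] * 3))


class TestFisherCompare:
    def test_equal_correlations_give_zero(self):
        assert fisher_compare(0.4, 30, 0.4, 50).z == 0.0

    def test_antisymmetry(self):
        a = fisher_compare(-0.369, 33, -0.418, 31)
        b = fisher_compare(-0.418, 31, -0.369, 33)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_formula_against_direct_computation(self):
        r1, n1, r2, n2 = 0.3, 28, -0.2, 41
        res = fisher_compare(r1, n1, r2, n2)
        z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / 25 + 1 / 38)
        assert res.z == pytest.approx(z, abs=1e-12)
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(AnalysisError):
            fisher_compare(1.0, 30, 0.2, 30)


class TestMancova:
    def _frame(self, n=65, p_out=7, seed=3):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            {
                "group": np.repeat(["VP", "term"], [n - n // 2, n // 2]),
                "age_years": rng.normal(9.4, 1.0, n),
            }
        )
        for j in range(p_out):
            frame[f"y{j}"] = rng.normal(size=n)
        return frame

    def test_df_identity_for_single_df_effects(self):
        frame = self._frame(n=65, p_out=7)
        res = mancova_pillai(frame, [f"y{j}" for j in range(7)])
        for effect in ("group", "age_years"):
            row = res.effect(effect)
            assert (row["df1"], row["df2"]) == (7, 56)
        assert res.n == 65

    def test_single_outcome_reduces_to_univariate_ancova(self):
        import statsmodels.api as sm

        frame = self._frame(n=40, p_out=1, seed=5)
        res = mancova_pillai(frame, ["y0"])
        g = (frame["group"] == "term").astype(float)
        X = sm.add_constant(
            pd.DataFrame({"g": g, "age_years": frame["age_years"]})
        )
        fit = sm.OLS(frame["y0"], X).fit()
        row = res.effect("group")
        V = row["pillai"]
        f_from_pillai = V / (1 - V) * row["df2"] / row["df1"]
        assert f_from_pillai == pytest.approx(fit.tvalues["g"] ** 2, rel=1e-9)

    def test_pillai_matches_direct_eigen_computation(self):
        """Brute-force oracle: V = tr(H (H+E)^-1) from explicit matrices."""
        frame = self._frame(n=20, p_out=3, seed=9)
        outcomes = ["y0", "y1", "y2"]
        res = mancova_pillai(frame, outcomes)

        g = (frame["group"] == "term").to_numpy(float)
        X = np.column_stack([np.ones(20), g, frame["age_years"]])
        Y = frame[outcomes].to_numpy()
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        E = (Y - X @ B).T @ (Y - X @ B)
        for effect, idx in (("group", 1), ("age_years", 2)):
            L = np.zeros((1, 3))
            L[0, idx] = 1
            H = (L @ B).T @ np.linalg.inv(
                L @ np.linalg.inv(X.T @ X) @ L.T
            ) @ (L @ B)
            V = np.trace(H @ np.linalg.inv(H + E))
            assert res.effect(effect)["pillai"] == pytest.approx(V, abs=1e-10)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        frame = self._frame(n=50, p_out=4, seed=13)
        outcomes = [f"y{j}" for j in range(4)]
        res = mancova_pillai(frame, outcomes)
        frame = frame.copy()
        frame["g"] = (frame["group"] == "term").astype(float)
        mv = MANOVA.from_formula(
            " + ".join(outcomes) + " ~ g + age_years", data=frame
        ).mv_test()
        ref = mv.results["g"]["stat"].loc["Pillai's trace"]
        row = res.effect("group")
        assert row["pillai"] == pytest.approx(float(ref["Value"]), abs=1e-10)
        assert row["F"] == pytest.approx(float(ref["F Value"]), rel=1e-9)
        assert row["p"] == pytest.approx(float(ref["Pr > F"]), abs=1e-10)


class TestStepwiseRegression:
    def test_df_identities_at_reference_sample_size(self):
        frame = _synthetic_analysis_frame(n=64, seed=1)
        models = hierarchical_stepwise_regression(frame)
        assert (models[0].df1, models[0].df2) == (2, 61)
        assert len(models) > 1, "the coupled measure should enter"
        assert (models[1].df1, models[1].df2) == (3, 60)
        assert models[1].delta_r2 >= 0
        assert models[1].n == 64

    def test_orthogonal_candidate_never_entered(self, rng):
        frame = _synthetic_analysis_frame(n=64, seed=2, coupled="v")
        frame["noise"] = rng.normal(size=64)
        models = hierarchical_stepwise_regression(
            frame, candidates=["v", "noise"]
        )
        entered = {p for m in models for p in m.predictors}
        assert "noise" not in entered

    def test_matches_independent_greedy_selection(self):
        """The entered set equals an independent greedy partial-F search
        recomputed from R-squared increments (numpy only)."""
        frame = _synthetic_analysis_frame(n=64, seed=11)
        candidates = ["hit_rate_pct", "sdrt_ms", "v"]
        models = hierarchical_stepwise_regression(frame, candidates=candidates)
        stepwise_set = set(models[-1].predictors) - {"group", "age_years"}

        work = frame.dropna().copy()
        work["group"] = (work["group"] == "VP").astype(float)
        y = work["swan_inattention"].to_numpy()

        def r2_of(cols):
            X = np.column_stack(
                [np.ones(len(work))] + [work[c].to_numpy() for c in cols]
            )
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            tss = ((y - y.mean()) ** 2).sum()
            return 1 - (resid**2).sum() / tss

        forced = ["group", "age_years"]
        entered: list[str] = []
        while True:
            base = r2_of(forced + entered)
            best, best_p = None, 1.0
            for c in candidates:
                if c in entered:
                    continue
                full = r2_of(forced + entered + [c])
                df2 = len(work) - len(forced + entered + [c]) - 1
                F = (full - base) / ((1 - full) / df2)
                p = sps.f.sf(F, 1, df2)
                if p < best_p:
                    best, best_p = c, p
            if best is not None and best_p <= 0.05:
                entered.append(best)
            else:
                break
            # removal pass at p >= .10
            while entered:
                full = r2_of(forced + entered)
                worst, worst_p = None, 0.0
                for c in entered:
                    reduced = r2_of(forced + [e for e in entered if e != c])
                    df2 = len(work) - len(forced + entered) - 1
                    F = (full - reduced) / ((1 - full) / df2)
                    p = sps.f.sf(F, 1, df2)
                    if p > worst_p:
                        worst, worst_p = c, p
                if worst_p >= 0.10:
                    entered.remove(worst)
                else:
                    break
        assert stepwise_set == set(entered)

    def test_standardized_betas_match_zscored_fit(self):
        import statsmodels.api as sm

        frame = _synthetic_analysis_frame(n=64, seed=4)
        models = hierarchical_stepwise_regression(frame)
        final = models[-1]
        work = frame.dropna().copy()
        work["group"] = (work["group"] == "VP").astype(float)
        zs = (work - work.mean()) / work.std(ddof=1)
        fit = sm.OLS(
            zs["swan_inattention"], sm.add_constant(zs[final.predictors])
        ).fit()
        for pred in final.predictors:
            assert final.beta[pred] == pytest.approx(fit.params[pred], abs=1e-10)

    def test_collinear_design_names_offenders(self):
        frame = _synthetic_analysis_frame(n=64, seed=6)
        frame["dup"] = frame["v"]
        with pytest.raises(AnalysisError, match="dup|v"):
            hierarchical_stepwise_regression(frame, candidates=["v", "dup"])


class TestInteractionRegression:
    def test_step1_equals_stepwise_model1(self):
        frame = _synthetic_analysis_frame(n=64, seed=8)
        stepwise = hierarchical_stepwise_regression(frame)
        inter = interaction_regression(frame)
        assert inter[0].r2 == pytest.approx(stepwise[0].r2, abs=1e-12)
        assert inter[0].f == pytest.approx(stepwise[0].f, abs=1e-9)

    def test_delta_r2_invariant_to_measure_shifts(self):
        frame = _synthetic_analysis_frame(n=64, seed=9)
        base = interaction_regression(frame)
        shifted = frame.copy()
        for c in ("hit_rate_pct", "sdrt_ms", "v"):
            shifted[c] = shifted[c] + 1000.0
        moved = interaction_regression(shifted)
        assert moved[2].delta_r2 == pytest.approx(base[2].delta_r2, abs=1e-10)

    def test_no_interaction_under_group_homogeneous_slopes(self):
        """Same slope in both groups: the interaction block adds ~nothing."""
        rng = np.random.default_rng(12)
        n = 5000
        frame = pd.DataFrame(
            {
                "group": np.repeat(["VP", "term"], n // 2),
                "age_years": rng.normal(9.4, 1.0, n),
                "hit_rate_pct": rng.normal(86, 8, n),
                "sdrt_ms": rng.normal(168, 40, n),
                "v": rng.normal(0.2, 0.09, n),
            }
        )
        frame["swan_inattention"] = (
            -50 * frame["v"] + rng.normal(0, 8, n)
        )
        inter = interaction_regression(frame)
        assert inter[2].delta_r2 < 0.002
        assert inter[2].delta_p > 0.01

    def test_nested_r2_never_decreases(self):
        frame = _synthetic_analysis_frame(n=64, seed=10)
        inter = interaction_regression(frame)
        assert inter[0].r2 <= inter[1].r2 + 1e-12
        assert inter[1].r2 <= inter[2].r2 + 1e-12


class TestAdjustedMeans:
    def test_balanced_covariate_recovers_group_means(self, rng):
        n = 200
        frame = pd.DataFrame(
            {
                "group": np.tile(["VP", "term"], n // 2),
                "age_years": np.tile(rng.normal(9.4, 1.0, n // 2), 2),
            }
        )
        frame["y"] = np.where(frame["group"] == "VP", 10.0, 12.0)
        table = age_adjusted_means(frame, ["y"])
        for _, row in table.iterrows():
            expected = 10.0 if row["group"] == "VP" else 12.0
            assert row["adjusted_mean"] == pytest.approx(expected, abs=1e-9)
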