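"""ANOVA, K-S normality, Pearson matrix and Mantel test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from limnoindex import (DegenerateInputError, DomainError, ks_normality,
                        mantel_screen, mantel_test, one_way_anova,
                        pearson_matrix)
from limnoindex import reference


def brute_force_anova(groups):
    """Independent oracle: explicit sums over group means, plain Python."""
    obs = [float(x) for g in groups for x in g]
    grand = sum(obs) / len(obs)
    ssb = ssw = 0.0
    for g in groups:
        mean = sum(g) / len(g)
        ssb += len(g) * (mean - grand) ** 2
        for x in g:
            ssw += (x - mean) ** 2
    dfb = len(groups) - 1
    dfw = len(obs) - len(groups)
    return ssb, ssw, (ssb / dfb) / (ssw / dfw)


class TestAnova:
    def test_seasonal_tli_table(self):
        groups = [reference.tli_by_season().loc[s].to_numpy()
                  for s in ("April", "July", "October")]
        t = one_way_anova(groups)
        assert t.F == pytest.approx(8.4604, abs=5e-5)
        assert t.p == pytest.approx(0.002569, abs=5e-6)
        assert t.ss_between == pytest.approx(734.1882, abs=5e-4)
        assert (t.df_between, t.df_within) == (2, 18)
        assert t.f_crit == pytest.approx(3.5546, abs=5e-4)

    def test_layer_wqi_table(self):
        groups = [reference.wqi_by_layer().loc[l].to_numpy()
                  for l in ("upper", "middle", "lower")]
        t = one_way_anova(groups)
        assert t.F == pytest.approx(0.115154, abs=5e-6)

    def test_identical_groups_give_zero_f(self):
        t = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert t.F == pytest.approx(0.0)
        assert t.p == pytest.approx(1.0)

    def test_matches_bruteforce_and_scipy_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(), 1, rng.integers(2, 8))
                      for _ in range(k)]
            t = one_way_anova(groups)
            ssb, ssw, f = brute_force_anova(groups)
            assert t.ss_between == pytest.approx(ssb, rel=1e-9)
            assert t.ss_within == pytest.approx(ssw, rel=1e-9)
            assert t.F == pytest.approx(f, rel=1e-9)
            scipy_res = sps.f_oneway(*groups)
            assert t.F == pytest.approx(scipy_res.statistic, rel=1e-9)
            assert t.p == pytest.approx(scipy_res.pvalue, rel=1e-9)

    def test_invariance_to_shift_and_scale(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(i, 1, 6) for i in range(3)]
        f0 = one_way_anova(groups).F
        assert one_way_anova([g + 100 for g in groups]).F == pytest.approx(f0, rel=1e-9)
        assert one_way_anova([g * 3.5 for g in groups]).F == pytest.approx(f0, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(DegenerateInputError):
            one_way_anova([[1], [2, 3]])
        with pytest.raises(DegenerateInputError, match="zero within-group"):
            one_way_anova([[1, 1], [2, 2]])

    def test_table_layout(self):
        frame = one_way_anova([[1, 2, 3], [2, 3, 5]]).to_frame()
        assert list(frame.columns) == ["Source of Variation", "SS", "df", "MS",
                                       "F", "P-value", "F crit"]
        assert frame["SS"].iloc[2] == pytest.approx(frame["SS"].iloc[:2].sum())


class TestKsNormality:
    def test_normal_sample_passes(self):
        passes = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(3, 2, 1000)
            passes += ks_normality(x).passed
        assert passes >= 45

    def test_skewed_sample_fails(self):
        x = np.exp(np.random.default_rng(0).normal(0, 1.5, 1000))
        assert not ks_normality(x).passed
        assert not ks_normality(x, lilliefors=True).passed

    def test_too_small_or_constant(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            ks_normality([2.0] * 10)


class TestPearsonMatrix:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        r, p = pearson_matrix(pd.DataFrame({"a": x, "b": x, "c": -x}))
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(r) == 1).all()
        np.testing.assert_allclose(r, r.T)

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(1000, 8)))
        r, _ = pearson_matrix(X)
        off = r.to_numpy()[np.triu_indices(8, 1)]
        assert (np.abs(off) < 0.1).mean() >= 0.95

    def test_pairwise_complete_and_zero_variance_flagged(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4, np.nan], "b": [2, 4, 6, 8, 10],
                          "c": [5, 5, 5, 5, 5]})
        r, p = pearson_matrix(X)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(r.loc["a", "c"]) and np.isnan(p.loc["b", "c"])


def _random_distance_matrix(rng, n=10, d=3):
    pts = rng.normal(size=(n, d))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return D


class TestMantel:
    def test_identity_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        A = _random_distance_matrix(rng)
        assert mantel_test(A, A).r == pytest.approx(1.0)
        assert mantel_test(A, 2 * A).r == pytest.approx(1.0)

    def test_r_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel
        rng = np.random.default_rng(4)
        A = _random_distance_matrix(rng, n=12)
        B = _random_distance_matrix(rng, n=12)
        ours = mantel_test(A, B, n_permutations=999, seed=0)
        theirs = skbio_mantel(DistanceMatrix(A), DistanceMatrix(B),
                              permutations=999, alternative="greater")
        assert ours.r == pytest.approx(theirs[0], rel=1e-9)
        # permutation p-values agree to sampling noise
        assert ours.p == pytest.approx(theirs[1], abs=0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        A = _random_distance_matrix(rng)
        B = _random_distance_matrix(rng)
        r1 = mantel_test(A, B, seed=11)
        r2 = mantel_test(A, B, seed=11)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_p_resolution(self):
        rng = np.random.default_rng(6)
        A = _random_distance_matrix(rng)
        B = _random_distance_matrix(rng)
        res = mantel_test(A, B, n_permutations=99, seed=0)
        assert res.p >= 1 / 100
        assert round(res.p * 100, 9) == int(round(res.p * 100))

    def test_shape_errors(self):
        rng = np.random.default_rng(7)
        A = _random_distance_matrix(rng, n=6)
        with pytest.raises(DomainError, match="symmetric"):
            mantel_test(A + np.triu(np.ones((6, 6)), 1), A)
        with pytest.raises(DomainError, match="mismatch"):
            mantel_test(A, _random_distance_matrix(rng, n=7))


class TestMantelScreen:
    def test_driving_parameter_has_largest_r(self):
        # index built from TP alone: TP must dominate the screen
        rng = np.random.default_rng(8)
        n = 30
        frame = pd.DataFrame({
            "site_id": [f"S{i}" for i in range(n)],
            "season": ["dry"] * n, "layer": ["upper"] * n,
            "TP_mgL": rng.lognormal(-3, 0.5, n),
            "TN_mgL": rng.lognormal(1, 0.3, n),
            "CODMn_mgL": rng.lognormal(0.7, 0.3, n),
        })
        indices = pd.DataFrame({"WQI": 2000 * frame["TP_mgL"],
                                "TLI": 500 * frame["TP_mgL"]})
        out = mantel_screen(frame, indices, parameters=["TP", "TN", "CODMn"],
                            n_permutations=99, seed=0)
        best = out.loc[out["r_wqi"].idxmax(), "parameter"]
        assert best == "TP"
        assert out.loc[out["parameter"] == "TP", "p_tli"].iloc[0] <= 0.05

    def test_duplicated_parameter_gives_identical_rows(self, survey):
        frame = survey.frame.copy()
        indices = pd.DataFrame({"WQI": frame["TP_mgL"] * 100})
        a = mantel_screen(frame, indices, parameters=["TP"],
                          n_permutations=99, seed=3)
        frame["TP2"] = frame["TP_mgL"]  # falls back to the literal column name
        b = mantel_screen(frame, indices, parameters=["TP2"],
                          n_permutations=99, seed=3)
        assert a["r_wqi"].iloc[0] == b["r_wqi"].iloc[0]
        assert a["p_wqi"].iloc[0] == b["p_wqi"].iloc[0]
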