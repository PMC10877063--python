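"""Environmental transforms, collinearity, group tests, geography, PCNM."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from _oracles import bf_kruskal
from edaphonet.env_spatial import (
    EnvMatrix,
    geodesic_distance_matrix,
    kruskal_wallis,
    pairwise_wilcoxon,
    pcnm,
    pearson_matrix,
    select_pcnms,
    stepwise_lm,
    transform_env,
    vif_stepwise,
    EARTH_RADIUS_M,
)


def _env_from(df: pd.DataFrame) -> EnvMatrix:
    scaled = (df - df.mean()) / df.std(ddof=1)
    return EnvMatrix(scaled, {c: "none" for c in df.columns})


class TestTransformEnv:
    def test_standard_normal_column_scaled(self, rng):
        meta = pd.DataFrame({"pH": rng.normal(7, 0.5, 200)})
        env = transform_env(meta, scheme={"pH": "none"})
        assert env.values["pH"].mean() == pytest.approx(0, abs=1e-9)
        assert env.values["pH"].std(ddof=1) == pytest.approx(1, abs=1e-9)
        assert abs(env.diagnostics.loc["pH", "skew_before"]) < 0.5

    def test_log_reduces_lognormal_skewness(self, rng):
        meta = pd.DataFrame({"TOC": np.exp(rng.normal(0, 1, 300))})
        env = transform_env(meta, scheme={"TOC": "log"})
        d = env.diagnostics.loc["TOC"]
        assert abs(d["skew_after"]) < abs(d["skew_before"])

    def test_log_of_zero_with_offset_and_without(self, rng):
        vals = np.concatenate([[0.0], np.exp(rng.normal(0, 1, 50))])
        meta = pd.DataFrame({"N_NO3": vals})
        env = transform_env(meta, scheme={"N_NO3": "log"})
        assert np.isfinite(env.values["N_NO3"]).all()
        with pytest.raises(ValueError, match="N_NO3"):
            transform_env(meta, scheme={"N_NO3": "log"}, log_offset=None)

    def test_sqrt_of_negative_errors(self):
        meta = pd.DataFrame({"P_PO4": [-1.0, 2.0]})
        with pytest.raises(ValueError, match="P_PO4"):
            transform_env(meta, scheme={"P_PO4": "sqrt"})

    def test_constant_column_flagged_not_scaled(self):
        meta = pd.DataFrame({"pH": [7.0, 7.0, 7.0]})
        env = transform_env(meta, scheme={"pH": "none"})
        assert env.constant_variables == ["pH"]


class TestCollinearity:
    def test_orthogonal_predictors_all_vif_one(self):
        from scipy.linalg import hadamard

        # non-constant Hadamard columns: exactly orthogonal, n > p + 1
        x = pd.DataFrame(hadamard(8)[:, 1:5].astype(float),
                         columns=list("abcd"))
        retained, trace = vif_stepwise(_env_from(x))
        assert retained == list("abcd")
        assert np.allclose(trace[-1].to_numpy(), 1.0, atol=1e-8)

    def test_pairwise_r08_closed_form(self, rng):
        # construct two columns with exact sample correlation 0.8
        n = 50
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std(ddof=1)
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std(ddof=1)
        x = pd.DataFrame({"u": a, "v": 0.8 * a + 0.6 * b})
        _, trace = vif_stepwise(_env_from(x))
        assert trace[0]["u"] == pytest.approx(1.0 / (1 - 0.64), rel=1e-9)

    def test_exact_linear_combination_removed_first(self, rng):
        x1, x2 = rng.standard_normal(30), rng.standard_normal(30)
        x = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        retained, trace = vif_stepwise(_env_from(x))
        assert len(retained) == 2
        assert np.isinf(trace[0].max())

    def test_vif_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = pd.DataFrame(rng.standard_normal((40, 5)),
                         columns=list("abcde"))
        x["e"] = x["a"] * 0.9 + rng.standard_normal(40) * 0.4
        env = _env_from(x)
        _, trace = vif_stepwise(env, threshold=np.inf)
        for var in x.columns:
            others = [c for c in x.columns if c != var]
            r2 = sm.OLS(
                env.values[var], sm.add_constant(env.values[others])
            ).fit().rsquared
            assert trace[0][var] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_pearson_matrix_symmetric_unit_diagonal(self, rng):
        x = pd.DataFrame(rng.standard_normal((20, 4)))
        r = pearson_matrix(_env_from(x))
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)


class TestGroupTests:
    def test_hand_computed_h(self):
        h, p = kruskal_wallis([1, 2, 3, 4], ["g1", "g1", "g2", "g2"])
        assert h == pytest.approx(2.4)
        assert p == pytest.approx(sps.chi2.sf(2.4, 1))

    def test_identical_groups_h_zero(self):
        h, _ = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert h == 0.0

    def test_matches_bruteforce_rank_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            values = rng.integers(0, 10, n).astype(float)  # forces ties
            groups = rng.choice(["a", "b", "c"], n)
            if len(set(groups)) < 2:
                continue
            h, _ = kruskal_wallis(values, groups)
            if np.ptp(values) == 0:
                assert h == 0.0
            else:
                assert h == pytest.approx(bf_kruskal(values, groups))

    def test_two_group_h_equals_squared_normal_wilcoxon(self, rng):
        """Asymptotic identity: k=2 KW H = z^2 of the rank-sum statistic."""
        x = rng.standard_normal(40)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        h, _ = kruskal_wallis(x, groups)
        n1 = n2 = 20
        ranks = sps.rankdata(x)
        w = ranks[groups == "a"].sum()
        z = (w - n1 * (n1 + n2 + 1) / 2) / np.sqrt(
            n1 * n2 * (n1 + n2 + 1) / 12
        )
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_pairwise_wilcoxon_bonferroni_caps_at_one(self, rng):
        values = rng.standard_normal(30)
        groups = np.array(["a", "b", "c"] * 10)
        out = pairwise_wilcoxon(values, groups)
        off = out.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all((off > 0) & (off <= 1))
        raw = sps.mannwhitneyu(
            values[groups == "a"], values[groups == "b"],
            alternative="two-sided",
        ).pvalue
        assert out.loc["a", "b"] == pytest.approx(min(1.0, raw * 3))

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(300):
            vals = rng.standard_normal(24)
            groups = np.repeat(["a", "b", "c", "d"], 6)
            pvals.append(kruskal_wallis(vals, groups)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestGeodesic:
    def test_identical_points_zero(self):
        coords = pd.DataFrame(
            {"latitude": [10.0, 10.0], "longitude": [20.0, 20.0]}
        )
        d = geodesic_distance_matrix(coords)
        assert np.allclose(d, 0.0)

    def test_antipodal_half_circumference(self):
        coords = pd.DataFrame(
            {"latitude": [0.0, 0.0], "longitude": [0.0, 180.0]}
        )
        d = geodesic_distance_matrix(coords)
        assert d.iloc[0, 1] == pytest.approx(np.pi * EARTH_RADIUS_M)

    def test_matches_spherical_law_of_cosines(self):
        coords = pd.DataFrame(
            {"latitude": [0.0, 0.0], "longitude": [0.0, 1.0]}
        )
        d = geodesic_distance_matrix(coords)
        lat1 = lat2 = 0.0
        dlon = np.radians(1.0)
        expected = EARTH_RADIUS_M * np.arccos(
            np.sin(lat1) * np.sin(lat2)
            + np.cos(lat1) * np.cos(lat2) * np.cos(dlon)
        )
        assert abs(d.iloc[0, 1] - expected) < 1e-3  # < 1 mm

    def test_out_of_range_rejected(self):
        coords = pd.DataFrame({"latitude": [95.0], "longitude": [0.0]})
        with pytest.raises(ValueError, match="latitude"):
            geodesic_distance_matrix(coords)


class TestPcnm:
    @staticmethod
    def _transect(n=20, step=1000.0):
        lat = -72.0 + np.arange(n) * step / 111_195.0
        return pd.DataFrame(
            {"latitude": lat, "longitude": np.full(n, 23.0)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_basis_orthogonal_and_centered(self):
        d = geodesic_distance_matrix(self._transect())
        basis = pcnm(d)
        v = basis.eigenvectors.to_numpy()
        gram = v.T @ v
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)
        assert np.allclose(v.sum(axis=0), 0.0, atol=1e-8)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-9)

    def test_transect_axes_are_sinusoid_like(self):
        """Sign-change count increases with axis index on a 1-D transect."""
        d = geodesic_distance_matrix(self._transect())
        basis = pcnm(d)
        v = basis.eigenvectors.to_numpy()
        changes = [
            int((np.diff(np.sign(v[:, k])) != 0).sum())
            for k in range(min(5, v.shape[1]))
        ]
        assert all(a < b for a, b in zip(changes, changes[1:]))

    def test_three_equidistant_points_hand_eigenvalues(self):
        # equilateral geometry: truncation leaves the matrix unchanged
        d = pd.DataFrame(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float,
            index=list("abc"), columns=list("abc"),
        )
        basis = pcnm(d)
        b = -0.5 * d.to_numpy() ** 2
        j = np.eye(3) - np.ones((3, 3)) / 3
        expected = np.sort(np.linalg.eigvalsh(j @ b @ j))[::-1]
        assert basis.truncation_threshold == pytest.approx(1.0)
        assert np.allclose(basis.eigenvalues, expected[: len(basis.eigenvalues)])

    def test_coincident_points_degenerate(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="coincident"):
            pcnm(d)

    def test_invariant_to_sample_order(self):
        coords = self._transect(12)
        d1 = geodesic_distance_matrix(coords)
        perm = np.random.default_rng(0).permutation(12)
        d2 = d1.iloc[perm, perm]
        b1, b2 = pcnm(d1), pcnm(d2)
        assert np.allclose(b1.eigenvalues, b2.eigenvalues, atol=1e-8)


class TestPcnmEnvironmentStep:
    def test_env_equal_to_axis_selected_r2_one(self):
        d = geodesic_distance_matrix(TestPcnm._transect())
        basis = pcnm(d)
        env = EnvMatrix(
            basis.eigenvectors[["PCNM1"]].rename(columns={"PCNM1": "pH"}),
            {"pH": "none"},
        )
        kept = select_pcnms(basis, env)
        assert "PCNM1" in kept
        fit = stepwise_lm(env.values["pH"], basis.eigenvectors[kept])
        assert fit.selected == ["PCNM1"]
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_environment_rarely_selected(self, rng):
        d = geodesic_distance_matrix(TestPcnm._transect(24))
        basis = pcnm(d)
        n_axes = basis.eigenvectors.shape[1]
        picked = []
        for _ in range(30):
            env = EnvMatrix(
                pd.DataFrame(
                    {"pH": rng.standard_normal(24)},
                    index=basis.eigenvectors.index,
                ),
                {"pH": "none"},
            )
            kept = select_pcnms(basis, env, alpha=0.05)
            picked.append(len(kept))
        # per-replicate false-positive count is approximately alpha * axes
        assert np.mean(picked) < 0.05 * n_axes * 3 + 0.5
        # with no spatial signal most replicates keep no axis at all
        assert np.mean([k == 0 for k in picked]) >= 0.3

    def test_planted_axes_recovered(self):
        """Dependence planted on axes {1, 3} is recovered by the pipeline
        chain: correlation screening followed by AICc stepwise."""
        d = geodesic_distance_matrix(TestPcnm._transect(24))
        basis = pcnm(d)
        exact = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(500 + rep)
            y = (
                1.0 * basis.eigenvectors["PCNM1"]
                + 0.8 * basis.eigenvectors["PCNM3"]
                + 0.05 * r.standard_normal(24)
            )
            ystd = (y - y.mean()) / y.std(ddof=1)
            env = EnvMatrix(
                pd.DataFrame({"y": ystd}, index=basis.eigenvectors.index),
                {"y": "none"},
            )
            kept = select_pcnms(basis, env, alpha=0.05)
            fit = stepwise_lm(y, basis.eigenvectors[kept])
            exact += set(fit.selected) == {"PCNM1", "PCNM3"}
        assert exact >= 0.9 * reps
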