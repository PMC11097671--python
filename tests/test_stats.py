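"""Covariate-adjusted OLS associations, BH-FDR, growth and intercorrelation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import cerebgrad as cg
from conftest import brute_force_bh, brute_force_pearson

# Printed uncorrected p-values of the gradient association table
# (10 gradients x 4 domains), used as worked examples for the BH step-up.
TABLE5_P = {
    "Externalizing": [0.230, 0.200, 0.146, 0.241, 0.728, 0.872, 0.001, 0.962, 0.447, 0.226],
    "Internalizing": [0.713, 0.442, 0.796, 0.912, 0.852, 0.157, 0.032, 0.936, 0.514, 0.273],
    "Dysregulation": [0.357, 0.689, 0.051, 0.794, 0.838, 0.559, 0.238, 0.368, 0.588, 0.245],
    "Competence": [0.015, 0.468, 0.248, 0.544, 0.996, 0.167, 0.464, 0.258, 0.539, 0.042],
}


def _design(n, seed, slope=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "feature": rng.normal(0, 1, n),
            "sex": rng.integers(0, 2, n),
            "pma_weeks": rng.normal(42, 1.9, n),
            "birthweight_g": rng.normal(3300, 430, n),
        }
    )
    df["score"] = (
        50
        + slope * df["feature"]
        + 0.5 * (df["pma_weeks"] - 42)
        + rng.normal(0, 10, n)
    )
    return df


class TestFitFeatureModel:
    def test_perfect_signal_tiny_p(self):
        df = _design(40, 0)
        df["score"] = 50 + 3.0 * df["feature"] + 0.1 * df["pma_weeks"]
        res = cg.fit_feature_model(df, "score", "feature")
        assert res.p_unc < 1e-10

    def test_matches_normal_equations_oracle(self):
        df = _design(10, 1, slope=1.2)
        res = cg.fit_feature_model(df, "score", "feature")
        X = np.column_stack(
            [np.ones(10), df["feature"], df["sex"], df["pma_weeks"], df["birthweight_g"]]
        )
        y = df["score"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        dof = 10 - 5
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        assert res.t_stat == pytest.approx(t, abs=1e-8)
        assert res.p_unc == pytest.approx(2 * sps.t.sf(abs(t), dof), abs=1e-10)
        assert res.n == 10

    def test_null_p_values_uniform(self):
        """Feature of pure noise: p_unc ~ U(0,1) (KS not rejected at 1%)."""
        ps = [
            cg.fit_feature_model(_design(30, seed), "score", "feature").p_unc
            for seed in range(1000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_t_invariant_to_covariate_rescaling(self):
        df = _design(40, 2, slope=0.8)
        res1 = cg.fit_feature_model(df, "score", "feature")
        df2 = df.copy()
        df2["birthweight_g"] = df2["birthweight_g"] / 1000.0 + 3.0
        res2 = cg.fit_feature_model(df2, "score", "feature")
        assert res1.t_stat == pytest.approx(res2.t_stat, abs=1e-8)

    def test_small_n_raises(self):
        with pytest.raises(ValueError, match="too small"):
            cg.fit_feature_model(_design(5, 3), "score", "feature")

    def test_rank_deficiency_raises(self):
        df = _design(20, 4)
        df["feature"] = df["pma_weeks"]
        with pytest.raises(ValueError, match="rank"):
            cg.fit_feature_model(df, "score", "feature")

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing"):
            cg.fit_feature_model(_design(20, 5), "score", "nope")

    def test_complete_cases_only(self):
        df = _design(30, 6, slope=1.0)
        df.loc[:4, "score"] = np.nan
        assert cg.fit_feature_model(df, "score", "feature").n == 25


class TestBhFdr:
    def test_internalizing_worked_example(self):
        adj = cg.bh_fdr(TABLE5_P["Internalizing"])
        assert adj[6] == pytest.approx(0.32, abs=0.005)

    def test_competence_worked_example(self):
        adj = cg.bh_fdr(TABLE5_P["Competence"])
        assert adj[0] == pytest.approx(0.15, abs=0.005)
        assert adj[9] == pytest.approx(0.21, abs=0.005)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(cg.bh_fdr([0.3] * 7), 0.3)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cg.bh_fdr([0.1, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_brute_force_and_monotone(self, p):
        adj = cg.bh_fdr(p)
        np.testing.assert_allclose(adj, brute_force_bh(p), atol=1e-12)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        # order preserved: sorting by raw p sorts adjusted too
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestAssociationTable:
    def _cohort_frame(self, seed, n=40, n_features=10):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "sex": rng.integers(0, 2, n),
                "pma_weeks": rng.normal(42, 1.9, n),
                "birthweight_g": rng.normal(3300, 430, n),
            }
        )
        for i in range(n_features):
            df[f"F{i + 1}"] = rng.normal(0, 1, n)
        for d in cg.DOMAINS:
            df[d] = rng.normal(50, 10, n)
        return df

    def test_gradient_table_shape(self):
        df = self._cohort_frame(0)
        table = cg.association_table(df, [f"F{i + 1}" for i in range(10)], list(cg.DOMAINS))
        assert len(table) == 40
        assert table.groupby("outcome").size().eq(10).all()

    def test_volume_table_shape(self):
        df = self._cohort_frame(1, n_features=8)
        table = cg.association_table(df, [f"F{i + 1}" for i in range(8)], list(cg.DOMAINS))
        assert len(table) == 32

    def test_fdr_scope_per_domain(self):
        df = self._cohort_frame(2)
        table = cg.association_table(df, [f"F{i + 1}" for i in range(10)], list(cg.DOMAINS))
        for dom in cg.DOMAINS:
            sub = table[table["outcome"] == dom]
            np.testing.assert_allclose(
                sub["p_fdr"].to_numpy(), cg.bh_fdr(sub["p_unc"].to_numpy()), atol=1e-12
            )

    def test_null_type_one_error_rate(self):
        """Scrambled outcomes: ~5% of uncorrected p-values fall below 0.05."""
        ps = []
        for seed in range(40):
            df = self._cohort_frame(seed, n=30, n_features=5)
            table = cg.association_table(df, [f"F{i + 1}" for i in range(5)], list(cg.DOMAINS))
            ps.extend(table["p_unc"].tolist())
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= rate <= 0.09

    def test_bh_fdr_controls_under_generator_null(self):
        """coupling_r=0: per-domain BH at q=0.05 falsely rejects in <= ~5% of
        families across simulated cohorts."""
        from cerebgrad.synth import make_ground_truth, make_subject_records, records_to_frame

        false_families = 0
        n_rep = 500
        rng = np.random.default_rng(0)
        for seed in range(n_rep):
            cfg = cg.CohortConfig(n_subjects=40, coupling_r=0.0, seed=seed)
            truth = make_ground_truth(cfg)
            frame = records_to_frame(make_subject_records(cfg, truth))
            for j in range(cfg.n_latent):
                frame[f"F{j + 1}"] = truth.subject_strengths[:, j]
            for j in range(cfg.n_latent, 10):
                frame[f"F{j + 1}"] = rng.normal(0, 1, len(frame))
            table = cg.association_table(
                frame, [f"F{j + 1}" for j in range(10)], [cfg.coupled_domain]
            )
            false_families += bool((table["p_fdr"] < 0.05).any())
        rate = false_families / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_missing_column_raises(self):
        df = self._cohort_frame(3)
        with pytest.raises(ValueError, match="missing"):
            cg.association_table(df, ["F1", "nope"], list(cg.DOMAINS))


class TestVolumeGrowth:
    def test_noiseless_growth(self):
        pma = np.linspace(38, 46, 20)
        vols = pd.DataFrame({"subject_id": range(20), "roi_a": 1 + 0.2 * pma})
        out = cg.volume_growth(vols, pma)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "pct_variance"] == pytest.approx(100.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(1)
        pma = rng.normal(42, 2, 30)
        vols = pd.DataFrame(
            {"subject_id": range(30), "a": rng.normal(3, 1, 30), "b": 0.2 * pma + rng.normal(0, 0.3, 30)}
        )
        out = cg.volume_growth(vols, pma)
        for _, row in out.iterrows():
            assert row["r"] == pytest.approx(
                brute_force_pearson(vols[row["roi"]], pma), abs=1e-10
            )

    def test_zero_variance_column_raises(self):
        vols = pd.DataFrame({"subject_id": range(10), "a": np.ones(10)})
        with pytest.raises(ValueError, match="zero-variance"):
            cg.volume_growth(vols, np.linspace(38, 44, 10))


class TestDomainIntercorrelation:
    def test_identical_columns_unit_correlation(self):
        base = np.random.default_rng(0).normal(50, 10, 30)
        scores = pd.DataFrame({d: base for d in cg.DOMAINS})
        rmat, _ = cg.domain_intercorrelation(scores)
        np.testing.assert_allclose(rmat.to_numpy(), 1.0)

    def test_generator_default_sign_pattern(self):
        """Problem domains positively intercorrelated; Competence ~ independent."""
        from cerebgrad.synth import make_ground_truth, make_subject_records, records_to_frame

        acc = np.zeros((4, 4))
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = cg.CohortConfig(seed=seed)
            truth = make_ground_truth(cfg)
            frame = records_to_frame(make_subject_records(cfg, truth))
            rmat, _ = cg.domain_intercorrelation(frame[list(cg.DOMAINS)])
            acc += rmat.to_numpy()
        acc /= n_seeds
        idx = {d: i for i, d in enumerate(cg.DOMAINS)}
        for a, b in [("Externalizing", "Internalizing"),
                     ("Externalizing", "Dysregulation"),
                     ("Internalizing", "Dysregulation")]:
            assert acc[idx[a], idx[b]] > 0.1
        for other in ("Externalizing", "Internalizing", "Dysregulation"):
            assert abs(acc[idx["Competence"], idx[other]]) < 0.1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame({d: rng.normal(50, 10, 25) for d in cg.DOMAINS})
        rmat, pmat = cg.domain_intercorrelation(scores)
        for a in cg.DOMAINS:
            for b in cg.DOMAINS:
                if a != b:
                    assert rmat.loc[a, b] == pytest.approx(
                        brute_force_pearson(scores[a], scores[b]), abs=1e-10
                    )

    def test_constant_column_raises(self):
        scores = pd.DataFrame(
            {d: np.random.default_rng(3).normal(50, 10, 20) for d in cg.DOMAINS}
        )
        scores["Competence"] = 50.0
        with pytest.raises(ValueError, match="constant"):
            cg.domain_intercorrelation(scores)
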