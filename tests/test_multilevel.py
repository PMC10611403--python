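import numpy as np
import pytest

from mmjive.domain_models import JIVEModel
from mmjive.errors import ValidationError
from mmjive.multilevel import (
    ScoreSet,
    anova_decompose,
    compare_components,
    ml_jive,
    ml_pls,
    mpca_fit,
    score_feature_correlations,
)
from mmjive.panel import scale_panel
from mmjive.synthetic import SyntheticSpec, simulate_multilevel

from conftest import PROPORTIONAL_SPLIT, make_panel, random_panel


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

class TestAnovaDecompose:
    def test_hand_example(self):
        rows = [
            ("A", 1, 1.0, 10.0),
            ("A", 2, 3.0, 10.0),
            ("B", 1, 5.0, 10.0),
            ("B", 2, 7.0, 10.0),
        ]
        panel = make_panel(rows, pa=["a"], gait=["g"])
        d = anova_decompose(panel)
        assert d.grand_mean["a"] == pytest.approx(4.0)
        np.testing.assert_allclose(d.between["a"].to_numpy(), [-2.0, 2.0])
        np.testing.assert_allclose(d.within["a"].to_numpy(), [-1.0, 1.0, -1.0, 1.0])

    def test_single_day_subjects_have_zero_within(self):
        rows = [("A", 1, 1.0, 2.0), ("B", 1, 3.0, 4.0), ("C", 1, 5.0, 0.0)]
        panel = make_panel(rows, pa=["a"], gait=["g"])
        d = anova_decompose(panel)
        assert np.abs(d.within.to_numpy()).max() == 0.0

    def test_reconstruction_identity(self, rng):
        panel = random_panel(rng, n_subjects=6, days=4)
        d = anova_decompose(panel)
        np.testing.assert_allclose(d.reconstruct(), panel.values(), atol=1e-10)

    def test_within_rows_sum_to_zero_per_subject(self, rng):
        panel = random_panel(rng, n_subjects=5, days=3)
        d = anova_decompose(panel)
        W = d.within.to_numpy()
        for s in range(5):
            np.testing.assert_allclose(
                W[d.subject_index == s].sum(axis=0), 0.0, atol=1e-10
            )

    def test_ss_partition(self, rng):
        panel = random_panel(rng, n_subjects=7, days=5)
        ss = anova_decompose(panel).sums_of_squares
        np.testing.assert_allclose(
            ss["between"] + ss["within"], ss["total"], rtol=1e-8
        )

    def test_accepts_scaled_panel(self, rng):
        panel = random_panel(rng, n_subjects=6, days=3)
        d = anova_decompose(scale_panel(panel, scope="daily_rows"))
        assert np.abs(d.grand_mean.to_numpy()).max() < 1e-10


# ---------------------------------------------------------------------------
# MPCA
# ---------------------------------------------------------------------------

class TestMPCA:
    def test_between_fraction_recovery(self):
        spec = SyntheticSpec(
            n_subjects=300, days_mean=9, days_sd=1.5, var_between=0.46,
            noise_sd=0.1, seed=4,
            joint_block_split=PROPORTIONAL_SPLIT, ind_block_split=PROPORTIONAL_SPLIT,
        )
        panel, _ = simulate_multilevel(spec)
        m = mpca_fit(anova_decompose(panel))
        assert m.level_variance_fractions["between"] == pytest.approx(0.46, abs=0.04)

    def test_no_within_signal(self):
        spec = SyntheticSpec(
            n_subjects=60, days_mean=5, days_sd=0, r_w=0, r1_w=0, r2_w=0,
            var_between=1.0, noise_sd=1e-3, seed=5,
        )
        panel, _ = simulate_multilevel(spec)
        m = mpca_fit(anova_decompose(panel))
        assert m.level_variance_fractions["within"] < 0.02

    def test_full_retention_reconstructs_effects(self, rng):
        panel = random_panel(rng, n_subjects=10, days=4, P=4, Q=3)
        d = anova_decompose(panel)
        m = mpca_fit(d, retained_fraction=1.0, method="empirical")
        B = d.between.to_numpy()
        W = d.within.to_numpy()
        np.testing.assert_allclose(
            m.between_scores @ m.between_components.to_numpy().T, B, atol=1e-8
        )
        np.testing.assert_allclose(
            m.within_scores @ m.within_components.to_numpy().T, W, atol=1e-8
        )

    def test_all_single_day_errors(self):
        rows = [("A", 1, 1.0, 2.0), ("B", 1, 3.0, 4.0), ("C", 1, 0.0, 1.0)]
        panel = make_panel(rows, pa=["a"], gait=["g"])
        with pytest.raises(ValidationError, match="single day"):
            mpca_fit(anova_decompose(panel))

    def test_loadings_orthonormal(self, rng):
        panel = random_panel(rng, n_subjects=12, days=4, P=5, Q=4)
        m = mpca_fit(anova_decompose(panel))
        for V in (m.between_components.to_numpy(), m.within_components.to_numpy()):
            np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_consistent_with_anova_ss_in_large_day_limit(self):
        # the empirical between SS carries a within/n_days leakage term, so
        # the two estimates agree only once day counts are large
        spec = SyntheticSpec(
            n_subjects=500, days_mean=40, days_sd=3, var_between=0.5,
            noise_sd=0.1, seed=6,
            joint_block_split=PROPORTIONAL_SPLIT, ind_block_split=PROPORTIONAL_SPLIT,
        )
        panel, _ = simulate_multilevel(spec)
        d = anova_decompose(panel)
        m = mpca_fit(d)
        ss = d.sums_of_squares
        anova_frac = ss["between"].sum() / ss["total"].sum()
        assert m.level_variance_fractions["between"] == pytest.approx(anova_frac, abs=0.02)


# ---------------------------------------------------------------------------
# multilevel PLS
# ---------------------------------------------------------------------------

class TestMlPls:
    def test_shared_joint_direction_across_levels(self):
        spec = SyntheticSpec(
            n_subjects=200, days_mean=9, days_sd=1.5, var_between=0.5,
            var_joint_b=0.7, var_joint_w=0.7, noise_sd=0.1, seed=7,
            shared_joint_loadings=True,
        )
        panel, _ = simulate_multilevel(spec)
        b, w = ml_pls(anova_decompose(panel))
        for vecs in ("x_weights", "y_weights"):
            vb = getattr(b, vecs)[:, 0]
            vw = getattr(w, vecs)[:, 0]
            assert abs(vb @ vw) / (np.linalg.norm(vb) * np.linalg.norm(vw)) > 0.95

    def test_single_day_subjects_warn_and_skip_within(self):
        rows = [(f"S{i}", 1, *np.random.default_rng(i).normal(size=4)) for i in range(12)]
        panel = make_panel(rows, pa=["a", "b"], gait=["g", "h"])
        with pytest.warns(UserWarning, match="within"):
            b, w = ml_pls(anova_decompose(panel))
        assert w is None
        assert b is not None

    def test_between_weights_match_svd_oracle(self, rng):
        panel = random_panel(rng, n_subjects=15, days=4, P=5, Q=4)
        d = anova_decompose(panel)
        b, _ = ml_pls(d)
        B = d.between.to_numpy()
        B = B - B.mean(axis=0)
        u, s, vt = np.linalg.svd(B[:, :5].T @ B[:, 5:])
        w = b.x_weights[:, 0]
        assert min(np.linalg.norm(w - u[:, 0]), np.linalg.norm(w + u[:, 0])) < 1e-8


# ---------------------------------------------------------------------------
# multilevel JIVE
# ---------------------------------------------------------------------------

class TestMlJive:
    def test_monte_carlo_fraction_recovery(self):
        stats = {"betw": [], "jb": [], "ib": [], "jw": [], "iw": []}
        for seed in range(3):
            spec = SyntheticSpec(
                n_subjects=200, days_mean=9, days_sd=1.5, var_between=0.5,
                var_joint_b=0.5, var_joint_w=0.5, noise_sd=0.2, seed=seed,
                joint_block_split=PROPORTIONAL_SPLIT,
                ind_block_split=PROPORTIONAL_SPLIT,
            )
            panel, _ = simulate_multilevel(spec)
            mlj = ml_jive(
                anova_decompose(panel), retained_fraction=0.95,
                ranks_between=(1, 2, 2), ranks_within=(1, 2, 2),
            )
            lt = mlj.level_table
            stats["betw"].append(lt.loc["mpca_explained", "between"])
            stats["jb"].append(lt.loc["joint", "between"])
            stats["ib"].append(lt.loc["individual", "between"])
            stats["jw"].append(lt.loc["joint", "within"])
            stats["iw"].append(lt.loc["individual", "within"])
        assert np.mean(stats["betw"]) == pytest.approx(0.5, abs=0.05)
        for key in ("jb", "ib", "jw", "iw"):
            assert np.mean(stats[key]) == pytest.approx(0.5, abs=0.05)

    def test_noiseless_between_only_fixture(self):
        spec = SyntheticSpec(
            n_subjects=60, days_mean=4, days_sd=0, r_w=0, r1_w=0, r2_w=0,
            var_between=1.0, var_joint_b=0.4, noise_sd=0.0, seed=8,
            joint_block_split=PROPORTIONAL_SPLIT, ind_block_split=PROPORTIONAL_SPLIT,
        )
        panel, _ = simulate_multilevel(spec)
        mlj = ml_jive(
            anova_decompose(panel), retained_fraction=1.0, mpca_method="empirical",
            ranks_between=(1, 2, 2), ranks_within=(0, 0, 0), tol=1e-16,
        )
        lt = mlj.level_table
        assert lt.loc["mpca_explained", "between"] == pytest.approx(1.0, abs=1e-6)
        assert lt.loc["joint", "between"] == pytest.approx(0.4, abs=1e-6)
        assert lt.loc["individual", "between"] == pytest.approx(0.6, abs=1e-6)
        assert lt.loc["joint", "within"] == 0.0
        assert lt.loc["individual", "within"] == 0.0

    def test_zero_ranks_give_zero_fractions(self, rng):
        panel = random_panel(rng, n_subjects=10, days=4, P=4, Q=3)
        mlj = ml_jive(
            anova_decompose(panel), ranks_between=(0, 0, 0), ranks_within=(0, 0, 0)
        )
        lt = mlj.level_table
        for lvl in ("between", "within"):
            assert lt.loc["joint", lvl] == 0.0
            assert lt.loc["individual", lvl] == 0.0

    def test_auto_ranks_recovers_planted(self, stryde_shaped):
        panel, truth = stryde_shaped
        mlj = ml_jive(anova_decompose(panel), ranks_between="auto",
                      ranks_within="auto", n_perm=50, seed=0)
        assert mlj.ranks["between"] == (1, 2, 2)
        assert mlj.ranks["within"] == (1, 2, 2)


# ---------------------------------------------------------------------------
# score-feature correlations
# ---------------------------------------------------------------------------

class TestScoreFeatureCorrelations:
    def fit(self, stryde_shaped):
        panel, _ = stryde_shaped
        decomp = anova_decompose(panel)
        mlj = ml_jive(decomp, ranks_between=(1, 1, 2), ranks_within=(1, 1, 2))
        return mlj, decomp

    def test_table_dimensions(self, stryde_shaped):
        mlj, decomp = self.fit(stryde_shaped)
        tables = score_feature_correlations(mlj, decomp)
        for level in ("between", "within"):
            assert tables[level].r.shape == (24, 1 + 1 + 2)

    def test_feature_equal_to_score_has_unit_correlation(self, stryde_shaped):
        mlj, decomp = self.fit(stryde_shaped)
        # plant a feature column equal to the between joint score
        decomp.between.iloc[:, 0] = mlj.between_jive.joint_scores[0]
        tables = score_feature_correlations(mlj, decomp)
        assert tables["between"].r.iloc[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert tables["between"].mask.iloc[0, 0]

    def test_orthogonal_feature_has_null_correlation(self, stryde_shaped):
        mlj, decomp = self.fit(stryde_shaped)
        score = mlj.between_jive.joint_scores[0]
        col = decomp.between.iloc[:, 1].to_numpy()
        col = col - score * (score @ col) / (score @ score)
        decomp.between.iloc[:, 1] = col
        tables = score_feature_correlations(mlj, decomp)
        n = len(score)
        assert abs(tables["between"].r.iloc[1, 0]) < 2 / np.sqrt(n)


# ---------------------------------------------------------------------------
# component comparison
# ---------------------------------------------------------------------------

class TestCompareComponents:
    def test_self_comparison_diagonal(self, rng):
        scores = rng.normal(size=(10, 2))
        subs = [f"s{i}" for i in range(10)]
        sets = [ScoreSet("M1", scores, "subject", subs),
                ScoreSet("M2", scores.copy(), "subject", subs)]
        corr = compare_components(sets)
        assert corr.loc["M1.PC1", "M2.PC1"] == pytest.approx(1.0)
        assert corr.loc["M1.PC2", "M2.PC2"] == pytest.approx(1.0)

    def test_sign_flip_preserves_magnitude(self, rng):
        scores = rng.normal(size=(12, 2))
        subs = [f"s{i}" for i in range(12)]
        c1 = compare_components([ScoreSet("A", scores, "subject", subs),
                                 ScoreSet("B", scores * [1, 1], "subject", subs)])
        c2 = compare_components([ScoreSet("A", scores, "subject", subs),
                                 ScoreSet("B", scores * [-1, 1], "subject", subs)])
        np.testing.assert_allclose(
            c1.abs().to_numpy(), c2.abs().to_numpy(), atol=1e-12
        )

    def test_disjoint_subjects_error(self, rng):
        s1 = ScoreSet("A", rng.normal(size=(5, 2)), "subject", list("abcde"))
        s2 = ScoreSet("B", rng.normal(size=(5, 2)), "subject", list("vwxyz"))
        with pytest.raises(ValidationError, match="subjects"):
            compare_components([s1, s2])

    def test_strong_joint_signal_aligns_models(self):
        from mmjive.domain_models import jive_fit, pls_fit
        from mmjive.panel import scale_panel, subject_means

        spec = SyntheticSpec(
            n_subjects=200, days_mean=9, days_sd=1.5, var_between=0.6,
            var_joint_b=0.8, var_joint_w=0.8, noise_sd=0.1, seed=9,
            shared_joint_loadings=True,
        )
        panel, _ = simulate_multilevel(spec)
        means = subject_means(scale_panel(panel, scope="subject_means").panel)
        pls = pls_fit(
            means.x() - means.x().mean(axis=0),
            means.y() - means.y().mean(axis=0),
            n_components=2,
        )
        decomp = anova_decompose(scale_panel(panel, scope="daily_rows"))
        mlj = ml_jive(decomp, ranks_between=(1, 2, 2), ranks_within=(1, 2, 2))
        sets = [
            ScoreSet("PLS", pls.x_scores, "subject", means.subject_ids),
            ScoreSet("JIVE.B.JT", mlj.between_jive.joint_scores.T, "subject", decomp.subjects),
        ]
        corr = compare_components(sets)
        assert abs(corr.loc["PLS.PC1", "JIVE.B.JT.PC1"]) > 0.9
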