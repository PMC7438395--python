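"""TWAS engine: weight training, imputation linearity, covariate-adjusted
association, genotype PCs and QQ calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemohf.simulate import ReferencePanelSpec, simulate_reference_panel
from chemohf.twas import (
    TwasAnalysis,
    WeightModel,
    associate_expression,
    compute_genotype_pcs,
    impute_expression,
    qq_data,
    read_weights,
    train_weights,
    write_weights,
)

from conftest import make_matrix


def _weight_model(variant_ids, weights, mean=None, scale=None, **kw):
    k = len(variant_ids)
    return WeightModel(
        gene_id=kw.pop("gene_id", "g"),
        variant_ids=list(variant_ids),
        weights=np.asarray(weights, float),
        ref_mean=np.zeros(k) if mean is None else np.asarray(mean, float),
        ref_scale=np.ones(k) if scale is None else np.asarray(scale, float),
        training_n=100,
        cv_r2=kw.pop("cv_r2", 0.5),
        **kw,
    )


class TestTrainWeights:
    def test_noiseless_single_snp_recovered_with_near_perfect_cv_r2(self):
        spec = ReferencePanelSpec(
            n_samples=120, n_snps=5,
            causal_weights={"panel_snp_2": 1.0},
            expression_noise_sd=0.0, seed=3,
        )
        gm, expr = simulate_reference_panel(spec)
        model = train_weights(gm, expr, seed=0)
        assert model.cv_r2 > 0.99
        w = np.abs(model.weights)
        assert np.argmax(w) == 2
        assert w[2] > 0.9 * w.sum()

    def test_pure_noise_expression_flagged_unusable(self):
        spec = ReferencePanelSpec(n_samples=200, n_snps=10, seed=4)
        gm, _ = simulate_reference_panel(spec)
        unusable = 0
        for s in range(10):
            y = np.random.default_rng(s).normal(size=200)
            unusable += not train_weights(gm, y, seed=s).usable
        assert unusable >= 9

    def test_constant_expression_or_genotypes_give_unusable_not_crash(self):
        spec = ReferencePanelSpec(n_samples=50, n_snps=4, seed=5)
        gm, _ = simulate_reference_panel(spec)
        m1 = train_weights(gm, np.ones(50), seed=0)
        assert not m1.usable and "constant" in m1.note
        gm2 = make_matrix(np.ones((30, 3)) * 2)
        m2 = train_weights(gm2, np.random.default_rng(0).normal(size=30), seed=0)
        assert not m2.usable

    def test_standardization_statistics_travel_with_model(self):
        spec = ReferencePanelSpec(n_samples=80, n_snps=6, seed=6)
        gm, expr = simulate_reference_panel(spec)
        model = train_weights(gm, expr, seed=1)
        assert np.allclose(model.ref_mean, gm.dosages.mean(axis=0))
        assert (model.ref_scale > 0).all()


class TestImputeExpression:
    def test_single_unit_weight_identity_standardization(self):
        gm = make_matrix([[0], [1], [2]])
        model = _weight_model(["snp0"], [1.0])
        assert np.allclose(impute_expression(gm, model), [0, 1, 2])

    def test_zero_weights_give_zero_scores(self):
        gm = make_matrix([[0, 2], [1, 1]])
        model = _weight_model(["snp0", "snp1"], [0.0, 0.0])
        assert np.allclose(impute_expression(gm, model), 0.0)

    def test_hand_computed_dot_products(self):
        gm = make_matrix([[0, 2], [1, 1], [2, 0]])
        model = _weight_model(
            ["snp0", "snp1"], [0.5, -2.0], mean=[1.0, 1.0], scale=[2.0, 1.0]
        )
        # score_i = 0.5*(d0-1)/2 - 2*(d1-1)
        expected = [0.5 * (-1) / 2 - 2 * 1, 0.0, 0.5 * 1 / 2 - 2 * (-1)]
        assert np.allclose(impute_expression(gm, model), expected)

    def test_imputation_is_linear_in_weights(self, rng):
        gm = make_matrix(rng.integers(0, 3, size=(20, 4)).astype(float))
        vids = gm.variant_ids
        w1 = _weight_model(vids, rng.normal(size=4))
        w2 = _weight_model(vids, rng.normal(size=4))
        combo = _weight_model(vids, 2.0 * w1.weights + 3.0 * w2.weights)
        assert np.allclose(
            impute_expression(gm, combo),
            2 * impute_expression(gm, w1) + 3 * impute_expression(gm, w2),
        )

    def test_missing_weight_mass_over_half_raises(self):
        gm = make_matrix([[0], [1]])
        model = _weight_model(["snp0", "absent"], [0.3, 0.7])
        with pytest.raises(ValueError, match="weight mass"):
            impute_expression(gm, model)


class TestAssociateExpression:
    def test_recovers_expression_effect_within_3_se(self, rng):
        n = 800
        score = rng.normal(size=n)
        cov = pd.DataFrame({"age": rng.normal(60, 10, n)})
        y = -2.0 * score + 0.1 * cov["age"] + rng.normal(0, 5, n)
        res = associate_expression(score, y.to_numpy(), cov)
        assert abs(res.beta - (-2.0)) < 3 * res.se

    def test_collinear_score_raises_named_error(self, rng):
        n = 50
        score = rng.normal(size=n)
        cov = pd.DataFrame({"dup": score})
        with pytest.raises(ValueError, match="collinear"):
            associate_expression(score, rng.normal(size=n), cov)

    def test_null_scores_give_uniform_pvalues(self, rng):
        pvals = []
        n = 150
        for _ in range(300):
            score = rng.normal(size=n)
            y = rng.normal(size=n)
            pvals.append(associate_expression(score, y).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_snp_weight_model_matches_per_snp_linear_p(self, rng):
        from chemohf.assoc import linear_lvef_assoc

        d = rng.integers(0, 3, 120).astype(float)
        y = -1.5 * d + rng.normal(0, 3, 120)
        gm = make_matrix(d[:, None])
        model = _weight_model(["snp0"], [1.0])
        scores = impute_expression(gm, model)
        twas = associate_expression(scores, y)
        snp = linear_lvef_assoc(d, y)
        assert twas.p == pytest.approx(snp.p, rel=1e-10)
        assert twas.beta == pytest.approx(snp.beta, rel=1e-10)


class TestGenotypePcs:
    def test_pc1_separates_two_frequency_clusters(self, rng):
        n, m = 60, 40
        a = rng.binomial(2, 0.1, size=(n, m))
        b = rng.binomial(2, 0.6, size=(n, m))
        gm = make_matrix(
            np.vstack([a, b]).astype(float),
            variant_ids=[f"v{j}" for j in range(m)],
            sample_ids=[f"x{i}" for i in range(2 * n)],
        )
        scores, var = compute_genotype_pcs(gm, k=2)
        pc1 = scores[:, 0]
        assert (pc1[:n].mean() < pc1[n:].mean()) or (
            pc1[:n].mean() > pc1[n:].mean()
        )
        gap = abs(pc1[:n].mean() - pc1[n:].mean())
        spread = pc1[:n].std() + pc1[n:].std()
        assert gap > spread

    def test_axes_orthonormal_and_variance_ordered(self, rng):
        gm = make_matrix(rng.integers(0, 3, size=(50, 10)).astype(float))
        X = gm.dosages - gm.dosages.mean(axis=0)
        scores, var = compute_genotype_pcs(gm, k=3)
        # scores are X @ V with orthonormal V: cross-products vanish
        G = scores.T @ scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        assert (np.diff(var) <= 1e-12).all()

    def test_k_above_rank_raises(self):
        gm = make_matrix(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            compute_genotype_pcs(gm, k=2)


class TestQq:
    def test_diagonal_for_matched_quantiles(self):
        exp, obs = qq_data([0.25, 0.5, 0.75])
        assert np.allclose(exp, obs)

    def test_uniform_draws_stay_near_diagonal(self, rng):
        p = rng.uniform(size=1000)
        exp, obs = qq_data(p)
        # Kolmogorov–Smirnov-style bound on uniform order statistics
        assert np.max(np.abs(10**-obs - 10**-exp)) < 1.63 / np.sqrt(1000)

    def test_injected_signal_departs_above_diagonal(self, rng):
        p = np.append(rng.uniform(0.1, 1, 200), 1e-8)
        exp, obs = qq_data(p)
        # smallest p sorts first: the top-most point sits far above y = x
        assert obs[0] - exp[0] > 4

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            qq_data([0.0, 0.5])


class TestAnalysisAndIo:
    def test_weights_tsv_round_trip(self, tmp_path):
        m = _weight_model(
            ["a", "b", "c"], [0.5, 0.0, -1.0], mean=[0.1, 0.2, 0.3],
            scale=[1.0, 1.1, 1.2], gene_id="gene1",
        )
        write_weights([m], tmp_path / "w.tsv")
        back = read_weights(tmp_path / "w.tsv")[0]
        assert back.gene_id == "gene1"
        assert back.nonzero() == m.nonzero()

    def test_analysis_ranks_genes_by_pvalue(self, rng):
        n = 300
        dos = rng.integers(0, 3, size=(n, 4)).astype(float)
        gm = make_matrix(dos, variant_ids=["a", "b", "c", "d"])
        models = [
            _weight_model(["a"], [1.0], gene_id="causal"),
            _weight_model(["c"], [1.0], gene_id="decoy"),
        ]
        samples = pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "age": rng.normal(60, 8, n),
                "baseline_lvef": rng.normal(62, 5, n),
                "antihtn": rng.integers(0, 2, n),
                "delta_lvef": -3.0 * dos[:, 0] + rng.normal(0, 4, n),
            }
        )
        res = TwasAnalysis(
            gm, samples, models, covariates=["age", "baseline_lvef", "antihtn"]
        ).fit()
        assert list(res.table["rank"]) == [1, 2]
        assert res.gene("causal")["rank"] == 1
        assert sorted(res.table["rank"]) == [1, 2]
        assert "causal" in res.summary()
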