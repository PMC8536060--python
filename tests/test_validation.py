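"""Fold splitting, Fisher's method, and the internal/external protocols."""

import numpy as np
import pytest
from scipy import stats

from egenscore import (
    EqtlModel,
    PipelineConfig,
    align_samples,
    external_validate,
    fisher_combine,
    internal_validate,
    kfold_split,
    make_trainer,
)
from egenscore.datatypes import ExpressionMatrix
from egenscore.simulate import SimConfig, simulate_study


class TestKfoldSplit:
    def test_balanced_sizes(self):
        assignment = kfold_split(10, 5, seed=1)
        sizes = np.bincount(assignment, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_uneven_split_arithmetic(self):
        assignment = kfold_split(127, 5, seed=1)
        sizes = sorted(np.bincount(assignment, minlength=5).tolist())
        assert sizes == [25, 25, 25, 26, 26]

    def test_deterministic_given_seed(self):
        a = kfold_split(50, 5, seed=42)
        b = kfold_split(50, 5, seed=42)
        np.testing.assert_array_equal(a, b)
        c = kfold_split(50, 5, seed=43)
        assert not np.array_equal(a, c)

    def test_folds_partition_the_cohort(self):
        assignment = kfold_split(33, 4, seed=0)
        assert assignment.size == 33
        assert set(assignment) == {0, 1, 2, 3}

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            kfold_split(4, 5, seed=0)


class TestFisherCombine:
    def test_single_uninformative_p(self):
        stat, df, p = fisher_combine([1.0])
        assert stat == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_five_marginal_pvalues(self):
        stat, df, p = fisher_combine([0.05] * 5)
        assert stat == pytest.approx(-2 * 5 * np.log(0.05), rel=1e-12)
        assert stat == pytest.approx(29.957, abs=1e-3)
        assert df == 10
        assert p == pytest.approx(stats.chi2.sf(stat, 10), rel=1e-12)
        assert p == pytest.approx(8.6e-4, abs=5e-5)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    @pytest.mark.parametrize("p_in", [0.9, 0.5, 0.1, 0.01, 1e-5])
    def test_closed_form_identities(self, p_in):
        """Chi-square closed forms: a single p is returned unchanged
        (chi2(2) tail of -2 ln p is exp(ln p) = p), and two p-values with
        product q combine to q * (1 - ln q) (chi2(4) tail)."""
        _, df, combined = fisher_combine([p_in])
        assert df == 2
        assert combined == pytest.approx(p_in, rel=1e-10)
        _, df4, combined4 = fisher_combine([p_in, 0.3])
        q = p_in * 0.3
        assert df4 == 4
        assert combined4 == pytest.approx(q * (1 - np.log(q)), rel=1e-10)

    def test_zero_pvalues_are_clamped(self):
        stat, df, p = fisher_combine([0.0, 0.5])
        assert np.isfinite(stat)
        assert 0.0 <= p <= 1.0


@pytest.fixture(scope="module")
def strong_study():
    """One highly heritable gene, desk-sized cohorts."""
    return simulate_study(
        SimConfig(
            n_train=300, n_panel=200, n_external=150, n_genes=1,
            snps_per_gene=40, block_size=5, h2=0.9, n_causal=1,
            missing_rate=0.02, seed=77,
        )
    )


class TestInternalValidate:
    def test_strong_gene_is_significant(self, strong_study):
        res = internal_validate(
            make_trainer("egenscore"),
            strong_study.genes[0],
            strong_study.train_genotypes,
            strong_study.train_expression,
            strong_study.panel,
            PipelineConfig(seed=3),
        )
        assert res.significant
        assert res.r_avg > 0.5
        assert res.r_avg_sq == pytest.approx(res.r_avg**2, rel=1e-12)
        assert res.fisher_df == 10
        assert len(res.folds) == 5
        sizes = [f.n_test for f in res.folds]
        assert sum(sizes) == 300 and max(sizes) - min(sizes) <= 1

    def test_null_trainer_gives_zero_r_and_no_significance(self, strong_study):
        def null_trainer(gene, geno, expr, panel, config, training_label=""):
            return EqtlModel(gene.gene_id, "egenscore", [])

        res = internal_validate(
            null_trainer,
            strong_study.genes[0],
            strong_study.train_genotypes,
            strong_study.train_expression,
            strong_study.panel,
            PipelineConfig(seed=3),
        )
        assert res.r_avg == 0.0
        assert res.fisher_p == pytest.approx(1.0)
        assert not res.significant
        assert res.fisher_df == 10  # degenerate folds are retained

    def test_trainer_never_sees_holdout_samples(self, strong_study):
        seen = []

        def spy_trainer(gene, geno, expr, panel, config, training_label=""):
            seen.append(set(geno.sample_ids))
            assert geno.sample_ids == expr.sample_ids
            return EqtlModel(gene.gene_id, "egenscore", [])

        config = PipelineConfig(seed=3)
        internal_validate(
            spy_trainer,
            strong_study.genes[0],
            strong_study.train_genotypes,
            strong_study.train_expression,
            strong_study.panel,
            config,
        )
        all_samples = set(strong_study.train_genotypes.sample_ids)
        holdouts = [all_samples - s for s in seen]
        # every sample is held out exactly once across the folds
        assert sorted(len(h) for h in holdouts) == sorted(
            np.bincount(kfold_split(300, 5, config.seed)).tolist()
        )
        union = set().union(*holdouts)
        assert union == all_samples

    def test_significance_flag_is_the_conjunction_of_thresholds(self, strong_study):
        config = PipelineConfig(seed=3)
        res = internal_validate(
            make_trainer("elasticnet"),
            strong_study.genes[0],
            strong_study.train_genotypes,
            strong_study.train_expression,
            strong_study.panel,
            config,
        )
        assert res.significant == (
            abs(res.r_avg) > config.sig_r_threshold
            and res.fisher_p < config.sig_p_threshold
        )


class TestExternalValidate:
    def _model(self, study, config=None):
        geno, expr = align_samples(study.train_genotypes, study.train_expression)
        return make_trainer("egenscore")(
            study.genes[0], geno, expr, study.panel, config or PipelineConfig(seed=3)
        )

    def test_empty_model_not_significant(self, strong_study):
        model = EqtlModel(strong_study.genes[0].gene_id, "egenscore", [])
        res = external_validate(
            model, strong_study.external_genotypes, strong_study.external_expression
        )
        assert res.r == 0.0 and res.p == 1.0
        assert not res.significant

    def test_strong_gene_external_r2_tracks_internal(self, strong_study):
        model = self._model(strong_study)
        internal = internal_validate(
            make_trainer("egenscore"),
            strong_study.genes[0],
            strong_study.train_genotypes,
            strong_study.train_expression,
            strong_study.panel,
            PipelineConfig(seed=3),
        )
        ext = external_validate(
            model, strong_study.external_genotypes, strong_study.external_expression
        )
        assert ext.significant
        assert ext.r_sq == pytest.approx(internal.r_avg_sq, abs=0.15)
        assert ext.r_sq == pytest.approx(ext.r**2, rel=1e-12)

    def test_permuted_expression_rarely_significant(self, strong_study):
        """Permuting external expression across samples destroys the
        genotype link; at most chance-level significance (5%) remains."""
        model = self._model(strong_study)
        expr = strong_study.external_expression
        n_sig = 0
        for perm_seed in range(40):
            rng = np.random.default_rng(perm_seed)
            perm = rng.permutation(len(expr.sample_ids))
            shuffled = ExpressionMatrix(
                expr.gene_ids, expr.sample_ids, expr.values[:, perm]
            )
            res = external_validate(model, strong_study.external_genotypes, shuffled)
            n_sig += res.significant
        # binomial(40, 0.05) upper bound: P(X > 5) ~ 1.6%
        assert n_sig <= 5
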