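"""Panel proportions, adjustment factors, and the centered polygenic score."""

import numpy as np
import pytest

from egenscore import (
    EqtlModel,
    GenotypeMatrix,
    ModelWeight,
    PipelineConfig,
    ReferencePanel,
    SNPRecord,
    adjustment_factor,
    align_samples,
    build_egenscore_model,
    genotype_proportions,
    score_egenscore,
)
from egenscore.score import AbsentFromPanelError, PanelProportions
from egenscore.simulate import SimConfig, simulate_study


def _panel(dosages):
    dosages = np.asarray(dosages, float).reshape(-1, 1)
    snps = [SNPRecord("rs1", "1", 100, "A", "G")]
    samples = [f"p{i}" for i in range(dosages.shape[0])]
    return ReferencePanel(GenotypeMatrix(samples, snps, dosages))


class TestGenotypeProportions:
    def test_simple_counting(self):
        props = genotype_proportions(_panel([0, 1, 1, 2]), _panel([0]).genotypes.snps[0])
        assert props.prop_one == pytest.approx(0.5)
        assert props.prop_two == pytest.approx(0.25)

    def test_monomorphic_zeros(self):
        props = genotype_proportions(_panel([0, 0, 0, 0]), _panel([0]).genotypes.snps[0])
        assert (props.prop_one, props.prop_two) == (0.0, 0.0)

    def test_called_samples_only(self):
        props = genotype_proportions(
            _panel([0, 1, np.nan, 2]), _panel([0]).genotypes.snps[0]
        )
        assert props.prop_one == pytest.approx(1 / 3)
        assert props.prop_two == pytest.approx(1 / 3)

    def test_absent_snp_raises(self):
        stranger = SNPRecord("rsX", "2", 999, "A", "G")
        with pytest.raises(AbsentFromPanelError):
            genotype_proportions(_panel([0, 1, 2]), stranger)


class TestAdjustmentFactor:
    @pytest.mark.parametrize(
        "beta, p1, p2, expected",
        [
            (0.5, 0.5, 0.25, 0.5),
            (0.0, 0.9, 0.05, 0.0),
            (1.0, 0.0, 0.0, 0.0),
            (-2.0, 0.25, 0.5, -2.0 * 1.25),
        ],
    )
    def test_expected_dosage_times_beta(self, beta, p1, p2, expected):
        props = PanelProportions("rs1", p1, p2)
        assert adjustment_factor(beta, props) == pytest.approx(expected)


def _cohort(dosages, snps=None):
    dosages = np.asarray(dosages, float)
    if snps is None:
        snps = [
            SNPRecord(f"rs{j + 1}", "1", (j + 1) * 100, "A", "G")
            for j in range(dosages.shape[1])
        ]
    return GenotypeMatrix([f"s{i}" for i in range(dosages.shape[0])], snps, dosages)


class TestScoreEgenscore:
    def _model(self, weights):
        return EqtlModel("G", "egenscore", weights)

    def test_direct_evaluation(self):
        model = self._model([ModelWeight(SNPRecord("rs1", "1", 100, "A", "G"), 1.0, 0.5)])
        out = score_egenscore(model, _cohort([[2.0]]))
        assert out.score[0] == pytest.approx(1.5)

    def test_missing_genotype_contributes_zero(self):
        model = self._model([ModelWeight(SNPRecord("rs1", "1", 100, "A", "G"), 1.0, 0.5)])
        out = score_egenscore(model, _cohort([[np.nan]]))
        assert out.score[0] == 0.0

    def test_empty_model_scores_zero(self):
        out = score_egenscore(self._model([]), _cohort([[0.0], [1.0], [2.0]]))
        np.testing.assert_array_equal(out.score, 0.0)

    def test_model_snp_absent_from_cohort_contributes_zero(self):
        model = self._model(
            [
                ModelWeight(SNPRecord("rs1", "1", 100, "A", "G"), 2.0, 1.0),
                ModelWeight(SNPRecord("rs9", "9", 900, "A", "G"), 5.0, 1.0),
            ]
        )
        out = score_egenscore(model, _cohort([[1.0]]))
        assert out.score[0] == pytest.approx(2.0 * 1.0 - 1.0)

    def test_all_missing_sample_scores_exactly_zero(self, small_study, pipeline_config):
        geno, expr = align_samples(
            small_study.train_genotypes, small_study.train_expression
        )
        model = build_egenscore_model(
            small_study.genes[0], geno, expr, small_study.panel, pipeline_config
        )
        assert not model.is_null
        blank = GenotypeMatrix(
            ["ghost"],
            geno.snps,
            np.full((1, geno.n_snps), np.nan),
        )
        assert score_egenscore(model, blank).score[0] == 0.0

    def test_panel_centering_per_snp_term(self, small_study, pipeline_config):
        """Adjustments computed from the panel zero each SNP's mean
        contribution over that same panel."""
        geno, expr = align_samples(
            small_study.train_genotypes, small_study.train_expression
        )
        panel = small_study.panel
        model = build_egenscore_model(
            small_study.genes[0], geno, expr, panel, pipeline_config
        )
        assert not model.is_null
        for w in model.weights:
            d = panel.dosages_for(w.snp)
            term = w.beta * d - w.adjustment
            assert abs(term.mean()) < 1e-12

    def test_additive_over_snp_subsets(self, small_study, pipeline_config):
        geno, expr = align_samples(
            small_study.train_genotypes, small_study.train_expression
        )
        model = build_egenscore_model(
            small_study.genes[0], geno, expr, small_study.panel, pipeline_config
        )
        assert len(model.weights) >= 2
        half = len(model.weights) // 2
        m1 = EqtlModel("G", "egenscore", model.weights[:half])
        m2 = EqtlModel("G", "egenscore", model.weights[half:])
        total = score_egenscore(model, small_study.external_genotypes).score
        parts = (
            score_egenscore(m1, small_study.external_genotypes).score
            + score_egenscore(m2, small_study.external_genotypes).score
        )
        np.testing.assert_allclose(total, parts, atol=1e-12)

    def test_matches_naive_per_sample_loop(self, rng):
        n, k = 25, 6
        dosage = rng.integers(0, 3, size=(n, k)).astype(float)
        dosage[rng.random((n, k)) < 0.2] = np.nan
        cohort = _cohort(dosage)
        weights = [
            ModelWeight(cohort.snps[j], float(rng.standard_normal()), float(rng.random()))
            for j in range(k)
        ]
        model = EqtlModel("G", "egenscore", weights)
        fast = score_egenscore(model, cohort).score
        slow = np.zeros(n)
        for i in range(n):
            for w in weights:
                j = cohort.locus_column(w.snp.chrom, w.snp.pos)
                d = cohort.dosage[i, j]
                if not np.isnan(d):
                    slow[i] += w.beta * d - w.adjustment
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestBuildModel:
    def test_no_nominal_snp_yields_null_model(self, small_study):
        geno, expr = align_samples(
            small_study.train_genotypes, small_study.train_expression
        )
        strict = PipelineConfig(assoc_p_threshold=1e-30, seed=0)
        model = build_egenscore_model(
            small_study.genes[0], geno, expr, small_study.panel, strict
        )
        assert model.is_null
        assert model.framework == "egenscore"

    def test_duplicate_snps_clumped_to_one(self):
        rng = np.random.default_rng(42)
        n = 200
        d = rng.integers(0, 3, size=n).astype(float)
        snps = [
            SNPRecord("rs1", "1", 100, "A", "G"),
            SNPRecord("rs2", "1", 200, "A", "G"),
        ]
        cohort = GenotypeMatrix(
            [f"s{i}" for i in range(n)], snps, np.column_stack([d, d])
        )
        panel_d = rng.integers(0, 3, size=100).astype(float)
        panel = ReferencePanel(
            GenotypeMatrix(
                [f"p{i}" for i in range(100)], snps, np.column_stack([panel_d, panel_d])
            )
        )
        from egenscore.datatypes import ExpressionMatrix
        from egenscore.datatypes import GeneRecord

        y = 0.8 * d + rng.standard_normal(n) * 0.5
        expr = ExpressionMatrix(["G"], cohort.sample_ids, y[None, :])
        gene = GeneRecord("G", "1", 100, 300)
        model = build_egenscore_model(gene, cohort, expr, panel, PipelineConfig(seed=0))
        assert len(model.weights) == 1

    def test_strong_causal_snp_recovered_with_correct_sign(self):
        cfg = SimConfig(
            n_train=500, n_panel=200, n_external=10, n_genes=1,
            snps_per_gene=50, block_size=5, h2=0.8, n_causal=1, seed=21,
        )
        study = simulate_study(cfg)
        gene = study.genes[0]
        truth = study.truth.genes[gene.gene_id]
        geno, expr = align_samples(study.train_genotypes, study.train_expression)
        model = build_egenscore_model(gene, geno, expr, study.panel, PipelineConfig(seed=1))
        weights = {w.snp.snp_id: w.beta for w in model.weights}
        causal_id = truth.causal_snp_ids[0]
        true_beta = truth.effects[0]
        # the causal SNP (or a near-perfect proxy) must carry the signal;
        # require the causal SNP itself to survive with the right sign
        assert causal_id in weights
        assert np.sign(weights[causal_id]) == np.sign(true_beta)
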