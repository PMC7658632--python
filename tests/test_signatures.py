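import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myelospat.io_model import ExpressionMatrix
from myelospat.signatures import (
    GeneSignature,
    correlate_genes_with_parameter,
    derive_distance_signature,
    permutation_test,
    score_gene_set,
    score_signed_signature,
)
from myelospat.synthetic import SyntheticCohortConfig, simulate_expression


def _matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples))


class TestScoreGeneSet:
    def test_top_two_of_six_genes_score_max(self):
        # set genes rank 5 and 6 of 6 -> U = 8 = n1·n2, r_rb = 1, scaled = 10
        expr = _matrix(np.array([[6.0], [5.0], [1.0], [2.0], [3.0], [4.0]]))
        score = score_gene_set(expr, {"G0", "G1"})
        assert score.raw.iloc[0] == pytest.approx(1.0)
        assert score.scaled.iloc[0] == pytest.approx(10.0)

    def test_interleaved_set_scores_zero(self):
        # set genes at ranks 2 and 5 of 6 -> U = n1·n2/2 -> r_rb = 0
        expr = _matrix(np.array([[2.0], [5.0], [1.0], [3.0], [4.0], [6.0]]))
        score = score_gene_set(expr, {"G0", "G1"})
        assert score.raw.iloc[0] == pytest.approx(0.0)

    def test_centered_scores_have_zero_median(self, rng):
        expr = _matrix(rng.normal(size=(50, 21)))
        score = score_gene_set(expr, {f"G{i}" for i in range(8)})
        assert score.centered.median() == 0.0

    def test_empty_intersection_names_genes(self, rng):
        expr = _matrix(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="XYZ"):
            score_gene_set(expr, {"XYZ"})

    def test_bounds_and_monotone_invariance(self, rng):
        """Scores depend only on within-sample ranks, so any monotone
        per-sample transform leaves them unchanged; raw scores stay in
        [-1, 1]."""
        expr = _matrix(rng.normal(size=(40, 12)))
        gene_set = {f"G{i}" for i in range(0, 40, 5)}
        base = score_gene_set(expr, gene_set)
        assert (base.scaled.abs() <= 10.0).all()
        warped = _matrix(np.exp(expr.values.to_numpy()) * 3.0 + 1.0)
        warped_score = score_gene_set(warped, gene_set)
        pd.testing.assert_series_equal(base.raw, warped_score.raw)


class TestSignedSignature:
    def test_extremal_sample_scores_highest(self, rng):
        n_samples = 10
        values = rng.normal(size=(20, n_samples))
        # sample 0: positive genes on top, negative genes at the bottom
        values[:5, 0] = 100.0 + np.arange(5)
        values[5:10, 0] = -100.0 - np.arange(5)
        expr = _matrix(values)
        sig = GeneSignature(
            name="sig",
            positive_genes={f"G{i}" for i in range(5)},
            negative_genes={f"G{i}" for i in range(5, 10)},
        )
        scores = score_signed_signature(expr, sig)
        assert scores.idxmax() == "S0"

    def test_identical_rank_profiles_cancel(self):
        # positive and negative genes tie rank-for-rank in every sample
        values = np.array([[1.0, 5.0], [1.0, 5.0], [3.0, 2.0], [4.0, 1.0]])
        expr = _matrix(values)
        sig = GeneSignature(name="sig", positive_genes={"G0"}, negative_genes={"G1"})
        scores = score_signed_signature(expr, sig)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_one_sided_signature_degrades_to_single_set(self, rng):
        expr = _matrix(rng.normal(size=(30, 8)))
        sig = GeneSignature(name="pos_only", positive_genes={"G1", "G2", "G3"})
        scores = score_signed_signature(expr, sig)
        expected = score_gene_set(expr, {"G1", "G2", "G3"}).centered
        assert np.allclose(scores.to_numpy(), expected.to_numpy())

    def test_empty_signature_errors(self, rng):
        expr = _matrix(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            score_signed_signature(expr, GeneSignature(name="empty", positive_genes=set()))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            GeneSignature(name="bad", positive_genes={"G1"}, negative_genes={"G1"})

    def test_signature_tsv_roundtrip(self, tmp_path):
        sig = GeneSignature(
            name="sig", positive_genes={"A", "B"}, negative_genes={"C"}, cutoff=0.4
        )
        sig.to_tsv(tmp_path / "sig.tsv")
        back = GeneSignature.from_tsv(tmp_path / "sig.tsv", name="sig")
        assert back.positive_genes == sig.positive_genes
        assert back.negative_genes == sig.negative_genes


class TestGeneCorrelation:
    def test_monotone_gene_has_r_one(self, rng):
        param = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0], index=[f"S{j}" for j in range(5)])
        values = np.vstack([param.to_numpy(), -param.to_numpy(), rng.normal(size=5)])
        expr = _matrix(values, samples=list(param.index))
        r = correlate_genes_with_parameter(expr, param)
        assert r["G0"] == pytest.approx(1.0)
        assert r["G1"] == pytest.approx(-1.0)

    def test_constant_parameter_errors(self, rng):
        expr = _matrix(rng.normal(size=(4, 6)))
        param = pd.Series(1.0, index=expr.samples)
        with pytest.raises(ValueError, match="constant"):
            correlate_genes_with_parameter(expr, param)

    def test_missing_samples_dropped_pairwise(self, rng):
        expr = _matrix(rng.normal(size=(4, 8)))
        param = pd.Series(rng.normal(size=8), index=expr.samples)
        param.iloc[0] = np.nan
        r_full = correlate_genes_with_parameter(expr, param)
        sub = ExpressionMatrix(values=expr.values.iloc[:, 1:])
        r_sub = correlate_genes_with_parameter(sub, param.iloc[1:])
        assert np.allclose(r_full.to_numpy(), r_sub.to_numpy())

    def test_matches_scipy_spearman(self, rng):
        expr = _matrix(rng.normal(size=(10, 30)))
        param = pd.Series(rng.normal(size=30), index=expr.samples)
        r = correlate_genes_with_parameter(expr, param)
        for g in ("G0", "G5", "G9"):
            ref = stats.spearmanr(expr.values.loc[g], param).statistic
            assert r[g] == pytest.approx(ref, abs=1e-12)

    def test_planted_copula_correlation_recovered(self, rng):
        cfg = SyntheticCohortConfig(n_genes=3, planted_rho={"G0000": 0.6})
        estimates = []
        for seed in range(30):
            param = pd.Series(rng.normal(size=80), index=[f"S{j}" for j in range(80)])
            expr = simulate_expression(param, cfg, seed)
            estimates.append(correlate_genes_with_parameter(expr, param)["G0000"])
        assert np.mean(estimates) == pytest.approx(0.6, abs=0.1)


class TestDeriveSignature:
    def test_threshold_rule(self):
        r = pd.Series({"g1": 0.5, "g2": -0.45, "g3": 0.2})
        sig = derive_distance_signature(r, cutoff=0.4)
        assert sig.positive_genes == {"g1"}
        assert sig.negative_genes == {"g2"}

    def test_cutoff_is_strict(self):
        r = pd.Series({"g1": 0.4, "g2": -0.4})
        with pytest.warns(UserWarning):
            sig = derive_distance_signature(r, cutoff=0.4)
        assert sig.size == 0


class TestPermutationTest:
    def test_self_correlation_gives_p_zero(self, rng):
        expr = _matrix(rng.normal(size=(100, 20)))
        sig = GeneSignature(
            name="sig",
            positive_genes={f"G{i}" for i in range(6)},
            negative_genes={f"G{i}" for i in range(6, 12)},
        )
        res = permutation_test(expr, sig, sig, n_permutations=200, seed=1)
        assert res.observed_correlation == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_reproducible_given_seed(self, rng):
        expr = _matrix(rng.normal(size=(80, 15)))
        sig = GeneSignature(name="sig", positive_genes={f"G{i}" for i in range(8)})
        a = permutation_test(expr, sig, "G70", n_permutations=300, seed=42)
        b = permutation_test(expr, sig, "G70", n_permutations=300, seed=42)
        assert a.p_value == b.p_value
        assert a.n_exceed == b.n_exceed
        assert a.observed_correlation == b.observed_correlation

    def test_absent_sgoi_errors(self, rng):
        expr = _matrix(rng.normal(size=(10, 5)))
        sig = GeneSignature(name="sig", positive_genes={"G0", "G1"})
        with pytest.raises(KeyError):
            permutation_test(expr, sig, "NOPE", n_permutations=10, seed=0)
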