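import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spliceome as sp
from spliceome.errors import InsufficientDataError, UnknownIdError


def brute_force_dominance(matrix, annotation, samples, theta, tau, rule, group_key):
    """Independent double-loop oracle for summarize_dominance."""
    rows = []
    for gene in annotation["gene_id"].unique():
        tx = [t for t in annotation.index if annotation.loc[t, "gene_id"] == gene]
        n_expr = 0
        for t in tx:
            vals = matrix.loc[t]
            if rule == "mean_tpm":
                if vals.mean() > tau:
                    n_expr += 1
            elif any(v > tau for v in vals):
                n_expr += 1
        dominant = set()
        group_dominant = set()
        groups = {}
        for s in matrix.columns:
            total = sum(matrix.loc[t, s] for t in tx)
            if total <= 0:
                continue
            for t in tx:
                frac = matrix.loc[t, s] / total
                if frac > theta:
                    dominant.add(t)
                if group_key is not None:
                    g = samples.loc[s, group_key]
                    groups.setdefault((t, g), []).append(frac)
        if group_key is not None:
            for (t, g), fr in groups.items():
                if np.mean(fr) > theta:
                    group_dominant.add(t)
        rows.append((gene, n_expr, len(dominant), len(group_dominant)))
    return rows


class TestComputeUsage:
    def test_normalization_and_undefined(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        assert usage.fractions.loc["T1", "S1"] == pytest.approx(0.8)
        assert usage.fractions.loc["T3", "S2"] == pytest.approx(0.05)
        # zero-total gene is undefined everywhere
        m2 = pd.DataFrame(
            [[3.0, 0.0], [1.0, 0.0]],
            index=pd.Index(["A", "B"], name="transcript_id"),
            columns=["S1", "S2"],
        )
        a2 = pd.DataFrame(
            {"gene_id": "G", "gene_symbol": "G", "biotype": "other", "protein_length_aa": np.nan},
            index=m2.index,
        )
        u2 = sp.compute_usage(m2, a2)
        assert u2.fractions["S1"].tolist() == pytest.approx([0.75, 0.25])
        assert u2.fractions["S2"].isna().all()

    def test_defined_fractions_sum_to_one(self, random_fixture):
        matrix, annotation, _ = random_fixture
        usage = sp.compute_usage(matrix, annotation)
        sums = usage.fractions.groupby(annotation["gene_id"]).sum(min_count=1)
        defined = usage.gene_totals > 0
        assert np.allclose(sums.to_numpy()[defined.to_numpy()], 1.0, atol=1e-9)

    def test_single_isoform_gene_fraction_one(self):
        m = pd.DataFrame([[4.2, 0.1]], index=pd.Index(["T"], name="transcript_id"), columns=["S1", "S2"])
        a = pd.DataFrame(
            {"gene_id": "G", "gene_symbol": "G", "biotype": "protein_coding", "protein_length_aa": 100.0},
            index=m.index,
        )
        u = sp.compute_usage(m, a)
        assert (u.fractions == 1.0).all().all()


class TestDominance:
    def test_toy_gene_counts(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        crit = sp.DominanceCriteria(fraction_threshold=0.5, expressed_tpm_floor=1.0)
        dom = sp.summarize_dominance(usage, matrix, None, crit).iloc[0]
        assert dom["n_sample_dominant"] == 2  # T1 in S1/S3, T2 in S2/S4
        assert dom["n_expressed_isoforms"] == 2  # mean TPM 5 and 4.125 pass, 0.875 fails
        assert dom["top_isoform_id"] == "T1"

    def test_high_threshold_no_dominant(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        crit = sp.DominanceCriteria(fraction_threshold=0.85)
        dom = sp.summarize_dominance(usage, matrix, None, crit).iloc[0]
        assert dom["n_sample_dominant"] == 0

    def test_matches_brute_force_oracle(self, random_fixture):
        matrix, annotation, samples = random_fixture
        usage = sp.compute_usage(matrix, annotation)
        crit = sp.DominanceCriteria(fraction_threshold=0.5, expressed_tpm_floor=1.0, group_key="tissue")
        dom = sp.summarize_dominance(usage, matrix, samples, crit)
        oracle = brute_force_dominance(matrix, annotation, samples, 0.5, 1.0, "mean_tpm", "tissue")
        got = list(
            dom[["gene_id", "n_expressed_isoforms", "n_sample_dominant", "n_group_dominant"]]
            .itertuples(index=False, name=None)
        )
        assert got == oracle

    def test_invariant_under_reorder_and_column_scaling(self, random_fixture):
        matrix, annotation, samples = random_fixture
        crit = sp.DominanceCriteria()
        base = sp.summarize_dominance(sp.compute_usage(matrix, annotation), matrix, None, crit)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.columns)
        scaled = matrix[perm] * rng.uniform(0.5, 3.0, size=matrix.shape[1])
        again = sp.summarize_dominance(sp.compute_usage(scaled, annotation), scaled, None, crit)
        pd.testing.assert_frame_equal(
            base.drop(columns="n_expressed_isoforms"), again.drop(columns="n_expressed_isoforms")
        )

    def test_strict_threshold_single_dominant_per_sample(self, random_fixture):
        matrix, annotation, _ = random_fixture
        usage = sp.compute_usage(matrix, annotation)
        frac = usage.fractions
        over = (frac > 0.5).groupby(annotation["gene_id"]).sum()
        assert (over.to_numpy() <= 1).all()

    def test_unknown_group_key_raises(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        with pytest.raises(UnknownIdError):
            sp.summarize_dominance(
                usage, matrix, None, sp.DominanceCriteria(group_key="nonexistent")
            )


class TestRecurrence:
    def test_toy_gene_strict_fraction(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        crit = sp.RecurrenceCriteria(fraction_threshold=0.2, min_samples=3, mean_tpm_floor=1.0)
        rec = sp.recurrent_isoforms(usage, matrix, crit).set_index("transcript_id")
        # T1 qualifies in S1/S2/S3 only: S4 usage is exactly 0.2, excluded by strict >
        assert sorted(rec.index) == ["T1", "T2"]
        assert rec.loc["T1", "n_qualifying_samples"] == 3
        assert rec.loc["T2", "n_qualifying_samples"] == 3

    def test_min_samples_exceeds_n(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        rec = sp.recurrent_isoforms(
            usage, matrix, sp.RecurrenceCriteria(fraction_threshold=0.2, min_samples=99)
        )
        assert rec.empty

    def test_vacuous_thresholds_keep_everything_expressed(self, toy_gene):
        matrix, annotation = toy_gene
        usage = sp.compute_usage(matrix, annotation)
        rec = sp.recurrent_isoforms(
            usage, matrix, sp.RecurrenceCriteria(fraction_threshold=0.0, min_samples=1, mean_tpm_floor=0.0)
        )
        assert sorted(rec["transcript_id"]) == ["T1", "T2", "T3"]

    def test_matches_brute_force_oracle(self, random_fixture):
        matrix, annotation, _ = random_fixture
        usage = sp.compute_usage(matrix, annotation)
        crit = sp.RecurrenceCriteria(fraction_threshold=0.2, min_samples=5, mean_tpm_floor=1.0)
        rec = sp.recurrent_isoforms(usage, matrix, crit)
        expected = []
        for t in matrix.index:
            gene = annotation.loc[t, "gene_id"]
            tx = annotation.index[annotation["gene_id"] == gene]
            n_qual = 0
            for s in matrix.columns:
                total = matrix.loc[tx, s].sum()
                if total > 0 and matrix.loc[t, s] / total > 0.2:
                    n_qual += 1
            if n_qual >= 5 and matrix.loc[t].mean() >= 1.0:
                expected.append((t, n_qual))
        assert list(rec[["transcript_id", "n_qualifying_samples"]].itertuples(index=False, name=None)) == expected


class TestPairAssociation:
    def test_identical_vectors(self):
        m = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4]], index=pd.Index(["A", "B"]), columns=list("wxyz")
        )
        res = sp.pair_association(m, "A", "B")
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_vector_degenerate(self):
        m = pd.DataFrame([[1.0, 2, 3], [5.0, 5, 5]], index=pd.Index(["A", "B"]), columns=list("xyz"))
        res = sp.pair_association(m, "A", "B")
        assert res.degenerate and res.r_squared == 0.0

    def test_hand_computed_r_squared(self):
        # a=(1,2,3), b=(1,3,2): Pearson r = 0.5 so r^2 = 0.25
        m = pd.DataFrame([[1.0, 2, 3], [1.0, 3, 2]], index=pd.Index(["A", "B"]), columns=list("xyz"))
        res = sp.pair_association(m, "A", "B")
        assert res.r_squared == pytest.approx(0.25, abs=1e-12)

    def test_errors(self):
        m = pd.DataFrame([[1.0, 2], [3.0, 4]], index=pd.Index(["A", "B"]), columns=["x", "y"])
        with pytest.raises(UnknownIdError):
            sp.pair_association(m, "A", "missing")
        with pytest.raises(InsufficientDataError):
            sp.pair_association(m, "A", "B")


class TestGeneCorrelation:
    def test_identical_and_reversed_profiles(self):
        m = pd.DataFrame(
            [[1.0, 2, 3], [2.0, 4, 6], [3.0, 2, 1]],
            index=pd.Index(["A", "B", "C"], name="transcript_id"),
            columns=list("xyz"),
        )
        ann = pd.DataFrame(
            {"gene_id": ["GA", "GB", "GC"], "gene_symbol": ["GA", "GB", "GC"],
             "biotype": "other", "protein_length_aa": np.nan},
            index=m.index,
        )
        corr = sp.gene_correlation(m, ann, method="spearman")
        assert corr.loc["GA", "GB"] == pytest.approx(1.0)
        assert corr.loc["GA", "GC"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_rank_then_pearson_oracle(self, random_fixture):
        matrix, annotation, _ = random_fixture
        corr = sp.gene_correlation(matrix, annotation, level="gene_sum", method="spearman")
        profiles = matrix.groupby(annotation["gene_id"], sort=False).sum()
        ranks = np.apply_along_axis(stats.rankdata, 1, profiles.to_numpy())
        oracle = np.corrcoef(ranks)
        assert np.allclose(corr.loc[profiles.index, profiles.index].to_numpy(), oracle, atol=1e-12)
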