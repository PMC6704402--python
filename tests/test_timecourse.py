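"""Normalization, the DE rule, transform, clustering and peak phases."""

import numpy as np
import pandas as pd
import pytest

from glaucokit import timecourse as tc
from glaucokit.synthetic_data import (
    TIMEPOINTS,
    TimecourseConfig,
    gen_timecourse_counts,
)


def _matrix(rows, genes=None):
    """Genes x 18 samples matrix from per-timepoint values (replicated)."""
    genes = genes or [f"g{i}" for i in range(len(rows))]
    cols = [f"{tp}_r{r}" for tp in TIMEPOINTS for r in (1, 2, 3)]
    data = [[v for v in row for _ in range(3)] for row in rows]
    return pd.DataFrame(data, index=genes, columns=cols)


class TestSizeFactors:
    def test_hand_computation(self):
        counts = pd.DataFrame(
            [[10, 20], [30, 60], [50, 100]], columns=["s1", "s2"]
        )
        f = tc.size_factors(counts)
        assert f["s1"] == pytest.approx(0.7071, abs=1e-4)
        assert f["s2"] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_columns_give_unity(self):
        counts = pd.DataFrame([[5, 5, 5], [9, 9, 9]], columns=list("abc"))
        assert tc.size_factors(counts).tolist() == pytest.approx([1, 1, 1])

    def test_scale_equivariance_of_relative_factors(self):
        # doubling one sample's counts doubles its factor relative to the
        # others (the geometric-mean reference itself rescales, so absolute
        # factors shift by a common constant)
        counts = pd.DataFrame(
            np.random.default_rng(0).integers(1, 100, size=(50, 4)),
            columns=list("abcd"),
        )
        f = tc.size_factors(counts)
        doubled = counts.copy()
        doubled["b"] *= 2
        f2 = tc.size_factors(doubled)
        assert f2["b"] / f2["a"] == pytest.approx(2 * f["b"] / f["a"])
        assert f2["c"] / f2["a"] == pytest.approx(f["c"] / f["a"])

    def test_no_common_nonzero_gene_errors(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            tc.size_factors(counts)

    def test_planted_factors_recovered(self):
        sfs = tuple(np.tile([0.7071, 1.4142, 1.0], 6))
        counts, truth = gen_timecourse_counts(
            TimecourseConfig(seed=5, n_de=100, n_flat=900, size_factors=sfs)
        )
        est = tc.size_factors(counts).to_numpy()
        ratio = est / np.array(sfs)
        assert np.all(np.abs(ratio - 1) < 0.02)


class TestDeGenes:
    def test_peaked_annotated_gene_is_de(self):
        counts = _matrix(
            [
                (10, 40, 10, 10, 10, 10),
                (100, 100, 100, 100, 100, 100),
                (50, 50, 50, 50, 50, 50),
                (70, 70, 70, 70, 70, 70),
            ]
        )
        res = {r.gene: r for r in tc.de_genes(counts, {g: True for g in counts.index})}
        # size factors are 1 (three constant genes dominate the median)
        assert res["g0"].max_abs_log2fc == pytest.approx(np.log2(41 / 11), abs=1e-6)
        assert res["g0"].is_de
        assert not res["g1"].is_de  # flat

    def test_annotation_gate(self):
        counts = _matrix(
            [
                (10, 40, 10, 10, 10, 10),
                (100, 100, 100, 100, 100, 100),
                (50, 50, 50, 50, 50, 50),
            ]
        )
        ann = {"g0": False, "g1": True, "g2": True}
        res = {r.gene: r for r in tc.de_genes(counts, ann)}
        assert res["g0"].max_abs_log2fc >= 1.5
        assert not res["g0"].is_de  # fold change alone is not enough

    def test_downregulation_counts(self):
        counts = _matrix(
            [
                (400, 400, 40, 400, 400, 400),
                (100, 100, 100, 100, 100, 100),
                (50, 50, 50, 50, 50, 50),
            ]
        )
        res = {r.gene: r for r in tc.de_genes(counts, {g: True for g in counts.index})}
        assert res["g0"].is_de

    def test_replicate_order_invariance(self):
        counts, truth = gen_timecourse_counts(
            TimecourseConfig(seed=3, n_de=50, n_flat=50)
        )
        shuffled = counts[list(np.random.default_rng(1).permutation(counts.columns))]
        a = tc.de_genes(counts, truth.annotations.to_dict())
        b = tc.de_genes(shuffled, truth.annotations.to_dict())
        assert [(r.gene, r.is_de) for r in a] == [(r.gene, r.is_de) for r in b]

    def test_missing_timepoint_errors(self):
        counts = _matrix([(10, 40, 10, 10, 10, 10)])
        dropped = counts[[c for c in counts.columns if not c.startswith("5AD")]]
        with pytest.raises(ValueError, match="5AD"):
            tc.de_genes(dropped, {"g0": True})


class TestVstTransform:
    def test_values(self):
        counts = pd.DataFrame([[0, 7]], columns=["a", "b"])
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        out = tc.vst_like_transform(counts, f)
        assert out.iloc[0].tolist() == [0.0, 3.0]

    def test_variance_grows_sublinearly_with_mean(self):
        rng = np.random.default_rng(0)
        disp = 0.05
        raw_var, vst_var = [], []
        for mean in (50, 500, 5000):
            n = 1 / disp
            x = rng.negative_binomial(n, n / (n + mean), size=(200, 18))
            df = pd.DataFrame(
                x, columns=[f"{tp}_r{r}" for tp in TIMEPOINTS for r in (1, 2, 3)]
            )
            f = pd.Series(1.0, index=df.columns)
            raw_var.append(x.var())
            vst_var.append(tc.vst_like_transform(df, f).to_numpy().var())
        assert raw_var[2] / raw_var[0] > 100  # raw variance explodes with mean
        assert vst_var[2] / vst_var[0] < 2  # transformed variance is flat-ish


class TestClustering:
    def test_two_planted_shapes_fully_separated(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        shape_a = np.array([1, 8, 1, 1, 1, 1], dtype=float)
        shape_b = np.array([8, 1, 1, 8, 1, 1], dtype=float)
        rows = []
        truth = []
        for i in range(100):
            base = shape_a if i < 50 else shape_b
            rows.append(base * 10 + rng.normal(0, 0.5, 6))
            truth.append(i < 50)
        means = pd.DataFrame(
            rows, columns=list(TIMEPOINTS),
            index=[f"g{i:03d}" for i in range(100)],
        )
        labels = tc.cluster_profiles(means, n_clusters=2)
        assert adjusted_rand_score(truth, labels.loc[means.index]) == 1.0

    def test_duplicated_gene_is_one_cluster(self):
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6]] * 10, columns=list(TIMEPOINTS),
            index=[f"g{i}" for i in range(10)],
        )
        labels = tc.cluster_profiles(means, height=0.1)
        assert labels.nunique() == 1

    def test_too_many_clusters_errors(self):
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6]] * 3, columns=list(TIMEPOINTS),
            index=list("abc"),
        )
        with pytest.raises(ValueError):
            tc.cluster_profiles(means, n_clusters=5)

    def test_exactly_one_cut_criterion(self):
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6]] * 3, columns=list(TIMEPOINTS),
            index=list("abc"),
        )
        with pytest.raises(ValueError):
            tc.cluster_profiles(means)
        with pytest.raises(ValueError):
            tc.cluster_profiles(means, n_clusters=2, height=1.0)


class TestPeakPhase:
    def test_pcna_like_peak(self):
        call = tc.peak_phase([10, 80, 20, 10, 10, 10])
        assert call.peak == "8ALO" and not call.declining_from_start

    def test_cycb_like_peak(self):
        assert tc.peak_phase([10, 20, 80, 15, 10, 10]).peak == "14ALO"

    def test_declining_from_start(self):
        call = tc.peak_phase([100, 60, 40, 20, 10, 5])
        assert call.peak == "1ALO" and call.declining_from_start

    def test_constant_profile_ties_to_first_and_flags_flat(self):
        call = tc.peak_phase([7, 7, 7, 7, 7, 7])
        assert call.peak == "1ALO" and call.flat and call.declining_from_start

    def test_planted_noiseless_profile(self):
        counts, truth = gen_timecourse_counts(
            TimecourseConfig(seed=2, n_de=20, n_flat=0, up_fraction=1.0)
        )
        for g in truth.per_gene.index:
            call = tc.peak_phase(truth.profiles.loc[g])
            assert call.peak == truth.per_gene.loc[g, "peak_time"]
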