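"""Frequency, classification, NRMSD, scaling, PCA and rank statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panepi.stats import (FrequencyTable, methylation_frequency,
                          classify_pan_epigenome, nrmsd, nrmsd_matrix,
                          scale_matrix, pca_contributions, kruskal_dunn)


def occ_table(rows):
    return pd.DataFrame(rows, columns=["strain_id", "motif_label",
                                       "region", "replicon_class",
                                       "methylated"])


class TestFrequency:
    def test_simple_fraction(self):
        occ = occ_table([("s1", "GANTC", "CDS", "chromosome", k < 3)
                         for k in range(10)])
        ft = methylation_frequency(occ, ("strain_id", "motif_label"))
        row = ft.data.iloc[0]
        assert (row.methylated, row.total, row.frequency) == (3, 10, 0.3)
        assert row.region == "ALL" and row.replicon_class == "ALL"

    def test_zero_total_emitted_missing(self):
        occ = occ_table([("s1", "GANTC", "CDS", "chromosome", True)])
        universe = pd.DataFrame({"strain_id": ["s1", "s1"],
                                 "motif_label": ["GANTC", "CCCGGG"]})
        ft = methylation_frequency(occ, ("strain_id", "motif_label"),
                                   universe=universe)
        missing = ft.data.set_index("motif_label").loc["CCCGGG"]
        assert missing.total == 0 and np.isnan(missing.frequency)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            methylation_frequency(occ_table([]), ("strand",))

    def test_region_totals_partition_genome_totals(self, mini_panel):
        occ = mini_panel.occurrences
        by_region = methylation_frequency(
            occ, ("strain_id", "motif_label", "region")).data
        genome = methylation_frequency(
            occ, ("strain_id", "motif_label")).data
        summed = (by_region.groupby(["strain_id", "motif_label"],
                                    observed=True)[["methylated", "total"]]
                  .sum().reset_index())
        merged = summed.merge(genome, on=["strain_id", "motif_label"],
                              suffixes=("_r", "_g"))
        assert (merged.methylated_r == merged.methylated_g).all()
        assert (merged.total_r == merged.total_g).all()

    def test_tsv_round_trip(self, tmp_path):
        occ = occ_table([("s1", "GANTC", "CDS", "chromosome", True),
                         ("s1", "GANTC", "tIG", "chromosome", False)])
        ft = methylation_frequency(occ, ("strain_id", "motif_label",
                                         "region"))
        p = tmp_path / "f.tsv"
        ft.to_tsv(p)
        back = FrequencyTable.from_tsv(p)
        pd.testing.assert_frame_equal(back.data, ft.data)
        assert set(back.group_by) == set(ft.group_by)


def freq_table(counts):
    """counts: {(strain, motif): (methylated, total)}"""
    rows = [(s, m, "ALL", "ALL", k, n, k / n if n else np.nan)
            for (s, m), (k, n) in counts.items()]
    return FrequencyTable(
        data=pd.DataFrame(rows, columns=["strain_id", "motif_label",
                                         "region", "replicon_class",
                                         "methylated", "total",
                                         "frequency"]),
        group_by=("strain_id", "motif_label"))


class TestPanEpigenome:
    def test_core_shell_exclusive_absent(self):
        strains = [f"s{i}" for i in range(5)]
        counts = {}
        for s in strains:
            counts[(s, "CORE")] = (10, 100)
            counts[(s, "SHELL")] = (10, 100) if s in ("s0", "s1") else (0, 100)
            counts[(s, "EXCL")] = (10, 100) if s == "s0" else (0, 100)
            counts[(s, "NONE")] = (0, 100)
        cls = classify_pan_epigenome(freq_table(counts))
        labels = dict(zip(cls.labels.motif_label, cls.labels.label))
        assert labels == {"CORE": "core", "SHELL": "shell",
                          "EXCL": "exclusive", "NONE": "absent"}
        assert "no strain-exclusive" not in cls.summary()

    def test_min_frequency_threshold(self):
        counts = {("s0", "M"): (1, 1000), ("s1", "M"): (300, 1000)}
        cls = classify_pan_epigenome(freq_table(counts), min_frequency=0.01)
        assert cls.labels.iloc[0].label == "exclusive"

    def test_min_count_floor(self):
        counts = {("s0", "M"): (3, 1000), ("s1", "M"): (300, 1000)}
        cls = classify_pan_epigenome(freq_table(counts), min_count=5)
        assert cls.labels.iloc[0].label == "exclusive"

    def test_requires_genome_wide_grouping(self):
        ft = freq_table({("s0", "M"): (1, 2)})
        ft.group_by = ("strain_id", "motif_label", "region")
        with pytest.raises(ValueError):
            classify_pan_epigenome(ft)


class TestNrmsd:
    def test_constant_vector_zero(self):
        assert nrmsd([0.5, 0.5, 0.5]) == 0.0

    def test_zero_one_pair(self):
        assert nrmsd([0.0, 1.0]) == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nrmsd([1.0])

    def test_zero_mean_with_spread_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(nrmsd([-1.0, 1.0]))

    def test_range_normalizer(self):
        # RMSD of (0,1) is 0.5; range is 1
        assert nrmsd([0.0, 1.0], normalizer="range") == pytest.approx(0.5)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20),
           st.floats(0.1, 100.0))
    @settings(deadline=None)
    def test_scale_invariance(self, values, c):
        a = nrmsd(values)
        b = nrmsd([c * v for v in values])
        assert a == pytest.approx(b, rel=1e-9)

    def test_matrix_low_variability_motif_smallest(self, mini_panel):
        """A motif methylated at ~0.99 everywhere varies least across
        strains, mirroring the near-invariant cell-cycle motif."""
        from panepi.stats import methylation_frequency
        ft = methylation_frequency(mini_panel.occurrences,
                                   ("strain_id", "motif_label", "region"))
        mat = nrmsd_matrix(ft)
        means = mat.mean(axis=1).dropna()
        assert means.idxmin() == "GANTC"


class TestScaleMatrix:
    def test_row_zscore(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]])
        out = scale_matrix(m, "row")
        assert list(out.iloc[0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_with_warning(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            out = scale_matrix(m, "row")
        assert list(out.iloc[0]) == [0.0, 0.0, 0.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((4, 6)))
        once = scale_matrix(m, "column")
        twice = scale_matrix(once, "column")
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-12)


class TestPca:
    def test_correlated_columns_pc1_everything(self):
        rng = np.random.default_rng(1)
        x = rng.random(10)
        m = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_contributions(m)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((6, 4)))
        res = pca_contributions(m)
        np.testing.assert_allclose(res.contributions.sum(axis=0), 100.0,
                                   atol=1e-9)

    def test_matches_direct_eigendecomposition(self):
        """Loadings agree (up to sign) with an independent dense
        eigensolve of the hand-assembled covariance matrix."""
        m = pd.DataFrame([[2.0, 0.0, 1.0], [4.0, 1.0, 1.0],
                          [1.0, 3.0, 2.0], [3.0, 2.0, 0.0]],
                         columns=list("xyz"))
        res = pca_contributions(m, center=True, scale=False)
        X = m.to_numpy() - m.to_numpy().mean(axis=0)
        cov = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                cov[i, j] = (X[:, i] * X[:, j]).sum() / (len(X) - 1)
        w, v = np.linalg.eig(cov)
        order = np.argsort(w)[::-1]
        np.testing.assert_allclose(res.eigenvalues, w[order], atol=1e-12)
        np.testing.assert_allclose(np.abs(res.loadings.to_numpy()),
                                   np.abs(v[:, order]), atol=1e-12)

    def test_constant_column_with_scaling_named(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_contributions(m, scale=True)


class TestKruskalDunn:
    def test_hand_computed_z(self):
        res = kruskal_dunn({"A": [1, 2, 3], "B": [4, 5, 6]})
        z = res.table.iloc[0].z
        assert abs(z) == pytest.approx(3 / np.sqrt(7 / 3), abs=1e-9)

    def test_identical_groups(self):
        res = kruskal_dunn({"A": [1.0, 1.0], "B": [1.0, 1.0]})
        assert res.h_statistic == 0.0
        assert res.table.iloc[0].z == 0.0
        assert res.table.iloc[0].p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"A": [1, 2, 3]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_dunn({"A": [1.0], "B": []})

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        samples = {g: rng.normal(size=12) for g in "ABC"}
        res1 = kruskal_dunn(samples)
        res2 = kruskal_dunn({g: np.exp(v) for g, v in samples.items()})
        np.testing.assert_allclose(res1.table.z, res2.table.z, atol=1e-12)

    def test_tie_correction_reduces_variance(self):
        """With ties the rank variance shrinks, so |z| grows relative to
        the uncorrected statistic computed by hand."""
        res = kruskal_dunn({"A": [1, 1, 2], "B": [3, 3, 4]})
        ranks_a, ranks_b = [1.5, 1.5, 3], [4.5, 4.5, 6]
        n = 6
        tie_term = ((2 ** 3 - 2) * 2) / (12 * (n - 1))
        var = n * (n + 1) / 12 - tie_term
        expected = (np.mean(ranks_a) - np.mean(ranks_b)) \
            / np.sqrt(var * (2 / 3))
        assert res.table.iloc[0].z == pytest.approx(expected, abs=1e-12)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        samples = {g: rng.normal(loc=i, size=8)
                   for i, g in enumerate("ABCD")}
        res = kruskal_dunn(samples, p_adjust="holm")
        assert (res.table.p_adj >= res.table.p - 1e-15).all()
        assert (res.table.p_adj <= 1.0).all()
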