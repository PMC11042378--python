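"""Promoter summaries, correlation classification, fits, sequence tensors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methrna import (
    GeneModel,
    ManifestRow,
    SampleMeta,
    ValidationError,
    assign_loci,
    build_frame,
    build_sequence_tensors,
    correlation_distribution,
    gene_correlations,
    gene_linear_fit,
    paired_density_table,
    pair_samples,
    promoter_summary,
)

from conftest import make_matrix


def _make_frame(meth_rows, expr_rows, locus_specs, n_pairs):
    """locus_specs: list of (locus_id, gene_id, tss_distance)."""
    genes, manifest = [], []
    gene_ids = list(dict.fromkeys(g for _, g, _ in locus_specs)) + [
        g for g in expr_rows if g not in {g for _, g, _ in locus_specs}
    ]
    for i, g in enumerate(gene_ids):
        tss = 1_000_000 * (i + 1)
        genes.append(GeneModel(g, "1", tss, tss + 10_000, "+"))
    tss_of = {g.gene_id: g.tss for g in genes}
    for locus, gene, d in locus_specs:
        manifest.append(ManifestRow(locus, "1", tss_of[gene] + d))
    loci = assign_loci(manifest, genes)

    meth_samples = [f"m{i}" for i in range(n_pairs)]
    expr_samples = [f"e{i}" for i in range(n_pairs)]
    meth = make_matrix(
        np.array([meth_rows[l] for l, _, _ in locus_specs]),
        "methylation", features=[l for l, _, _ in locus_specs], samples=meth_samples,
    )
    expr = make_matrix(
        np.array([expr_rows[g] for g in expr_rows]),
        "expression", features=list(expr_rows), samples=expr_samples,
    )
    meta = []
    for i in range(n_pairs):
        meta += [
            SampleMeta(f"m{i}", f"p{i}", "t", "methylation"),
            SampleMeta(f"e{i}", f"p{i}", "t", "expression"),
        ]
    return build_frame(meth, expr, loci, pair_samples(meta))


class TestPromoterSummary:
    def test_median_of_promoter_betas(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.2] * 4, "cg2": [0.4] * 4, "cg3": [0.9] * 4},
            expr_rows={"gA": [10, 20, 30, 40]},
            locus_specs=[("cg1", "gA", -100), ("cg2", "gA", -200), ("cg3", "gA", -300)],
            n_pairs=4,
        )
        s = promoter_summary(frame, statistic="median")
        assert np.allclose(s["gA"], 0.4)
        s_mean = promoter_summary(frame, statistic="mean")
        assert np.allclose(s_mean["gA"], 0.5)

    def test_single_locus_identity(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.1, 0.7, 0.3]},
            expr_rows={"gA": [1, 2, 3]},
            locus_specs=[("cg1", "gA", -10)],
            n_pairs=3,
        )
        assert list(promoter_summary(frame)["gA"]) == [0.1, 0.7, 0.3]

    def test_non_promoter_loci_excluded_and_gene_flagged(self, caplog):
        frame = _make_frame(
            meth_rows={"cg1": [0.1] * 3},
            expr_rows={"gA": [1, 2, 3]},
            locus_specs=[("cg1", "gA", 500)],  # downstream: not promoter
            n_pairs=3,
        )
        with caplog.at_level("WARNING"):
            s = promoter_summary(frame)
        assert s["gA"].isna().all()
        assert "gA" in caplog.text

    def test_invalid_statistic(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.1] * 3}, expr_rows={"gA": [1, 2, 3]},
            locus_specs=[("cg1", "gA", -10)], n_pairs=3,
        )
        with pytest.raises(ValidationError, match="statistic"):
            promoter_summary(frame, statistic="max")


class TestGeneCorrelations:
    def test_perfect_anticorrelation_is_canonical(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.1, 0.2, 0.3, 0.4]},
            expr_rows={"gA": list(np.exp([4, 3, 2, 1]) - 1)},
            locus_specs=[("cg1", "gA", -10)], n_pairs=4,
        )
        rec = gene_correlations(promoter_summary(frame), frame).iloc[0]
        assert rec.r == pytest.approx(-1.0)
        assert rec.label == "canonical"

    def test_constant_summary_unclassified(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.5, 0.5, 0.5, 0.5]},
            expr_rows={"gA": [1, 2, 3, 4]},
            locus_specs=[("cg1", "gA", -10)], n_pairs=4,
        )
        rec = gene_correlations(promoter_summary(frame), frame).iloc[0]
        assert rec.label == "unclassified" and rec.reason == "constant input"

    def test_insufficient_pairs_unclassified(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.5, 0.1, 0.9]},
            expr_rows={"gA": [1, 2, 3]},
            locus_specs=[("cg1", "gA", -10)], n_pairs=3,
        )
        # knock out one pair's summary
        s = promoter_summary(frame)
        s.iloc[0, 0] = np.nan
        rec = gene_correlations(s, frame).iloc[0]
        assert rec.label == "unclassified" and rec.reason == "insufficient pairs"
        assert rec.n_pairs == 2

    def test_r_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        betas = rng.uniform(0.1, 0.9, 20)
        counts = rng.integers(1, 1000, 20).astype(float)
        frame = _make_frame(
            meth_rows={"cg1": betas}, expr_rows={"gA": counts},
            locus_specs=[("cg1", "gA", -10)], n_pairs=20,
        )
        rec = gene_correlations(promoter_summary(frame), frame).iloc[0]
        x, y = betas, np.log(counts + 1)
        r_direct = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert rec.r == pytest.approx(r_direct, abs=1e-12)
        # two-sided p from the exact t transform with n-2 df
        t = r_direct * np.sqrt(18 / (1 - r_direct**2))
        assert rec.p == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-6)

    def test_sign_agrees_with_linear_fit_slope(self):
        rng = np.random.default_rng(1)
        frames = _make_frame(
            meth_rows={"cg1": rng.uniform(0.1, 0.9, 10), "cg2": rng.uniform(0.1, 0.9, 10)},
            expr_rows={"gA": rng.integers(1, 100, 10), "gB": rng.integers(1, 100, 10)},
            locus_specs=[("cg1", "gA", -10), ("cg2", "gB", -20)], n_pairs=10,
        )
        s = promoter_summary(frames)
        recs = gene_correlations(s, frames).set_index("gene_id")
        fits = gene_linear_fit(s, frames).set_index("gene_id")
        for g in ("gA", "gB"):
            assert np.sign(recs.loc[g, "r"]) == np.sign(fits.loc[g, "slope"])
            assert fits.loc[g, "r_squared"] == pytest.approx(recs.loc[g, "r"] ** 2, abs=1e-10)


class TestDistributionAndDensity:
    def test_tallies_count_labels(self):
        records = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "n_pairs": [10] * 3,
                "r": [-0.9, -0.9, 0.9],
                "p": [1e-6] * 3,
                "q": [1e-6] * 3,
                "label": ["canonical", "canonical", "non_canonical"],
                "reason": [""] * 3,
            }
        )
        hist, tallies = correlation_distribution(records)
        assert tallies == {"n_canonical": 2, "n_non_canonical": 1, "n_unclassified": 0}
        assert hist["count"].sum() == 3
        assert len(hist) == 40  # bin width 0.05 over [-1, 1]

    def test_empty_records(self):
        hist, tallies = correlation_distribution(pd.DataFrame())
        assert hist["count"].sum() == 0
        assert tallies == {"n_canonical": 0, "n_non_canonical": 0, "n_unclassified": 0}

    def test_density_table_row_count_matches_complete_cells(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.1] * 4, "cg2": [0.2] * 4},
            expr_rows={"gA": [1, 2, 3, 4], "gB": [5, 6, 7, 8], "gC": [1, 1, 2, 2]},
            locus_specs=[("cg1", "gA", -10), ("cg2", "gB", -20)], n_pairs=4,
        )
        s = promoter_summary(frame)
        s.loc[s.index[0], "gA"] = np.nan
        table = paired_density_table(s, frame)
        # gC has no promoter summary at all; gA lost one pair
        expected = int(s.notna().to_numpy().sum())
        assert len(table) == expected == 7
        assert set(table.columns) == {
            "gene_id", "patient_id", "tissue", "promoter_summary", "log_expr"
        }


class TestLinearFit:
    def test_exact_line_recovered(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = -2 * x + 5
        frame = _make_frame(
            meth_rows={"cg1": x}, expr_rows={"gA": np.exp(y) - 1},
            locus_specs=[("cg1", "gA", -10)], n_pairs=4,
        )
        fit = gene_linear_fit(promoter_summary(frame), frame).iloc[0]
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_predictor_skipped(self):
        frame = _make_frame(
            meth_rows={"cg1": [0.5] * 4}, expr_rows={"gA": [1, 2, 3, 4]},
            locus_specs=[("cg1", "gA", -10)], n_pairs=4,
        )
        fit = gene_linear_fit(promoter_summary(frame), frame).iloc[0]
        assert np.isnan(fit.slope) and fit.reason == "constant predictor"


class TestSequenceTensors:
    def _frame(self, specs, n_pairs=3):
        rng = np.random.default_rng(2)
        meth_rows = {l: rng.uniform(0.1, 0.9, n_pairs) for l, _, _ in specs}
        return _make_frame(
            meth_rows=meth_rows, expr_rows={"gA": [1, 2, 3][:n_pairs]},
            locus_specs=specs, n_pairs=n_pairs,
        )

    def test_padding_rule(self):
        specs = [("cg1", "gA", -900), ("cg2", "gA", -100), ("cg3", "gA", 400)]
        t = build_sequence_tensors(self._frame(specs), L=5)
        assert t.values.shape == (1, 3, 5)
        np.testing.assert_array_equal(t.mask[0], [True, True, True, False, False])
        np.testing.assert_array_equal(t.tss_distance[0], [-900, -100, 400, 0, 0])
        assert (t.values[0, :, 3:] == 0).all()

    def test_truncation_keeps_nearest_tss_in_order(self):
        specs = [(f"cg{i}", "gA", d) for i, d in enumerate([-1400, -900, -500, -100, 200, 700, 1200])]
        t = build_sequence_tensors(self._frame(specs), L=5)
        # the 5 smallest |tss_distance|, still ascending
        np.testing.assert_array_equal(t.tss_distance[0], [-900, -500, -100, 200, 700])
        assert t.mask[0].all()

    def test_window_excludes_far_loci_and_counts_tensors(self):
        specs = [("cg1", "gA", -3000), ("cg2", "gA", -100)]
        frame = self._frame(specs)
        t = build_sequence_tensors(frame, L=4, window=(-1500, 1500))
        assert t.tss_distance[0][t.mask[0]].tolist() == [-100]
        assert t.n_tensors == 1 * len(frame.pairs)

    def test_targets_align_with_expression(self):
        specs = [("cg1", "gA", -100)]
        frame = self._frame(specs)
        t = build_sequence_tensors(frame, L=2)
        np.testing.assert_allclose(t.target[0], frame.expression()["gA"].to_numpy())

    def test_invalid_length(self):
        with pytest.raises(ValidationError, match="L"):
            build_sequence_tensors(self._frame([("cg1", "gA", -10)]), L=0)

    def test_flat_table_shape(self):
        specs = [("cg1", "gA", -100), ("cg2", "gA", 50)]
        t = build_sequence_tensors(self._frame(specs), L=4)
        table = t.to_table()
        assert len(table) == 1 * 3 * 4
        assert table["mask"].sum() == 2 * 3
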