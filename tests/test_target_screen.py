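"""DEG calling, SMD filtering, target-score handling and intersections."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import metamarker as mm
from metamarker.exceptions import FormatError, InsufficientDataError
from metamarker.synthetic_data import (
    SimConfig,
    generate_collection,
    target_table_from_truth,
)
from metamarker.target_screen import _bh_adjust

from .conftest import make_cohort


class TestDifferentialExpression:
    def _cohort(self, n_genes=50, n_per=20, seed=0, planted_logfc=None, sigma=1.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(7, sigma, size=(n_genes, 2 * n_per))
        groups = ["cancer"] * n_per + ["control"] * n_per
        if planted_logfc is not None:
            X[0, :n_per] += planted_logfc
        return make_cohort(X, [f"G{i}" for i in range(n_genes)], groups)

    def test_equal_means_zero_logfc(self):
        X = np.tile([5.0, 5.0, 5.0, 5.0, 5.0, 5.0], (2, 1))
        cohort = make_cohort(X, ["GA", "GB"], ["cancer"] * 3 + ["control"] * 3)
        recs = mm.differential_expression(cohort)
        assert all(r.log_fc == 0.0 for r in recs)
        assert all(r.direction is None for r in recs)

    def test_bh_adjustment_matches_statsmodels(self):
        recs = mm.differential_expression(self._cohort(seed=3))
        p = np.array([r.p for r in recs])
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose([r.p_adj for r in recs], expected, atol=1e-12)

    def test_bh_is_monotone(self):
        recs = mm.differential_expression(self._cohort(seed=4))
        df = pd.DataFrame({"p": [r.p for r in recs], "p_adj": [r.p_adj for r in recs]})
        adj_in_p_order = df.sort_values("p")["p_adj"].to_numpy()
        assert (np.diff(adj_in_p_order) >= -1e-15).all()
        assert (df.p_adj >= df.p - 1e-15).all()

    def test_planted_deg_power(self):
        # log FC 2, sigma 0.5, n = 20+20: detected in >= 95/100 replicates
        hits = 0
        for i in range(100):
            recs = mm.differential_expression(
                self._cohort(seed=70_000 + i, planted_logfc=2.0, sigma=0.5)
            )
            r0 = recs[0]
            hits += abs(r0.log_fc) > 1.0 and r0.p_adj < 0.05
        assert hits >= 95

    def test_fdr_calibrated_on_null_genes(self):
        total_sig = 0
        n_reps, n_genes = 10, 1000
        for i in range(n_reps):
            recs = mm.differential_expression(
                self._cohort(n_genes=n_genes, n_per=10, seed=80_000 + i)
            )
            total_sig += sum(r.p_adj < 0.05 for r in recs)
        assert total_sig / (n_reps * n_genes) <= 0.05

    def test_small_group_errors(self):
        cohort = make_cohort(
            np.ones((2, 4)), ["GA", "GB"], ["cancer"] * 2 + ["control"] * 2
        )
        with pytest.raises(InsufficientDataError):
            mm.differential_expression(cohort)


class TestCallDegs:
    def test_up_in_one_cohort_never_down(self):
        recs = [
            mm.DEGRecord(dataset_id="D1", gene="G", log_fc=1.5, t_stat=5, p=1e-4, p_adj=1e-3),
            mm.DEGRecord(dataset_id="D2", gene="G", log_fc=0.2, t_stat=1, p=0.3, p_adj=0.6),
        ]
        up, down = mm.call_degs(recs)
        assert up == {"G"} and down == set()

    def test_significant_both_directions_dropped(self):
        recs = [
            mm.DEGRecord(dataset_id="D1", gene="G", log_fc=1.5, t_stat=5, p=1e-4, p_adj=1e-3),
            mm.DEGRecord(dataset_id="D2", gene="G", log_fc=-1.5, t_stat=-5, p=1e-4, p_adj=1e-3),
        ]
        up, down = mm.call_degs(recs)
        assert "G" not in up and "G" not in down


class TestDegMetaFilter:
    def test_planted_gene_survives_and_null_gene_eliminated(self):
        cfg = SimConfig(
            n_cohorts=6, cohort_sizes=((20, 20),) * 6, n_genes=6, anchor_delta=0.0,
            target_block_size=1, target_rho=0.0, n_deg_up=1, n_deg_down=1,
            deg_logfc=1.5, batch_sd=0.0, seed=5,
        )
        coll, truth = generate_collection(cfg)
        planted = next(iter(truth.regulated_up))
        survivors, audit = mm.deg_meta_filter(
            coll, {planted: "up", "G0005": "up"}
        )
        assert planted in survivors
        assert "G0005" not in survivors  # null gene: CI crosses 0

    def test_absent_gene_gets_audit_note(self):
        cfg = SimConfig(
            n_cohorts=3, cohort_sizes=((10, 10),) * 3, n_genes=5, target_block_size=1,
            target_rho=0.0, n_deg_up=1, n_deg_down=1, deg_logfc=0.0, batch_sd=0.0, seed=6,
        )
        coll, _ = generate_collection(cfg)
        for c in coll.cohorts[1:]:
            c.matrix = c.matrix.drop(index="G0004")
        survivors, audit = mm.deg_meta_filter(coll, {"G0004": "up"})
        assert "G0004" not in survivors
        assert any(a["status"] == "insufficient replication" for a in audit)


class TestReadTargetScores:
    def test_threshold_rule(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\tscore\nA\t1.2\nB\t0.0\nC\t-0.5\n")
        targets = mm.read_target_scores(p)
        assert [t.gene for t in targets] == ["A"]

    def test_duplicates_keep_max_score(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\tscore\nA\t0.2\nA\t0.9\n")
        (t,) = mm.read_target_scores(p)
        assert t.score == 0.9

    def test_non_numeric_score_names_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\tscore\nA\t1.2\nB\tNA_text\n")
        with pytest.raises(FormatError, match="line 3"):
            mm.read_target_scores(p)


class TestTripleIntersect:
    def test_set_algebra(self):
        cegs = mm.CEGSet(positive={"B", "C", "D"}, negative=set(), support={})
        res = mm.triple_intersect({"A", "B", "C"}, set(), cegs, {"C", "D", "E"})
        assert res.up_pos_target == {"C"}

    def test_disjoint_inputs_empty(self):
        cegs = mm.CEGSet(positive={"X"}, negative={"Y"}, support={})
        res = mm.triple_intersect({"A"}, {"B"}, cegs, {"Z"})
        assert res.up_pos_target == set() and res.down_neg_target == set()

    def test_result_no_larger_than_smallest_input(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(50)]
        up = set(rng.choice(genes, 20, replace=False))
        pos = set(rng.choice(genes, 15, replace=False))
        tgt = set(rng.choice(genes, 10, replace=False))
        cegs = mm.CEGSet(positive=pos, negative=set(), support={})
        res = mm.triple_intersect(up, set(), cegs, tgt)
        assert len(res.up_pos_target) <= min(len(up), len(pos), len(tgt))

    def test_audit_records_filter_membership(self):
        cegs = mm.CEGSet(positive={"B"}, negative=set(), support={})
        res = mm.triple_intersect({"B"}, set(), cegs, {"B"})
        row = res.audit.set_index("gene").loc["B"]
        assert row.deg_up and row.ceg_positive and row.chip_target and row.selected


class TestPromoterOverlap:
    def _tss(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "tss_1based", "strand"])

    def test_peak_inside_window_reported(self):
        tss = self._tss([("G1", "chr1", 1100, "+")])
        hits = mm.promoter_overlap([("chr1", 1000, 1200)], tss, window=2000)
        assert hits == {"G1"}

    def test_half_open_boundary_excluded(self):
        # TSS (1-based) 5001 -> 0-based 5000; window 1000 -> [4000, 6001);
        # a peak ending exactly at 4000 (half-open) does not overlap
        tss = self._tss([("G1", "chr1", 5001, "+")])
        assert mm.promoter_overlap([("chr1", 3900, 4000)], tss, window=1000) == set()
        assert mm.promoter_overlap([("chr1", 3900, 4001)], tss, window=1000) == {"G1"}

    def test_agrees_with_all_pairs_scan(self):
        rng = np.random.default_rng(9)
        peaks = [("chr1", int(s), int(s) + int(rng.integers(50, 400)))
                 for s in rng.integers(0, 50_000, 30)]
        tss = self._tss(
            [(f"G{i}", "chr1", int(p), "+") for i, p in enumerate(rng.integers(1, 50_000, 15))]
        )
        window = 500
        result = mm.promoter_overlap(peaks, tss, window=window)
        expected = set()
        for row in tss.itertuples():
            t0 = row.tss_1based - 1
            lo, hi = max(0, t0 - window), t0 + window + 1
            for _, s, e in peaks:
                if s < hi and e > lo:
                    expected.add(row.gene)
        assert result == expected

    def test_malformed_bed_names_line(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t200\nchr1\tnotanumber\t300\n")
        with pytest.raises(FormatError, match="line 2"):
            mm.promoter_overlap(p, self._tss([("G1", "chr1", 150, "+")]))


class TestEndToEndScreen:
    def test_planted_regulated_genes_recovered(self):
        # 25 up + 25 down regulated genes planted with full triple evidence
        cfg = SimConfig(
            n_genes=600, target_block_size=25, n_deg_up=25, n_deg_down=25, seed=11
        )
        coll, truth = generate_collection(cfg)
        assert len(truth.regulated) == 50
        records = []
        for c in coll:
            try:
                records.extend(mm.correlate_anchor(c, coll.anchor_gene))
            except InsufficientDataError:
                continue
        cegs = mm.screen_cegs(records)
        deg_records = []
        for c in coll:
            deg_records.extend(mm.differential_expression(c))
        up, down = mm.call_degs(deg_records)
        survivors, _ = mm.deg_meta_filter(
            coll, {g: "up" for g in up} | {g: "down" for g in down}
        )
        up_f = {g for g in up if g in survivors}
        down_f = {g for g in down if g in survivors}
        table = target_table_from_truth(truth, coll.cohorts[0].gene_ids, seed=11)
        targets = set(table.loc[table.score > 0, "gene"])
        res = mm.triple_intersect(up_f, down_f, cegs, targets)
        found = res.up_pos_target | res.down_neg_target
        recall = len(found & truth.regulated) / len(truth.regulated)
        assert recall >= 0.9
        assert len(found - truth.regulated) <= 5

    def test_screen_outputs_deterministic(self, tmp_path):
        from metamarker.pipeline import PipelineConfig, run_pipeline

        payloads = []
        for run_dir in ("a", "b"):
            cfg = PipelineConfig(
                anchor_gene="ANCHOR",
                synthetic=SimConfig(seed=42, n_genes=200),
                out_dir=str(tmp_path / run_dir),
                seed=42,
            )
            run_pipeline(cfg)
            payloads.append((tmp_path / run_dir / "screen.tsv").read_bytes())
        assert payloads[0] == payloads[1]


def test_bh_adjust_reference_values():
    p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
    np.testing.assert_allclose(_bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)
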