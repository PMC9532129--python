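"""Cohort I/O, normalisation, merging, batch adjustment and summaries."""

import numpy as np
import pandas as pd
import pytest

from metamarker.cohort_io import (
    batch_adjust,
    ensure_log2,
    merge_platform,
    read_cohort,
    summarize_gene,
    write_cohort,
)
from metamarker.exceptions import (
    ConfoundingError,
    DomainError,
    DuplicateGeneError,
    EmptyJoinError,
    FormatError,
    InsufficientDataError,
    LookupError_,
    ValidationError,
)

from .conftest import make_cohort


def _write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadWrite:
    def test_round_trip_preserves_values(self, tmp_path):
        # values representable at the writer's 6-decimal precision
        vals = np.round(np.random.default_rng(1).normal(7, 1, (3, 4)), 6)
        cohort = make_cohort(vals, ["GA", "GB", "GC"], ["cancer"] * 2 + ["control"] * 2)
        ep, sp = tmp_path / "e.tsv", tmp_path / "s.tsv"
        write_cohort(cohort, ep, sp)
        back = read_cohort(ep, sp)
        assert back.matrix.shape == (3, 4)
        np.testing.assert_allclose(back.matrix.to_numpy(), vals, atol=1e-12)
        assert list(back.samples["group"]) == list(cohort.samples["group"])

    def test_sheet_sample_absent_from_matrix_is_dropped(self, tmp_path):
        ep = _write_tsv(tmp_path / "e.tsv", "gene_id\tS1\tS2\nGA\t1.0\t2.0\n")
        sp = _write_tsv(
            tmp_path / "s.tsv",
            "sample_id\tgroup\tdataset_id\tplatform_id\n"
            "S1\tcancer\tD\tP\nS2\tcontrol\tD\tP\nS3\tcontrol\tD\tP\n",
        )
        cohort = read_cohort(ep, sp)
        assert cohort.n_samples == 2
        assert "S3" not in cohort.matrix.columns

    def test_duplicate_gene_error_names_gene(self, tmp_path):
        ep = _write_tsv(tmp_path / "e.tsv", "gene_id\tS1\nGA\t1.0\nGA\t2.0\n")
        sp = _write_tsv(
            tmp_path / "s.tsv",
            "sample_id\tgroup\tdataset_id\tplatform_id\nS1\tcancer\tD\tP\n",
        )
        with pytest.raises(DuplicateGeneError, match="GA"):
            read_cohort(ep, sp)

    def test_missing_sheet_column_is_format_error(self, tmp_path):
        ep = _write_tsv(tmp_path / "e.tsv", "gene_id\tS1\nGA\t1.0\n")
        sp = _write_tsv(tmp_path / "s.tsv", "sample_id\tgroup\nS1\tcancer\n")
        with pytest.raises(FormatError):
            read_cohort(ep, sp)

    def test_zero_overlap_is_empty_join_error(self, tmp_path):
        ep = _write_tsv(tmp_path / "e.tsv", "gene_id\tS1\nGA\t1.0\n")
        sp = _write_tsv(
            tmp_path / "s.tsv",
            "sample_id\tgroup\tdataset_id\tplatform_id\nS9\tcancer\tD\tP\n",
        )
        with pytest.raises(EmptyJoinError):
            read_cohort(ep, sp)


class TestEnsureLog2:
    def test_below_threshold_unchanged(self):
        cohort = make_cohort([[14.2, 3.0, 4.0, 5.0]], ["GA"], ["cancer"] * 2 + ["control"] * 2)
        assert ensure_log2(cohort) is cohort

    def test_raw_counts_transformed(self):
        cohort = make_cohort([[10000.0, 10.0, 3.0, 0.0]], ["GA"], ["cancer"] * 2 + ["control"] * 2)
        out = ensure_log2(cohort)
        assert out.log2_transformed
        assert out.matrix.to_numpy().max() == pytest.approx(np.log2(10001), abs=1e-12)

    def test_idempotent(self):
        cohort = make_cohort([[10000.0, 10.0, 3.0, 0.0]], ["GA"], ["cancer"] * 2 + ["control"] * 2)
        once = ensure_log2(cohort)
        twice = ensure_log2(once)
        np.testing.assert_array_equal(once.matrix.to_numpy(), twice.matrix.to_numpy())

    def test_negative_value_with_trigger_is_domain_error(self):
        cohort = make_cohort([[100.0, -1.0, 3.0, 0.0]], ["GA"], ["cancer"] * 2 + ["control"] * 2)
        with pytest.raises(DomainError):
            ensure_log2(cohort)


class TestMergePlatform:
    def _pair(self):
        a = make_cohort(
            np.arange(12.0).reshape(3, 4), ["A", "B", "C"],
            ["cancer"] * 2 + ["control"] * 2, dataset_id="D1", platform_id="P",
        )
        b = make_cohort(
            np.arange(12.0).reshape(3, 4) + 1, ["B", "C", "D"],
            ["cancer"] * 2 + ["control"] * 2, dataset_id="D2", platform_id="P",
        )
        return a, b

    def test_gene_intersection_and_sample_concatenation(self):
        a, b = self._pair()
        merged = merge_platform([a, b])
        assert set(merged.gene_ids) == {"B", "C"}
        assert merged.n_samples == 8
        assert merged.dataset_id == "P"
        assert set(merged.batch) == {"D1", "D2"}

    def test_three_cohorts_batch_labels(self):
        rng = np.random.default_rng(0)
        cohorts = [
            make_cohort(rng.normal(size=(2, 10)), ["A", "B"],
                        ["cancer"] * 5 + ["control"] * 5, dataset_id=f"D{i}", platform_id="P")
            for i in range(3)
        ]
        merged = merge_platform(cohorts)
        assert merged.n_samples == 30
        assert merged.batch.nunique() == 3

    def test_platform_mismatch_errors(self):
        a, b = self._pair()
        b.platform_id = "OTHER"
        with pytest.raises(ValidationError):
            merge_platform([a, b])

    def test_empty_gene_intersection_errors(self):
        a, _ = self._pair()
        c = make_cohort(np.ones((1, 4)), ["Z"], ["cancer"] * 2 + ["control"] * 2,
                        dataset_id="D3", platform_id="P")
        with pytest.raises(EmptyJoinError):
            merge_platform([a, c])

    def test_single_cohort_errors(self):
        a, _ = self._pair()
        with pytest.raises(InsufficientDataError):
            merge_platform([a])


class TestBatchAdjust:
    def _shifted_cohort(self, shift=5.0, n_genes=40, n_per=10, seed=0):
        """Two batches, identical group mix; batch 2 = batch 1 signal + shift."""
        rng = np.random.default_rng(seed)
        base = rng.normal(7, 1, size=(n_genes, 2 * n_per))
        base[:, 2 * n_per // 2:] += 0.0
        X = np.hstack([base[:, :n_per], base[:, n_per:] + shift])
        groups = (["cancer"] * (n_per // 2) + ["control"] * (n_per // 2)) * 2
        cohort = make_cohort(X, [f"G{i}" for i in range(n_genes)], groups)
        batch = np.array(["B1"] * n_per + ["B2"] * n_per)
        return cohort, batch

    def test_additive_shift_removed(self):
        # a 5-unit additive batch shift is overwhelmingly removed; the
        # empirical-Bayes location shrinkage leaves a small per-gene residue
        # (it does not mean-center exactly), but across genes the batch
        # difference is centred on zero
        cohort, batch = self._shifted_cohort()
        before = cohort.matrix.to_numpy()
        out = batch_adjust(cohort, batch=batch)
        X = out.matrix.to_numpy()
        diff_before = before[:, 10:].mean(axis=1) - before[:, :10].mean(axis=1)
        diff = X[:, 10:].mean(axis=1) - X[:, :10].mean(axis=1)
        assert (np.abs(diff) < 0.2 * np.abs(diff_before)).all()
        assert abs(diff.mean()) < 0.1

    def test_matches_sva_combat_oracle(self, tmp_path):
        # independent oracle: Bioconductor sva::ComBat on the same matrix
        import subprocess

        cohort, batch = self._shifted_cohort()
        in_tsv = tmp_path / "in.tsv"
        out_tsv = tmp_path / "out.tsv"
        pd.DataFrame(cohort.matrix.to_numpy()).to_csv(
            in_tsv, sep="\t", index=False, header=False
        )
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            f'X <- as.matrix(read.table("{in_tsv}", sep="\\t"))\n'
            'batch <- c(rep(1,10), rep(2,10))\n'
            'group <- factor(rep(c(rep("cancer",5), rep("control",5)), 2))\n'
            'mod <- model.matrix(~group)\n'
            'out <- ComBat(dat=X, batch=batch, mod=mod, par.prior=TRUE)\n'
            f'write.table(out, "{out_tsv}", sep="\\t", row.names=FALSE, col.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        expected = pd.read_csv(out_tsv, sep="\t", header=None).to_numpy()
        ours = batch_adjust(cohort, batch=batch).matrix.to_numpy()
        # sva iterates its EB fixed point to conv = 1e-4; agreement beyond
        # that tolerance is not expected
        np.testing.assert_allclose(ours, expected, atol=1e-3)

    def test_single_batch_is_noop(self, small_cohort):
        out = batch_adjust(small_cohort, batch=np.array(["B1"] * 6))
        np.testing.assert_array_equal(out.matrix.to_numpy(), small_cohort.matrix.to_numpy())

    def test_confounded_batch_refused(self, small_cohort):
        batch = np.where(small_cohort.samples["group"] == "cancer", "B1", "B2")
        with pytest.raises(ConfoundingError):
            batch_adjust(small_cohort, batch=batch)

    def test_group_signal_preserved_for_planted_deg(self):
        # planted group effect of 2 units must survive adjustment within 10%
        rng = np.random.default_rng(3)
        n_genes, n_per = 60, 12
        X = rng.normal(7, 1, size=(n_genes, 2 * n_per))
        groups = (["cancer"] * 6 + ["control"] * 6) * 2
        case_mask = np.array([g == "cancer" for g in groups])
        X[0, case_mask] += 2.0
        X[:, n_per:] += 4.0  # batch shift
        cohort = make_cohort(X, [f"G{i}" for i in range(n_genes)], groups)
        batch = np.array(["B1"] * n_per + ["B2"] * n_per)
        before = X[0, case_mask].mean() - X[0, ~case_mask].mean()
        out = batch_adjust(cohort, batch=batch)
        row = out.matrix.to_numpy()[0]
        after = row[case_mask].mean() - row[~case_mask].mean()
        assert after == pytest.approx(before, rel=0.10)


class TestSummarizeGene:
    def test_symmetric_groups(self):
        cohort = make_cohort(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], ["GA"], ["cancer"] * 3 + ["control"] * 3
        )
        s = summarize_gene(cohort, "GA")
        assert (s.mean_case, s.sd_case) == (2.0, 1.0)
        assert (s.mean_control, s.sd_control) == (2.0, 1.0)

    def test_hand_computed_sd(self):
        cohort = make_cohort(
            [[6.93, 6.95, 6.97, 1.0, 2.0, 3.0]], ["GA"], ["cancer"] * 3 + ["control"] * 3
        )
        s = summarize_gene(cohort, "GA")
        assert s.mean_case == pytest.approx(6.95)
        assert s.sd_case == pytest.approx(0.02)

    def test_unknown_gene_errors(self, small_cohort):
        with pytest.raises(LookupError_):
            summarize_gene(small_cohort, "XYZ")
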