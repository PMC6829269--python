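"""Six-round selection: per-round rules, boundaries, and whole-pipeline recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tcelsig.io import GeneSignature, GroupMeanTable, SampleClass
from tcelsig.selection import (
    SelectionConfig,
    round1_immune_filter,
    round2_tissue_filter,
    round3_range_filter,
    round45_outlier_filter,
    round6_cellline_filter,
    run_selection,
)
from tcelsig.simulate import CorpusSpec, generate_corpus


def _table(means: dict, classes: dict, t_ref: float | dict = 10.0, lineage=None):
    df = pd.DataFrame(means)
    ref = (
        pd.Series(t_ref, index=df.index)
        if np.isscalar(t_ref)
        else pd.Series(t_ref)
    )
    return GroupMeanTable(
        means=df,
        group_class={g: SampleClass(c) for g, c in classes.items()},
        t_ref=ref.astype(float),
        source_lineage=lineage or {},
    )


IMM = {"B": "IMMUNE_NON_T", "DC": "IMMUNE_NON_T", "gran": "IMMUNE_NON_T", "mono": "IMMUNE_NON_T"}


class TestRound1:
    @pytest.mark.parametrize(
        "mono_mean, expect_kept",
        [
            (6.0, True),   # min margin 4 >= 3.32
            (7.0, False),  # margin 3 < 3.32
            (10.0 - 3.32, True),  # margin exactly at threshold survives
        ],
    )
    def test_per_group_margins(self, mono_mean, expect_kept):
        table = _table(
            {"B": {"g": 4.0}, "DC": {"g": 5.0}, "gran": {"g": 3.0}, "mono": {"g": mono_mean}},
            IMM,
        )
        res = round1_immune_filter(table, SelectionConfig())
        assert ("g" in res.kept) is expect_kept

    def test_pooled_mode_uses_mean_of_group_means(self):
        # group means {4, 5, 3, 7}: pooled mean 4.75, margin 5.25 -> kept,
        # while per_group would exclude (margin vs mono = 3).
        table = _table(
            {"B": {"g": 4.0}, "DC": {"g": 5.0}, "gran": {"g": 3.0}, "mono": {"g": 7.0}},
            IMM,
        )
        cfg = SelectionConfig(immune_compare_mode="pooled")
        assert round1_immune_filter(table, cfg).kept == ["g"]

    def test_requires_immune_groups(self):
        table = _table({"colon": {"g": 4.0}}, {"colon": "TISSUE"})
        with pytest.raises(ValueError, match="IMMUNE_NON_T"):
            round1_immune_filter(table, SelectionConfig())


TIS3 = {"t1": "TISSUE", "t2": "TISSUE", "t3": "TISSUE"}


class TestRound2:
    def test_aggregate_mode_margin(self):
        table = _table({"t1": {"g": 4.0}, "t2": {"g": 5.0}, "t3": {"g": 6.0}}, TIS3)
        res = round2_tissue_filter(table, SelectionConfig())
        assert res.kept == ["g"]
        assert res.diagnostics.loc["g", "margin_vs_mean_tissue"] == pytest.approx(5.0)

    def test_mode_divergence_on_one_hot_tissue(self):
        # means {4, 9}: aggregate margin 3.5 keeps; per-tissue margin vs 9 is 1.
        table = _table({"t1": {"g": 4.0}, "t2": {"g": 9.0}}, {"t1": "TISSUE", "t2": "TISSUE"})
        assert round2_tissue_filter(table, SelectionConfig()).kept == ["g"]
        per_tissue = SelectionConfig(tissue_compare_mode="per_tissue")
        assert round2_tissue_filter(table, per_tissue).excluded == ["g"]

    def test_requires_two_tissues(self):
        table = _table({"t1": {"g": 4.0}}, {"t1": "TISSUE"})
        with pytest.raises(ValueError, match="two TISSUE"):
            round2_tissue_filter(table, SelectionConfig())


class TestRound3:
    @pytest.mark.parametrize(
        "means, expect_kept",
        [
            ((4.0, 8.0), True),    # range 4 inside window
            ((4.0, 13.0), False),  # range 9 > 8.5
            ((4.0, 6.5), True),    # range exactly 2.5: inclusive lower edge
            ((4.0, 12.5), True),   # range exactly 8.5: inclusive upper edge
            ((4.0, 5.0), False),   # range 1 < 2.5
        ],
    )
    def test_range_window(self, means, expect_kept):
        table = _table(
            {"t1": {"g": means[0]}, "t2": {"g": means[1]}},
            {"t1": "TISSUE", "t2": "TISSUE"},
        )
        res = round3_range_filter(table, SelectionConfig())
        assert ("g" in res.kept) is expect_kept


class TestRound45:
    def _nl_table(self, nl_rows: dict):
        # tissue mean = t_ref + nl/Tc with t_ref = 10
        means = {
            t: {g: 10.0 + v[i] for g, v in nl_rows.items()}
            for i, t in enumerate(["t1", "t2"])
        }
        return _table(means, {"t1": "TISSUE", "t2": "TISSUE"})

    def test_outlier_excluded_by_hand_computation(self):
        # nl/Tc rows: g1 = g2 = (-5, -5); g3 = (-5, 0). M = (-5, -10/3);
        # g3's deviation at t2 is 10/3 = 3.33 > 3.32.
        table = self._nl_table({"g1": (-5, -5), "g2": (-5, -5), "g3": (-5, 0)})
        res = round45_outlier_filter(table, SelectionConfig(), ["g1", "g2", "g3"])
        assert res.excluded == ["g3"]
        assert res.diagnostics.loc["g3", "max_deviation"] == pytest.approx(10 / 3)

    def test_identical_profiles_keep_everything(self):
        table = self._nl_table({f"g{i}": (-4, -6) for i in range(5)})
        res = round45_outlier_filter(table, SelectionConfig(), [f"g{i}" for i in range(5)])
        assert res.excluded == []
        assert np.allclose(res.diagnostics["max_deviation"], 0.0)

    def test_second_pass_excludes_gene_masked_by_first_outlier(self):
        # 12 cohort genes at nl/Tc (-6, -6); A = (-6, -1) is a strong outlier;
        # B = (-6, -2.2) hides behind A in pass 1 (dev 3.17 <= 3.32) but is
        # exposed once A's exclusion lowers M (dev 3.51 > 3.32).
        rows = {f"g{i}": (-6.0, -6.0) for i in range(12)}
        rows["A"] = (-6.0, -1.0)
        rows["B"] = (-6.0, -2.2)
        table = self._nl_table(rows)
        genes = list(rows)
        cfg = SelectionConfig()
        pass1 = round45_outlier_filter(table, cfg, genes, round_index=4)
        assert pass1.excluded == ["A"]
        pass2 = round45_outlier_filter(table, cfg, pass1.kept, round_index=5)
        assert pass2.excluded == ["B"]
        # brute-force check of the pass-2 statistic
        nl_t2 = np.array([rows[g][1] for g in pass1.kept])
        dev_b = rows["B"][1] - nl_t2.mean()
        assert dev_b > cfg.deviation_threshold
        assert pass2.diagnostics.loc["B", "max_deviation"] == pytest.approx(dev_b)

    def test_single_gene_pass_skipped_with_warning(self):
        table = self._nl_table({"g1": (-5, -5)})
        with pytest.warns(UserWarning, match="skipped"):
            res = round45_outlier_filter(table, SelectionConfig(), ["g1"])
        assert res.skipped and res.kept == ["g1"]


LINES = {"lu1": "CELL_LINE", "lu2": "CELL_LINE", "co1": "CELL_LINE", "bc1": "CELL_LINE"}
LINEAGE = {"lu1": "lung", "lu2": "lung", "co1": "colon", "bc1": "immune"}


class TestRound6:
    def _res(self, line_means):
        table = _table(
            {ln: {"g": m} for ln, m in line_means.items()},
            LINES,
            lineage=LINEAGE,
        )
        return round6_cellline_filter(table, SelectionConfig())

    def test_two_parenchymal_sources_exclude(self):
        res = self._res({"lu1": 8.0, "lu2": 4.0, "co1": 8.0, "bc1": 4.0})
        assert res.excluded == ["g"]
        assert res.diagnostics.loc["g", "n_parenchymal_sources"] == 2

    def test_single_source_multiple_lines_kept(self):
        res = self._res({"lu1": 8.0, "lu2": 8.0, "co1": 4.0, "bc1": 4.0})
        assert res.kept == ["g"]

    def test_immune_line_violation_excludes_alone(self):
        res = self._res({"lu1": 4.0, "lu2": 4.0, "co1": 4.0, "bc1": 8.0})
        assert res.excluded == ["g"]
        assert bool(res.diagnostics.loc["g", "immune_line_violation"])


class TestRunSelection:
    def test_planted_recovery_and_round_attribution(self, corpus, all_candidates):
        report = run_selection(
            corpus.matrix, corpus.annotation, all_candidates, SelectionConfig()
        )
        assert report.check_counts()
        assert set(report.surviving_genes) == set(corpus.signature.genes)
        # each confounder is excluded at the round it was planted to violate
        round_of = {}
        for rnd in report.rounds:
            for g in rnd.excluded:
                round_of[g] = rnd.name
        expected_round = {
            "r1": "round1_immune",
            "r2": "round2_tissue",
            "r3_low": "round3_range",
            "r3_high": "round3_range",
            "r45": "round4_outlier",
            "r6": "round6_cellline",
        }
        for gene, cls in corpus.planted_round.items():
            assert round_of[gene] == expected_round[cls], gene

    def test_all_t_restricted_candidates_survive(self, corpus):
        report = run_selection(
            corpus.matrix, corpus.annotation, corpus.signature, SelectionConfig()
        )
        assert report.surviving_genes == list(corpus.signature.genes)
        assert all(r.n_excluded == 0 for r in report.rounds)

    def test_missing_candidates_dropped_with_warning(self, corpus):
        cands = GeneSignature("c", list(corpus.signature.genes) + ["NOT_A_GENE"])
        with pytest.warns(UserWarning, match="absent"):
            report = run_selection(corpus.matrix, corpus.annotation, cands)
        assert report.dropped_missing == ["NOT_A_GENE"]
        assert report.check_counts()

    def test_raising_threshold_never_grows_survivor_set(self, all_candidates):
        for seed in range(3):
            c = generate_corpus(CorpusSpec(), seed=seed)
            survivors = []
            for thr in (3.32, 4.0, 5.0, 6.0):
                cfg = SelectionConfig(log2_min_overexpr=thr)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = run_selection(c.matrix, c.annotation, all_candidates, cfg)
                survivors.append(set(rep.surviving_genes))
            for smaller, larger in zip(survivors[1:], survivors):
                assert smaller <= larger

    def test_empty_survivors_reported_not_raised(self, corpus, all_candidates):
        cfg = SelectionConfig(log2_min_overexpr=30.0)
        with pytest.warns(UserWarning, match="no surviving"):
            report = run_selection(corpus.matrix, corpus.annotation, all_candidates, cfg)
        assert report.signature is None
        assert report.check_counts()

    def test_round_skipped_when_class_missing(self, corpus, all_candidates):
        keep = corpus.annotation.table["class"] != "CELL_LINE"
        from tcelsig.io import SampleAnnotation

        ann = SampleAnnotation(corpus.annotation.table[keep].copy())
        mat_cols = [s for s in corpus.matrix.sample_ids if s in set(ann.table.index)]
        from tcelsig.io import ExpressionMatrix

        mat = ExpressionMatrix(corpus.matrix.values[mat_cols])
        with pytest.warns(UserWarning, match="round6_cellline skipped"):
            report = run_selection(mat, ann, all_candidates)
        names = {r.name: r for r in report.rounds}
        assert names["round6_cellline"].skipped
        assert report.check_counts()


class TestBruteForceEquivalence:
    """Each round must agree with a naive loop re-implementation on random stats."""

    @pytest.fixture
    def random_table(self, rng):
        genes = [f"g{i}" for i in range(30)]
        groups = {
            "B": "IMMUNE_NON_T",
            "mono": "IMMUNE_NON_T",
            "t1": "TISSUE",
            "t2": "TISSUE",
            "t3": "TISSUE",
            "t4": "TISSUE",
            "lu1": "CELL_LINE",
            "co1": "CELL_LINE",
            "bc1": "CELL_LINE",
        }
        means = pd.DataFrame(
            rng.normal(6.5, 2.5, (30, len(groups))), index=genes, columns=list(groups)
        )
        t_ref = pd.Series(rng.normal(10, 0.5, 30), index=genes)
        return GroupMeanTable(
            means=means,
            group_class={g: SampleClass(c) for g, c in groups.items()},
            t_ref=t_ref,
            source_lineage={"lu1": "lung", "co1": "colon", "bc1": "immune"},
        )

    def test_round1(self, random_table):
        cfg = SelectionConfig()
        res = round1_immune_filter(random_table, cfg)
        for g in random_table.means.index:
            margins = [
                random_table.t_ref[g] - random_table.means.at[g, grp]
                for grp in ("B", "mono")
            ]
            expect = "excluded" if min(margins) < cfg.log2_min_overexpr else "kept"
            assert (g in res.excluded) == (expect == "excluded")

    def test_round2_both_modes(self, random_table):
        tissues = ["t1", "t2", "t3", "t4"]
        for mode in ("mean_of_tissue_means", "per_tissue"):
            cfg = SelectionConfig(tissue_compare_mode=mode)
            res = round2_tissue_filter(random_table, cfg)
            for g in random_table.means.index:
                tmeans = [random_table.means.at[g, t] for t in tissues]
                if mode == "mean_of_tissue_means":
                    margin = random_table.t_ref[g] - np.mean(tmeans)
                else:
                    margin = min(random_table.t_ref[g] - m for m in tmeans)
                assert (g in res.excluded) == (margin < cfg.log2_min_overexpr)

    def test_round3(self, random_table):
        cfg = SelectionConfig()
        res = round3_range_filter(random_table, cfg)
        for g in random_table.means.index:
            tmeans = [random_table.means.at[g, t] for t in ("t1", "t2", "t3", "t4")]
            rng_g = max(tmeans) - min(tmeans)
            kept = cfg.range_min <= rng_g <= cfg.range_max
            assert (g in res.kept) == kept

    def test_round45_single_pass(self, random_table):
        cfg = SelectionConfig()
        genes = list(random_table.means.index)
        res = round45_outlier_filter(random_table, cfg, genes)
        tissues = ["t1", "t2", "t3", "t4"]
        nl = {
            g: [random_table.means.at[g, t] - random_table.t_ref[g] for t in tissues]
            for g in genes
        }
        m = [np.mean([nl[g][i] for g in genes]) for i in range(len(tissues))]
        for g in genes:
            max_dev = max(nl[g][i] - m[i] for i in range(len(tissues)))
            assert (g in res.excluded) == (max_dev > cfg.deviation_threshold)

    def test_round6(self, random_table):
        cfg = SelectionConfig()
        res = round6_cellline_filter(random_table, cfg)
        for g in random_table.means.index:
            viol = [
                ln
                for ln in ("lu1", "co1", "bc1")
                if random_table.t_ref[g] - random_table.means.at[g, ln]
                < cfg.log2_min_overexpr
            ]
            lineages = [random_table.source_lineage[ln] for ln in viol]
            parenchymal = {l for l in lineages if l != "immune"}
            excluded = len(parenchymal) >= 2 or "immune" in lineages
            assert (g in res.excluded) == excluded
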