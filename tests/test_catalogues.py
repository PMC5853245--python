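import numpy as np
import pandas as pd
import pytest

from woxnet import (
    TimeCourse,
    build_report,
    classify_cytokinin_inducible,
    classify_root_specific,
    cytokinin_fold_change,
    read_time_course,
    write_time_course,
)
from woxnet.catalogues import CatalogueError
from woxnet.motif_scan import MotifHit


def hit(gene_id, category="intron"):
    return MotifHit(gene_id, "c", 0, "forward", "TTAATGG", category, 5)


class TestRootSpecific:
    def matrix(self, rows):
        return pd.DataFrame(rows, columns=["root", "leaf", "shoot"]).rename(
            index=lambda i: f"g{i}"
        )

    def test_dominant_root_included(self):
        m = self.matrix([[100, 10, 10]])
        assert classify_root_specific(m) == {"g0"}

    def test_ratio_boundary_excluded(self):
        # root 100 vs leaf 60 at ratio 2: 100 < 120 -> excluded
        m = self.matrix([[100, 60, 10]])
        assert classify_root_specific(m) == set()

    def test_min_expression_filter(self):
        m = self.matrix([[8, 1, 1]])
        assert classify_root_specific(m, min_expr=10) == set()
        assert classify_root_specific(m, min_expr=5) == {"g0"}

    def test_missing_root_tissue(self):
        m = pd.DataFrame({"leaf": [1.0]}, index=["g0"])
        with pytest.raises(CatalogueError, match="root"):
            classify_root_specific(m)

    def test_matches_bruteforce_rule(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.uniform(0, 150, size=(200, 5)),
            columns=["root", "leaf", "shoot", "seed", "callus"],
            index=[f"g{i}" for i in range(200)],
        )
        expected = {
            g
            for g in m.index
            if m.at[g, "root"] >= 10
            and all(m.at[g, "root"] >= 2.0 * m.at[g, t] for t in m.columns if t != "root")
        }
        assert classify_root_specific(m, 10, 2.0) == expected


def make_tc(treated_rows, mock_rows, genes, times=("0", "1", "2")):
    idx = pd.Index(genes, name="gene_id")
    return TimeCourse(
        treated=pd.DataFrame(treated_rows, index=idx, columns=list(times)),
        mock=pd.DataFrame(mock_rows, index=idx, columns=list(times)),
        t0="0",
    )


class TestCytokininFoldChange:
    def test_null_identity(self):
        tc = make_tc([[10, 20, 30]], [[10, 20, 30]], ["g"])
        assert cytokinin_fold_change(tc, "g", "1") == pytest.approx(1.0)
        assert cytokinin_fold_change(tc, "g", "2") == pytest.approx(1.0)

    def test_doubled_ratio_gives_two(self):
        tc = make_tc([[10, 40]], [[10, 20]], ["g"], times=("0", "1"))
        assert cytokinin_fold_change(tc, "g", "1") == pytest.approx(2.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(4)
        treated = rng.uniform(1, 50, size=(30, 4))
        mock = rng.uniform(1, 50, size=(30, 4))
        genes = [f"g{i}" for i in range(30)]
        tc = make_tc(treated, mock, genes, times=("0", "1", "2", "3"))
        tc_scaled = make_tc(treated * 7.3, mock * 0.2, genes, times=("0", "1", "2", "3"))
        for g in genes[:5]:
            for t in ("1", "2", "3"):
                assert cytokinin_fold_change(tc_scaled, g, t) == pytest.approx(
                    cytokinin_fold_change(tc, g, t)
                )

    def test_t0_and_zero_denominator_errors(self):
        tc = make_tc([[10, 20]], [[10, 0]], ["g"], times=("0", "1"))
        with pytest.raises(CatalogueError):
            cytokinin_fold_change(tc, "g", "0")
        with pytest.raises(CatalogueError):
            cytokinin_fold_change(tc, "g", "1")

    def test_treated_only_mode(self):
        tc = make_tc([[10, 30]], [[10, 5]], ["g"], times=("0", "1"))
        assert cytokinin_fold_change(tc, "g", "1", mode="treated_only") == pytest.approx(3.0)


class TestInducibleClassification:
    def test_inclusive_boundary_at_two(self):
        # max fold change exactly 2.0 -> inducible; 1.999 -> not
        tc = make_tc(
            [[10, 20, 10], [10, 19.99, 10]], [[10, 10, 10], [10, 10, 10]], ["a", "b"]
        )
        assert classify_cytokinin_inducible(tc, 2.0) == {"a"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(40)]
        tc = make_tc(
            rng.uniform(1, 80, size=(40, 3)), rng.uniform(1, 80, size=(40, 3)), genes
        )
        loose = classify_cytokinin_inducible(tc, 1.5)
        tight = classify_cytokinin_inducible(tc, 3.0)
        assert tight <= loose

    def test_matches_bruteforce_evaluation(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        treated = rng.uniform(1, 60, size=(50, 4))
        mock = rng.uniform(1, 60, size=(50, 4))
        tc = make_tc(treated, mock, genes, times=("0", "1", "2", "3"))
        expected = set()
        for i, g in enumerate(genes):
            r0 = treated[i, 0] / mock[i, 0]
            if any(treated[i, j] / mock[i, j] / r0 >= 2.0 for j in (1, 2, 3)):
                expected.add(g)
        assert classify_cytokinin_inducible(tc, 2.0) == expected

    def test_time_course_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(5)]
        tc = make_tc(rng.uniform(1, 9, (5, 3)), rng.uniform(1, 9, (5, 3)), genes)
        write_time_course(tc, tmp_path / "tc.tsv")
        reread = read_time_course(tmp_path / "tc.tsv")
        assert reread.t0 == "0"
        pd.testing.assert_frame_equal(reread.treated, tc.treated, atol=1e-4, check_names=False)


class TestBuildReport:
    def de_table(self, calls: dict):
        return pd.DataFrame(
            {
                "fold_change": 1.0,
                "p_value": 1.0,
                "call": pd.Series(calls),
            }
        )

    def test_empty_de_table(self):
        report = build_report(self.de_table({}), [], set(), set())
        assert report.n_de == 0 and report.n_motif_de == 0
        assert report.distribution is None
        assert report.annotation.empty

    def test_counts_by_set_algebra(self):
        de = self.de_table({"a": "down", "b": "up", "c": "not_de", "d": "down"})
        hits = [hit("a"), hit("a", "promoter"), hit("b"), hit("c")]
        report = build_report(de, hits, root_set={"a", "c"}, ck_set={"b", "d"})
        assert (report.n_de, report.n_up, report.n_down) == (3, 1, 2)
        assert (report.n_motif_de, report.n_motif_up, report.n_motif_down) == (2, 1, 1)
        assert report.n_root_specific_down == 1
        assert report.n_root_specific_down_with_motif == 1
        assert report.n_ck_inducible == 2
        assert report.n_ck_inducible_with_motif == 1
        # hits in not_de genes are excluded from the distribution
        assert report.distribution.total == 3

    def test_universe_mismatch_is_error(self):
        de = self.de_table({"a": "up"})
        with pytest.raises(CatalogueError, match="zz"):
            build_report(de, [hit("zz")], set(), set())

    def test_intersection_bounds(self):
        de = self.de_table({f"g{i}": ("down" if i % 2 else "up") for i in range(20)})
        hits = [hit(f"g{i}") for i in range(0, 20, 3)]
        report = build_report(de, hits, {f"g{i}" for i in range(7)}, {f"g{i}" for i in range(5, 9)})
        assert report.n_root_specific_down_with_motif <= min(
            report.n_motif_down, report.n_root_specific_down
        )
        assert report.n_ck_inducible_with_motif <= min(report.n_ck_inducible, report.n_motif_de)

    def test_headline_counts_regenerate_from_annotation(self):
        de = self.de_table({f"g{i}": ("down" if i % 3 else "up") for i in range(30)})
        hits = [hit(f"g{i}") for i in range(0, 30, 4)]
        report = build_report(de, hits, {f"g{i}" for i in range(10)}, {f"g{i}" for i in range(20, 30)})
        ann = report.annotation
        assert report.n_de == len(ann)
        assert report.n_up == (ann["direction"] == "up").sum()
        assert report.n_motif_down == ((ann["direction"] == "down") & ann["motif"]).sum()
        assert report.n_ck_inducible_with_motif == (ann["ck_inducible"] & ann["motif"]).sum()
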