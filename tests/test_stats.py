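"""Dval / survival-index statistics, filtering, replicate combination, ranking."""

import numpy as np
import pytest

import tnsi
from tnsi import stats
from tnsi.model import (
    AnnotationSet,
    Feature,
    FeatureCounts,
    Genome,
    InsertionSite,
    SiteTable,
    SurvivalResult,
    ValidationError,
)


class TestPredictedReads:
    @pytest.mark.parametrize(
        "feature_len,genome_len,total_reads,expected",
        [
            (100, 1000, 1000, 100.0),       # 10% of the genome gets 10% of reads
            (4_641_652, 4_641_652, 777, 777.0),  # whole-genome identity
            (337, 4_641_652, 2_500_000, 2_500_000 * 337 / 4_641_652),  # 181.508...
        ],
    )
    def test_values(self, feature_len, genome_len, total_reads, expected):
        assert stats.predicted_reads(feature_len, genome_len, total_reads) == pytest.approx(
            expected
        )

    def test_mg1655_scale_value_frozen(self):
        # direct arithmetic: 2.5e6 reads x 337 bp / 4,641,652 bp
        assert stats.predicted_reads(337, 4_641_652, 2_500_000) == pytest.approx(
            181.50862, abs=1e-4
        )

    @pytest.mark.parametrize("args", [(0, 100, 10), (200, 100, 10), (10, 100, -1)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValidationError):
            stats.predicted_reads(*args)


class TestDvalAndSI:
    def test_dval_examples(self):
        assert stats.dval(200, 100.0) == 2.0
        assert stats.dval(0, 100.0) == 0.0
        with pytest.raises(ValidationError):
            stats.dval(5, 0.0)

    def test_survival_index_boundaries(self):
        assert stats.survival_index(3.0, 1.5) == 2.0
        assert stats.survival_index(0.0, 2.0) == 0.0
        assert stats.survival_index(1.0, 0.0) is None  # undefined, not infinity

    def test_identical_tables_give_si_one(self):
        """A fully neutral comparison: treated == control count tables."""
        g = tnsi.make_genome(3000, 0.5, seed=90)
        ann = tnsi.make_annotation(g, 3, 400, seed=90)
        rng = np.random.default_rng(91)
        counts = {
            InsertionSite(int(p), "+"): int(c)
            for p, c in zip(rng.integers(0, 3000, 200), rng.integers(1, 50, 200))
        }
        table = SiteTable("x", counts)
        fc, _ = tnsi.aggregate_counts(table, ann)
        fc = stats.add_dval(fc, ann, table.total_reads())
        for r in stats.compute_survival(fc, fc, ann):
            if r.dval_control > 0:
                assert r.si == pytest.approx(1.0)

    def test_dval_scale_invariance(self):
        """Multiplying every count in a sample by 10 changes no Dval."""
        ann = AnnotationSet(
            genome=Genome("g", 1000),
            features=[Feature("gA", "gene", 0, 400, "+"), Feature("gB", "gene", 400, 1000, "+")],
        )
        base = [FeatureCounts("gA", "s", 3, 30), FeatureCounts("gB", "s", 5, 70)]
        scaled = [FeatureCounts("gA", "s", 3, 300), FeatureCounts("gB", "s", 5, 700)]
        d1 = stats.add_dval(base, ann, 100)
        d2 = stats.add_dval(scaled, ann, 1000)
        for a, b in zip(d1, d2):
            assert a.dval == pytest.approx(b.dval)

    def test_si_depth_invariance_through_pipeline(self):
        """SI is unchanged under independent rescaling of either sample's
        sequencing depth."""
        g = tnsi.make_genome(4000, 0.5, seed=95)
        ann = tnsi.make_annotation(g, 4, 400, seed=95)
        make = lambda scale: SiteTable(
            "s",
            {
                InsertionSite(int(p), "+"): int(c) * scale
                for p, c in zip(rng2.integers(0, 4000, 150), rng2.integers(1, 20, 150))
            },
        )
        rng2 = np.random.default_rng(96)
        t_ctrl = make(1)
        rng2 = np.random.default_rng(97)
        t_trt = make(1)
        rng2 = np.random.default_rng(97)
        t_trt10 = make(10)

        def si_of(ctrl, trt):
            fc_c = stats.add_dval(tnsi.aggregate_counts(ctrl, ann)[0], ann, ctrl.total_reads())
            fc_t = stats.add_dval(tnsi.aggregate_counts(trt, ann)[0], ann, trt.total_reads())
            return [r.si for r in stats.compute_survival(fc_c, fc_t, ann)]

        a, b = si_of(t_ctrl, t_trt), si_of(t_ctrl, t_trt10)
        for x, y in zip(a, b):
            assert (x is None and y is None) or x == pytest.approx(y)


def _sr(fid, n_sites, si=1.0, kind="gene"):
    return SurvivalResult(fid, kind, 1.0, si, si, n_sites, n_sites >= 3)


class TestFilterMinSites:
    def test_threshold(self):
        results = [_sr(f"f{i}", n) for i, n in enumerate([0, 2, 3, 7])]
        assert len(stats.filter_min_sites(results, 3)) == 2
        assert stats.filter_min_sites(results, 0) == results

    def test_matches_one_line_brute_force(self):
        rng = np.random.default_rng(8)
        results = [_sr(f"f{i}", int(n)) for i, n in enumerate(rng.integers(0, 10, 200))]
        for min_sites in (0, 1, 3, 5):
            kept = stats.filter_min_sites(results, min_sites)
            assert len(kept) == sum(1 for r in results if r.n_sites >= min_sites)

    def test_report_counts_by_kind(self):
        results = [
            _sr("g1", 5), _sr("g2", 1),
            _sr("i1", 4, kind="intergenic"), _sr("i2", 2, kind="intergenic"),
        ]
        rep = stats.filter_report(results, 3)
        assert rep == {"kept_genes": 1, "kept_intergenic": 1, "dropped": 2}


class TestCombineReplicates:
    def test_textbook_sem(self):
        reps = [[_sr("a", 5, si)] for si in (2.0, 4.0, 6.0)]
        (c,) = stats.combine_replicates(reps)
        assert c.si_mean == pytest.approx(4.0)
        assert c.si_sem == pytest.approx(2 / np.sqrt(3))

    def test_constant_si(self):
        reps = [[_sr("a", 5, 1.0)] for _ in range(3)]
        (c,) = stats.combine_replicates(reps)
        assert (c.si_mean, c.si_sem) == (1.0, 0.0)

    def test_undefined_replicates_excluded(self):
        reps = [
            [SurvivalResult("a", "gene", 0.0, 1.0, None, 5, True)],
            [_sr("a", 5, 2.0)],
            [_sr("a", 5, 4.0)],
        ]
        (c,) = stats.combine_replicates(reps)
        assert c.si_mean == pytest.approx(3.0)
        assert c.n_replicates_defined == 2
        assert c.si_per_replicate == [None, 2.0, 4.0]

    def test_all_undefined(self):
        reps = [[SurvivalResult("a", "gene", 0.0, 1.0, None, 5, True)]] * 3
        (c,) = stats.combine_replicates(reps)
        assert c.si_mean is None and c.n_replicates_defined == 0

    def test_geometric_mode(self):
        reps = [[_sr("a", 5, si)] for si in (1.0, 4.0, 16.0)]
        (c,) = stats.combine_replicates(reps, geometric=True)
        assert c.si_mean == pytest.approx(4.0)  # (1*4*16)^(1/3)


class TestRankReport:
    def test_resistant_order(self):
        combined = stats.combine_replicates(
            [[_sr("a", 5, 5.0), _sr("b", 5, 1.0), _sr("c", 5, 0.2)]]
        )
        ranked = stats.rank_report(combined, "resistant")
        assert [r.feature_id for r in ranked] == ["a", "b", "c"]
        ranked = stats.rank_report(combined, "sensitive")
        assert [r.feature_id for r in ranked] == ["c", "b", "a"]

    def test_tie_break_lexicographic(self):
        combined = stats.combine_replicates([[_sr("y", 5, 2.0), _sr("x", 5, 2.0)]])
        ranked = stats.rank_report(combined, "resistant")
        assert [r.feature_id for r in ranked] == ["x", "y"]

    def test_undefined_si_sorts_last(self):
        combined = stats.combine_replicates(
            [[_sr("a", 5, 0.1), SurvivalResult("z", "gene", 0.0, 1.0, None, 5, True)]]
        )
        ranked = stats.rank_report(combined, "resistant")
        assert ranked[-1].feature_id == "z"


class TestNeutralNullDispersion:
    def test_no_feature_exceeds_bootstrap_null(self):
        """In a fully neutral selection, every filtered feature's |log2 SI|
        stays below the 99.9th percentile of a multinomial bootstrap null
        that resamples both samples from the pooled site frequencies."""
        g = tnsi.make_genome(50_000, 0.5, seed=200)
        ann = tnsi.make_annotation(g, 40, 800, seed=201)
        lib = tnsi.make_library(ann, seed=202)
        sc = tnsi.SelectionScenario(
            plating_counts={"control": 50_000, "treated": 50_000},
            read_depth={"control": 1_000_000, "treated": 1_000_000},
            baseline_survival=0.5,
            seed=203,
        )
        tabs = tnsi.simulate_selection(lib, ann, sc)
        depth = 1_000_000

        def per_feature(table):
            fc, _ = tnsi.aggregate_counts(table, ann)
            fc = stats.add_dval(fc, ann, table.total_reads())
            return fc

        fc_c, fc_t = per_feature(tabs["control"]), per_feature(tabs["treated"])
        res = stats.filter_min_sites(stats.compute_survival(fc_c, fc_t, ann), 3)
        observed = np.array(
            [abs(np.log2(r.si)) for r in res if r.si is not None and r.si > 0]
        )

        # bootstrap null: resample counts from the pooled frequencies and
        # recompute per-feature log2 ratios with a flat feature membership map
        sites_sorted = sorted(set(tabs["control"].counts) | set(tabs["treated"].counts))
        pooled = np.array(
            [
                tabs["control"].counts.get(s, 0) + tabs["treated"].counts.get(s, 0)
                for s in sites_sorted
            ],
            dtype=float,
        )
        p = pooled / pooled.sum()
        fid_order = [f.feature_id for f in ann.features]
        fidx = {f: i for i, f in enumerate(fid_order)}
        member = np.zeros(len(sites_sorted), dtype=int)
        index = tnsi.sites.FeatureIndex(ann)
        for j, s in enumerate(sites_sorted):
            member[j] = fidx[index.features_at(s.position)[0].feature_id]
        kept_idx = np.array([fidx[r.feature_id] for r in res])

        # the null must include both sampling stages: the 50,000-colony
        # plating bottleneck and the sequencing multinomial
        plating = 50_000
        rng = np.random.default_rng(204)

        def draw():
            col = rng.multinomial(plating, p)
            return rng.multinomial(depth, col / plating)

        null: list[float] = []
        for _ in range(120):
            c1 = draw()
            c2 = draw()
            r1 = np.bincount(member, weights=c1, minlength=len(fid_order))
            r2 = np.bincount(member, weights=c2, minlength=len(fid_order))
            with np.errstate(divide="ignore", invalid="ignore"):
                lr = np.abs(np.log2(r2[kept_idx] / r1[kept_idx]))
            null.extend(lr[np.isfinite(lr)])
        cutoff = np.quantile(null, 0.999)
        assert observed.max() <= cutoff

    def test_log_si_test_detects_systematic_shift(self):
        t, p = stats.log_si_test([2.0, 2.2, 1.9])
        assert t > 0 and p < 0.05
        _, p_neutral = stats.log_si_test([0.9, 1.1, 1.0])
        assert p_neutral > 0.1
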