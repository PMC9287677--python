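"""Intron derivation, containment counting, pri-miRNA fold changes, and
the transcriptional-vs-processing classifier."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import miraxis as mx
from miraxis.intervals import merge_intervals, subtract_intervals
from miraxis.primirna import (
    classify_regulation,
    correlate_mature_vs_pri,
    count_intronic_reads,
    intronic_regions,
    pri_fold_change,
)
from miraxis.types import CountMatrix, GeneModel, ValidationError


class TestIntronicRegions:
    def test_simple_subtraction(self):
        models = {"g1": GeneModel("g1", "chr1", "+", 100, 1000, [(100, 200), (800, 1000)])}
        assert intronic_regions(models, "g1") == [(200, 800)]

    def test_neighbour_exon_also_subtracted(self):
        models = {
            "g1": GeneModel("g1", "chr1", "+", 100, 1000, [(100, 200), (800, 1000)]),
            "g2": GeneModel("g2", "chr1", "+", 250, 450, [(300, 400)]),
        }
        assert intronic_regions(models, "g1") == [(200, 300), (400, 800)]

    def test_other_chromosome_ignored(self):
        models = {
            "g1": GeneModel("g1", "chr1", "+", 100, 1000, [(100, 200)]),
            "g2": GeneModel("g2", "chr2", "+", 100, 1000, [(300, 400)]),
        }
        assert intronic_regions(models, "g1") == [(200, 1000)]

    def test_exonless_gene_is_whole_span(self, caplog):
        models = {"g1": GeneModel("g1", "chr1", "+", 100, 1000, [])}
        with caplog.at_level("WARNING"):
            assert intronic_regions(models, "g1") == [(100, 1000)]

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            intronic_regions({}, "nope")

    @given(st.data())
    @settings(deadline=None, max_examples=40)
    def test_subtraction_matches_per_base_oracle(self, data):
        span_len = data.draw(st.integers(50, 2000))
        start = data.draw(st.integers(0, 500))
        span = (start, start + span_len)
        n_blocks = data.draw(st.integers(0, 6))
        blocks = []
        for _ in range(n_blocks):
            s = data.draw(st.integers(start - 20, start + span_len + 20))
            e = s + data.draw(st.integers(1, 300))
            blocks.append((s, e))
        result = subtract_intervals(span, blocks)
        # per-base membership oracle
        base_in = np.ones(span_len, dtype=bool)
        for s, e in blocks:
            lo, hi = max(s, span[0]), min(e, span[1])
            if hi > lo:
                base_in[lo - start : hi - start] = False
        oracle = np.zeros(span_len, dtype=bool)
        for s, e in result:
            assert span[0] <= s < e <= span[1]
            oracle[s - start : e - start] = True
        assert np.array_equal(base_in, oracle)
        # disjoint and sorted
        for (s1, e1), (s2, e2) in zip(result, result[1:]):
            assert e1 < s2


class TestCounting:
    MODELS = {"g1": GeneModel("g1", "chr1", "+", 100, 1000, [(100, 200), (800, 1000)])}
    INTRONS = {"g1": [(200, 800)]}

    def _count(self, reads_df):
        cm = count_intronic_reads({"s1": reads_df}, self.INTRONS, self.MODELS)
        return int(cm.counts.loc["g1", "s1"])

    def test_contained_read_counted(self):
        assert self._count(pd.DataFrame(dict(chrom=["chr1"], start=[250], end=[280]))) == 1

    def test_junction_read_not_counted(self):
        assert self._count(pd.DataFrame(dict(chrom=["chr1"], start=[190], end=[210]))) == 0
        assert self._count(pd.DataFrame(dict(chrom=["chr1"], start=[790], end=[810]))) == 0

    def test_exonic_read_not_counted(self):
        assert self._count(pd.DataFrame(dict(chrom=["chr1"], start=[120], end=[160]))) == 0

    def test_wrong_chromosome_not_counted(self):
        assert self._count(pd.DataFrame(dict(chrom=["chr9"], start=[250], end=[280]))) == 0

    def test_order_invariant_and_multiplicity_doubles(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(150, 900, 200)
        df = pd.DataFrame(dict(chrom="chr1", start=starts, end=starts + 30))
        c1 = self._count(df)
        c2 = self._count(df.sample(frac=1, random_state=0).reset_index(drop=True))
        c3 = self._count(pd.concat([df, df], ignore_index=True))
        assert c1 == c2 and c3 == 2 * c1

    def test_malformed_read_rejected(self):
        bad = pd.DataFrame(dict(chrom=["chr1"], start=[300], end=[300]))
        with pytest.raises(ValidationError):
            self._count(bad)

    def test_null_simulation_matches_expected_depth(self):
        models, host_map = mx.make_host_gene_models(6, seed=20)
        depth = 400
        reads, mature_cm, _ = mx.generate_host_gene_experiment(
            models, host_map, "null", intronic_depth=depth, seed=21
        )
        introns = {g: intronic_regions(models, g) for g in host_map.values()}
        cm = count_intronic_reads(reads, introns, models)
        counts = cm.counts.to_numpy()
        # every intronic read is fully contained by construction; totals are
        # Poisson(depth), so 5 sigma covers all genes x samples
        assert np.all(np.abs(counts - depth) < 5 * np.sqrt(depth))


class TestPriFoldChange:
    def test_identical_conditions_near_zero(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(500, (10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        cond = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        fc = pri_fold_change(CountMatrix(counts=counts, condition=cond), "a", "b")
        assert np.all(np.abs(fc["pri_log2fc"]) < 0.2)

    def test_low_coverage_flagged(self):
        counts = pd.DataFrame(
            [[1000, 1000, 900, 950], [3, 2, 4, 1]],
            index=["deep", "shallow"],
            columns=["a1", "a2", "b1", "b2"],
        )
        cond = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        fc = pri_fold_change(CountMatrix(counts=counts, condition=cond), "a", "b")
        assert not fc.set_index("host_gene_id").loc["deep", "low_coverage"]
        assert fc.set_index("host_gene_id").loc["shallow", "low_coverage"]

    @pytest.mark.parametrize("planted", [mx.PRI_LFC_60PCT, mx.PRI_LFC_30PCT])
    def test_planted_regime_recovered(self, planted):
        models, host_map = mx.make_host_gene_models(24, seed=30)
        plant = {"mir_001": planted, "mir_002": planted}
        reads, mature_cm, _ = mx.generate_host_gene_experiment(
            models, host_map, "transcriptional", pri_log2fc=plant, seed=31
        )
        introns = {g: intronic_regions(models, g) for g in host_map.values()}
        cm = count_intronic_reads(reads, introns, models, condition=mature_cm.condition)
        fc = pri_fold_change(cm, "ctrl", "case").set_index("host_gene_id")
        for gene in ("HOST001", "HOST002"):
            assert abs(fc.loc[gene, "pri_log2fc"] - planted) <= 0.2

    def test_missing_condition_rejected(self):
        counts = pd.DataFrame([[1, 2]], index=["g"], columns=["s1", "s2"])
        cm = CountMatrix(counts=counts, condition={"s1": "a", "s2": "a"})
        with pytest.raises(ValidationError):
            pri_fold_change(cm, "a", "b")


class TestClassifier:
    @pytest.mark.parametrize(
        "mature,pri,expected",
        [
            (-1.0, -0.8, "transcriptional"),
            (-1.0, 0.05, "post_transcriptional"),
            (-0.1, -0.1, "unchanged"),
            (1.2, 0.9, "transcriptional"),
            (-1.0, 1.0, "discordant"),
            (0.6, 0.05, "post_transcriptional"),
        ],
    )
    def test_rule_application(self, mature, pri, expected):
        assert classify_regulation(mature, pri) == expected

    def test_call_is_rederivable_from_row(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m, p = rng.normal(0, 1, 2)
            call = classify_regulation(m, p)
            assert call == classify_regulation(m, p)  # pure function
            if call == "transcriptional":
                assert abs(m) >= 0.5 and m * p > 0 and abs(p) >= 0.5 * abs(m)


class TestCorrelation:
    def test_identical_vectors_give_unit_correlations(self):
        mature = pd.DataFrame(dict(feature_id=["m1", "m2", "m3", "m4"],
                                   log2fc=[-1.0, 0.5, 2.0, -0.2],
                                   pvalue=[0.1] * 4))
        pri = pd.DataFrame(dict(host_gene_id=["h1", "h2", "h3", "h4"],
                                pri_log2fc=[-1.0, 0.5, 2.0, -0.2],
                                low_coverage=[False] * 4))
        host_map = {"m1": "h1", "m2": "h2", "m3": "h3", "m4": "h4"}
        corr, rows = correlate_mature_vs_pri(mature, pri, host_map)
        assert corr.rho == pytest.approx(1.0)
        assert corr.r == pytest.approx(1.0)
        assert rows["included"].all()

    def test_low_coverage_pairs_excluded(self):
        mature = pd.DataFrame(dict(feature_id=["m1", "m2", "m3", "m4"],
                                   log2fc=[-1.0, 0.5, 2.0, -0.2], pvalue=[0.1] * 4))
        pri = pd.DataFrame(dict(host_gene_id=["h1", "h2", "h3", "h4"],
                                pri_log2fc=[-1.0, 0.5, 2.0, -0.2],
                                low_coverage=[False, False, False, True]))
        host_map = {"m1": "h1", "m2": "h2", "m3": "h3", "m4": "h4"}
        corr, rows = correlate_mature_vs_pri(mature, pri, host_map)
        assert corr.n_mirs == 3
        assert rows.set_index("mir_id").loc["m4", "scenario_call"] == "not_assessed"

    def test_fewer_than_three_pairs_rejected(self):
        mature = pd.DataFrame(dict(feature_id=["m1"], log2fc=[1.0], pvalue=[0.1]))
        pri = pd.DataFrame(dict(host_gene_id=["h1"], pri_log2fc=[1.0],
                                low_coverage=[False]))
        with pytest.raises(ValidationError):
            correlate_mature_vs_pri(mature, pri, {"m1": "h1"})
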