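"""Region merging, DE operon calling and direct/indirect classification."""

import numpy as np
import pandas as pd
import pytest

from regulonscan import (
    BindingSiteCall,
    OperonRecord,
    PeakRegion,
    assign_regions_to_operons,
    call_de_operons,
    classify_regulon,
    hierarchy_report,
    indirect_site_search,
    merge_region_sets,
    promoter_overlap,
    site_position_table,
)
from regulonscan.simulate import simulate_expression


def region(start, end, chrom="chr", support=None):
    return PeakRegion(
        chrom, start, end, (start + end) // 2, 1.0,
        support=set(support or []),
    )


class TestMergeRegionSets:
    def test_rescue_rules(self, dr_matrix):
        cons = dr_matrix.consensus
        genome = {
            "chr": "G" * 1000 + cons + "C" + cons + "G" * 979
            + "ATCGGCTAAC" * 200
        }
        both = [region(100, 300, support={"rep1", "rep2"})]
        with_box = region(950, 1100)  # contains the planted consensus
        random_seq = region(3200, 3400)  # background only
        out = merge_region_sets(
            both, [with_box, random_seq], [], genome, dr_matrix,
            rescue_cutoff_bits=dr_matrix.max_score - 1e-6,
        )
        spans = [(r.start, r.end) for r in out]
        assert (100, 300) in spans
        assert (950, 1100) in spans
        assert (3200, 3400) not in spans
        rescued = [r for r in out if "rescued_by_box" in r.filters]
        assert [(r.start, r.end) for r in rescued] == [(950, 1100)]

    def test_overlapping_duplicates_merged(self, dr_matrix):
        genome = {"chr": "ACGT" * 300}
        both = [
            region(100, 300, support={"rep1", "rep2"}),
            region(250, 400, support={"rep1", "rep2"}),
        ]
        out = merge_region_sets(both, [], [], genome, dr_matrix)
        assert [(r.start, r.end) for r in out] == [(100, 400)]


def operon(oid, genes, strand="+", start=1000, **kw):
    return OperonRecord(oid, tuple(genes), strand, start, chrom="chr", **kw)


def expr_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])


class TestCallDeOperons:
    def test_two_passing_genes_consistent_sign(self):
        ops = [operon("opA", ["a1", "a2"])]
        expr = expr_table(
            [("a1", np.log2(3.0), 0.01), ("a2", np.log2(2.5), 0.01)]
        )
        verdicts, _ = call_de_operons(expr, ops)
        assert verdicts["opA"] == "up"

    def test_one_of_three_not_de(self):
        ops = [operon("opA", ["a1", "a2", "a3"])]
        expr = expr_table(
            [("a1", 2.0, 0.001), ("a2", 0.1, 0.5), ("a3", 0.2, 0.9)]
        )
        verdicts, _ = call_de_operons(expr, ops)
        assert verdicts["opA"] == "none"

    def test_mixed_signs_veto(self):
        ops = [operon("opA", ["a1", "a2"])]
        expr = expr_table([("a1", 2.0, 0.001), ("a2", -2.0, 0.001)])
        verdicts, _ = call_de_operons(expr, ops)
        assert verdicts["opA"] == "none"

    def test_single_gene_operon_passes_alone(self):
        ops = [operon("opA", ["a1"])]
        expr = expr_table([("a1", -1.5, 0.001)])
        verdicts, _ = call_de_operons(expr, ops)
        assert verdicts["opA"] == "down"
        strict, _ = call_de_operons(expr, ops, single_gene_passes=False)
        assert strict["opA"] == "none"

    def test_empty_expression_all_none(self):
        ops = [operon("opA", ["a1", "a2"])]
        verdicts, _ = call_de_operons(expr_table([]), ops)
        assert verdicts == {"opA": "none"}

    def test_unassigned_genes_reported(self):
        ops = [operon("opA", ["a1"])]
        expr = expr_table([("a1", 0.0, 1.0), ("orphan", 3.0, 0.001)])
        _, unassigned = call_de_operons(expr, ops)
        assert unassigned == ["orphan"]

    def test_fold_change_threshold_is_inclusive_log2(self):
        ops = [operon("opA", ["a1"])]
        expr = expr_table([("a1", 1.0, 0.001)])  # exactly 2-fold
        verdicts, _ = call_de_operons(expr, ops, fc_threshold=2.0)
        assert verdicts["opA"] == "up"


class TestAssignRegions:
    def test_divergent_promoter_maps_to_both(self):
        ops = [
            operon("left", ["l1"], strand="-", start=980),
            operon("right", ["r1"], strand="+", start=1220),
        ]
        rmap = assign_regions_to_operons([region(1050, 1150)], ops, 500)
        assert sorted(rmap[0]) == ["left", "right"]

    def test_distant_region_unmapped(self):
        ops = [operon("opA", ["a1"], start=20000)]
        rmap = assign_regions_to_operons([region(100, 300)], ops, 500)
        assert rmap[0] == []

    def test_matches_brute_force_window_search(self):
        rng = np.random.default_rng(31)
        ops = []
        for i in range(30):
            strand = "+" if rng.integers(2) else "-"
            ops.append(
                operon(f"op{i}", [f"g{i}"], strand=strand,
                       start=int(rng.integers(500, 50000)))
            )
        regions = [
            region(int(s), int(s) + int(rng.integers(50, 400)))
            for s in rng.integers(0, 50000, size=20)
        ]
        rmap = assign_regions_to_operons(regions, ops, 500)
        for i, r in enumerate(regions):
            expected = []
            for op in ops:
                if op.strand == "+":
                    w0, w1 = op.anchor - 500, op.anchor + 1
                else:
                    w0, w1 = op.anchor, op.anchor + 501
                if r.start < w1 and w0 < r.end:
                    expected.append(op.operon_id)
            assert sorted(rmap[i]) == sorted(expected)

    def test_flagged_regions_not_assigned(self):
        ops = [operon("opA", ["a1"], start=1200)]
        r = region(900, 1100)
        r.filters.add("rnap_crosslink_fail")
        rmap = assign_regions_to_operons([r], ops, 500)
        assert rmap[0] == []


class TestClassifyRegulon:
    def test_planted_cohort_recovered(self):
        de = {
            **{f"rep{i}": "up" for i in range(5)},
            **{f"act{i}": "down" for i in range(2)},
            **{f"ind{i}": "up" for i in range(3)},
            "silent": "none",
        }
        rmap = {
            i: [f"rep{i}"] for i in range(5)
        }
        rmap.update({5 + i: [f"act{i}"] for i in range(2)})
        rmap[7] = ["silent"]
        assignments, venn = classify_regulon(de, rmap)
        by_id = {a.operon_id: a.classification for a in assignments}
        assert all(by_id[f"rep{i}"] == "direct-repressed" for i in range(5))
        assert all(by_id[f"act{i}"] == "direct-activated" for i in range(2))
        assert all(by_id[f"ind{i}"] == "indirect" for i in range(3))
        assert by_id["silent"] == "bound-not-DE"
        assert venn["direct"] == 7
        assert venn["direct_repressed"] == 5
        assert venn["direct_activated"] == 2
        assert venn["indirect"] == 3

    def test_venn_identity(self):
        de = {"a": "up", "b": "down", "c": "none", "d": "up"}
        rmap = {0: ["a"], 1: ["c"]}
        _, venn = classify_regulon(de, rmap)
        assert venn["direct"] + venn["de_not_bound"] == venn["total_de"]

    def test_no_regions_all_de_become_indirect(self):
        de = {"a": "up", "b": "down"}
        _, venn = classify_regulon(de, {})
        assert venn["indirect"] == 2 and venn["direct"] == 0

    def test_predicted_site_blocks_indirect_label(self):
        de = {"a": "up"}
        assignments, venn = classify_regulon(de, {}, {"a"})
        assert assignments[0].classification == "DE-not-bound"
        assert venn["indirect"] == 0

    def test_order_independence(self):
        de = {"a": "up", "b": "none", "c": "down"}
        rmap = {0: ["a"], 1: ["b"]}
        a1, v1 = classify_regulon(dict(reversed(list(de.items()))), rmap)
        a2, v2 = classify_regulon(de, rmap)
        assert a1 == a2 and v1 == v2


class TestIndirectSiteSearch:
    def test_planted_upstream_site_found(self, dr_matrix):
        cons = dr_matrix.consensus
        genome = {"chr": "G" * 700 + cons + "G" * 300}
        ops = [operon("opA", ["a1"], start=900)]
        hits = indirect_site_search(
            ops, genome, dr_matrix, cutoff_bits=dr_matrix.max_score - 1e-6,
            upstream_bp=500,
        )
        assert "opA" in hits
        assert hits["opA"][0].start == 700

    def test_cutoff_above_max_finds_nothing(self, dr_matrix):
        genome = {"chr": "G" * 500 + dr_matrix.consensus + "G" * 500}
        ops = [operon("opA", ["a1"], start=800)]
        hits = indirect_site_search(
            ops, genome, dr_matrix, cutoff_bits=dr_matrix.max_score + 1.0
        )
        assert hits == {}

    def test_random_upstream_matches_exhaustive_scan(self, dr_matrix):
        from regulonscan.motif import localbest, scan

        rng = np.random.default_rng(37)
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        genome = {"chr": seq}
        ops = [
            operon(f"op{i}", [f"g{i}"], start=int(p))
            for i, p in enumerate(range(500, 20000, 700))
        ]
        cutoff = 8.0
        hits = indirect_site_search(
            ops, genome, dr_matrix, cutoff, upstream_bp=500
        )
        for op in ops:
            w0 = max(0, op.anchor - 500)
            sub = {"chr": seq[w0 : op.anchor]}
            expected = localbest(scan(dr_matrix, sub, cutoff), 200)
            got = hits.get(op.operon_id, [])
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g.start == w0 + e.start


class TestPromoterOverlap:
    def make_operon(self, strand="+"):
        # promoter anatomy on the forward strand: -35 at 960, -10 at 985,
        # TSS at 1000
        return operon(
            "opA", ["a1"], strand=strand, start=1050,
            tss=1000, minus10=985, minus35=960,
        )

    def test_site_spanning_tss_overlaps(self):
        site = BindingSiteCall("chr", 995, 1013, "+", 12.0)
        assert promoter_overlap(site, self.make_operon()) == "overlap"

    def test_site_far_upstream(self):
        site = BindingSiteCall("chr", 800, 818, "+", 12.0)
        assert promoter_overlap(site, self.make_operon()) == "upstream"

    def test_site_downstream(self):
        site = BindingSiteCall("chr", 1020, 1038, "+", 12.0)
        assert promoter_overlap(site, self.make_operon()) == "downstream"

    def test_no_tss_unknown(self):
        site = BindingSiteCall("chr", 995, 1013, "+", 12.0)
        assert promoter_overlap(site, operon("opA", ["a1"])) == "unknown"

    def test_position_table_hand_distances(self):
        op = self.make_operon()
        sites = {
            "opA": [
                BindingSiteCall("chr", 991, 1009, "+", 12.0),  # mid 1000
                BindingSiteCall("chr", 900, 918, "+", 10.0),  # mid 909
            ]
        }
        df = site_position_table(sites, [op])
        assert df["distance_to_tss"].tolist() == [0, -91]
        assert df["category"].tolist() == ["overlap", "upstream"]

    def test_position_table_minus_strand_sign(self):
        op = operon("opB", ["b1"], strand="-", start=900, tss=1000)
        sites = {"opB": [BindingSiteCall("chr", 1041, 1059, "-", 12.0)]}
        df = site_position_table(sites, [op])
        # site midpoint 1050 is upstream (5') of a minus-strand TSS
        assert df["distance_to_tss"].tolist() == [-50]


class TestHierarchyReport:
    def assignments(self):
        from regulonscan.regulon import RegulonAssignment

        return [
            RegulonAssignment("tfA", "up", (0,), "direct-repressed"),
            RegulonAssignment("other", "up", (1,), "direct-repressed"),
        ]

    def test_empty_annotation(self):
        df = hierarchy_report(
            self.assignments(), pd.DataFrame(columns=["tf_gene", "target_operon"]),
            ["x"],
        )
        assert df.empty

    def test_chain_attribution(self):
        ann = pd.DataFrame(
            [
                {"tf_gene": "tfA", "target_operon": "t1"},
                {"tf_gene": "tfA", "target_operon": "t2"},
                {"tf_gene": "unrelated", "target_operon": "t1"},
            ]
        )
        df = hierarchy_report(self.assignments(), ann, ["t1", "t2"])
        assert len(df) == 2
        assert set(df["target_operon"]) == {"t1", "t2"}

    def test_self_regulation_excluded(self):
        ann = pd.DataFrame([{"tf_gene": "tfA", "target_operon": "tfA"}])
        df = hierarchy_report(self.assignments(), ann, ["tfA"])
        assert df.empty


class TestFullClassificationPipeline:
    def test_noise_free_parameter_recovery(self):
        # planted direct-repressed / direct-activated / indirect structure
        rng = np.random.default_rng(41)
        ops = [
            operon(f"op{i}", [f"g{i}a", f"g{i}b"], start=2000 + 3000 * i)
            for i in range(12)
        ]
        truth = {
            "op0": ("direct", +1), "op1": ("direct", +1),
            "op2": ("direct", -1),
            "op3": ("indirect", +1), "op4": ("indirect", -1),
        }
        regulated = {k: s for k, (kind, s) in truth.items()}
        expr, _ = simulate_expression(ops, regulated, noise_sd=0.0, seed=43)
        verdicts, _ = call_de_operons(expr, ops)
        regions = [
            region(op.anchor - 200, op.anchor - 50)
            for op in ops
            if truth.get(op.operon_id, ("", 0))[0] == "direct"
        ]
        rmap = assign_regions_to_operons(regions, ops, 500)
        assignments, venn = classify_regulon(verdicts, rmap)
        by_id = {a.operon_id: a.classification for a in assignments}
        assert by_id["op0"] == "direct-repressed"
        assert by_id["op1"] == "direct-repressed"
        assert by_id["op2"] == "direct-activated"
        assert by_id["op3"] == "indirect"
        assert by_id["op4"] == "indirect"
        assert all(
            by_id[f"op{i}"] == "none" for i in range(5, 12)
        )
        assert venn["direct"] == 3 and venn["indirect"] == 2
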