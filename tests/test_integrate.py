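import numpy as np
import pandas as pd
import pytest

from meripairray import (
    RunConfig,
    ValidationError,
    classify_all_lncrnas,
    classify_lncrna,
    find_cis_targets,
    nine_quadrant,
    venn_counts,
)

# ---------------------------------------------------------------------------
# nine-quadrant

# hand-enumerated truth table over sign {-,0,+} x significance {yes,no} per
# axis: expected (meth_class, expr_class, mode).  log2fc magnitude 1.5 for
# signed states, 0 for the zero state; "significant" means p = 0.01 < 0.05.
_AXIS_STATES = {
    ("+", True): 1.5,
    ("+", False): 1.5,
    ("0", True): 0.0,
    ("0", False): 0.0,
    ("-", True): -1.5,
    ("-", False): -1.5,
}
_MC = {("+", True): "hyper", ("-", True): "hypo"}
_EC = {("+", True): "up", ("-", True): "down"}

_TRUTH_TABLE = {}
for m_state in _AXIS_STATES:
    for e_state in _AXIS_STATES:
        mc = _MC.get(m_state, "ns")
        ec = _EC.get(e_state, "ns")
        mode = f"{mc}-{ec}" if mc != "ns" and ec != "ns" else "none"
        _TRUTH_TABLE[(m_state, e_state)] = (mc, ec, mode)


def _records(states, layer):
    rows = []
    for i, (sign, sig) in enumerate(states):
        rows.append(
            {
                "transcript_id": f"t{i}",
                "biotype": "mRNA",
                "log2fc": _AXIS_STATES[(sign, sig)],
                "p_value": 0.01 if sig else 0.5,
            }
        )
    return pd.DataFrame(rows)


class TestNineQuadrant:
    def test_center_cell_for_null_transcript(self):
        meth = _records([("0", False)], "meth")
        expr = _records([("0", False)], "expr")
        q = nine_quadrant(meth, expr, RunConfig())
        assert q["quadrant"].iloc[0] == "ns/ns"
        assert q["mode"].iloc[0] == "none"

    def test_strong_concordant_transcript_is_hyper_up(self):
        meth = _records([("+", True)], "meth")
        expr = _records([("+", True)], "expr")
        q = nine_quadrant(meth, expr, RunConfig())
        assert q["mode"].iloc[0] == "hyper-up"

    def test_exhaustive_36_case_truth_table(self):
        """Every sign x significance combination on both axes lands in the
        hand-enumerated cell."""
        cases = list(_TRUTH_TABLE)
        meth = _records([m for m, _ in cases], "meth")
        expr = _records([e for _, e in cases], "expr")
        q = nine_quadrant(meth, expr, RunConfig()).set_index("transcript_id")
        for i, key in enumerate(cases):
            mc, ec, mode = _TRUTH_TABLE[key]
            row = q.loc[f"t{i}"]
            assert (row["meth_class"], row["expr_class"], row["mode"]) == (
                mc,
                ec,
                mode,
            ), key

    def test_boundary_log2fc_of_exactly_one_is_included(self):
        meth = _records([("+", True)], "meth").assign(log2fc=1.0)
        expr = _records([("+", True)], "expr").assign(log2fc=1.0)
        q = nine_quadrant(meth, expr, RunConfig())
        assert q["mode"].iloc[0] == "hyper-up"

    def test_mismatched_transcripts_rejected(self):
        meth = _records([("0", False)], "meth")
        expr = _records([("0", False)], "expr").assign(transcript_id="other")
        with pytest.raises(ValidationError, match="other"):
            nine_quadrant(meth, expr, RunConfig())

    def test_cells_partition_all_transcripts(self, small_sim):
        from meripairray import MeripArrayModel

        res = MeripArrayModel(
            small_sim.intensities, small_sim.annotation, small_sim.design
        ).fit()
        q = res.quadrants
        assert len(q) == res.quant["transcript_id"].nunique()
        assert q["quadrant"].notna().all()
        counts = venn_counts(q)
        total = sum(e["n_transcripts"] for e in counts.values())
        assert total == len(q)


# ---------------------------------------------------------------------------
# lncRNA positional classification


def _ann(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_symbol",
            "biotype",
            "chrom",
            "start",
            "end",
            "strand",
        ],
    )


class TestClassifyLncrna:
    def test_lone_chromosome_is_intergenic(self):
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 100, 200, "+"),
                ("l1", "L1", "lncRNA", "chr2", 100, 200, "+"),
            ]
        )
        out = classify_all_lncrnas(ann)
        assert out["lncrna_class"].iloc[0] == "intergenic"

    def test_identical_span_same_strand_takes_precedence_rule_one(self):
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 100, 200, "+"),
                ("l1", "L1", "lncRNA", "chr1", 100, 200, "+"),
            ]
        )
        out = classify_all_lncrnas(ann)
        assert out["lncrna_class"].iloc[0] == "exon-sense-overlapping"

    def test_opposite_strand_overlap_is_natural_antisense(self):
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 100, 200, "+"),
                ("l1", "L1", "lncRNA", "chr1", 150, 300, "-"),
            ]
        )
        assert classify_all_lncrnas(ann)["lncrna_class"].iloc[0] == "natural-antisense"

    def test_divergent_promoters_within_1kb_are_bidirectional(self):
        # mRNA on + starting at 5000; lncRNA on - ending (TSS) at 4500
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 5000, 9000, "+"),
                ("l1", "L1", "lncRNA", "chr1", 3000, 4500, "-"),
            ]
        )
        assert classify_all_lncrnas(ann)["lncrna_class"].iloc[0] == "bidirectional"

    def test_random_placements_match_independent_rule_oracle(self):
        """500 random lncRNA placements classified identically by a plain
        reimplementation of the precedence rules."""

        def oracle(lnc, mrnas, bw=1000):
            hits = {"ov_same": False, "cont_same": False, "ov_anti": False,
                    "cont_anti": False, "bidir": False}
            for m in mrnas.itertuples():
                if m.chrom != lnc["chrom"]:
                    continue
                ov = lnc["start"] < m.end and m.start < lnc["end"]
                cont = m.start <= lnc["start"] and lnc["end"] <= m.end
                same = m.strand == lnc["strand"]
                if ov and same:
                    hits["ov_same"] = True
                if cont and same:
                    hits["cont_same"] = True
                if ov and not same:
                    hits["ov_anti"] = True
                if cont and not same:
                    hits["cont_anti"] = True
                m_tss = m.start if m.strand == "+" else m.end
                l_tss = lnc["start"] if lnc["strand"] == "+" else lnc["end"]
                if not same and abs(m_tss - l_tss) <= bw and not ov:
                    hits["bidir"] = True
            if hits["ov_same"]:
                return "exon-sense-overlapping"
            if hits["cont_same"]:
                return "intronic"
            if hits["ov_anti"]:
                return "natural-antisense"
            if hits["cont_anti"]:
                return "intronic-antisense"
            # reachable only when nothing overlaps at all
            if not (hits["ov_same"] or hits["ov_anti"]) and hits["bidir"]:
                return "bidirectional"
            return "intergenic"

        rng = np.random.default_rng(99)
        m_rows = []
        for i in range(40):
            start = int(rng.integers(0, 50_000))
            m_rows.append(
                (f"m{i}", f"G{i}", "mRNA", f"chr{rng.integers(1, 3)}",
                 start, start + int(rng.integers(500, 5000)),
                 rng.choice(["+", "-"]))
            )
        mrnas = _ann(m_rows)
        for i in range(500):
            start = int(rng.integers(0, 55_000))
            lnc = pd.Series(
                {
                    "transcript_id": f"l{i}",
                    "chrom": f"chr{rng.integers(1, 3)}",
                    "start": start,
                    "end": start + int(rng.integers(200, 4000)),
                    "strand": rng.choice(["+", "-"]),
                }
            )
            assert classify_lncrna(lnc, mrnas) == oracle(lnc, mrnas), lnc.to_dict()


# ---------------------------------------------------------------------------
# cis targets


class TestCisTargets:
    def test_overlapping_pair_has_distance_zero(self):
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 100, 500, "+"),
                ("l1", "L1", "lncRNA", "chr1", 400, 900, "-"),
            ]
        )
        pairs = find_cis_targets(ann, 100_000)
        assert len(pairs) == 1
        assert pairs["distance_bp"].iloc[0] == 0

    def test_window_boundary_is_inclusive(self):
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 0, 100_000, "+"),
                ("l1", "L1", "lncRNA", "chr1", 200_000, 201_000, "+"),
                ("l2", "L2", "lncRNA", "chr1", 200_001, 201_000, "+"),
            ]
        )
        pairs = find_cis_targets(ann, 100_000)
        assert set(pairs["lncrna_id"]) == {"l1"}
        assert pairs["distance_bp"].iloc[0] == 100_000

    def test_same_coordinates_other_chromosome_excluded(self):
        ann = _ann(
            [
                ("m1", "G1", "mRNA", "chr1", 100, 500, "+"),
                ("l1", "L1", "lncRNA", "chr2", 100, 500, "+"),
            ]
        )
        assert find_cis_targets(ann, 100_000).empty

    def test_matches_all_pairs_oracle_on_random_genome(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(300):
            start = int(rng.integers(0, 2_000_000))
            rows.append(
                (
                    f"t{i}",
                    f"G{i}",
                    rng.choice(["mRNA", "lncRNA"]),
                    f"chr{rng.integers(1, 4)}",
                    start,
                    start + int(rng.integers(200, 20_000)),
                    rng.choice(["+", "-"]),
                )
            )
        ann = _ann(rows)
        window = 50_000
        got = set(
            map(tuple, find_cis_targets(ann, window)[
                ["lncrna_id", "mrna_id", "distance_bp"]
            ].itertuples(index=False))
        )
        expected = set()
        lncs = ann[ann["biotype"] == "lncRNA"]
        mrnas = ann[ann["biotype"] == "mRNA"]
        for l in lncs.itertuples():
            for m in mrnas.itertuples():
                if l.chrom != m.chrom:
                    continue
                gap = max(m.start - l.end, l.start - m.end, 0)
                if gap <= window:
                    expected.add((l.transcript_id, m.transcript_id, gap))
        assert got == expected
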