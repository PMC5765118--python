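"""IR measurement tests against brute-force pileup and gap-scan oracles."""

import numpy as np
import pandas as pd
import pytest

from platesplice.annotation_io import (
    AlignmentBlockRecord,
    Annotation,
    AuxFeature,
    GeneModel,
    derive_introns,
)
from platesplice.ir_quant import (
    IRFilterParams,
    SampleAlignmentIndex,
    compute_fpkm,
    filter_retained,
    intronic_abundance,
    ir_ratio,
    measurable_region,
    splice_abundance,
)
from conftest import plus_gene


def rec(blocks, strand="+", contig="c1", read_id="r"):
    return AlignmentBlockRecord(read_id=read_id, contig=contig,
                                fragment_strand=strand, blocks=tuple(blocks))


def make_index(records, contig_lengths={"c1": 1000}):
    idx = SampleAlignmentIndex(dict(contig_lengths))
    for r in records:
        idx.add(r)
    return idx


# ---------------------------------------------------------------------------
# measurable region
# ---------------------------------------------------------------------------

class TestMeasurableRegion:
    def test_whole_intron_when_nothing_overlaps(self):
        ann = Annotation(genes=[plus_gene()])
        (intron,) = derive_introns(ann.genes[0])
        region = measurable_region(intron, ann)
        assert np.array_equal(region.positions, np.arange(100, 200))

    def test_snorna_is_subtracted(self):
        ann = Annotation(
            genes=[plus_gene()],
            aux_features=[AuxFeature("snoRNA", "c1", 120, 140, "+")])
        (intron,) = derive_introns(ann.genes[0])
        region = measurable_region(intron, ann)
        expected = np.concatenate([np.arange(100, 120), np.arange(140, 200)])
        assert np.array_equal(region.positions, expected)

    def test_overlapping_exon_of_other_gene_empties_region(self):
        ann = Annotation(genes=[
            plus_gene(),
            plus_gene("g2", exons=[(90, 210)], tx_id="t9"),
        ])
        (intron,) = derive_introns(ann.genes[0])
        assert len(measurable_region(intron, ann)) == 0


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def _oracle_depth(records, contig, positions, strand):
    out = []
    for pos in positions:
        n = 0
        for r in records:
            if r.contig != contig:
                continue
            if r.fragment_strand is not None and r.fragment_strand != strand:
                continue
            if any(s <= pos < e for s, e in r.blocks):
                n += 1
        out.append(n)
    return out


def _oracle_gap_count(records, contig, start, end, strand):
    n = 0
    for r in records:
        if r.contig != contig:
            continue
        if r.fragment_strand is not None and r.fragment_strand != strand:
            continue
        n += sum(1 for g in r.gaps if g == (start, end))
    return n


class TestAbundances:
    def setup_method(self):
        self.ann = Annotation(genes=[plus_gene()])
        (self.intron,) = derive_introns(self.ann.genes[0])
        self.region = measurable_region(self.intron, self.ann)

    def test_uniform_coverage_gives_that_depth(self):
        records = [rec([(100, 200)], read_id=f"r{i}") for i in range(10)]
        idx = make_index(records)
        assert intronic_abundance(idx, self.intron, self.region) == 10.0

    def test_no_reads_gives_zero(self):
        idx = make_index([])
        assert intronic_abundance(idx, self.intron, self.region) == 0.0

    def test_staggered_reads_match_pileup_oracle(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(200):
            s = int(rng.integers(60, 230))
            records.append(rec([(s, s + 50)], read_id=f"r{i}",
                               strand=str(rng.choice(["+", "-"]))))
        idx = make_index(records)
        expected = float(np.median(_oracle_depth(
            records, "c1", self.region.positions, "+")))
        assert intronic_abundance(idx, self.intron, self.region) == expected

    def test_exact_gap_counts_and_boundary_mismatch(self):
        records = [
            rec([(50, 100), (200, 250)]),        # gap == intron: counts
            rec([(50, 100), (150, 250)]),        # gap (100,150): no
            rec([(60, 100), (200, 240)]),        # counts
            rec([(50, 100), (200, 250)], strand="-"),  # wrong strand
        ]
        idx = make_index(records)
        assert splice_abundance(idx, self.intron) == 2
        assert splice_abundance(idx, self.intron) == _oracle_gap_count(
            records, "c1", 100, 200, "+")

    def test_mixed_gap_set_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(100):
            a = int(rng.integers(50, 100))
            gap_start = int(rng.choice([100, 101, 110]))
            gap_end = int(rng.choice([200, 199, 190]))
            records.append(rec([(a, gap_start), (gap_end, gap_end + 40)],
                               read_id=f"r{i}"))
        idx = make_index(records)
        assert splice_abundance(idx, self.intron) == _oracle_gap_count(
            records, "c1", 100, 200, "+")


# ---------------------------------------------------------------------------
# IR ratio and retention filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("intronic,splice,expected", [
    (30.0, 70.0, 0.3),
    (5.0, 0.0, 1.0),
    (70.0, 30.0, 0.7),
])
def test_ir_ratio_formula(intronic, splice, expected):
    assert ir_ratio(intronic, splice) == pytest.approx(expected)


def test_ir_ratio_missing_when_denominator_zero():
    assert np.isnan(ir_ratio(0.0, 0.0))


class TestFilterRetained:
    GROUPS = {f"CTRL_{i}": "CTRL" for i in (1, 2, 3)}

    def test_all_missing_gives_empty_set(self):
        m = pd.DataFrame(np.nan, index=["i1", "i2"], columns=list(self.GROUPS))
        assert filter_retained(m, IRFilterParams(), "CTRL", self.GROUPS) == set()

    def test_two_of_three_rule(self):
        # i_hi is above each sample's Q1 in >= 2 replicates; i_lo never is
        m = pd.DataFrame({
            "CTRL_1": [0.9, 0.05, 0.2, 0.3, 0.4],
            "CTRL_2": [0.8, 0.04, 0.3, 0.2, 0.5],
            "CTRL_3": [0.05, 0.04, 0.3, 0.4, 0.5],
        }, index=["i_hi", "i_lo", "i3", "i4", "i5"])
        kept = filter_retained(m, IRFilterParams(), "CTRL", self.GROUPS)
        assert "i_hi" in kept
        assert "i_lo" not in kept

    def test_matches_direct_rule_evaluation(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.uniform(0, 1, (5, 3)),
                         index=[f"i{k}" for k in range(5)],
                         columns=list(self.GROUPS))
        m.iloc[0, 0] = np.nan
        params = IRFilterParams()
        expected = set()
        for intron in m.index:
            n_pass = 0
            for s in m.columns:
                col = m[s].dropna()
                cut = np.quantile(col.to_numpy(), params.quantile_cut)
                v = m.loc[intron, s]
                if not np.isnan(v) and v > cut:
                    n_pass += 1
            if n_pass >= params.min_replicates:
                expected.add(intron)
        assert filter_retained(m, params, "CTRL", self.GROUPS) == expected

    def test_absent_group_is_an_error(self):
        m = pd.DataFrame(0.5, index=["i1"], columns=list(self.GROUPS))
        with pytest.raises(ValueError, match="COLL"):
            filter_retained(m, IRFilterParams(), "COLL", self.GROUPS)


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("count,length,total,expected", [
    (100, 1000, 1e6, 100.0),
    (0, 1000, 1e6, 0.0),
    (50, 500, 2e6, 50.0),
])
def test_fpkm_definition(count, length, total, expected):
    assert compute_fpkm([count], [length], total)[0] == pytest.approx(expected)


def test_fpkm_zero_length_is_an_error():
    with pytest.raises(ValueError):
        compute_fpkm([10], [0], 1e6)
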