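import pytest

from aavstruct import (
    AlignmentBlock, SimConfig, anchor_dataset, chain_blocks,
    classify_structure, concatemeric_fraction, control_comparison, revcomp,
    simulate_reads, summarize_categories,
)
from aavstruct.errors import EmptyInputError


def _block(rs, re, ref_s, ref_e, orient="+", ref="pVector", rid="r"):
    return AlignmentBlock(
        read_id=rid, ref_name=ref, read_start=rs, read_end=re,
        ref_start=ref_s, ref_end=ref_e, orientation=orient,
        longest_match_run=min(re - rs, ref_e - ref_s), aligned_length=re - rs,
    )


class TestChainBlocks:
    def test_ref_contiguous_blocks_merge(self):
        chain = chain_blocks([
            _block(0, 1000, 100, 1100),
            _block(1010, 2000, 1110, 2100),
        ])
        assert len(chain.segments) == 1
        s = chain.segments[0]
        assert (s.read_start, s.read_end) == (0, 2000)
        assert (s.ref_start, s.ref_end) == (100, 2100)

    def test_blocks_on_different_references_stay_separate(self):
        chain = chain_blocks([
            _block(0, 1000, 0, 1000, ref="pVector"),
            _block(1005, 2000, 500, 1495, ref="host_chr"),
        ])
        assert len(chain.segments) == 2 and chain.junction_count == 1

    def test_reverse_strand_merge_is_orientation_aware(self):
        # on '-' strand, later read positions map to earlier ref positions
        chain = chain_blocks([
            _block(0, 1000, 1100, 2100, orient="-"),
            _block(1010, 2000, 100, 1090, orient="-"),
        ])
        assert len(chain.segments) == 1

    def test_contained_secondary_block_dropped(self):
        # a decoy/ITR-homology block inside a longer alignment is discarded
        chain = chain_blocks([
            _block(0, 3000, 0, 3000),
            _block(1200, 1700, 100, 600, ref="host_chr"),
        ])
        assert len(chain.segments) == 1
        assert chain.segments[0].ref_name == "pVector"

    def test_large_read_gaps_recorded(self):
        chain = chain_blocks([
            _block(0, 1000, 0, 1000),
            _block(1500, 2500, 2000, 3000),
        ])
        assert chain.gaps == [(1000, 1500)]

    def test_chain_count_matches_truth_error_free(self, panel):
        cfg = SimConfig(
            seed=23, n_reads=500,
            substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
        )
        reads, truth = simulate_reads(cfg, panel)
        blocks = anchor_dataset(reads, panel)
        agree = 0
        for (rid, _), row in zip(reads, truth.itertuples(index=False)):
            chain = chain_blocks(blocks[rid], read_id=rid, panel=panel)
            expected = row.n_segments + (1 if row.artifact != "none" else 0)
            agree += len(chain.segments) == expected
        assert agree / len(reads) >= 0.99


class TestClassifyStructure:
    def _call(self, blocks, panel, **kw):
        return classify_structure(chain_blocks(blocks), panel, **kw)

    def test_repeated_forward_copies_are_head_to_tail(self, panel):
        blocks = [
            _block(i * 1000, i * 1000 + 990, 500, 1490) for i in range(3)
        ]
        assert self._call(blocks, panel).category == "head_to_tail"

    def test_mirror_inverted_pair_is_duplex_artifact(self, panel):
        blocks = [
            _block(0, 2000, 500, 2500, "+"),
            _block(2000, 4000, 500, 2500, "-"),
        ]
        assert self._call(blocks, panel).category == "duplex_artifact"

    def test_truncated_arm_inverted_pair_is_head_to_head(self, panel):
        call = self._call([
            _block(0, 2000, 500, 2500, "+"),
            _block(2000, 3300, 1200, 2500, "-"),
        ], panel)
        assert call.category == "head_to_head"
        assert "self-complementary" in call.notes

    def test_alternating_orientations(self, panel):
        blocks = [
            _block(i * 1000, i * 1000 + 990, 500, 1490, "+-"[i % 2])
            for i in range(4)
        ]
        assert self._call(blocks, panel).category == "alternating"

    def test_host_plus_vector_is_host_fusion(self, panel):
        blocks = [
            _block(0, 1500, 500, 2000),
            _block(1510, 3000, 30000, 31490, ref="host_chr"),
        ]
        assert self._call(blocks, panel).category == "host_fusion"

    def test_two_plasmids_are_interplasmid(self, panel):
        blocks = [
            _block(0, 1500, 500, 2000),
            _block(1510, 3000, 300, 1790, ref="pRepCap"),
        ]
        assert self._call(blocks, panel).category == "interplasmid_recombinant"

    def test_disjoint_segments_are_complex(self, panel):
        blocks = [
            _block(0, 900, 0, 900),
            _block(910, 1800, 2000, 2890),
            _block(1810, 2700, 1000, 1890, "-"),
        ]
        assert self._call(blocks, panel).category == "complex"

    def test_empty_and_single_segment(self, panel):
        assert self._call([], panel).category == "unclassified"
        assert self._call([_block(0, 3000, 0, 3000)], panel).category == "monomer"

    def test_overlength_flag_follows_packaging_limit(self, panel):
        short = self._call([_block(0, 3000, 0, 3000)], panel)
        assert not short.overlength_flag
        long_call = self._call([
            _block(i * 3000, i * 3000 + 2990, 0, 2990) for i in range(2)
        ], panel)
        assert long_call.total_span > 5000 and long_call.overlength_flag

    def test_category_recovery_on_noisy_reads(self, panel):
        cfg = SimConfig(seed=11, n_reads=200)  # default 5% sub, 1% indel
        reads, truth = simulate_reads(cfg, panel)
        blocks = anchor_dataset(reads, panel)
        ok = sum(
            classify_structure(chain_blocks(blocks[rid], read_id=rid, panel=panel), panel).category
            == row.category
            for (rid, _), row in zip(reads, truth.itertuples(index=False))
        )
        assert ok / len(reads) >= 0.95

    def test_strand_involution_of_classification(self, panel, clean_reads):
        blocks_cache = anchor_dataset(clean_reads[0][:15], panel)
        rc = [(rid, revcomp(seq)) for rid, seq in clean_reads[0][:15]]
        blocks_rc = anchor_dataset(rc, panel)
        for rid, _ in clean_reads[0][:15]:
            a = classify_structure(chain_blocks(blocks_cache[rid], read_id=rid, panel=panel), panel)
            b = classify_structure(chain_blocks(blocks_rc[rid], read_id=rid, panel=panel), panel)
            assert a.category == b.category


class TestSummaries:
    def _calls(self, cats):
        from aavstruct.structure import StructureCall

        return [
            StructureCall(
                read_id=f"r{i}", category=c, overlength_flag=False,
                total_span=3000, n_segments=1, refs_involved=("pVector",),
            )
            for i, c in enumerate(cats)
        ]

    def test_degenerate_single_category(self):
        df = summarize_categories(self._calls(["monomer"] * 10))
        assert df["count"].tolist() == [10]
        assert df["fraction"].tolist() == [1.0]

    def test_counts_conserved_and_additive(self):
        a = self._calls(["monomer"] * 5 + ["complex"] * 3)
        b = self._calls(["head_to_tail"] * 4)
        df_all = summarize_categories(a + b)
        assert df_all["count"].sum() == 12
        assert abs(df_all["fraction"].sum() - 1.0) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_categories([])

    def test_identical_sets_have_zero_difference(self):
        calls = self._calls(["monomer"] * 8 + ["head_to_tail"] * 2)
        rep = control_comparison(calls, calls)
        assert rep["difference"] == 0.0
        assert rep["fisher_p"] == 1.0

    def test_concatemeric_vector_vs_monomeric_control(self):
        vector = self._calls(["head_to_tail"] * 100 + ["monomer"] * 100)
        control = self._calls(["monomer"] * 196 + ["duplex_artifact"] * 4)
        rep = control_comparison(vector, control)
        assert rep["vector_concatemeric_fraction"] == 0.5
        assert rep["control_concatemeric_fraction"] == 0.0
        assert rep["fisher_p"] < 0.001
        assert concatemeric_fraction(control) <= 0.01
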