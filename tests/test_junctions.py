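import numpy as np
import pandas as pd
import pytest

from aavstruct import (
    AlignmentBlock, Junction, chain_blocks, extract_junctions,
    genes_from_panel, hotspot_assessment, junction_position_profile,
    nearest_gene, parse_star_chimeric, self_link_arcs,
)
from aavstruct.errors import ConsistencyError, EmptyInputError, ParseError
from aavstruct.junctions import write_star_chimeric
from aavstruct.structure import SegmentChain


def _block(rs, re, ref_s, ref_e, orient="+", ref="pVector", rid="r"):
    return AlignmentBlock(
        read_id=rid, ref_name=ref, read_start=rs, read_end=re,
        ref_start=ref_s, ref_end=ref_e, orientation=orient,
        longest_match_run=min(re - rs, ref_e - ref_s), aligned_length=re - rs,
    )


def _junction(left, right, jtype, rid="r"):
    return Junction(read_id=rid, left=left, right=right, read_offset=0, jtype=jtype)


class TestExtractJunctions:
    def test_vector_host_pair(self, panel):
        chain = chain_blocks([
            _block(0, 1500, 500, 2000, "+"),
            _block(1510, 3000, 30000, 31490, "+", ref="host_chr"),
        ])
        js = extract_junctions(chain, panel)
        assert len(js) == 1
        j = js[0]
        assert j.jtype == "vector_host"
        assert j.left == ("pVector", 2000, "+")
        assert j.right == ("host_chr", 30000, "+")

    def test_head_to_tail_trimer_has_two_self_links(self, panel):
        chain = chain_blocks([
            _block(i * 1000, i * 1000 + 990, 500, 1490) for i in range(3)
        ])
        js = extract_junctions(chain, panel)
        assert len(js) == 2
        assert all(j.jtype == "self_link" for j in js)

    def test_orientation_aware_breakpoints(self, panel):
        chain = chain_blocks([
            _block(0, 1000, 1000, 2000, "-"),
            _block(1010, 2000, 3000, 3990, "-", ref="pRepCap"),
        ])
        (j,) = extract_junctions(chain, panel)
        # '-' left segment ends at its ref_start; '-' right starts at ref_end
        assert j.left == ("pVector", 1000, "-")
        assert j.right == ("pRepCap", 3990, "-")
        assert j.jtype == "interplasmid"

    def test_single_segment_yields_empty(self, panel):
        chain = SegmentChain(read_id="r", segments=[_block(0, 1000, 0, 1000)])
        assert extract_junctions(chain, panel) == []


class TestStarChimeric:
    def test_parse_typed_lines(self, panel, tmp_path):
        path = tmp_path / "chim.tsv"
        path.write_text(
            "pVector\t101\t+\thost_chr\t30001\t+\t-1\t-1\t-1\trA\n"
            "host_chr\t5001\t-\tpVector\t2001\t+\t-1\t-1\t-1\trB\n"
            "pVector\t201\t+\tpVector\t3001\t-\t-1\t-1\t-1\trC\n"
        )
        js = parse_star_chimeric(path, panel)
        assert [j.jtype for j in js] == ["vector_host", "vector_host", "self_link"]
        assert js[0].left == ("pVector", 100, "+")
        assert js[0].read_id == "rA"

    def test_empty_file(self, panel, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_star_chimeric(path, panel) == []

    def test_unknown_reference_listed(self, panel, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrUn\t100\t+\thost_chr\t200\t+\n")
        with pytest.raises(ParseError, match="chrUn"):
            parse_star_chimeric(path, panel)

    def test_malformed_line_number(self, panel, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pVector\t100\t+\thost_chr\t200\t+\n" "pVector\t100\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_star_chimeric(path, panel)

    def test_round_trip_field_identical(self, panel, tmp_path):
        rng = np.random.default_rng(0)
        refs = list(panel.sequences)
        js = []
        for i in range(50):
            ra, rb = rng.choice(refs, size=2)
            js.append(Junction(
                read_id=f"r{i}",
                left=(ra, int(rng.integers(0, 3000)), "+" if rng.random() < 0.5 else "-"),
                right=(rb, int(rng.integers(0, 3000)), "+" if rng.random() < 0.5 else "-"),
                read_offset=None,
                jtype=(
                    "host_host" if panel.is_host(ra) and panel.is_host(rb)
                    else "vector_host" if panel.is_host(ra) or panel.is_host(rb)
                    else "self_link" if ra == rb
                    else "interplasmid"
                ),
            ))
        path = tmp_path / "rt.tsv"
        write_star_chimeric(js, path)
        assert parse_star_chimeric(path, panel) == js


class TestProfile:
    def test_no_junctions_gives_full_zero_vector(self):
        prof = junction_position_profile([], "pVector", 6000)
        assert len(prof) == 6000 and prof.sum() == 0

    def test_counts_accumulate(self):
        js = [
            _junction(("pVector", 100, "+"), ("pVector", 3000, "+"), "self_link"),
            _junction(("pVector", 100, "+"), ("host_chr", 5, "+"), "vector_host"),
        ]
        prof = junction_position_profile(js, "pVector", 6000)
        assert prof[100] == 2 and prof[3000] == 1

    def test_endpoint_conservation_across_references(self, panel):
        rng = np.random.default_rng(4)
        refs = list(panel.sequences)
        js = []
        for i in range(200):
            ra, rb = rng.choice(refs, size=2)
            la = int(rng.integers(0, len(panel.sequences[ra])))
            lb = int(rng.integers(0, len(panel.sequences[rb])))
            js.append(_junction((ra, la, "+"), ((rb, lb, "+")), "self_link", rid=f"r{i}"))
        total = sum(
            junction_position_profile(js, r, len(panel.sequences[r])).sum()
            for r in refs
        )
        assert total == 2 * len(js)

    def test_out_of_bounds_position_rejected(self):
        js = [_junction(("pVector", 9000, "+"), ("pVector", 10, "+"), "self_link")]
        with pytest.raises(ConsistencyError):
            junction_position_profile(js, "pVector", 6000)


class TestNearestGene:
    def test_inside_gene_distance_zero(self, panel):
        genes = genes_from_panel(panel)
        g = genes.iloc[0]
        gid, dist, inside = nearest_gene((g["ref_name"], int(g["start"]) + 5), genes)
        assert (gid, dist, inside) == (g["gene_id"], 0, True)

    def test_equidistant_tie_goes_to_smaller_start(self):
        genes = pd.DataFrame({
            "gene_id": ["b_gene", "a_gene"],
            "ref_name": ["host_chr"] * 2,
            "start": [200, 0],
            "end": [300, 101],
        })
        # position 150 is 50 bp from both gene boundaries
        gid, dist, inside = nearest_gene(("host_chr", 150), genes)
        assert gid == "a_gene" and dist == 50 and not inside

    def test_empty_annotation_rejected(self):
        with pytest.raises(EmptyInputError):
            nearest_gene(("host_chr", 5), pd.DataFrame())

    def test_matches_brute_force_scan(self, panel):
        genes = genes_from_panel(panel)
        host = panel.host_refs()[0]
        hlen = len(panel.sequences[host])
        rng = np.random.default_rng(8)
        sub = genes[genes["ref_name"] == host]
        for pos in rng.integers(0, hlen, size=200):
            pos = int(pos)
            got = nearest_gene((host, pos), genes)
            best = None
            for row in sub.itertuples(index=False):
                if row.start <= pos < row.end:
                    d = 0
                else:
                    d = min(abs(row.start - pos), abs(pos - row.end + 1))
                if best is None or d < best[1] or (d == best[1] and row.start < best[3]):
                    best = (row.gene_id, d, d == 0, row.start)
            assert got == best[:3]


class TestHotspots:
    def test_single_loaded_bin_flagged(self):
        prof = np.zeros(5000, dtype=int)
        prof[250:260] = 50
        df = hotspot_assessment(prof, bin_size=100, fdr=0.05)
        flagged = df[df["hotspot"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["bin_start"] == 200

    def test_empty_profile_rejected(self):
        with pytest.raises(EmptyInputError):
            hotspot_assessment(np.zeros(1000, dtype=int))

    def test_bin_larger_than_profile_rejected(self):
        prof = np.ones(50, dtype=int)
        with pytest.raises(ValueError):
            hotspot_assessment(prof, bin_size=100)

    def test_uniform_null_rarely_flags(self):
        rng = np.random.default_rng(12)
        zero_flag_replicates = 0
        n_rep = 30
        for _ in range(n_rep):
            prof = np.bincount(rng.integers(0, 5000, size=1000), minlength=5000)
            df = hotspot_assessment(prof, bin_size=100, fdr=0.05)
            zero_flag_replicates += int(df["hotspot"].sum() == 0)
        assert zero_flag_replicates / n_rep >= 0.9


class TestSelfLinkArcs:
    def test_single_link_ordered(self):
        js = [_junction(("pVector", 3000, "+"), ("pVector", 150, "+"), "self_link")]
        df = self_link_arcs(js)
        assert df.iloc[0].tolist() == [150, 3000, 1]

    def test_identical_links_aggregate(self):
        js = [
            _junction(("pVector", 3001, "+"), ("pVector", 149, "+"), "self_link"),
            _junction(("pVector", 2999, "+"), ("pVector", 151, "+"), "self_link"),
        ]
        df = self_link_arcs(js, arc_round=10)
        assert df.iloc[0]["count"] == 2

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        js = [
            _junction(("pVector", int(rng.integers(0, 6000)), "+"),
                      ("pVector", int(rng.integers(0, 6000)), "+"), "self_link")
            for _ in range(100)
        ] + [
            _junction(("pVector", 10, "+"), ("host_chr", 10, "+"), "vector_host")
        ]
        df = self_link_arcs(js)
        assert df["count"].sum() == 100
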