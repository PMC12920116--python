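"""Segment chaining and structural classification of vector reads.

A read's alignment blocks are reduced to an ordered chain of segments
(collinear blocks merged, redundant overlapping blocks resolved), then the
chain is assigned one structural category:

``monomer``
    a single vector segment;
``head_to_tail`` / ``head_to_head`` / ``alternating``
    concatemeric repeats of one unit in the orientation patterns produced by
    rolling-circle / rolling-hairpin replication;
``interplasmid_recombinant``
    segments from two or more distinct manufacturing plasmids;
``host_fusion``
    vector (or other plasmid) joined to host sequence;
``duplex_artifact``
    the nanopore artifact in which a molecule's complementary strand is
    sequenced directly after its template — recognized as an exact
    read-mirror inverted pair and deliberately kept out of ``complex``;
``complex``
    everything else with two or more segments.

Rules are evaluated in a fixed precedence order (inter-reference junctions
first, since those are the rarer, higher-stakes calls), documented on
:func:`classify_structure`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from scipy.stats import fisher_exact

from .align import AlignmentBlock
from .errors import EmptyInputError
from .panel import ReferencePanel

STRUCTURE_CATEGORIES = (
    "unclassified", "monomer", "head_to_tail", "head_to_head", "alternating",
    "interplasmid_recombinant", "host_fusion", "complex", "duplex_artifact",
)

#: categories counted as concatemeric in the control comparison
CONCATEMERIC = ("head_to_tail", "head_to_head", "alternating", "complex")


@dataclass
class SegmentChain:
    """Read-ordered, merged segments of one read."""

    read_id: str
    segments: list[AlignmentBlock]
    gaps: list[tuple[int, int]] = field(default_factory=list)  # unanchored read gaps

    @property
    def junction_count(self) -> int:
        return max(0, len(self.segments) - 1)

    @property
    def refs_involved(self) -> set[str]:
        return {s.ref_name for s in self.segments}

    @property
    def total_span(self) -> int:
        """Molecule span estimate: sum of reference interval lengths."""
        return sum(s.ref_end - s.ref_start for s in self.segments)


def _select_primary(
    blocks: list[AlignmentBlock],
    panel: ReferencePanel | None = None,
    overlap_cap: float = 0.5,
):
    """Drop blocks mostly contained in longer kept blocks on the read.

    Handles ITR self-homology and vector-homologous host loci, which produce
    short secondary blocks inside a longer alignment's read interval.  Exact
    ties (a read interval matching a plasmid and a homologous host locus
    equally well) are resolved toward the plasmid, then toward the reference
    and orientation of the read's dominant block.
    """
    if not blocks:
        return []

    def class_rank(b):
        return 1 if panel is not None and panel.is_host(b.ref_name) else 0

    dominant = min(blocks, key=lambda b: (
        -(b.read_end - b.read_start), -b.longest_match_run,
        class_rank(b), b.ref_name, b.read_start,
    ))
    kept: list[AlignmentBlock] = []
    for b in sorted(blocks, key=lambda b: (
        -(b.read_end - b.read_start), -b.longest_match_run,
        class_rank(b),
        b.ref_name != dominant.ref_name,
        b.orientation != dominant.orientation,
        b.ref_name, b.read_start,
    )):
        own = b.read_end - b.read_start
        ov = 0
        for k in kept:
            lo = max(b.read_start, k.read_start)
            hi = min(b.read_end, k.read_end)
            ov = max(ov, hi - lo)
        if ov <= overlap_cap * own:
            kept.append(b)
    kept.sort(key=lambda b: b.read_start)
    return kept


def _collinear(a: AlignmentBlock, b: AlignmentBlock, tol: int, gap_tol: int) -> bool:
    # gaps (anchor deserts from clustered errors) may span up to gap_tol;
    # diagonal drift stays bounded by the tighter merge tolerance
    if a.ref_name != b.ref_name or a.orientation != b.orientation:
        return False
    read_gap = b.read_start - a.read_end
    if not -tol <= read_gap <= gap_tol:
        return False
    if a.orientation == "+":
        ref_gap = b.ref_start - a.ref_end
    else:
        ref_gap = a.ref_start - b.ref_end
    if not -tol <= ref_gap <= gap_tol:
        return False
    return abs(read_gap - ref_gap) <= tol


def _merge(a: AlignmentBlock, b: AlignmentBlock) -> AlignmentBlock:
    return replace(
        a,
        read_start=min(a.read_start, b.read_start),
        read_end=max(a.read_end, b.read_end),
        ref_start=min(a.ref_start, b.ref_start),
        ref_end=max(a.ref_end, b.ref_end),
        longest_match_run=max(a.longest_match_run, b.longest_match_run),
        aligned_length=max(a.read_end, b.read_end) - min(a.read_start, b.read_start),
    )


def chain_blocks(
    blocks: list[AlignmentBlock],
    merge_tol: int = 50,
    max_read_gap: int = 100,
    merge_gap: int = 250,
    read_id: str | None = None,
    panel: ReferencePanel | None = None,
) -> SegmentChain:
    """Order blocks along the read and merge collinear neighbours.

    Collinear means same reference and orientation, diagonal drift within
    ``merge_tol``, and read/ref gaps no larger than ``merge_gap``.  The gap
    bound is looser than the drift bound because clustered sequencing errors
    regularly leave unanchorable stretches of one to two hundred bases that
    split a single true alignment; the drift condition is what separates
    such splits from genuine junctions (a real junction shifts the diagonal
    by the distance between the joined loci).  Read gaps larger than
    ``max_read_gap`` between surviving segments are recorded as unanchored
    gaps.
    """
    if read_id is None:
        read_id = blocks[0].read_id if blocks else "read"
    if not blocks:
        return SegmentChain(read_id=read_id, segments=[])
    primary = _select_primary(blocks, panel=panel)
    if panel is not None and len(primary) > 1:
        # an ITR is its own reverse complement's twin, so a block confined to
        # an ITR carries no reliable orientation or position signal; drop it
        # when the read has any substantive alignment elsewhere
        itrs = [f for f in panel.features if f.label in ("ITR_left", "ITR_right")]
        def _itr_only(b):
            return any(
                f.ref_name == b.ref_name
                and b.ref_start >= f.start - 25 and b.ref_end <= f.end + 25
                for f in itrs
            )
        substantive = [b for b in primary if not _itr_only(b)]
        if substantive:
            primary = substantive
    merged: list[AlignmentBlock] = []
    for b in primary:
        if merged and _collinear(merged[-1], b, merge_tol, max(merge_tol, merge_gap)):
            merged[-1] = _merge(merged[-1], b)
        else:
            merged.append(b)
    gaps = [
        (a.read_end, b.read_start)
        for a, b in zip(merged, merged[1:])
        if b.read_start - a.read_end > max_read_gap
    ]
    return SegmentChain(read_id=read_id, segments=merged, gaps=gaps)


@dataclass
class StructureCall:
    read_id: str
    category: str
    overlength_flag: bool
    total_span: int
    n_segments: int
    refs_involved: tuple[str, ...]
    notes: str = ""


def reciprocal_overlap(a: AlignmentBlock, b: AlignmentBlock) -> float:
    """Overlap of the two reference intervals over the longer of the two."""
    lo = max(a.ref_start, b.ref_start)
    hi = min(a.ref_end, b.ref_end)
    if hi <= lo:
        return 0.0
    la, lb = a.ref_end - a.ref_start, b.ref_end - b.ref_start
    return (hi - lo) / max(la, lb)


def _is_mirror(chain: SegmentChain, tol: int) -> bool:
    """Second segment mirrors the first across the read midpoint."""
    a, b = chain.segments
    lo, hi = a.read_start, b.read_end
    return (
        abs(b.read_start - (lo + hi - a.read_end)) <= tol
        and abs(b.read_end - (lo + hi - a.read_start)) <= tol
    )


def classify_structure(
    chain: SegmentChain,
    panel: ReferencePanel,
    overlap_frac: float = 0.5,
    packaging_limit: int = 5000,
    duplex_overlap: float = 0.9,
    duplex_mirror_tol: int = 250,
) -> StructureCall:
    """Assign one structural category by first matching rule.

    Precedence: unclassified (0 segments) > monomer (1) > host_fusion >
    interplasmid_recombinant > duplex_artifact > head_to_head >
    head_to_tail > alternating > complex.  The duplex rule requires exactly
    two opposite-orientation segments of the same reference with reciprocal
    overlap >= ``duplex_overlap`` *and* mirror symmetry across the read
    midpoint; genuine inverted dimers that fail either condition fall
    through to head_to_head.  Reads whose estimated molecule span exceeds
    ``packaging_limit`` (the ~5 kb AAV capsid capacity) carry
    ``overlength_flag``.
    """
    segs = chain.segments
    n = len(segs)
    span = chain.total_span
    over = span > packaging_limit
    notes = ""

    def call(cat):
        return StructureCall(
            read_id=chain.read_id, category=cat, overlength_flag=over,
            total_span=span, n_segments=n,
            refs_involved=tuple(sorted(chain.refs_involved)), notes=notes,
        )

    if n == 0:
        return call("unclassified")
    if n == 1:
        return call("monomer")

    refs = chain.refs_involved
    has_host = any(panel.is_host(r) for r in refs)
    plasmids = {r for r in refs if panel.is_plasmid(r)}
    if has_host and plasmids:
        return call("host_fusion")
    if len(plasmids) >= 2:
        return call("interplasmid_recombinant")

    same_ref = len(refs) == 1
    if n == 2 and same_ref and segs[0].orientation != segs[1].orientation:
        ov = reciprocal_overlap(segs[0], segs[1])
        if ov >= duplex_overlap and _is_mirror(chain, duplex_mirror_tol):
            return call("duplex_artifact")
        if ov >= overlap_frac:
            ref = segs[0].ref_name
            if panel.ref_class.get(ref) == "vector_plasmid":
                notes = "consistent with self-complementary genome"
            return call("head_to_head")

    if same_ref and n >= 2:
        orients = [s.orientation for s in segs]
        consec = [reciprocal_overlap(a, b) for a, b in zip(segs, segs[1:])]
        if len(set(orients)) == 1 and all(o >= overlap_frac for o in consec):
            return call("head_to_tail")
        if (
            n >= 3
            and all(x != y for x, y in zip(orients, orients[1:]))
            and all(o >= overlap_frac for o in consec)
        ):
            return call("alternating")

    return call("complex")


def summarize_categories(calls: list[StructureCall], group_label: str = "all") -> pd.DataFrame:
    """Count and fraction per category; totals conserved."""
    if not calls:
        raise EmptyInputError("no structure calls to summarize")
    counts = pd.Series([c.category for c in calls]).value_counts()
    df = pd.DataFrame({
        "group": group_label,
        "category": counts.index,
        "count": counts.values,
    })
    df["fraction"] = df["count"] / df["count"].sum()
    return df.sort_values("category").reset_index(drop=True)


def concatemeric_fraction(calls: list[StructureCall]) -> float:
    if not calls:
        raise EmptyInputError("no structure calls")
    return sum(c.category in CONCATEMERIC for c in calls) / len(calls)


def control_comparison(
    vector_calls: list[StructureCall],
    control_calls: list[StructureCall],
) -> dict:
    """Compare a vector read set against a host-gene negative control.

    Reports side-by-side category fractions, the concatemeric fraction
    (head_to_tail + head_to_head + alternating + complex) in each set, and a
    two-sided Fisher exact test of concatemeric vs non-concatemeric counts.
    """
    if not vector_calls or not control_calls:
        raise EmptyInputError("both call sets must be nonempty")
    sv = summarize_categories(vector_calls, "vector")
    sc = summarize_categories(control_calls, "control")
    table = (
        pd.concat([sv, sc])
        .pivot_table(index="category", columns="group", values="fraction", fill_value=0.0)
        .reset_index()
    )
    cv = sum(c.category in CONCATEMERIC for c in vector_calls)
    cc = sum(c.category in CONCATEMERIC for c in control_calls)
    nv, nc = len(vector_calls), len(control_calls)
    odds, p = fisher_exact([[cv, nv - cv], [cc, nc - cc]], alternative="two-sided")
    return {
        "per_category": table,
        "vector_concatemeric_fraction": cv / nv,
        "control_concatemeric_fraction": cc / nc,
        "difference": cv / nv - cc / nc,
        "fisher_odds_ratio": float(odds),
        "fisher_p": float(p),
        "n_vector": nv,
        "n_control": nc,
    }


def calls_to_dataframe(calls: list[StructureCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "read_id": c.read_id, "category": c.category,
            "overlength_flag": c.overlength_flag, "total_span": c.total_span,
            "n_segments": c.n_segments,
            "refs_involved": ",".join(c.refs_involved),
            "notes": c.notes,
        }
        for c in calls
    ])
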