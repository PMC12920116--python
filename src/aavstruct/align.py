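"""Alignment blocks from standard formats or the built-in k-mer anchorer.

Reads are represented as chains of :class:`AlignmentBlock` records — one
local alignment of a read interval to a reference interval, carrying the
longest contiguous match/mismatch run (no insertions or deletions), the
statistic the downstream retention filter requires.

Blocks come from two sources: parsing SAM/PAF produced by an external
long-read aligner such as minimap2, or the built-in exact-k-mer
anchor-and-chain aligner intended for desk-scale synthetic data where
substitution/indel rates are modest (<= ~5%, leaving abundant intact
15-mers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pysam

from .errors import ParseError
from .panel import ReferencePanel, revcomp

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric convention)
_CIG_MATCH = {0, 7, 8}   # M, =, X extend a match run
_CIG_BREAK = {1, 2, 3}   # I, D, N break it
_CIG_QUERY = {0, 1, 4, 7, 8}  # consume query
_CIG_CLIP = {4, 5}


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment of a read interval to a reference interval."""

    read_id: str
    ref_name: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    orientation: str  # '+' or '-'
    longest_match_run: int
    aligned_length: int  # bp on the read

    def __post_init__(self):
        if not (self.read_start < self.read_end and self.ref_start < self.ref_end):
            raise ValueError(f"degenerate block for read {self.read_id}")
        if self.longest_match_run > self.aligned_length:
            raise ValueError("longest_match_run exceeds aligned_length")


def longest_run_from_cigar(cigartuples) -> int:
    """Longest contiguous M/=/X stretch, broken by I/D/N."""
    best = cur = 0
    for op, length in cigartuples:
        if op in _CIG_MATCH:
            cur += length
            best = max(best, cur)
        elif op in _CIG_BREAK:
            cur = 0
    return best


def _sam_blocks(path) -> list[AlignmentBlock]:
    blocks = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped += 1
                continue
            if aln.cigartuples is None:
                raise ParseError(f"SAM record {aln.query_name} lacks a CIGAR")
            full_len = aln.infer_read_length()
            lead = trail = 0
            cig = aln.cigartuples
            if cig and cig[0][0] in _CIG_CLIP:
                lead = cig[0][1]
            if len(cig) > 1 and cig[-1][0] in _CIG_CLIP:
                trail = cig[-1][1]
            qspan = sum(l for op, l in cig if op in _CIG_QUERY) - lead - trail
            if aln.is_reverse:
                read_start = full_len - lead - qspan
                read_end = full_len - lead
            else:
                read_start = lead
                read_end = lead + qspan
            blocks.append(AlignmentBlock(
                read_id=aln.query_name,
                ref_name=aln.reference_name,
                read_start=read_start,
                read_end=read_end,
                ref_start=aln.reference_start,
                ref_end=aln.reference_end,
                orientation="-" if aln.is_reverse else "+",
                longest_match_run=longest_run_from_cigar(cig),
                aligned_length=read_end - read_start,
            ))
    if skipped:
        logger.info("skipped %d unmapped SAM records", skipped)
    return _dedup(blocks)


def _cigar_tuples_from_string(cg: str, line: int):
    ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}
    out, num = [], ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        elif ch in ops and num:
            out.append((ops[ch], int(num)))
            num = ""
        else:
            raise ParseError(f"bad CIGAR '{cg}'", line)
    if num:
        raise ParseError(f"bad CIGAR '{cg}'", line)
    return out


def _paf_blocks(path) -> list[AlignmentBlock]:
    blocks = []
    downgraded = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            cols = raw.split("\t")
            if len(cols) < 12:
                raise ParseError(f"PAF needs 12 columns, got {len(cols)}", lineno)
            try:
                qname, _qlen, qstart, qend = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
                strand = cols[4]
                tname, _tlen, tstart, tend = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
            except ValueError as exc:
                raise ParseError(f"non-numeric PAF field: {exc}", lineno) from None
            if strand not in "+-":
                raise ParseError(f"bad strand '{strand}'", lineno)
            cg = None
            for tag in cols[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
            aligned = qend - qstart
            if cg is not None:
                run = longest_run_from_cigar(_cigar_tuples_from_string(cg, lineno))
            else:
                run = aligned
                downgraded += 1
            blocks.append(AlignmentBlock(
                read_id=qname, ref_name=tname,
                read_start=qstart, read_end=qend,
                ref_start=tstart, ref_end=tend,
                orientation=strand,
                longest_match_run=run, aligned_length=aligned,
            ))
    if downgraded:
        logger.warning(
            "%d PAF records lacked cg tags; longest_match_run downgraded "
            "to aligned_length", downgraded,
        )
    return _dedup(blocks)


def _dedup(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    seen, out = set(), []
    for b in blocks:
        key = (b.read_id, b.ref_name, b.read_start, b.read_end,
               b.ref_start, b.ref_end, b.orientation)
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


def parse_alignments(path, format: str = "auto") -> list[AlignmentBlock]:
    """Parse SAM or PAF into alignment blocks.

    Secondary and supplementary records are retained; exact-duplicate blocks
    are removed.  PAF records without a ``cg`` CIGAR tag fall back to
    ``longest_match_run = aligned_length`` with a logged downgrade.
    """
    fmt = format.lower()
    if fmt == "auto":
        fmt = "paf" if str(path).endswith(".paf") else "sam"
    if fmt == "sam":
        return _sam_blocks(path)
    if fmt == "paf":
        return _paf_blocks(path)
    raise ValueError(f"unknown alignment format '{format}'")


def write_paf(blocks, path, read_lengths: dict[str, int], ref_lengths: dict[str, int]):
    """Serialize blocks as 12-column PAF with a cg tag preserving the run."""
    with open(path, "w") as fh:
        for b in blocks:
            rspan = b.read_end - b.read_start
            tspan = b.ref_end - b.ref_start
            run = min(b.longest_match_run, rspan, tspan)
            rr, tr = rspan - run, tspan - run
            cg = f"{run}M"
            if rr > 0:
                cg += f"{rr}I"
            if tr > 0:
                cg += f"{tr}D"
            fh.write("\t".join(map(str, [
                b.read_id, read_lengths[b.read_id], b.read_start, b.read_end,
                b.orientation, b.ref_name, ref_lengths[b.ref_name],
                b.ref_start, b.ref_end, run, max(rspan, tspan), 60,
                f"cg:Z:{cg}",
            ])) + "\n")


# ------------------------------------------------------- built-in anchorer


class KmerIndex:
    """Exact k-mer index over a reference panel (forward strands only)."""

    def __init__(self, panel: ReferencePanel, k: int = 15):
        self.k = k
        self.panel = panel
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in panel.sequences.items():
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos:pos + k], []).append((name, pos))

    def lookup(self, kmer: str):
        return self.index.get(kmer, ())


class _Chain:
    __slots__ = ("anchors_r0", "last_r", "last_p", "diag",
                 "min_r", "max_r", "min_p", "max_p",
                 "run_diag", "run_start", "run_end", "best_run")

    def __init__(self, r, p, k, diag):
        self.last_r, self.last_p, self.diag = r, p, diag
        self.min_r, self.max_r = r, r + k
        self.min_p, self.max_p = p, p + k
        self.run_diag, self.run_start, self.run_end = diag, r, r + k
        self.best_run = k

    def add(self, r, p, k, diag):
        self.last_r, self.last_p = r, p
        self.diag = diag
        self.min_r, self.max_r = min(self.min_r, r), max(self.max_r, r + k)
        self.min_p, self.max_p = min(self.min_p, p), max(self.max_p, p + k)
        # same diagonal means no net indel since the previous anchor, so the
        # match/mismatch run continues across substitution-only gaps; any
        # diagonal change implies an indel and resets the run
        if diag == self.run_diag:
            self.run_end = r + k
        else:
            self.run_diag, self.run_start, self.run_end = diag, r, r + k
        self.best_run = max(self.best_run, self.run_end - self.run_start)


def anchor_segments(
    read: str,
    panel: ReferencePanel,
    k: int = 15,
    min_anchor_chain: int = 100,
    max_diag_drift: int = 30,
    max_read_gap: int = 100,
    read_id: str = "read",
    index: KmerIndex | None = None,
) -> list[AlignmentBlock]:
    """Anchor-and-chain alignment of one read against the panel.

    Exact k-mer matches on both strands are chained when they share the
    reference and strand, drift no more than ``max_diag_drift`` off the
    diagonal, and sit within ``max_read_gap`` on the read.  Chains shorter
    than ``min_anchor_chain`` on the read are discarded.
    ``longest_match_run`` is the extent of the longest same-diagonal stretch
    of anchors within a chain — the longest indel-free (match/mismatch only)
    alignment stretch, matching the statistic a CIGAR M-run yields.
    """
    if len(read) < k:
        return []
    if index is None:
        index = KmerIndex(panel, k)
    elif index.k != k:
        raise ValueError("index built with a different k")

    # anchors[(ref, strand)] -> list of (read_pos, ref_pos) sorted by read_pos
    anchors: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in range(len(read) - k + 1):
        kmer = read[r:r + k]
        for ref, p in index.lookup(kmer):
            anchors.setdefault((ref, "+"), []).append((r, p))
        for ref, p in index.lookup(revcomp(kmer)):
            anchors.setdefault((ref, "-"), []).append((r, p))

    blocks = []
    for (ref, strand), alist in anchors.items():
        active: list[_Chain] = []
        done: list[_Chain] = []
        for r, p in alist:
            diag = r - p if strand == "+" else r + p
            # retire chains too far behind on the read
            still = []
            for c in active:
                if r - c.last_r > max_read_gap:
                    done.append(c)
                else:
                    still.append(c)
            active = still
            best, bestd = None, None
            for c in active:
                d = abs(diag - c.diag)
                if d <= max_diag_drift and (bestd is None or d < bestd):
                    best, bestd = c, d
            if best is None:
                active.append(_Chain(r, p, k, diag))
            else:
                best.add(r, p, k, diag)
        done.extend(active)
        for c in done:
            if c.max_r - c.min_r < min_anchor_chain:
                continue
            blocks.append(AlignmentBlock(
                read_id=read_id, ref_name=ref,
                read_start=c.min_r, read_end=c.max_r,
                ref_start=c.min_p, ref_end=c.max_p,
                orientation=strand,
                longest_match_run=c.best_run,
                aligned_length=c.max_r - c.min_r,
            ))
    blocks.sort(key=lambda b: (b.read_start, b.read_end, b.ref_name,
                               b.ref_start, b.ref_end, b.orientation))
    return _dedup(blocks)


def anchor_dataset(
    reads: list[tuple[str, str]],
    panel: ReferencePanel,
    k: int = 15,
    min_anchor_chain: int = 100,
    **kwargs,
) -> dict[str, list[AlignmentBlock]]:
    """Anchor a list of (read_id, sequence) pairs; index built once."""
    index = KmerIndex(panel, k)
    out = {}
    for rid, seq in reads:
        out[rid] = anchor_segments(
            seq, panel, k=k, min_anchor_chain=min_anchor_chain,
            read_id=rid, index=index, **kwargs,
        )
    return out


def blocks_to_dataframe(blocks_by_read: dict[str, list[AlignmentBlock]]):
    import pandas as pd

    from dataclasses import asdict

    rows = [asdict(b) for bl in blocks_by_read.values() for b in bl]
    cols = ["read_id", "ref_name", "read_start", "read_end", "ref_start",
            "ref_end", "orientation", "longest_match_run", "aligned_length"]
    return pd.DataFrame(rows, columns=cols)


def dataframe_to_blocks(df) -> dict[str, list[AlignmentBlock]]:
    out: dict[str, list[AlignmentBlock]] = {}
    for row in df.itertuples(index=False):
        b = AlignmentBlock(
            read_id=row.read_id, ref_name=row.ref_name,
            read_start=int(row.read_start), read_end=int(row.read_end),
            ref_start=int(row.ref_start), ref_end=int(row.ref_end),
            orientation=row.orientation,
            longest_match_run=int(row.longest_match_run),
            aligned_length=int(row.aligned_length),
        )
        out.setdefault(b.read_id, []).append(b)
    return out


def mirror_blocks(blocks: list[AlignmentBlock], read_length: int) -> list[AlignmentBlock]:
    """Blocks of the reverse-complemented read: strand flipped, coords mirrored."""
    out = []
    for b in blocks:
        out.append(replace(
            b,
            read_start=read_length - b.read_end,
            read_end=read_length - b.read_start,
            orientation="-" if b.orientation == "+" else "+",
        ))
    out.sort(key=lambda b: (b.read_start, b.read_end, b.ref_name,
                            b.ref_start, b.ref_end, b.orientation))
    return out
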