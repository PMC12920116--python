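"""Read-retention filter.

A read is kept when it is over 1,000 bp long, at least 80% of its length is
covered by alignments, and at least one alignment contains a continuous
stretch of matches/mismatches (no insertions or deletions) of at least
100 bp.  Coverage is computed on the union of read-coordinate intervals by
default so that concatemeric self-overlapping alignments are not
double-counted; a summation mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentBlock
from .errors import ConsistencyError


@dataclass
class FilterVerdict:
    read_id: str
    read_length: int
    total_aligned: int
    aligned_fraction: float
    max_match_run: int
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)


def union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    total = 0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def filter_reads(
    read_lengths: dict[str, int],
    blocks_by_read: dict[str, list[AlignmentBlock]],
    min_length: int = 1000,
    min_fraction: float = 0.8,
    min_run: int = 100,
    coverage_mode: str = "union",
) -> list[FilterVerdict]:
    """Emit one verdict per read in ``read_lengths`` (zero-block reads too).

    Length is a strict inequality (``read_length > min_length``); fraction
    and run thresholds are inclusive.  ``coverage_mode`` is ``"union"``
    (default) or ``"sum"``.
    """
    if coverage_mode not in ("union", "sum"):
        raise ValueError(f"coverage_mode '{coverage_mode}'")
    verdicts = []
    for read_id in read_lengths:
        length = read_lengths[read_id]
        blocks = blocks_by_read.get(read_id, [])
        for b in blocks:
            if b.read_end > length:
                raise ConsistencyError(
                    f"read {read_id}: block [{b.read_start},{b.read_end}) "
                    f"exceeds read length {length}"
                )
        intervals = [(b.read_start, b.read_end) for b in blocks]
        if coverage_mode == "union":
            aligned = union_length(intervals)
        else:
            aligned = sum(e - s for s, e in intervals)
        fraction = aligned / length if length else 0.0
        max_run = max((b.longest_match_run for b in blocks), default=0)

        reasons = []
        if length <= min_length:
            reasons.append("too_short")
        if fraction < min_fraction:
            reasons.append("low_aligned_fraction")
        if max_run < min_run:
            reasons.append("no_long_match_run")
        verdicts.append(FilterVerdict(
            read_id=read_id, read_length=length, total_aligned=aligned,
            aligned_fraction=fraction, max_match_run=max_run,
            passed=not reasons, fail_reasons=reasons,
        ))
    return verdicts


def verdicts_to_dataframe(verdicts: list[FilterVerdict]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "read_id": v.read_id, "read_length": v.read_length,
            "total_aligned": v.total_aligned,
            "aligned_fraction": v.aligned_fraction,
            "max_match_run": v.max_match_run,
            "passed": v.passed,
            "fail_reasons": ",".join(v.fail_reasons),
        }
        for v in verdicts
    ])
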