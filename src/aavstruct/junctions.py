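"""Breakpoint extraction, annotation and spatial statistics.

Each pair of consecutive segments in a read chain defines a junction whose
reference-side breakpoints are taken orientation-aware: the coordinate of
the last aligned base boundary of the left segment and the first of the
right segment (0-based).  Junctions are typed from the reference classes:
``self_link`` (both sides on the same plasmid — vector-to-vector
interactions), ``interplasmid``, ``vector_host`` and ``host_host``.

Host-side breakpoints are annotated with the nearest gene and the distance
to its body boundaries (0 when the breakpoint falls inside the gene).
Junction-position profiles report every reference position, including those
with zero coverage, and a binned binomial test with Benjamini–Hochberg
correction flags positional hotspots against the uniform expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, EmptyInputError, ParseError
from .panel import ReferencePanel
from .structure import SegmentChain

logger = logging.getLogger(__name__)

JUNCTION_TYPES = ("self_link", "interplasmid", "vector_host", "host_host")


@dataclass
class Junction:
    read_id: str
    left: tuple[str, int, str]   # (ref_name, ref_pos, orientation)
    right: tuple[str, int, str]
    read_offset: int | None
    jtype: str
    nearest_gene: tuple[str, int, bool] | None = None  # (gene_id, distance, inside)


def _jtype(panel: ReferencePanel, ref_a: str, ref_b: str) -> str:
    a_host, b_host = panel.is_host(ref_a), panel.is_host(ref_b)
    if a_host and b_host:
        return "host_host"
    if a_host or b_host:
        return "vector_host"
    if ref_a == ref_b:
        return "self_link"
    return "interplasmid"


def extract_junctions(chain: SegmentChain, panel: ReferencePanel) -> list[Junction]:
    """One junction per consecutive segment pair; empty for single segments."""
    out = []
    for a, b in zip(chain.segments, chain.segments[1:]):
        left_pos = a.ref_end if a.orientation == "+" else a.ref_start
        right_pos = b.ref_start if b.orientation == "+" else b.ref_end
        out.append(Junction(
            read_id=chain.read_id,
            left=(a.ref_name, left_pos, a.orientation),
            right=(b.ref_name, right_pos, b.orientation),
            read_offset=(a.read_end + b.read_start) // 2,
            jtype=_jtype(panel, a.ref_name, b.ref_name),
        ))
    return out


# ---------------------------------------------------- STAR chimeric table


def parse_star_chimeric(path, panel: ReferencePanel) -> list[Junction]:
    """Parse a STAR ``Chimeric.out.junction``-style table.

    Columns 1-6 are consumed: chrA, posA (1-based), strandA, chrB, posB,
    strandB; column 10, when present, is taken as the read id.  Reference
    names must exist in the panel (the combined vector+host reference
    convention).
    """
    known = set(panel.sequences)
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            cols = raw.split("\t")
            if len(cols) < 6:
                raise ParseError(f"expected >=6 columns, got {len(cols)}", lineno)
            chr_a, pos_a, str_a, chr_b, pos_b, str_b = cols[:6]
            for c in (chr_a, chr_b):
                if c not in known:
                    raise ParseError(
                        f"unknown reference '{c}'; known: {sorted(known)}", lineno
                    )
            try:
                pa, pb = int(pos_a) - 1, int(pos_b) - 1
            except ValueError:
                raise ParseError("non-integer junction position", lineno) from None
            if str_a not in "+-" or str_b not in "+-":
                raise ParseError(f"bad strand '{str_a}'/'{str_b}'", lineno)
            read_id = cols[9] if len(cols) >= 10 else f"junction_{lineno}"
            out.append(Junction(
                read_id=read_id,
                left=(chr_a, pa, str_a),
                right=(chr_b, pb, str_b),
                read_offset=None,
                jtype=_jtype(panel, chr_a, chr_b),
            ))
    return out


def write_star_chimeric(junctions: list[Junction], path) -> None:
    """Serialize junctions in the 10-column chimeric-table dialect."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write("\t".join(map(str, [
                j.left[0], j.left[1] + 1, j.left[2],
                j.right[0], j.right[1] + 1, j.right[2],
                -1, -1, -1, j.read_id,
            ])) + "\n")


# ------------------------------------------------------------ profiles


def junction_position_profile(
    junctions: list[Junction], ref_name: str, ref_length: int
) -> np.ndarray:
    """Per-position junction-endpoint counts, zero-coverage positions included."""
    profile = np.zeros(ref_length, dtype=np.int64)
    for j in junctions:
        for ref, pos, _ in (j.left, j.right):
            if ref != ref_name:
                continue
            if not 0 <= pos <= ref_length:
                raise ConsistencyError(
                    f"junction position {pos} outside {ref_name} "
                    f"(length {ref_length})"
                )
            profile[min(pos, ref_length - 1)] += 1
    return profile


def nearest_gene(
    junction: Junction | tuple[str, int],
    genes: pd.DataFrame,
) -> tuple[str, int, bool]:
    """Nearest gene to the host-side breakpoint of a junction.

    ``genes`` needs columns ``gene_id``, ``ref_name``, ``start``, ``end``
    (0-based half-open).  Distance is 0 inside the gene body, otherwise the
    gap to the nearest boundary.  Ties go to the gene with the smaller
    start; both candidates are logged.
    """
    if genes is None or len(genes) == 0:
        raise EmptyInputError("empty gene annotation")
    if isinstance(junction, Junction):
        gene_refs = set(genes["ref_name"])
        host_sides = [s for s in (junction.left, junction.right) if s[0] in gene_refs]
        if not host_sides:
            raise ConsistencyError(
                f"junction {junction.read_id} has no side on an annotated reference"
            )
        ref, pos = host_sides[0][0], host_sides[0][1]
    else:
        ref, pos = junction

    sub = genes[genes["ref_name"] == ref]
    if len(sub) == 0:
        raise EmptyInputError(f"no genes annotated on {ref}")
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    dist = np.maximum(0, np.maximum(starts - pos, pos - ends + 1))
    best = dist.min()
    idx = np.nonzero(dist == best)[0]
    if len(idx) > 1:
        order = np.argsort(starts[idx], kind="stable")
        idx = idx[order]
        logger.info(
            "nearest-gene tie at %s:%d between %s (kept gene with smaller start)",
            ref, pos, list(sub.iloc[idx]["gene_id"]),
        )
    chosen = sub.iloc[int(idx[0])]
    return str(chosen["gene_id"]), int(best), bool(best == 0)


def annotate_junctions(junctions: list[Junction], genes: pd.DataFrame) -> list[Junction]:
    """Attach nearest-gene annotation to every junction with a host side."""
    gene_refs = set(genes["ref_name"]) if len(genes) else set()
    out = []
    for j in junctions:
        if any(s[0] in gene_refs for s in (j.left, j.right)):
            j = Junction(**{**vars(j), "nearest_gene": nearest_gene(j, genes)})
        out.append(j)
    return out


def hotspot_assessment(
    profile: np.ndarray, bin_size: int = 100, fdr: float = 0.05
) -> pd.DataFrame:
    """Binned enrichment test against a uniform junction distribution.

    Each bin's count is tested one-sided against Binomial(n_total,
    bin_length / ref_length); p-values are Benjamini–Hochberg adjusted and
    bins rejected at the given FDR are flagged as hotspots.
    """
    total = int(profile.sum())
    if total <= 0:
        raise EmptyInputError("profile has no junction endpoints")
    length = len(profile)
    if bin_size > length:
        raise ValueError(f"bin_size {bin_size} exceeds profile length {length}")
    edges = list(range(0, length, bin_size)) + [length]
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        x = int(profile[lo:hi].sum())
        frac = (hi - lo) / length
        p = float(binom.sf(x - 1, total, frac)) if x > 0 else 1.0
        rows.append({"bin_start": lo, "bin_end": hi, "count": x,
                     "expected": total * frac, "pvalue": min(1.0, p)})
    df = pd.DataFrame(rows)
    reject, qvals, _, _ = multipletests(df["pvalue"], alpha=fdr, method="fdr_bh")
    df["qvalue"] = qvals
    df["hotspot"] = reject
    return df


def self_link_arcs(
    junctions: list[Junction],
    vector_length: int | None = None,
    arc_round: int = 10,
) -> pd.DataFrame:
    """Aggregate self-link junctions into (start, end, count) arcs.

    Positions are rounded to ``arc_round`` bp and ordered start <= end,
    ready for circular plotting against the plasmid map.
    """
    rows = []
    for j in junctions:
        if j.jtype != "self_link":
            continue
        a = int(round(j.left[1] / arc_round)) * arc_round
        b = int(round(j.right[1] / arc_round)) * arc_round
        if vector_length is not None:
            a, b = min(a, vector_length), min(b, vector_length)
        rows.append({"start": min(a, b), "end": max(a, b)})
    if not rows:
        return pd.DataFrame(columns=["start", "end", "count"])
    df = pd.DataFrame(rows).groupby(["start", "end"]).size().reset_index(name="count")
    return df.sort_values(["start", "end"]).reset_index(drop=True)


def junctions_to_dataframe(junctions: list[Junction]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "read_id": j.read_id,
            "left_ref": j.left[0], "left_pos": j.left[1], "left_strand": j.left[2],
            "right_ref": j.right[0], "right_pos": j.right[1], "right_strand": j.right[2],
            "read_offset": -1 if j.read_offset is None else j.read_offset,
            "jtype": j.jtype,
            "nearest_gene": "" if j.nearest_gene is None else j.nearest_gene[0],
            "gene_distance": -1 if j.nearest_gene is None else j.nearest_gene[1],
            "inside_gene": False if j.nearest_gene is None else j.nearest_gene[2],
        }
        for j in junctions
    ])


def genes_from_panel(panel: ReferencePanel) -> pd.DataFrame:
    """Host gene table (gene_id, ref_name, start, end) from panel features."""
    rows = [
        {
            "gene_id": f"gene_{i:02d}", "ref_name": f.ref_name,
            "start": f.start, "end": f.end,
        }
        for i, f in enumerate(panel.host_genes())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "ref_name", "start", "end"])


def read_gene_bed(path) -> pd.DataFrame:
    """Load a BED file of gene bodies into the gene-table layout."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["ref_name", "start", "end", "gene_id", "score", "strand"],
        usecols=[0, 1, 2, 3],
    )
    return df[["gene_id", "ref_name", "start", "end"]]
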