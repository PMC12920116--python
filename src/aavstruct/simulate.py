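"""Simulate long reads with known structural ground truth.

Each simulated molecule is described by a :class:`StructureSpec` — an ordered
list of ``(ref_name, start, end, orientation)`` segments drawn to realize one
of the structural categories observed in rAAV-transduced tissue: vector
monomers, head-to-tail / head-to-head / alternating concatemers,
interplasmid recombinants, vector–host fusions and non-periodic complex
rearrangements.  Library artifacts are layered on top: duplex reads (the
complementary strand sequenced immediately after its template, which mimics
an inverted dimer) and random ligation chimeras (an unrelated host fragment
joined during library preparation).  Finally nanopore-like substitution and
indel errors are applied per base.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; outputs are pure functions of the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import ReferencePanel, HOST_REF, revcomp

CATEGORIES = (
    "monomer",
    "head_to_tail",
    "head_to_head",
    "alternating",
    "interplasmid_recombinant",
    "host_fusion",
    "complex",
    "duplex_artifact",
)

DEFAULT_WEIGHTS = {
    "monomer": 0.20,
    "head_to_tail": 0.20,
    "head_to_head": 0.10,
    "alternating": 0.10,
    "interplasmid_recombinant": 0.125,
    "host_fusion": 0.125,
    "complex": 0.10,
    "duplex_artifact": 0.05,
}

#: end-jitter applied to repeated concatemer copies, in bp
COPY_JITTER = 25

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a nanopore-like mixed library."""

    seed: int = 0
    n_reads: int = 100
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    substitution_rate: float = 0.05
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005
    duplex_rate: float = 0.0
    ligation_rate: float = 0.0
    unit_length_range: tuple[int, int] = (1200, 2500)
    copies_range: tuple[int, int] = (2, 4)

    def __post_init__(self):
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"category_weights sum to {total}, expected 1")
        unknown = set(self.category_weights) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown categories in weights: {sorted(unknown)}")
        for name in (
            "substitution_rate", "insertion_rate", "deletion_rate",
            "duplex_rate", "ligation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("unit_length_range", "copies_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StructureSpec:
    """Ground truth for one simulated molecule."""

    spec_id: str
    segments: list[tuple[str, int, int, str]]  # (ref, start, end, orientation)
    truth_category: str
    truth_junctions: list[tuple[tuple[str, int], tuple[str, int]]]
    artifact: str = "none"  # none | duplex | ligation_chimera

    def __post_init__(self):
        if len(self.truth_junctions) != len(self.segments) - 1:
            raise ValueError("truth_junctions must be segments - 1")

    @property
    def molecule_span(self) -> int:
        """Total constructed molecule length (before artifacts/errors)."""
        return sum(e - s for _, s, e, _ in self.segments)


def _breakpoints(segments) -> list:
    """Reference breakpoints between consecutive segments, orientation-aware."""
    out = []
    for (ra, sa, ea, oa), (rb, sb, eb, ob) in zip(segments, segments[1:]):
        left = (ra, ea if oa == "+" else sa)
        right = (rb, sb if ob == "+" else eb)
        out.append((left, right))
    return out


def _jitter(rng, start, end, lo, hi) -> tuple[int, int]:
    s = int(np.clip(start + rng.integers(-COPY_JITTER, COPY_JITTER + 1), lo, hi - 1))
    e = int(np.clip(end + rng.integers(-COPY_JITTER, COPY_JITTER + 1), s + 1, hi))
    return s, e


def sample_structure(
    config: SimConfig,
    panel: ReferencePanel,
    rng: np.random.Generator,
    category: str | None = None,
    spec_id: str = "mol",
) -> StructureSpec:
    """Draw one ground-truth molecule structure.

    ``category`` forces a specific truth category; forcing a category whose
    configured weight is zero is a configuration error.
    """
    weights = config.category_weights
    if category is not None:
        if weights.get(category, 0.0) == 0.0:
            raise ConfigError(f"category '{category}' has zero weight")
    else:
        names = sorted(weights)
        probs = np.array([weights[n] for n in names])
        category = names[rng.choice(len(names), p=probs / probs.sum())]

    vec, v0, v1 = panel.vector_region()
    host = panel.host_refs()[0]
    host_len = len(panel.sequences[host])

    def draw_unit(lo_len=None, hi_len=None):
        lo, hi = config.unit_length_range if lo_len is None else (lo_len, hi_len)
        length = int(rng.integers(lo, min(hi, v1 - v0) + 1))
        start = int(rng.integers(v0, v1 - length + 1))
        return start, start + length

    def draw_host_seg(lo=800, hi=2500):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, host_len - length + 1))
        return start, start + length

    orient = "+" if rng.random() < 0.5 else "-"
    artifact = "none"

    if category == "monomer":
        segments = [(vec, v0, v1, orient)]
    elif category == "duplex_artifact":
        segments = [(vec, v0, v1, orient)]
        artifact = "duplex"
    elif category == "head_to_tail":
        k = int(rng.integers(config.copies_range[0], config.copies_range[1] + 1))
        u0, u1 = draw_unit()
        segments = [(vec, *_jitter(rng, u0, u1, v0, v1), orient) for _ in range(k)]
    elif category == "head_to_head":
        # fold-back product: second arm truncated, sharing the junction end
        u0, u1 = draw_unit()
        frac = rng.uniform(0.55, 0.85)
        alen = int(round((u1 - u0) * frac))
        if orient == "+":
            segments = [(vec, u0, u1, "+"), (vec, u1 - alen, u1, "-")]
        else:
            segments = [(vec, u0, u1, "-"), (vec, u0, u0 + alen, "+")]
    elif category == "alternating":
        k = max(3, int(rng.integers(config.copies_range[0], config.copies_range[1] + 1)))
        u0, u1 = draw_unit()
        segments = []
        o = orient
        for _ in range(k):
            segments.append((vec, *_jitter(rng, u0, u1, v0, v1), o))
            o = {"+": "-", "-": "+"}[o]
    elif category == "interplasmid_recombinant":
        others = sorted(
            r for r, c in panel.ref_class.items()
            if panel.is_plasmid(r) and r != vec
        )
        n_extra = int(rng.integers(1, len(others) + 1))
        chosen = list(rng.choice(others, size=n_extra, replace=False))
        segments = [(vec, *draw_unit(800, 2000), orient)]
        for ref in chosen:
            rlen = len(panel.sequences[ref])
            length = int(rng.integers(800, 2001))
            start = int(rng.integers(0, rlen - length + 1))
            o = "+" if rng.random() < 0.5 else "-"
            segments.append((ref, start, start + length, o))
        rng.shuffle(segments)
        segments = [tuple(s) for s in segments]
    elif category == "host_fusion":
        vseg = (vec, *draw_unit(800, 2500), orient)
        hseg = (host, *draw_host_seg(), "+" if rng.random() < 0.5 else "-")
        segments = [vseg, hseg] if rng.random() < 0.5 else [hseg, vseg]
    elif category == "complex":
        # non-periodic: disjoint vector intervals in random orientations;
        # arrangements where two chunks rejoin contiguously are rejected,
        # since such a boundary reconstructs the reference and is no junction
        k = int(rng.integers(3, 5))
        cuts = np.sort(rng.choice(np.arange(v0 + 200, v1 - 200), size=k - 1, replace=False))
        bounds = [v0, *cuts.tolist(), v1]
        chunks = []
        for i in range(k):
            lo, hi = bounds[i], bounds[i + 1]
            if hi - lo < 150:
                hi = lo + 150
            chunks.append((int(lo), int(min(hi, v1))))

        def _contiguous(a, b):
            if a[3] != b[3]:
                return False
            return (b[1] == a[2]) if a[3] == "+" else (a[1] == b[2])

        for _ in range(50):
            order = rng.permutation(k)
            segments = [
                (vec, *chunks[i], "+" if rng.random() < 0.5 else "-")
                for i in order
            ]
            if not any(_contiguous(a, b) for a, b in zip(segments, segments[1:])):
                break
    else:  # pragma: no cover - guarded by SimConfig validation
        raise ConfigError(f"unknown category '{category}'")

    if artifact == "none":
        r = rng.random()
        if r < config.duplex_rate:
            artifact = "duplex"
            category = "duplex_artifact"
        elif r < config.duplex_rate + config.ligation_rate:
            artifact = "ligation_chimera"

    return StructureSpec(
        spec_id=spec_id,
        segments=segments,
        truth_category=category,
        truth_junctions=_breakpoints(segments),
        artifact=artifact,
    )


# ------------------------------------------------------------------ errors


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.zeros(arr.size, dtype=np.uint8)
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def apply_errors(
    seq: str,
    rng: np.random.Generator,
    substitution_rate: float,
    insertion_rate: float,
    deletion_rate: float,
    offsets: Iterable[int] = (),
) -> tuple[str, list[int]]:
    """Apply per-base substitutions and indels; map offsets through.

    ``offsets`` are positions in the clean sequence (breakpoints between
    bases); the returned list gives their images in the erroneous read.
    """
    codes = _encode(seq)
    n = codes.size
    deleted = rng.random(n) < deletion_rate
    substituted = rng.random(n) < substitution_rate
    inserted = rng.random(n) < insertion_rate

    codes = codes.copy()
    subs = substituted & ~deleted
    codes[subs] = (codes[subs] + rng.integers(1, 4, size=int(subs.sum()))) % 4

    # per source base: 0 or 1 emitted copies, plus 1 for an insertion after it
    out_per_base = (~deleted).astype(np.int64) + inserted.astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(out_per_base)))

    ins_bases = rng.integers(0, 4, size=int(inserted.sum()))
    total = int(prefix[-1])
    out = np.empty(total, dtype=np.uint8)
    keep_idx = np.nonzero(~deleted)[0]
    out[prefix[keep_idx]] = codes[keep_idx]
    ins_idx = np.nonzero(inserted)[0]
    # an insertion after base i lands at prefix[i+1] - 1
    out[prefix[ins_idx + 1] - 1] = ins_bases

    mapped = [int(prefix[min(o, n)]) for o in offsets]
    return _decode(out), mapped


@dataclass
class TruthRecord:
    """One truth-table row for a simulated read."""

    read_id: str
    category: str
    artifact: str
    n_segments: int
    read_length: int
    molecule_span: int
    segments: str  # "ref:start-end:strand;..."
    junction_read_offsets: str  # comma-separated, post-error read coords
    junction_ref_breakpoints: str  # "refL:pos|refR:pos;..."


TRUTH_COLUMNS = [
    "read_id", "category", "artifact", "n_segments", "read_length",
    "molecule_span", "segments", "junction_read_offsets",
    "junction_ref_breakpoints",
]


def realize_read(
    spec: StructureSpec,
    panel: ReferencePanel,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, TruthRecord]:
    """Materialize a spec into a read sequence plus its truth record."""
    parts = []
    offsets = []
    pos = 0
    for ref, s, e, o in spec.segments:
        sub = panel.sequences[ref][s:e]
        parts.append(sub if o == "+" else revcomp(sub))
        pos += e - s
        offsets.append(pos)
    offsets = offsets[:-1]  # junctions only between segments
    molecule = "".join(parts)

    junction_refs = list(spec.truth_junctions)
    if spec.artifact == "duplex":
        offsets = offsets + [len(molecule)]
        last = spec.segments[-1]
        mirror_bp = (last[0], last[2] if last[3] == "+" else last[1])
        junction_refs = junction_refs + [(mirror_bp, mirror_bp)]
        molecule = molecule + revcomp(molecule)
    elif spec.artifact == "ligation_chimera":
        host = panel.host_refs()[0]
        hlen = len(panel.sequences[host])
        flen = int(rng.integers(500, 1501))
        fstart = int(rng.integers(0, hlen - flen + 1))
        frag = panel.sequences[host][fstart:fstart + flen]
        last = spec.segments[-1]
        offsets = offsets + [len(molecule)]
        junction_refs = junction_refs + [
            ((last[0], last[2] if last[3] == "+" else last[1]), (host, fstart))
        ]
        molecule = molecule + frag

    read, mapped = apply_errors(
        molecule, rng,
        config.substitution_rate, config.insertion_rate, config.deletion_rate,
        offsets,
    )
    truth = TruthRecord(
        read_id=spec.spec_id,
        category=spec.truth_category,
        artifact=spec.artifact,
        n_segments=len(spec.segments),
        read_length=len(read),
        molecule_span=spec.molecule_span,
        segments=";".join(f"{r}:{s}-{e}:{o}" for r, s, e, o in spec.segments),
        junction_read_offsets=",".join(str(m) for m in mapped),
        junction_ref_breakpoints=";".join(
            f"{l[0]}:{l[1]}|{r[0]}:{r[1]}" for l, r in junction_refs
        ),
    )
    return read, truth


def simulate_reads(
    config: SimConfig, panel: ReferencePanel
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate in memory: returns [(read_id, sequence), ...] and truth table."""
    rng = np.random.default_rng(config.seed)
    reads, rows = [], []
    for i in range(config.n_reads):
        spec = sample_structure(config, panel, rng, spec_id=f"read_{i:06d}")
        seq, truth = realize_read(spec, panel, config, rng)
        reads.append((truth.read_id, seq))
        rows.append(asdict(truth))
    return reads, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


#: constant placeholder base quality (qualities are unused downstream)
PLACEHOLDER_QUAL = 12


def simulate_dataset(config: SimConfig, panel: ReferencePanel, fastq_path, truth_path):
    """Simulate and write a FASTQ plus its tab-separated truth table."""
    reads, truth = simulate_reads(config, panel)
    qchar = chr(PLACEHOLDER_QUAL + 33)
    with open(fastq_path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")
    truth.to_csv(truth_path, sep="\t", index=False)
    return fastq_path, truth_path


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"junction_read_offsets": str})
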