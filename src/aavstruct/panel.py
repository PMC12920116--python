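"""Desk-scale reference panel: manufacturing plasmids plus a miniature host.

The panel mimics a triple-transfection rAAV manufacturing system — a vector
plasmid whose transgene cassette is flanked by inverted terminal repeats
(ITRs), a packaging plasmid carrying AAV *rep* and *cap*, a helper plasmid
carrying adenovirus-derived helper genes — together with one host chromosome
segment that carries annotated genes and a planted vector-homologous decoy
locus (a partial transgene copy) to exercise ambiguous-mapping handling.

Coordinates are 0-based half-open throughout; BED output is 0-based
half-open, GFF output is 1-based closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import PanelSizeError

VECTOR_PLASMID = "pVector"
PACKAGING_PLASMID = "pRepCap"
HELPER_PLASMID = "pHelper"
HOST_REF = "host_chr"

REF_CLASS_VECTOR = "vector_plasmid"
REF_CLASS_PACKAGING = "packaging_plasmid"
REF_CLASS_HELPER = "helper_plasmid"
REF_CLASS_HOST = "host"

PLASMID_CLASSES = {REF_CLASS_VECTOR, REF_CLASS_PACKAGING, REF_CLASS_HELPER}

FEATURE_LABELS = {
    "ITR_left", "ITR_right", "promoter", "transgene", "polyA", "backbone",
    "ori", "AMR", "rep", "cap", "helper_genes", "host_gene",
}

ITR_LEN = 145
#: a host gene within this distance of the decoy locus counts as adjacent
DECOY_ADJACENCY_BP = 1000
DECOY_LEN = 500

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Feature(NamedTuple):
    ref_name: str
    start: int
    end: int
    strand: str
    label: str


@dataclass
class ReferencePanel:
    """Named reference sequences, their feature annotations and classes."""

    sequences: dict[str, str]
    features: list[Feature]
    ref_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for f in self.features:
            n = len(self.sequences[f.ref_name])
            if not (0 <= f.start < f.end <= n):
                raise ValueError(
                    f"feature {f.label} [{f.start},{f.end}) outside "
                    f"{f.ref_name} (length {n})"
                )

    def features_on(self, ref_name: str, label: str | None = None) -> list[Feature]:
        return [
            f for f in self.features
            if f.ref_name == ref_name and (label is None or f.label == label)
        ]

    def vector_region(self) -> tuple[str, int, int]:
        """Interval spanning ITR_left through ITR_right, both inclusive."""
        vec = [r for r, c in self.ref_class.items() if c == REF_CLASS_VECTOR]
        if len(vec) != 1:
            raise ValueError("panel must contain exactly one vector plasmid")
        (name,) = vec
        (left,) = self.features_on(name, "ITR_left")
        (right,) = self.features_on(name, "ITR_right")
        return name, left.start, right.end

    def host_refs(self) -> list[str]:
        return [r for r, c in self.ref_class.items() if c == REF_CLASS_HOST]

    def is_host(self, ref_name: str) -> bool:
        return self.ref_class.get(ref_name) == REF_CLASS_HOST

    def is_plasmid(self, ref_name: str) -> bool:
        return self.ref_class.get(ref_name) in PLASMID_CLASSES

    def host_genes(self) -> list[Feature]:
        return [f for f in self.features if f.label == "host_gene"]

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=name, description=self.ref_class.get(name, ""))
            for name, s in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(f"{f.ref_name}\t{f.start}\t{f.end}\t{f.label}\t0\t{f.strand}\n")

    def write_gff(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.features:
                fh.write(
                    f"{f.ref_name}\taavstruct\t{f.label}\t{f.start + 1}\t{f.end}"
                    f"\t.\t{f.strand}\t.\tName={f.label}\n"
                )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n))


def build_panel(seed: int, vector_len: int = 6000, host_len: int = 50000) -> ReferencePanel:
    """Build a deterministic desk-scale panel.

    Parameters
    ----------
    seed
        Seeds a dedicated PRNG; identical seeds give byte-identical panels.
    vector_len
        Total vector plasmid length (cassette + backbone), >= 3000 bp.
    host_len
        Host chromosome segment length, >= 20000 bp.
    """
    if vector_len < 3000:
        raise PanelSizeError(f"vector_len {vector_len} < 3000")
    if host_len < 20000:
        raise PanelSizeError(f"host_len {host_len} < 20000")

    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    features: list[Feature] = []

    # --- vector plasmid: ITR - promoter - transgene - polyA - ITR - backbone
    region_len = max(2 * ITR_LEN + 300 + 200 + 800, int(round(vector_len * 0.6)))
    backbone_len = vector_len - region_len
    prom_len, polya_len = 300, 200
    transgene_len = region_len - 2 * ITR_LEN - prom_len - polya_len

    itr = _random_seq(rng, ITR_LEN)
    promoter = _random_seq(rng, prom_len)
    transgene = _random_seq(rng, transgene_len)
    polya = _random_seq(rng, polya_len)
    backbone = _random_seq(rng, backbone_len)
    vec_seq = itr + promoter + transgene + polya + revcomp(itr) + backbone
    sequences[VECTOR_PLASMID] = vec_seq

    pos = 0
    for label, length in [
        ("ITR_left", ITR_LEN), ("promoter", prom_len), ("transgene", transgene_len),
        ("polyA", polya_len), ("ITR_right", ITR_LEN),
    ]:
        features.append(Feature(VECTOR_PLASMID, pos, pos + length, "+", label))
        pos += length
    features.append(Feature(VECTOR_PLASMID, pos, vector_len, "+", "backbone"))
    if backbone_len >= 1600:
        features.append(Feature(VECTOR_PLASMID, pos + 100, pos + 700, "+", "ori"))
        features.append(Feature(VECTOR_PLASMID, pos + 800, pos + 1600, "+", "AMR"))

    # --- packaging plasmid: rep + cap on a 7 kb backbone
    pkg_len = 7000
    pkg = _random_seq(rng, pkg_len)
    sequences[PACKAGING_PLASMID] = pkg
    features.append(Feature(PACKAGING_PLASMID, 200, 2000, "+", "rep"))
    features.append(Feature(PACKAGING_PLASMID, 2100, 4300, "+", "cap"))
    features.append(Feature(PACKAGING_PLASMID, 4300, pkg_len, "+", "backbone"))

    # --- helper plasmid: adenovirus-derived helper gene block
    helper_len = 9000
    helper = _random_seq(rng, helper_len)
    sequences[HELPER_PLASMID] = helper
    features.append(Feature(HELPER_PLASMID, 500, 6500, "+", "helper_genes"))
    features.append(Feature(HELPER_PLASMID, 6500, helper_len, "+", "backbone"))

    # --- host chromosome with a planted transgene decoy and >=2 genes
    host = list(_random_seq(rng, host_len))
    decoy_start = (host_len * 3) // 5
    host[decoy_start:decoy_start + DECOY_LEN] = transgene[:DECOY_LEN]
    sequences[HOST_REF] = "".join(host)

    gene_a_start = decoy_start + DECOY_LEN + 200  # adjacent to the decoy
    features.append(Feature(HOST_REF, gene_a_start, gene_a_start + 2000, "+", "host_gene"))
    features.append(Feature(HOST_REF, 2000, 4500, "+", "host_gene"))
    features.append(Feature(HOST_REF, 10000, 12500, "-", "host_gene"))

    ref_class = {
        VECTOR_PLASMID: REF_CLASS_VECTOR,
        PACKAGING_PLASMID: REF_CLASS_PACKAGING,
        HELPER_PLASMID: REF_CLASS_HELPER,
        HOST_REF: REF_CLASS_HOST,
    }
    return ReferencePanel(sequences, features, ref_class)
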