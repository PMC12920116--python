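# Methods

## Problem setting

Recombinant AAV vectors are manufactured by triple transfection: a vector
plasmid carrying the therapeutic cassette between inverted terminal repeats
(ITRs), a packaging plasmid supplying AAV *rep* and *cap*, and a helper
plasmid supplying adenovirus-derived helper genes. In transduced tissue,
long reads over vector-derived DNA show monomeric genomes alongside
concatemers, plasmid–plasmid recombinants, vector–host fusions and
sequencing artifacts. `aavstruct` assigns each read one structural category
and extracts the breakpoints, using a read-level segment-chain model.

## Reference panel and simulator

`build_panel(seed, vector_len=6000, host_len=50000)` generates i.i.d.
uniform ACGT sequence with a fixed layout: the vector plasmid is
`ITR(145) – promoter(300) – transgene – polyA(200) – ITR(145) – backbone`
with the vector region set to 60% of the plasmid; the right ITR is the
exact reverse complement of the left (a true inverted-repeat pair, which
deliberately creates orientation-ambiguous alignments); the backbone
carries ori and a resistance marker. The packaging plasmid (7 kb) carries
*rep* and *cap* features, the helper plasmid (9 kb) a 6 kb helper-gene
block. The host chromosome carries three gene-body annotations and a
500 bp copy of the transgene planted at 60% of its length — a decoy locus
that forces the downstream chain logic to resolve vector/host mapping
ambiguity. One host gene starts 200 bp downstream of the decoy (within the
1 kb adjacency the panel guarantees).

`sample_structure` draws a category from configurable weights and realizes
it as an ordered segment list (0-based half-open intervals; `-` means
reverse complement):

* `monomer` — the full vector region, either orientation;
* `head_to_tail` — 2–4 same-orientation copies of one unit interval
  (1.2–2.5 kb), each copy's ends jittered ±25 bp, mirroring
  rolling-replication products;
* `head_to_head` — an inverted pair sharing the junction-side end, with
  the second arm truncated to 55–85% of the unit. Exactly symmetric
  inverted dimers are indistinguishable from duplex-read artifacts by
  construction, so the generator emits the physically common
  truncated-arm fold-back product, keeping the two truth categories
  separable;
* `alternating` — ≥3 copies with strictly alternating orientation;
* `interplasmid_recombinant` — a vector fragment joined to fragments of
  one or both other plasmids;
* `host_fusion` — one vector and one host segment in random order;
* `complex` — 3–4 disjoint vector intervals in random order/orientation;
  arrangements in which two chunks rejoin contiguously are rejected, since
  such a boundary reconstructs the reference and is not a junction;
* `duplex_artifact` — a monomer whose reverse complement is appended
  (the nanopore artifact where the complementary strand is sequenced
  directly after its template).

Artifacts can also be layered per read: `duplex_rate` appends the reverse
complement of the whole molecule (the truth category is then relabelled
`duplex_artifact`, because the read presents as a duplex); `ligation_rate`
appends an unrelated 0.5–1.5 kb host fragment, keeping the base category.
Errors are applied per base: substitution (default 5%), insertion (0.5%)
and deletion (0.5%), chosen as a nanopore-like operating point. Junction
offsets are mapped exactly through the indel process. All draws flow
through one `numpy.random.Generator` seeded from `SimConfig.seed`, in a
fixed order, so outputs are pure functions of the configuration. FASTQ
qualities are a constant Q12 placeholder; qualities are unused downstream.

What the simulator does **not** emulate: homopolymer-biased ONT error
profiles, basecaller behavior, chimera formation mid-molecule, host
structural variation, or realistic category abundances (which are unknown
and left user-configurable). Passing tests therefore demonstrate that the
chain/classification logic is correct under controlled error processes,
not that any particular biological mixture will be recovered from real
tissue.

## Alignment

`parse_alignments` consumes SAM (via pysam) or 12-column PAF, keeping
secondary and supplementary records and deduplicating identical blocks.
Every block carries `longest_match_run`: the longest contiguous stretch of
matches/mismatches with no insertions or deletions, computed from the
CIGAR (M/=/X runs broken by I/D/N). PAF records without a `cg` tag fall
back to `aligned_length` with a logged downgrade.

The built-in anchorer indexes all reference 15-mers and chains exact
anchor hits (both strands) greedily: an anchor joins the open chain with
the nearest diagonal within 30 bp, provided the read gap is ≤100 bp;
chains shorter than 100 bp on the read are discarded. At ≤5–6% total
error, intact 15-mers occur at ~1/3 of positions, which keeps chains dense
at desk scale. Within a chain, `longest_match_run` is the longest stretch
of *same-diagonal* anchors: a constant diagonal certifies that no net
indel occurred, while substitutions between anchors leave the
match/mismatch run intact — the same statistic a CIGAR M-run yields.

The dot plot cuts both sequences into non-overlapping windows (default
20 bp) and marks cell (i, j) as a forward hit when the windows agree
within Hamming distance 2, and a reverse hit against the reverse
complement of the j-th window; exact matching is too brittle at 5% error,
and the tolerance is exposed as a parameter. Note that fixed windows lose
phase after an indel, so indel-rich reads give sparse diagonals — a
property of any fixed-window plotter.

## Retention filter

A read is retained iff length > 1,000 bp (strict, "over 1,000 bp"), the
union of its block read-intervals covers ≥80% of the read, and some block
has `longest_match_run` ≥ 100 bp. Union coverage is the default because
summing alignment lengths can exceed 100% for concatemeric self-overlaps;
a summation mode is provided for comparison. Reads with zero blocks are
emitted as explicit failures rather than dropped, for auditability.

## Chaining and classification

`chain_blocks` first resolves redundant blocks: any block whose read
interval is >50% covered by longer kept blocks is dropped. Exact-score
ties (a read interval matching the vector and the homologous host decoy
equally) resolve toward the plasmid, then toward the reference and
orientation of the read's dominant block — the convention a combined
vector+host reference effectively imposes. Blocks confined to an ITR
(±25 bp) are dropped whenever the read has any other alignment: an
inverted repeat carries no orientation or position signal, and such
fragments otherwise surface as spurious segments when clustered errors
trim a neighbouring alignment's edge.

Collinear neighbours are merged when they share reference and orientation,
their diagonal drift is ≤50 bp (`merge_tol`), and the read/ref gaps are
≤250 bp (`merge_gap`). The gap bound is deliberately looser than the drift
bound: clustered errors regularly leave 100–250 bp stretches with no
intact 15-mer that split one true alignment, while a genuine junction
shifts the diagonal by the distance between the joined loci and is caught
by the drift condition. Read gaps >100 bp between surviving segments are
annotated as unanchored gaps.

Classification applies the first matching rule, in order: 0 segments →
`unclassified`; 1 → `monomer`; host + plasmid references → `host_fusion`;
≥2 distinct plasmids → `interplasmid_recombinant`; exactly 2
opposite-orientation segments of one reference with reciprocal overlap
≥0.9 *and* mirror symmetry about the read midpoint (tolerance 250 bp,
matching the edge-trimming scale) → `duplex_artifact`; the same pair
without the duplex conditions but overlap ≥0.5 → `head_to_head`
(annotated "consistent with self-complementary genome" on the vector);
≥2 same-orientation repeats with consecutive reciprocal overlap ≥0.5 →
`head_to_tail`; ≥3 strictly alternating → `alternating`; anything else
with ≥2 segments → `complex`. Inter-reference rules run first because
those are the rarer, higher-stakes calls; the duplex rule runs before
`head_to_head` so duplex reads are never absorbed into `complex`.
Reciprocal overlap is intersection over the longer interval. The rule set
is an explicit reconstruction — the field describes these categories
pictorially rather than algorithmically — and every threshold is a
keyword argument.

`total_span` (the molecule-size estimate behind the over-length flag) is
the sum of reference-interval lengths, which is robust to read indels;
molecules above the `packaging_limit` (default 5,000 bp, the approximate
AAV capsid capacity) are flagged.

The negative-control comparison reports per-category fractions
side-by-side, each set's concatemeric fraction (`head_to_tail` +
`head_to_head` + `alternating` + `complex`), and a two-sided Fisher exact
test on concatemeric vs non-concatemeric counts.

## Junctions

Each consecutive segment pair yields one junction; the reference-side
breakpoint is the orientation-aware end of the left segment and start of
the right one (0-based; the convention is ours to fix, as none is standard).
Junction types follow reference classes: `self_link` (both sides one
plasmid), `interplasmid`, `vector_host`, `host_host`. STAR-style chimeric
junction tables are imported by consuming columns 1–6 (chrA, posA 1-based,
strandA, chrB, posB, strandB) against the combined reference naming.

Position profiles are full-length integer vectors (every position
reported, zero-coverage included; an endpoint at the reference end is
counted in the final position so endpoint totals are conserved).
Nearest-gene annotation minimizes the distance to gene-body boundaries
(0 inside the gene; no promoter window), ties broken toward the smaller
gene start with both candidates logged. The hotspot assessment bins the
profile (default 100 bp), tests each bin one-sided against
Binomial(total, bin/length) and applies Benjamini–Hochberg at FDR 0.05 —
a transparent default for a question the field usually answers by eye;
measured type-I behavior under a uniform null is ~97% of replicates with
zero flagged bins. Self-link arcs round positions to 10 bp, order start ≤
end and aggregate counts for circular plotting.

## Verification scales

The shipped tests and `scripts/acceptance.py` use desk-scale problem
sizes chosen to exercise every code path with comfortable statistical
margins: 500-read mixtures for category recovery (observed ≥99% at 5%
substitution + 1% indel, 100% error-free), 1,000 random block sets for
the filter-vs-rasterization oracle, 300 fusion reads for breakpoint
accuracy (median error 0 bp at 2% substitution), 1,000 replicates for
hotspot null calibration, and 200 error-free molecules for
packaging-limit flagging. The over-length check runs error-free because
its claim is exact span bookkeeping, not robustness; the recovery and
duplex checks run at full error rates.

## Known limitations

* Duplex artifacts of multi-segment molecules (e.g. a duplexed dimer) are
  not recognized as duplex — only monomer-based duplex reads present the
  two-segment mirror signature; others land in the repeat or complex
  categories, exactly as they would from their read structure alone.
* Equal-arm inverted dimers and duplex reads are genuinely
  indistinguishable; the classifier resolves the ambiguity in favour of
  `duplex_artifact` when the mirror is exact, and `head_to_head` calls on
  a self-complementary vector design should be read with that caveat.
* The anchorer is for desk-scale synthetic data; real datasets should be
  aligned with a production long-read aligner and imported via SAM/PAF.
* Episomal vs integrated state, and whether recombination happened during
  manufacture or in vivo, are out of scope — read structure alone cannot
  determine them.
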