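# Methods

## Model and assumptions

`seedtax` classifies shotgun metagenomic fragments by homology: a fragment
is assigned the deepest taxon consistent with every reference genome it
aligns to competitively. The method assumes the sampled organisms (or
close relatives) are present in the reference database — like every
homology-based classifier it cannot place truly novel clades — and that
reads are long enough and clean enough to contain at least one exact,
error-free k-mer shared with the reference.

The non-overlapping "grid" split of genome k-mers trades sensitivity for
memory: a read is only *guaranteed* to cover a full grid k-mer when its
length is at least 2k − 1 (127 bp at the default k = 32). Shorter reads
may still seed by luck of alignment with the grid, but the guarantee is
gone; reads shorter than k are rejected at parse time with a counted
warning. A lower error rate permits a longer k and hence a faster run;
with per-base error rate e, the chance a 150 bp read contains zero intact
32-mers is negligible below e ≈ 2%.

## Stages and parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 32 (max 32) | seed k-mer length; runtime parameter so tiny-k instances stay testable |
| `match/mismatch/gap_open/gap_extend` | 2/2/3/1 | Smith–Waterman scheme; a gap of length g costs `gap_open + (g−1)·gap_extend` |
| `margin` | 32 bp | genome window slack on each side of the seed-implied read placement |
| `min_score` | 0 (off) | absolute alignment-score screen; ~`read_length` (half the bases matching at match=2) is a reasonable operating point |
| `fraction` | 0.9 | fractional score cutoff before the LCA: hits below `fraction × best` are dropped |
| `min_overlap` | 20 bp | strict overlap required to join an alignment to the running chain interval |
| `chunk_size` | 10⁶ fragments | memory bound: reads are processed in chunks; genome k-mers are built once |
| `repeat_cap` | 1000 | equal-code blocks with more genome entries are skipped (low-complexity guard) and counted |

Stage order: absolute-score screen → pairing + insert screen →
chaining → fractional screen + LCA. Pairing before chaining lets the
insert screen demote aberrant joins before their alignments influence
chain scores; demoted pairs fall back to two single-end alignments rather
than vanishing, so their ends can still be classified individually.

**Seeding.** One seed is kept per (read, genome, strand, diagonal);
several grid k-mers hit by one read at one locus trigger a single
verification (the lowest read offset survives). The diagonal is
`genome_offset − read_offset` forward and `genome_offset + read_offset`
reverse. Exact duplicate alignments produced by windows from distinct
diagonals (as happens around indels) are collapsed afterwards.

**Alignment.** The full Gotoh affine-gap DP (numba-compiled) is the
correctness contract; ties are resolved deterministically (first best
cell in row-major order; traceback prefers diagonal moves, i.e. fewest
gaps). Ambiguous bases never match. A zero score yields a degenerate
empty alignment that screening removes.

**Insert model.** Outer distance (leftmost start to rightmost end) is
used as the insert size — robust to read-length asymmetry. Quartiles use
linear interpolation between order statistics ("type 7"); the SD is the
sample (n−1) form; the model needs at least two candidate pairs, else
screening is disabled. With all inserts identical, σ = 0 and the screen
`I ≥ μ + 6σ` reduces to `I ≥ μ` (boundary demoted). The model is pooled
across genomes (one library assumed) and fitted per chunk — a streaming
constraint; a frozen (μ, σ) can be supplied instead, which also makes
runs chunk-size-invariant. Mate orientation is recorded but not
filtered; only the insert size is screened.

**Chaining.** The overlap test is against the chain's *running* interval
[bₛ, max bₑ), i.e. transitive chaining, which is what lets chains extend
beyond conserved sections; the required overlap is strictly greater than
`min_overlap`. N_b sums full read lengths, not aligned lengths. Chains
are strand-agnostic. Algebraically S = C·μ_s·L collapses to Σs; the
decomposition is computed and reported as defined (coverage, span and
per-base quality are meaningful diagnostics), and the identity is
asserted in tests rather than replaced by an alternative weighting.
Whether this decomposition was meant to be a non-degenerate weighting is
an open question we resolve by implementing it literally.

**Classification.** Chain scores are the effective scores cut by
`fraction` (they are "applied to all alignments in the chain", so the
fractional cutoff sees them, not the raw s). Hits are merged per taxid
(chromosome + plasmid count once, at their best score) before the LCA;
ties with the best score always survive. A paired fragment is classified
as one unit on pair combined effective scores; orphaned mates contribute
their single-end alignments to the same pool. Fragments (pairs), not
reads, are the counting unit throughout, including gene counts.

**Genes.** The per-fragment call is the gene with maximal base overlap
with the fragment's best-scoring surviving alignment (ties: smaller
feature start). Report entries merge on the full key
(taxid, name, protein id, product): merging on *any* coinciding field
would chain unrelated genes transitively, so the conservative full-tuple
key is used. CDS and gene features are considered; rRNA/tRNA optionally.

## The simulator, and what passing tests show

The generator emulates the construction used to validate classifiers:
reads sampled from genomes in defined proportions with an error profile
and a normal insert distribution. Genomes are i.i.d.-uniform over
{A,C,G,T}; genus structure is created by copying one conserved block per
genus (a fixed fraction of the genome, at a shared offset) into every
member. Defaults are paired-end 150 bp reads, insert Normal(300, 30),
substitution rate 0.005 (several-fold above a typical Illumina run) and
indel rate 5·10⁻⁴; quality strings are constant. An optional chimera
rate places R2 at least 5 kb downstream, emulating aberrant joins for
the insert screen.

Uniform genomes make cross-genome k-mer collisions essentially
impossible, so "distant genomes" are *perfectly* distant: a clean probe
of the seeding/chaining logic, but an easier problem than real genomes
with mobile elements, shared operons and compositional bias. Passing
tests therefore demonstrate the mechanisms (seed completeness, chain
arithmetic, screen calibration, the pseudo-assembly gain), not field
accuracy on real communities. The single contiguous conserved block is
the hardest shape for chaining (only two conserved/unique boundaries to
extend across); the pseudo-assembly gain materializes once coverage is
high enough that chains rarely break (mean alignment spacing well below
read length minus `min_overlap` — around 10× for 150 bp reads).

## Problem sizes and numerical choices

The validation runs use desk-scale inputs chosen so each mechanism is
measured, not starved: 6 × 20 kb distant genomes with 5 000 error-free
pairs (species recovery, chunk invariance); 2 genera × 3 × 50 kb genomes
at 80% conservation with 10 000 error-bearing pairs sampled from one
species per genus (pseudo-assembly gain — sampling *all* genus members
equally would make conserved-block evidence exactly symmetric and the
species unidentifiable in principle); 5 000 genuine + 1% chimeric
inserts (screen rates). Floating-point: the chain identity is exact to
relative 10⁻⁹; the fractional cutoff uses a 10⁻⁹ slack so exact ties at
the maximum survive; all sorts have total, deterministic keys, so the
classifier is RNG-free and run-to-run stable.

## Known limitations

- No protein-level search; references are nucleotide genomes only.
- The repeat cap skips ultra-repetitive k-mer blocks rather than
  down-weighting them.
- Insert-model fitting per chunk means chunked and unchunked runs can
  differ slightly unless the model is frozen.
- The optional SAM export is a convenience view of surviving alignments
  (soft-clipped, unpaired flags), not a lossless interchange format.
- Genome-grid seeding bounds sensitivity for reads shorter than 2k − 1;
  choose a smaller k for short-read or high-error data at a cost in
  speed and specificity.
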