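# Methods

This note documents the models and procedures contigforge implements, the
parameter choices that matter, the numerical details, and the limits of
what the synthetic tests demonstrate.

## Read QC

Three filters, each with a strict ("more than") boundary: drop a read when
more than 33% of bases are N, when more than 34% of bases have Phred
quality below 20 (Q20 = 1% expected error, 10^(−Q/10)), or when more than
33% of bases are adenine (suspected poly-A tail). Fractions use the full
read length, case-insensitively. The poly-A rule counts A only — not T —
so reverse-complemented tails pass; a config switch can extend it.
Mates are filtered independently by default; `drop_pairs` removes both
when either fails. Tail trimming is a fixed-length cut (e.g. 87 → 75 bp to
discard error-prone terminal cycles before mapping), not quality-adaptive.
Qualities are Sanger Phred+33 only; suspected Phred+64 input triggers a
warning rather than a guess.

## Iterative assembly

The unit assembler is a plain de Bruijn unitig assembler: canonical
k-mers (lexicographic minimum of k-mer and reverse complement; k odd to
exclude palindromes), a k-mer coverage floor, and maximal non-branching
paths spelled as contigs. There is deliberately no bubble popping and no
paired-end scaffolding: ambiguity is left unresolved, to be cleaned up by
the downstream clustering and validation stages rather than by
heuristics inside the assembler. (Assembler-level N-scaffolding is avoided
on purpose: ambiguous-base runs at contig centres disturb the
alignment-score rules the clustering stages depend on.) An `assemble`
(reads + k → contigs) call is the unit of composition, so an external
assembler could be slotted in.

The iteration strategy is the point: exploratory assemblies at
k ∈ {21, 25, 31, 35, 41, 49, 59}; one more assembly at k = 57 of reads
none of whose k-mers appear in the exploratory outputs of k ∈ {21, 35,
49, 59}; three summary assemblies at k ∈ {29, 39, 49} each consuming the
union of all contigs so far (contigs are k-merised directly as single
observations, coverage floor 1 — a floor above 1 would delete unique
contigs); and a final assembly at k = 39 merging the summary outputs. All
k values are config-overridable. The read-stage coverage floor defaults to
2 (singleton k-mers are overwhelmingly sequencing errors); no cutoff
beyond that is applied, matching a defaults-like exploratory run.

Properties verified on synthetic data: exact reconstruction of repeat-free
transcripts at ≥20× error-free coverage (up to reverse complement),
k-mer-level coverage of every single-k assembly by the final set, and
bitwise determinism for a fixed input order.

## Target-based clustering

**EST stage.** Contig–EST matches come from the built-in nucleotide
search (or an external tabular file). Matches are kept only when the
pairwise alignment raw score exceeds 50 + 3 × min(len(contig), len(EST)) —
an absolute-score rule meaningful because a perfect match scores 5
per base under the default scheme (match +5 / mismatch −4 / gap −10,−1),
so the rule demands roughly two-thirds of the shorter sequence aligned
perfectly. Contig–EST alignments use free end gaps (contigs are expected
to extend beyond the EST). Per EST group, search scores are divided by the
group maximum and members below 0.7 discarded; groups with several
survivors are re-scored by their EST-alignment raw scores, renormalised,
and re-thresholded at 0.7. Survivor overhangs beyond each EST edge are
grafted on (per side, the longest overhang wins), and survivors are
consumed — they do not re-enter the peptide stage. ESTs are first
de-duplicated: exact duplicates and sequences contained in a longer EST
(either strand) are dropped, keeping the longest (ties by id).

**Peptide stage.** Contigs untouched by the EST stage are grouped by
their best peptide hit from the translated search and filtered at the same
0.7 normalised cutoff. Two survivors whose peptide HSPs do not overlap are
scaffolded: contig A + N-run + contig B, the run 3 × (aa gap between
their HSP target coordinates) nucleotides, floored at one N when the HSPs
abut. Two overlapping survivors merge when their overlap alignment
exceeds 90% identity; groups of three or more merge transitively along
pairs above 80% identity (connected components, merged in HSP order).
At disagreeing columns of a merge the higher-scoring contig's base wins
(ties: first by id). Contigs are oriented to the target strand/frame
before any join. The two clustering thresholds live on different scales
by design: 50 + 3L is a raw alignment score, while 80/90 are percent
identities over aligned non-gap columns — the only reading under which
both rule families are satisfiable.

## Alignment and search machinery

Global and overlap (free-end-gap) pairwise alignments are Needleman–
Wunsch with affine gaps via Biopython's PairwiseAligner (nucleotide
+5/−4/−10/−1; protein BLOSUM62 with −11/−1). The local search is a
word-seeded (11-mer nucleotide, 3-mer protein), X-drop ungapped extension
followed by a windowed gapped refinement, with Karlin–Altschul e-values
E = K·m·n·e^(−λS) using fixed approximate constants (λ=1.28, K=0.46
nucleotide; λ=0.267, K=0.041 protein). The e-values are used for
thresholding at 1e-6 and ordering only; no edge-effect or sum-statistic
corrections are attempted, and every consumer also accepts externally
produced 12-column tabular hits in their place.

## ORF selection and contig validation

All six frames are scanned for the longest Met→stop region (type A) and
the longest stop-free region (type B); ties resolve by frame order +1, +2,
+3, −1, −2, −3, then leftmost. N-containing codons translate to X and are
not stops; runs of ≥10 Ns (scaffolded joins) split a frame into
independent segments. The selected ORF is the type A unless none exists or
the type B reaches the contig's 5' boundary in its frame *and* starts
upstream of the type A — the signature of a truncated start codon. When
the two candidates sit on opposite strands no shared reading direction
exists; the edge-reaching type B then wins only if longer (a documented
heuristic). Contigs whose selected ORF is under 50 aa are discarded, and
of the rest only contigs holding at least one evidence tag (homology or
domain hit at E ≤ 1e-6, uniform across sources) are retained — a
conjunction, so evidence cannot rescue a short-ORF contig. Summary
statistics include N50: the largest L such that contigs ≥ L contain at
least half the assembled bases.

## Orthology

Per query, the score of a target is its best single HSP raw score (the
conservative reading; HSP sums are not used). A best hit is declared for a
single-target query, or when second-best/best < 0.7; equal top scores
declare nothing. Reference peptides shorter than 50 aa are removed before
the reverse search. Pairs declared in both directions form the 1:1 set,
which is a partial bijection by construction. On synthetic families at
≤15% divergence recovery of planted pairs is complete, and adding a
near-identical decoy paralog removes the affected pair (the ambiguity rule
working as intended).

## SND calling and diversity

A site is called when depth ≥ 6 and exactly one non-reference allele
(SNP base or indel string; they compete under the same rule) has count
≥ t(d), where t(d) = 2 for d ≤ 80 and max(2, ⌈0.025·d⌉) above — so
singleton errors are never called and the threshold tracks coverage where
errors accumulate linearly. MAPQ filtering (≥20) happens in the pileup
reader; reads below threshold still occupy depth but contribute no
counts. Indels pool only on exact string identity.

Raw diversity is π̂ = SNDs / callable length (positions with depth ≥ 6;
absent positions count as zero depth). Because a true heterozygous site
can miss the count threshold by binomial sampling alone, π̂ is biased
downward at low depth. The correction divides by the detection
probability Φ(d̃) = P[Binomial(d̃, 0.5) ≥ t(d̃)] at the median callable
depth d̃ (non-integer medians rounded half-up) — a balanced-pool
(allele frequency ½) binomial model matching the caller's own threshold.
Φ(6) = 57/64 ≈ 0.891. The correction is an explicit detection model of
this package, with the per-contig median depth as its operating point; a
user-supplied Φ(d) table can replace it (`phi=` hook), e.g. to encode a
different ascertainment model. Parameter recovery is verified by Monte
Carlo: with 1% heterozygosity planted at uniform 10× depth over ~10^6
bases, mean π̂_adj lands within 3 SE of 0.01 while mean π̂ undershoots.

RPKM is c·10⁹/(N·L) for count c, contig length L and library size N, with
the algebraic conservation Σ rpkm·L/1000 = 10⁶ when N = Σc used as an
exactness check. Read mapping itself is out of scope: pileups and counts
are inputs (or synthetic).

## Divergence and enrichment

Protein distance between orthologues is √p, p the proportion of aligned
positions that differ; by default every aligned column counts and gap
columns count as differences (a gap-excluded mode exists). Identity — used
for the 30% floor below which alignments are deemed untrustworthy — is
measured over non-gap columns. Binning is Low/Intermediate/High, either at
the fixed cutoffs Low ≤ 0.058 / High ≥ 0.138 or at empirical terciles,
computed so that with distinct values exactly ⌈n/3⌉-quantile boundaries
put a third of records in each bin. Group comparisons use the two-sided
Mann–Whitney U (exact enumeration when n_a·n_b ≤ 10⁴ and tie-free,
otherwise the tie-corrected normal approximation; the two agree within
10% at n ≥ 20 per group). Category enrichment is a χ² goodness-of-fit
(df=2) of each category's bin counts against expected proportions — by
default the global bin proportions of the full record set, which under
tercile binning are thirds, making the "equal proportions" and
"global proportions" readings coincide; a flag forces exact thirds. Only
categories with ≥15 members are tested, the per-test α is 0.05/m for m
tested categories, records with several categories count in each, and the
flagged direction is the bin with the largest standardised residual.

## Synthetic data

The generator emulates: uniform-codon CDS transcripts (ATG…stop) in a
configurable length range; an orthologous peptide set produced by
per-site substitution at a chosen rate (default 10%, with a block of
"immune" transcripts at 16% to exercise group comparisons); transcript
fragmentation into overlapping or gapped pairs (alternating, so both
peptide-stage join rules fire) with junction-spanning ESTs for a
configurable fraction; paired 75-bp reads at 30× with per-base error
10⁻³; uniform-depth pileups with biallelic sites planted at 1% (pool
frequency ½, matching the detection model's assumption; a knob admits
other frequencies); and log-normal expression counts.

Read starts are *stratified* uniform — one draw per equal-width stratum of
the start range, with both extreme starts duplicated — so no seed can
leave a coverage hole or an end covered by fewer than two reads; without
this, exact-reconstruction checks would fail sporadically for reasons
unrelated to the assembler. Defaults are desk-scale study conditions, not
realism: no UTRs, isoforms, codon bias, GC bias, quality-score decay, or
mapping ambiguity. Passing tests therefore demonstrate the *logic* of
each stage (filters, thresholds, joins, corrections) and calibrated
statistical behaviour under the stated models — not performance on real
libraries, where coverage is non-uniform and errors are structured.

## Numerical and edge-case conventions

Internal coordinates are 0-based half-open; pileup and tabular-hit files
are 1-based inclusive, converted only at the format boundary. Alignment
against an empty sequence returns the forced all-gap alignment (score
gap_open + (L−1)·gap_extend). Unitigs are reported in canonical
orientation, sorted by sequence, for deterministic output. Equal top
scores in best-hit declaration yield no declaration. Zero callable length
yields π̂ = π̂_adj = 0. The χ² test drops zero-expectation cells (with the
df reduced) only in the degenerate global-proportions case. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; the pipeline itself is deterministic.

## Known limitations

The assembler does not resolve isoforms or pop bubbles, so heterozygous
indels in reads can fragment contigs. The local search's e-values are
approximate and should not be compared across scoring schemes. The
depth correction assumes balanced allele sampling and within-contig depth
exchangeability summarised by the median; strongly skewed pool
frequencies or bimodal depth profiles violate it. Functional annotation
(GO mapping) is consumed as a pre-tabulated contig→category table, never
computed.
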