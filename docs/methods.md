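# Methods

## Spectrum construction

A proteome (FASTA, any wrapping; lower case is upper-cased) is decomposed
per record into all length-k windows at step 1; windows never span record
boundaries, and duplicate identifiers are counted separately — any upstream
deduplication of the collection is the caller's responsibility.  A window is
kept only if all k letters are among the 20 standard one-letter residue
codes; the filter is defined as "not in the 20" rather than as a fixed list
of bad letters, so B/X/Z (ambiguity), U/O (selenocysteine, pyrrolysine),
`-`, `*` and anything else are all dropped, never repaired.

Counts live in a dense `int64` array indexed by the base-20 encoding of the
k-mer (alphabetical residue order, so codes sort lexicographically).  This
caps k at 6 (20^6 = 64M counters ≈ 0.5 GB); the package refuses larger k by
design — the analysis is about short modules, and the dense array is what
makes the zero-count (never-expressed) set exactly enumerable.  Bookkeeping
invariant, checked in tests: `sum(counts) = Σ_records max(0, L−k+1) −
n_windows_dropped`.

Frequency classes are computed as `counts == target` over the dense array
and stored as sorted code arrays; the class for target 0 can hold millions
of members, so membership and decoding are lazy.  The default eleven targets
(0, 1, 4, 5, 50, 100, 341, 500, 1000, 1368, 2500) span the never-expressed
set, singletons, the distribution mode, the median frequency, and the high
tail.

The inverse-sequence analysis maps each class member to the count of its
letter-reversal via a precomputed reversal permutation of the code space
(vectorized; no string round-trip), reporting min/max/mean of the inverse
counts.  Reversal is an involution and preserves residue composition, which
is exactly why it separates composition effects from order effects.

## Physico-chemical scoring and comparison

Scales are per-residue tables covering all 20 residues:

- **codon number** — sense-codon multiplicities of the standard genetic code
  (Met = Trp = 1 … Leu = Arg = Ser = 6; the 20 values sum to 61).  Peptide
  scoring always sums, so pentapeptide codon numbers are integers in
  [5, 30].
- **bulkiness** — the Zimmerman–Eliezer–Simha (1968) scale, as exposed by
  ProtScale; shipped as an editable TSV with citation header
  (dimensionless).
- **hydrophobicity** — shipped default is Kyte–Doolittle (1982); any
  two-column residue/value TSV can be supplied instead (e.g. the
  Takano–Yutani stability-derived scale), since published analyses differ in
  which hydrophobicity table they use and the loader treats them uniformly.
- **energetics** — peptide-bond formation energies require quantum-chemistry
  software; the package deliberately computes none and instead loads
  precomputed per-peptide (kJ/mol) or per-residue tables.

Hydrophobicity and bulkiness default to the per-residue mean, codon number
to the sum; for fixed-length k-mers the two modes are proportional, and both
are exposed.

Group comparison is a classical one-way fixed-effects ANOVA computed by
explicit sum-of-squares decomposition, F = MS_between/MS_within with df
(g−1, N−g) and the upper-tail p from `scipy.stats.f`.  Degenerate cases are
defined, not NaN: identical-mean groups with zero within-variance give
F = 0, p = 1; zero within-variance with unequal means raises.  Tests
cross-check F and p against `scipy.stats.f_oneway` (independent route) to
1e-9 and verify the null rejection rate at α = 0.05 is ≈ 5% over 1,000
replicates of 11 groups of 20.

Boxplot statistics use linearly interpolated quartiles (the common "type 7"
convention; the choice matters only at small n) and Tukey 1.5·IQR whiskers
placed on the most extreme values inside the fences, values beyond them
reported individually as outliers.

## Reverse translation

Standard genetic code only (NCBI translation table 1, via Biopython's codon
table).  Degenerate enumeration is the Cartesian product of per-residue
codon sets, returned in lexicographic order; its size is the product of
codon multiplicities (1 for `WWWWW` … 6^5 = 7,776 for all-six-codon
peptides).  The most-likely coding sequence requires an explicit codon-usage
table (codon, residue, fraction; per-residue fractions must sum to 1 within
1e-9) — no organism's table is assumed silently — and picks the
highest-usage codon per residue, ties broken to the lexicographically
smallest codon.  `translate` refuses stop codons and non-sense codons,
naming codon and offset, and inverts every enumerated sequence back to its
peptide (property-tested).

## Genomic-context classification

Input hits are 12-column tabular alignment reports (query, subject,
%identity, length, mismatches, gaps, qstart, qend, sstart, send, evalue,
bitscore) with optional 13th/14th columns for taxon and strand;
sstart > send is normalized to minus-strand orientation.  Running the
alignment itself is out of scope — the module consumes hit tables.
Filtering keeps only full-length (span 15 for pentapeptide oligos),
100%-identity, gap-free, mismatch-free hits, i.e. exact matches.

Annotation is parsed with gffutils (in-memory DB) into per-sequence interval
trees; introns are taken from explicit `intron` features when present and
otherwise derived from exon gaps within each mRNA.  Coordinates are GFF3
1-based inclusive throughout.

A hit can overlap several features, so one category is assigned by an
explicit precedence ladder:

1. no overlapping gene-level feature → **intergenic** (kept as its own
   honest category rather than forced into the published table's columns);
2. overlapping genes on both strands → ambiguity error listing the features
   (the caller must resolve the locus);
3. hit antisense to every overlapping gene → **minus_strand**, regardless of
   finer feature type;
4. otherwise, on the sense strand: **pseudogene** > **UTR** > **intron**
   (containment required) > CDS frame test.

The frame test: a hit wholly inside one CDS is **coding_in_frame** when its
first base sits on a codon boundary — for a plus-strand CDS,
`(hit.start − (cds.start + phase)) mod 3 == 0`, mirrored from `cds.end` on
the minus strand — and **frameshift** otherwise; a hit overlapping CDS but
not contained in a single CDS feature spans an exon junction that interrupts
the 15-mer and is likewise **frameshift**.  This offset-modulo-3 plus
junction-spanning definition is a documented operational choice; the test is
total, so a CDS hit is always exactly one of the two.

## Synthetic data

The proteome generator emulates a large protein collection at desk scale:
background residues drawn i.i.d. from a configurable composition (uniform by
default), lengths from constant/uniform/normal families (default uniform
80–400 aa, a realistic protein-length band), a configurable fraction of
positions replaced by B/X/Z, and k-mers planted at **exact** total counts.
Exactness is enforced constructively: planted copies are written into
reserved non-overlapping slots, accidental background occurrences (including
those created at slot boundaries) are detected by brute scan and destroyed
by local single-letter resampling, bounded rounds, and the final counts are
re-verified before the proteome is returned — an infeasible request raises
rather than degrading to best-effort.  With `reversal_closed`, every
record's letter-reversal is also emitted, which makes the whole spectrum
exactly symmetric under k-mer reversal; note reversal closure adds
occurrences of the *reversed* k-mer, so palindromic plants appear in pairs
(even targets only) and a k-mer cannot be planted together with its distinct
reversal.

What it does **not** emulate: real residue covariance along chains, protein
domain structure, database redundancy, or taxonomic composition.  Passing
tests therefore demonstrate that the counting, selection and classification
machinery is exact, not that any biological conclusion transfers.

The genome generator allocates each planted 15-mer its own 400 bp slot
(fixture genomes stay ≤ 100 kb so brute-force checks run in seconds) and
realizes the declared context with consistent features: single-exon coding
genes (in-frame insert at a codon boundary; frameshift insert offset by 1),
two-exon genes with a 140 bp intron, 5'-UTR geometry, bare pseudogenes,
reverse-complemented inserts for minus-strand hits, and feature-free slots
for intergenic ones.  It emits the genome FASTA, GFF3, the exact-match hit
rows (sstart > send for minus-strand) and a truth label per hit, and
self-validates by re-extracting every hit's substring from the genome.
Codon usage, isochore structure and taxonomic realism are non-goals.

Both generators are deterministic functions of their seed (NumPy
`default_rng`); the seed is recorded in output headers.

## Problem sizes

The shipped verification runs use 50 proteomes of ~60 proteins × 40–300 aa
(≈10^4 residues each, comfortably inside the brute-force oracle's range),
200 planted genomic hits across 8 × 10 kb contigs, and 1,000 ANOVA null
replicates of 11 groups of 20 — sizes chosen so every oracle is exact and
the full suite runs in seconds.

## Known limitations

- No approximate or index-based matching (no suffix arrays/FM-index); k ≤ 6.
- The energetics analysis is table-driven only; no quantum chemistry, and no
  attempt to reproduce published formation-energy values.
- Which organism's codon-usage table generated any published "most likely"
  sequence is generally unstated, so printed example oligos are validated as
  members of the degenerate set, not as most-likely ground truth.
- Whether a "frameshift" should be annotation-declared rather than derived
  from offset arithmetic is a modelling choice; ours is documented above.
- Alternative genetic codes and taxonomy resolution are out of scope.
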