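# Methods

This note documents the model behind `varzip`, the file format it commits to,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Variant encoding

A decomposed, normalized variant is identified by (chromosome, POS, REF, ALT).
Chromosomes are kept outside the encoded value (they name directories in the
archive), and each chromosome is split into bins of 2^20 bases, so 20 bits
suffice for the position offset inside a bin. The remaining 12 bits of a
32-bit code carry the alleles of any variant with combined REF+ALT length ≤ 4
over the plain nucleotide alphabet: two 2-bit length fields (1–3 each; 0 is
reserved) and up to four 2-bit bases (A=0, C=1, G=2, T=3), REF before ALT,
first base most significant. Two properties follow from this layout and are
property-tested:

* unsigned-integer order of codes equals positional order within a bin, so
  the sorted table supports binary search with no decoding;
* a *placeholder* (all 12 allele bits zero) sorts before every real variant
  at the same offset.

Variants that do not fit — total allele length > 4, or any character outside
ACGT (an N, an IUPAC ambiguity code, a symbolic allele) — are stored verbatim
in a per-bin supplemental table ordered by (offset, REF, ALT) with plain
byte-wise string comparison, and contribute one placeholder to the primary
table. The placeholder's row in the sorted primary table is recorded as the
long record's `field_index`, which keeps the annotation columns exactly
one-to-one with variants regardless of type. One placeholder is inserted per
long variant (no deduplication), so column lengths are conserved trivially.

Positions are handled 0-based internally (bin = (POS−1) >> 20), making bin 0
cover POS 1..2^20 exactly. Alleles are uppercased on ingest; the code space is
case-insensitive. The boundary case — combined length exactly 4 — is encoded
in 32 bits.

## Compression

Within a bin the codes (placeholders included) are sorted — stably, so equal
codes (duplicate variants) keep input order and lookups return the first
occurrence. The sorted codes are delta-encoded (each value stored as the
difference from its predecessor; the inverse is a cumulative sum) and then
Stream VByte-encoded: each integer occupies 1–4 little-endian bytes and a
separate control block stores 2 bits per integer (byte length − 1), four
integers per control byte, first integer in the least-significant bits,
unused bits of a final partial group zero. Because consecutive variants in a
dense bin differ by small amounts, most deltas fit in one or two bytes; the
test suite checks the mean cost on dense synthetic bins stays under 4 bytes
per value, and the acceptance script reports the measured value (~3.2
bytes/variant under default conditions) before the ZIP layer's DEFLATE
shrinks it further.

Field columns hold one signed integer per variant and are zigzag-mapped
(0, −1, 1, −2 → 0, 1, 2, 3) before Stream VByte, so the −1 missing sentinel
and small negative scores cost one byte instead of four. Variant-code columns
are non-negative by construction and are not zigzagged. Every serialized
block is `[u32 count LE][control][data]` and is validated byte-exactly on
read.

Floats are quantized as `round(value × multiplier)` with ties rounded half
away from zero — symmetric for negative scores such as conservation values —
giving a reconstruction error of at most 0.5/multiplier. The multiplier is a
per-field positive integer (default 1); 10^5–10^6 is a sensible range for
probabilities and rank scores (10^5 keeps five decimal places, which exceeds
the precision VCF text usually carries). Strings are dictionary-coded: a
single global per-field table of unique values in first-seen order, stored
once per archive as one string per line; columns store the line number. Low-
cardinality fields (consequence classes, gene symbols) therefore cost one
small integer per variant.

Integer columns must fit signed 32 bits; the builder raises a named
field-overflow error otherwise. Flag-type INFO fields are rejected at
configuration time since they have no integer representation here.

## Archive format

A standard ZIP file (DEFLATE), so bins are randomly accessible with ordinary
tooling. Layout: `vz/config.json` (the field configuration, with each field's
VCF type recorded at encode time, so annotation needs no external
configuration), `vz/<chrom>/<bin>/var32.bin`, `vz/<chrom>/<bin>/long.bin`
(LEB128 varint record stream), `vz/<chrom>/<bin>/fields/<alias>.bin`, and
`vz/strings/<alias>.txt`. Chromosome names are normalized by stripping a
leading `chr` (case-insensitive) on both encode and annotate, so GRCh37- and
GRCh38-style naming interoperate. Bin directory names are plain decimal
integers. Entries carry a fixed timestamp, so building twice from the same
input — or reading every bin and re-serializing — yields byte-identical
archives (tested). Archives are write-once; there is no append or mutation.

## Annotation

The query VCF is streamed with one single-slot bin cache per archive: a query
in the same (chromosome, bin) as its predecessor reuses the in-memory tables;
any other bin triggers exactly one load (an absent bin loads as empty). This
makes sorted queries cheapest — one load per run of same-bin variants, which
the tests verify with an instrumented reader — while unsorted queries still
produce identical annotations, only more loads.

Each query variant is encoded exactly as at build time and binary-searched in
the primary (short) or supplemental (long) table. Found variants get one
value per configured field: integers as stored, floats divided by the
multiplier, strings decoded through the dictionary. Variants not found get
each field's configured missing value (−1 / "." by default), written
explicitly so downstream filters behave deterministically. Query records that
cannot be keyed — multi-allelic, symbolic (`<DEL>`), or spanning-deletion
alleles — pass through with missing values rather than failing the run.

With several archives, fields are merged in command-line order and a
duplicated alias is taken from the last archive that provides it (warned
once). The include expression is evaluated after all archives are applied.

## Filter expressions

The `-i` expression grammar covers numeric literals, field aliases, unary
`-`/`!`, arithmetic (`+ − * /`), comparisons, `&&`/`||` and parentheses, with
conventional precedence and left associativity. Expressions are parsed once
and type-checked against the archive-provided aliases before any record is
read, so an unknown field or a type error (string arithmetic, a numeric root)
fails fast rather than record-by-record. Design choices:

* Division is real-valued — `an / 2` yields exact halves, which the
  recessive-model ratio form requires; integer truncation would shift results
  unpredictably near the cutoff.
* `&&`/`||` short-circuit; the root must be boolean (a bare number is a type
  error, not truthy).
* Division by zero is a record-level evaluation error: the record does not
  pass, one warning is logged, processing continues.
* Missing values participate as their sentinel (−1 or ".") with no special
  NA logic; filters are written against fields whose default the user knows.
  Note the consequence: with the default sentinel, `af < 0.01` *keeps*
  variants absent from the archive (af = −1). Screens that should exclude
  unseen variants need an explicit bound, e.g. `af >= 0 && af < 0.01`.
* String-typed fields support only `==`/`!=` against quoted literals.
* No function calls in this version.

Equivalence with an independent straight-line recursive evaluator, the
short-circuit behaviour (via a poisoned division on the skipped branch) and
De Morgan consistency are property-tested.

## Synthetic data generator

`varzip.fixtures` generates coordinate-sorted, strictly decomposed VCFs with
a known truth table. Defaults are the study conditions used across the test
suite: 10^4 variants, two chromosomes named `1` and `chr2` (to exercise name
normalization), positions spanning three 2^20-base bins per chromosome, 30%
long alleles with boundary lengths 4 and 5 both well represented, 2%
N-containing alleles, and three annotation fields — a geometric allele count
(integer), a skewed beta-distributed allele frequency (float, quantized at
multiplier 10^5), and a categorical consequence (string over 10 classes) —
each missing at rate 5%. Tests that need cohort-scale totals add an
allele-number field drawn uniformly from 10 000–150 000. The same seed yields
byte-identical files.

The generator emulates only what the archive pipeline consumes: site-level
records with INFO fields. It does not model linkage, haplotypes, genotype
matrices, realistic allele-frequency spectra per population, or reference-
genome context (alleles are random sequences). Passing tests therefore
demonstrate the correctness of encoding, compression, lookup and filtering
semantics on realistic record *shapes*; they say nothing about biological
properties of real cohorts, and nothing about wall-clock performance at
population scale.

`fixtures.oracle_annotate` is the independent check: an exact hash map keyed
by (normalized chromosome, POS, REF, ALT) that applies the same quantization
rules (through a float32 cast, since VCF floats are single precision) and a
separate reference expression evaluator. The full pipeline must agree with it
value-for-value and on the surviving-record set, for sorted and shuffled
query order — this, together with self-annotation (annotating the source VCF
with its own archive and requiring every value back), is the core correctness
argument.

## Numerical and degenerate-input notes

* Quantization error is bounded by 0.5/multiplier; output floats additionally
  pass through VCF single precision, adding at most one float32 ulp.
* A quantized float that legitimately equals the missing sentinel (e.g.
  −10^−6 at multiplier 10^6 → −1) is indistinguishable from a missing value;
  choose sentinels outside the field's quantized range if this matters.
* Empty bins write no entries; reading an absent bin or chromosome returns an
  empty bin, not an error.
* Duplicate identical variants are all stored; lookup returns the leftmost.
* The builder rejects out-of-order positions, revisited chromosomes and
  multi-allelic records with errors naming the offending coordinates; it does
  not filter on FILTER status (pre-filter upstream if needed).
* Records are processed per-site; only INFO fields are read, never genotypes.

## Problem sizes

The test suite and the acceptance script run on 10^4-variant cohorts (plus
10^5-element arrays for the integer-codec identities), sizes at which every
check completes in seconds while still spanning multiple bins, chromosomes,
and both variant classes. These sizes are the package's chosen verification
conditions, not limits of the implementation: the streaming builder holds at
most one bin in memory, and the annotator at most one bin per archive.

## Known limitations

* 32-bit codes only; variants with combined allele length above 4 take the
  (larger, still compact) supplemental path. A 64-bit code space is a
  possible extension with a different compression trade-off.
* Symbolic alleles are not annotatable (they pass through with defaults).
* No multi-threading; no region-restricted annotation.
* Archives produced by other tools with a similar design are not readable:
  this package defines its own byte-exact layout and claims no external
  binary compatibility.
* TSV annotation sources must be converted to VCF upstream.
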