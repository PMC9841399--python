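# varzip

Compressed variant archives for rapid annotation and filtering of SNPs and
indels in VCF/BCF files.

## The problem

Interpreting germline or somatic variants requires decorating every candidate
site with information from population-scale resources — allele frequencies,
homozygote counts, precomputed deleteriousness scores, consequence classes.
Those resources are enormous (hundreds of millions to billions of sites), and
looking each query variant up by streaming or index-jumping through the source
VCFs becomes the bottleneck of an analysis pipeline. `varzip` converts the
annotation source, once, into a compact ZIP archive of integer-encoded
variants and annotation columns, and then annotates query VCFs against that
archive with cached per-bin binary search — fast enough to re-run a filter
interactively while choosing cutoffs.

It is aimed at anyone running variant-prioritisation pipelines: annotate a
whole-genome call set with cohort allele frequencies, keep only rare variants
(`af < 0.01`), apply a recessive-model constraint on homozygote counts, or
screen somatic calls against precomputed rank scores — all in one pass.

## How it works

Each chromosome is partitioned into bins of 2^20 = 1 048 576 bases. A variant
with combined REF+ALT length ≤ 4 over {A,C,G,T} is packed into a single
unsigned 32-bit integer:

    bits 31–12  position offset within the bin   (20 bits)
    bits 11–10  len(REF) ∈ 1..3
    bits  9–8   len(ALT) ∈ 1..3
    bits  7–0   REF then ALT bases, 2 bits each (A=0, C=1, G=2, T=3)

Integer order of the codes equals positional order, so a sorted code table
supports binary search without ever decoding. Longer (or non-ACGT) variants
go verbatim into a supplemental per-bin table; a *placeholder* code (allele
bits all zero) holds their row in the primary table so the annotation columns
stay aligned one-to-one with variants.

Sorted code tables are delta-encoded (store `xᵢ − xᵢ₋₁`, invert by prefix
sum) and then Stream VByte-compressed: each integer takes 1–4 little-endian
bytes and the per-integer byte lengths live in a separate control-byte block
(2 bits per integer). Per-field columns store one integer per variant: floats
are quantized by a per-field `multiplier` (value ≈ stored/multiplier), strings
are dictionary-coded against a global per-field table of unique values, and
absent values store a missing sentinel (−1 by default). Everything is wrapped
in an ordinary ZIP file with DEFLATE entries, so bins are randomly accessible
with standard tooling.

Annotation streams the query VCF with a single-slot bin cache per archive:
consecutive variants in the same (chromosome, bin) reuse the tables already in
memory. An optional include expression (comparisons, arithmetic, `&&`/`||`,
parentheses) is evaluated on the merged annotated values of each record, and
only passing records are written.

## Worked example

Build a synthetic gnomAD-like source (2 000 sites with AF, nhomalt and AN
INFO fields — the `varzip.fixtures` module generates these with a known truth
table) and a field configuration:

```python
import json
from varzip import SynthSpec, generate_vcf
from varzip.fixtures import FieldSpec, default_fields

spec = SynthSpec(seed=4, n_variants=2000,
                 fields=default_fields() + [FieldSpec("nhomalt", "integer"),
                                            FieldSpec("AN", "integer", dist="allele_number")])
generate_vcf(spec, "gnomad_like.vcf")
json.dump([
    {"field": "AF",      "alias": "gnomad_popmax_af", "multiplier": 100000},
    {"field": "nhomalt", "alias": "gnomad_popmax_nhomalt"},
    {"field": "AN",      "alias": "gnomad_popmax_an"},
], open("gnomad.json", "w"))
```

Encode it, then annotate the same file and keep only rare variants:

```console
$ varzip encode gnomad.varzip.zip gnomad.json gnomad_like.vcf
[varzip] encoded 2000 variants (632 long) into 6 bins, 2 chromosomes, 0.0s

$ varzip anno -e gnomad.varzip.zip -i 'gnomad_popmax_af < 0.01' gnomad_like.vcf rare.vcf
[varzip] 2000 variants read, 1077 written, 0.0s
```

632 of the 2 000 variants had combined allele length above 4 bases and went to
the supplemental long-variant tables; the archive (28.6 kB) is about 5× smaller
than the source VCF (156 kB). The filter kept the 1 077 records whose annotated
popmax allele frequency is below 1% — which includes variants absent from the
archive, whose `gnomad_popmax_af` is the missing sentinel −1:

```text
1  4753  .  T  G     ...  gnomad_popmax_af=0.00676;gnomad_popmax_nhomalt=-1;gnomad_popmax_an=62794
1  7553  .  G  GTGG  ...  gnomad_popmax_af=-1;gnomad_popmax_nhomalt=9;gnomad_popmax_an=138270
```

A recessive-model screen divides homozygote counts by sample counts (allele
number / 2) directly in the expression, writing to a null sink just to count:

```console
$ varzip anno -e gnomad.varzip.zip \
    -i 'gnomad_popmax_nhomalt / (gnomad_popmax_an / 2) < 0.005' \
    gnomad_like.vcf /dev/null
[varzip] 2000 variants read, 1994 written, 0.0s
```

Multiple archives can be given with repeated `-e`; their fields are merged in
order (a later archive wins alias clashes). `varzip validate archive.zip`
re-checks every bin's structural invariants and prints per-bin statistics.

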