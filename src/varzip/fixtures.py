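"""Synthetic sorted, decomposed VCFs with known truth, plus a naive oracle.

The generator emulates a population annotation source: site-level records
with integer (allele count), float (allele frequency) and categorical string
(consequence) INFO fields, a configurable share of long alleles (combined
REF+ALT length above 4) and of non-ACGT alleles, positions spanning several
2^20-base bins on chromosomes named both with and without a ``chr`` prefix.
It returns a truth table alongside the file so every downstream check can be
made against exact expected values.  It deliberately does not model LD,
haplotypes or genotypes — only what the archive pipeline consumes.

``oracle_annotate`` is the independent reference: a hash map keyed by
(normalized chrom, pos, ref, alt) with the same quantization rules as the
builder, against which the real pipeline must agree value-for-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .archive_io import FieldConfig, normalize_chrom
from .builder import dequantize, quantize
from .errors import EvaluationError
from .filter_expr import Ident, Num, Str, Unary

DEFAULT_CATEGORIES = (
    "missense",
    "synonymous",
    "stop_gained",
    "splice_donor",
    "intron",
    "intergenic",
    "5_prime_UTR",
    "frameshift",
    "inframe_deletion",
    "start_lost",
)


@dataclass(frozen=True)
class FieldSpec:
    """One synthetic INFO field: name, VCF type, and sampling distribution.

    ``dist`` selects the integer distribution: "geometric" for small counts
    (allele counts, homozygote counts) or "allele_number" for cohort-scale
    totals like gnomAD AN.
    """

    name: str
    ftype: str  # integer | float | string
    missing_rate: float = 0.05
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    dist: str = "geometric"


def default_fields() -> list[FieldSpec]:
    return [
        FieldSpec("AC", "integer"),
        FieldSpec("AF", "float"),
        FieldSpec("CSQ", "string"),
    ]


@dataclass
class SynthSpec:
    """Study conditions for one synthetic cohort VCF.

    Defaults match the conditions used throughout the test suite: 10^4
    variants, 30% long alleles, a small share of N-containing alleles,
    two chromosomes (one with a ``chr`` prefix to exercise normalization),
    positions spanning three bins per chromosome.
    """

    seed: int = 0
    n_variants: int = 10_000
    chrom_names: tuple[str, ...] = ("1", "chr2")
    position_span: tuple[int, int] = (1, 3 * (1 << 20))
    fraction_long: float = 0.3
    fraction_nonacgt: float = 0.02
    fields: list[FieldSpec] = dc_field(default_factory=default_fields)


@dataclass
class TruthRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict[str, object]  # absent fields simply missing from the dict

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)


_BASES = "ACGT"


def _random_allele(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _draw_alleles(rng: np.random.Generator, spec: SynthSpec) -> tuple[str, str]:
    long_variant = rng.random() < spec.fraction_long
    if long_variant:
        # first length past the 32-bit boundary is well represented
        total = int(rng.choice([5, 5, 6, 7, 8, 10, 12]))
    else:
        # boundary total length 4 is well represented too
        total = int(rng.choice([2, 2, 2, 3, 4, 4]))
    ref_len = int(rng.integers(1, total))
    ref = _random_allele(rng, ref_len)
    alt = _random_allele(rng, total - ref_len)
    while alt == ref:
        alt = _random_allele(rng, total - ref_len)
    if rng.random() < spec.fraction_nonacgt:
        which = rng.random() < 0.5
        allele = ref if which else alt
        i = int(rng.integers(0, len(allele)))
        allele = allele[:i] + "N" + allele[i + 1 :]
        if which:
            ref = allele
        else:
            alt = allele
        if ref == alt:  # degenerate after substitution; force a SNP change
            alt = "A" if ref != "A" else "C"
    return ref, alt


def _draw_value(rng: np.random.Generator, fs: FieldSpec):
    if fs.ftype == "integer":
        if fs.dist == "allele_number":
            return int(rng.integers(10_000, 150_000))
        return int(rng.geometric(0.1))
    if fs.ftype == "float":
        # skewed small frequencies, like population AFs; store the exact
        # value the VCF text will carry
        return float(f"{min(rng.beta(0.3, 8.0), 1.0):.6g}")
    return str(rng.choice(fs.categories))


def generate_truth(spec: SynthSpec) -> list[TruthRecord]:
    """Draw the records without rendering them to disk."""
    rng = np.random.default_rng(spec.seed)
    n_chrom = len(spec.chrom_names)
    counts = [spec.n_variants // n_chrom] * n_chrom
    counts[-1] += spec.n_variants - sum(counts)
    lo, hi = spec.position_span
    records: list[TruthRecord] = []
    for chrom, count in zip(spec.chrom_names, counts):
        positions = np.sort(rng.integers(lo, hi + 1, size=count))
        for pos in positions:
            ref, alt = _draw_alleles(rng, spec)
            info = {}
            for fs in spec.fields:
                if rng.random() >= fs.missing_rate:
                    info[fs.name] = _draw_value(rng, fs)
            records.append(TruthRecord(chrom, int(pos), ref, alt, info))
    return records


_VCF_TYPE = {"integer": "Integer", "float": "Float", "string": "String"}


def render_vcf(spec: SynthSpec, records: list[TruthRecord]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    contig_len = spec.position_span[1] + (1 << 20)
    for chrom in spec.chrom_names:
        lines.append(f"##contig=<ID={chrom},length={contig_len}>")
    for fs in spec.fields:
        lines.append(
            f"##INFO=<ID={fs.name},Number=1,Type={_VCF_TYPE[fs.ftype]},"
            f'Description="synthetic {fs.ftype} field">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        if r.info:
            info = ";".join(f"{k}={_render_info(v)}" for k, v in r.info.items())
        else:
            info = "."
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}")
    return "\n".join(lines) + "\n"


def _render_info(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def generate_vcf(spec: SynthSpec, out_path) -> list[TruthRecord]:
    """Write a synthetic VCF (bgzipped if the path ends in .gz); return truth."""
    records = generate_truth(spec)
    text = render_vcf(spec, records)
    out_path = str(out_path)
    if out_path.endswith(".gz"):
        import pysam  # only needed for compressed output

        import tempfile, os

        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False, dir=os.path.dirname(out_path) or "."
        ) as fh:
            fh.write(text)
            tmp = fh.name
        try:
            pysam.tabix_compress(tmp, out_path, force=True)
        finally:
            os.unlink(tmp)
    else:
        with open(out_path, "w") as fh:
            fh.write(text)
    return records


def truth_to_tsv(records: list[TruthRecord], fields: list[FieldSpec]) -> str:
    """Debug rendering of the truth table."""
    header = ["chrom", "pos", "ref", "alt"] + [fs.name for fs in fields]
    rows = ["\t".join(header)]
    for r in records:
        cells = [r.chrom, str(r.pos), r.ref, r.alt]
        cells += [_render_info(r.info[fs.name]) if fs.name in r.info else "." for fs in fields]
        rows.append("\t".join(cells))
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Naive oracle annotator


def reference_evaluate(ast, env):
    """Straightforward recursive evaluator, independent of the production one.

    No short-circuiting: both operands of && and || are always computed.
    """
    if isinstance(ast, Num):
        return ast.value
    if isinstance(ast, Str):
        return ast.value
    if isinstance(ast, Ident):
        v = env[ast.name]
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            return v
        return float(v)
    if isinstance(ast, Unary):
        v = reference_evaluate(ast.operand, env)
        return (not v) if ast.op == "!" else -v
    left = reference_evaluate(ast.left, env)
    right = reference_evaluate(ast.right, env)
    op = ast.op
    if op == "&&":
        return bool(left) and bool(right)
    if op == "||":
        return bool(left) or bool(right)
    if op == "/":
        if right == 0:
            raise EvaluationError("division by zero")
        return left / right
    import operator

    return {
        "<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge,
        "==": operator.eq, "!=": operator.ne,
        "+": operator.add, "-": operator.sub, "*": operator.mul,
    }[op](left, right)


def oracle_annotate(
    truth_table: list[TruthRecord],
    query_records,
    configs: list[FieldConfig],
    filter_ast=None,
):
    """Annotate query records from an exact hash map; the independent oracle.

    ``query_records`` are (chrom, pos, ref, alt) tuples or TruthRecords.
    Applies the builder's quantize/dequantize to float fields (through a
    float32 cast, since VCF floats are single precision) so values compare
    exactly with the real pipeline.  Returns (annotated, surviving) where
    ``annotated`` is a list of alias->value dicts aligned with the queries
    and ``surviving`` the indices passing the filter.
    """
    table: dict[tuple, dict] = {}
    for r in truth_table:
        table.setdefault(r.key, r.info)  # first occurrence wins (leftmost match)
    annotated = []
    surviving = []
    for i, q in enumerate(query_records):
        if isinstance(q, TruthRecord):
            key = q.key
        else:
            chrom, pos, ref, alt = q
            key = (normalize_chrom(chrom), pos, ref.upper(), alt.upper())
        info = table.get(key)
        env = {}
        for cfg in configs:
            raw = None if info is None else info.get(cfg.field)
            if cfg.ftype == "string":
                env[cfg.alias] = cfg.missing_string if raw is None else str(raw)
            elif cfg.ftype == "float":
                if raw is None:
                    env[cfg.alias] = float(cfg.missing_value)
                else:
                    q32 = quantize(float(np.float32(raw)), cfg.multiplier)
                    env[cfg.alias] = (
                        float(cfg.missing_value)
                        if q32 == cfg.missing_value
                        else dequantize(q32, cfg.multiplier)
                    )
            else:
                env[cfg.alias] = cfg.missing_value if raw is None else int(raw)
        annotated.append(env)
        if filter_ast is None:
            surviving.append(i)
        else:
            try:
                if bool(reference_evaluate(filter_ast, env)):
                    surviving.append(i)
            except EvaluationError:
                pass
    return annotated, surviving
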