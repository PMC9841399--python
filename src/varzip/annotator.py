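"""Annotate a query VCF/BCF from one or more archives.

Each archive keeps a single-slot bin cache: when a query variant falls in the
same (chromosome, bin) as the previous one, the bin's tables are already in
memory; otherwise the new bin is read (an absent bin reads as empty).  The
query variant is encoded exactly as at build time and binary-searched — short
variants against the 32-bit primary table, long ones against the supplemental
table — and the resulting row indexes one value out of every field column.
Variants not found receive each field's configured missing value.

Archives are applied in command-line order; when two archives define the same
alias the later one wins (a warning is logged once).  The optional include
expression is evaluated on the merged values after all archives; only records
for which it is true are written.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_left
from dataclasses import dataclass, field as dc_field

from cyvcf2 import VCF, Writer

from . import filter_expr
from .archive_io import ArchiveReader, BinData, FieldConfig, normalize_chrom
from .builder import dequantize
from .errors import ExpressionError
from .variant_codec import bin_of, encode32, is_short

logger = logging.getLogger(__name__)

_NULL_SINKS = {"/dev/null", os.devnull, "NUL", "nul"}


@dataclass
class AnnotationResult:
    """Values for one variant from one archive; all-missing when not found."""

    values: dict[str, object]
    found: bool


def lookup(
    bin_data: BinData,
    offset: int,
    ref: str,
    alt: str,
    configs: list[FieldConfig],
    strings: dict[str, list[str]],
) -> AnnotationResult:
    """Binary-search one variant in a loaded bin and extract its field values."""
    idx = -1
    if is_short(ref, alt):
        code = encode32(offset, ref, alt)
        i = bisect_left(bin_data.var32, code)
        if i < len(bin_data.var32) and bin_data.var32[i] == code:
            idx = i
    else:
        key = (offset, ref, alt)
        keys = [r.sort_key for r in bin_data.longs]
        i = bisect_left(keys, key)
        if i < len(keys) and keys[i] == key:
            idx = bin_data.longs[i].field_index
    found = idx >= 0
    values: dict[str, object] = {}
    for cfg in configs:
        if not found:
            values[cfg.alias] = _missing_value(cfg)
            continue
        stored = bin_data.columns[cfg.alias][idx]
        values[cfg.alias] = _decode_value(stored, cfg, strings)
    return AnnotationResult(values=values, found=found)


def _missing_value(cfg: FieldConfig):
    if cfg.ftype == "string":
        return cfg.missing_string
    if cfg.ftype == "float":
        return float(cfg.missing_value)
    return cfg.missing_value


def _decode_value(stored: int, cfg: FieldConfig, strings: dict[str, list[str]]):
    if cfg.ftype == "string":
        return strings[cfg.alias][stored]
    if cfg.ftype == "float":
        # the sentinel is stored unscaled, so it round-trips as itself
        if stored == cfg.missing_value:
            return float(cfg.missing_value)
        return dequantize(stored, cfg.multiplier)
    return stored


class BinCache:
    """At most one loaded bin per archive; exact (chrom, bin) match required."""

    def __init__(self, reader: ArchiveReader):
        self.reader = reader
        self.key: tuple[str, int] | None = None
        self.data: BinData | None = None

    def load_bin_if_needed(self, chrom: str, bin_index: int) -> BinData:
        key = (chrom, bin_index)
        if key != self.key:
            self.data = self.reader.read_bin(chrom, bin_index)
            self.key = key
        return self.data


@dataclass
class AnnotateSummary:
    variants_read: int = 0
    variants_written: int = 0
    eval_errors: int = 0


@dataclass
class _ArchiveSlot:
    reader: ArchiveReader
    cache: BinCache
    strings: dict[str, list[str]] = dc_field(default_factory=dict)


class Annotator:
    """Reusable annotation engine over an ordered list of archives."""

    def __init__(self, archive_paths, filter_expression: str | None = None):
        self.slots: list[_ArchiveSlot] = []
        for p in archive_paths:
            reader = ArchiveReader(p)
            slot = _ArchiveSlot(reader=reader, cache=BinCache(reader))
            slot.strings = {
                c.alias: reader.read_strings(c.alias)
                for c in reader.configs
                if c.ftype == "string"
            }
            self.slots.append(slot)
        if not self.slots:
            raise ExpressionError("at least one archive is required")

        # merged alias view: later archives overwrite earlier duplicates
        merged: dict[str, tuple[int, FieldConfig]] = {}
        for i, slot in enumerate(self.slots):
            for cfg in slot.reader.configs:
                if cfg.alias in merged:
                    logger.warning(
                        "alias %r provided by multiple archives; %s wins",
                        cfg.alias,
                        os.path.basename(str(slot.reader.path)),
                    )
                merged[cfg.alias] = (i, cfg)
        self.merged = merged

        self.ast = None
        if filter_expression is not None:
            self.ast = filter_expr.parse(filter_expression)
            types = {
                alias: ("str" if cfg.ftype == "string" else "num")
                for alias, (_, cfg) in merged.items()
            }
            filter_expr.check_types(self.ast, types)

    def annotate_record_values(self, chrom: str, pos1: int, ref: str, alt: str) -> dict:
        """Merged alias -> value for one decomposed variant."""
        chrom = normalize_chrom(chrom)
        bin_index, offset = bin_of(pos1)
        env: dict[str, object] = {}
        for slot in self.slots:
            data = slot.cache.load_bin_if_needed(chrom, bin_index)
            result = lookup(
                data, offset, ref.upper(), alt.upper(), slot.reader.configs, slot.strings
            )
            env.update(result.values)
        return env

    def default_values(self) -> dict:
        return {alias: _missing_value(cfg) for alias, (_, cfg) in self.merged.items()}

    def passes(self, env: dict, summary: AnnotateSummary) -> bool:
        if self.ast is None:
            return True
        try:
            return filter_expr.evaluate(self.ast, env)
        except filter_expr.EvaluationError as e:
            if summary.eval_errors == 0:
                logger.warning("filter evaluation failed for a record: %s", e)
            summary.eval_errors += 1
            return False

    def close(self):
        for slot in self.slots:
            slot.reader.close()


def _annotatable(record) -> tuple[str, str] | None:
    alts = record.ALT
    if len(alts) != 1:
        return None
    ref, alt = record.REF.upper(), alts[0].upper()
    if not ref or not alt or alt.startswith("<") or "*" in alt or "." in alt:
        return None
    return ref, alt


def annotate_vcf(
    query_path,
    archives,
    filter_expression: str | None = None,
    out_path: str = "/dev/null",
) -> AnnotateSummary:
    """Annotate ``query_path`` with every field from ``archives``; write output.

    Output format follows the extension (.vcf, .vcf.gz, .bcf); a null-device
    path discards records (the run still reads, annotates and filters).
    Query records with symbolic or multi-allelic ALTs pass through with each
    field's missing value.
    """
    engine = Annotator(archives, filter_expression)
    summary = AnnotateSummary()
    vcf = VCF(str(query_path))
    for alias, (i, cfg) in engine.merged.items():
        vcf_type = {"integer": "Integer", "float": "Float", "string": "String"}[cfg.ftype]
        source = os.path.basename(str(engine.slots[i].reader.path))
        vcf.add_info_to_header(
            {
                "ID": alias,
                "Number": "1",
                "Type": vcf_type,
                "Description": f"added by varzip from {source}",
            }
        )
    writer = None
    if str(out_path) not in _NULL_SINKS:
        writer = Writer(str(out_path), vcf)
    try:
        for record in vcf:
            summary.variants_read += 1
            alleles = _annotatable(record)
            if alleles is None:
                env = engine.default_values()
            else:
                env = engine.annotate_record_values(
                    record.CHROM, record.POS, alleles[0], alleles[1]
                )
            for alias, value in env.items():
                record.INFO[alias] = value
            if engine.passes(env, summary):
                summary.variants_written += 1
                if writer is not None:
                    writer.write_record(record)
    finally:
        if writer is not None:
            writer.close()
        vcf.close()
        engine.close()
    logger.info(
        "annotated %d variants, wrote %d", summary.variants_read, summary.variants_written
    )
    return summary
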