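"""Build an archive from a sorted, decomposed population VCF/BCF.

The input is streamed once.  Each record is binned by position; when the
stream leaves a (chromosome, bin) the accumulated bin is sorted by 32-bit
code (stable, so duplicate variants keep input order), the field columns are
permuted identically, and everything is written to the ZIP.

Short variants (combined REF+ALT length <= 4, ACGT only) become 32-bit codes.
Every other variant contributes a placeholder code at its offset plus a
verbatim record in the supplemental long-variant table whose field_index is
the placeholder's row in the sorted primary table.

Float INFO values are quantized to integers by the per-field multiplier
(round half away from zero); string values are dictionary-coded against a
single global per-field dictionary in first-seen order; absent values store
the configured missing sentinel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from cyvcf2 import VCF

from .archive_io import ArchiveWriter, BinData, FieldConfig, normalize_chrom
from .errors import (
    ConfigError,
    DecompositionError,
    FieldOverflowError,
    SortOrderError,
)
from .variant_codec import (
    LongVariantRecord,
    bin_of,
    encode32,
    is_short,
    placeholder32,
)

logger = logging.getLogger(__name__)

_I32_MIN, _I32_MAX = -(1 << 31), (1 << 31) - 1


def quantize(value: float, multiplier: int) -> int:
    """Float -> stored integer: round(value * multiplier), half away from zero."""
    scaled = value * multiplier
    if not math.isfinite(scaled) or abs(scaled) >= 1 << 31:
        raise FieldOverflowError(
            f"value {value} * multiplier {multiplier} exceeds signed 32 bits"
        )
    return int(math.copysign(math.floor(abs(scaled) + 0.5), scaled))


def dequantize(stored: int, multiplier: int) -> float:
    """Stored integer -> float; inverse of :func:`quantize` up to 0.5/multiplier."""
    return stored / multiplier


class StringDict:
    """Global per-field dictionary: first-seen order assigns integer codes."""

    def __init__(self):
        self.strings: list[str] = []
        self._codes: dict[str, int] = {}

    def encode(self, value: str) -> int:
        code = self._codes.get(value)
        if code is None:
            code = len(self.strings)
            self._codes[value] = code
            self.strings.append(value)
        return code


def encode_string_value(value: str, dictionary: StringDict) -> int:
    """Return the code for ``value``, growing the dictionary on first sight."""
    return dictionary.encode(value)


@dataclass
class BuildSummary:
    variants: int = 0
    longs: int = 0
    bins: int = 0
    chromosomes: int = 0


_HEADER_TYPE_MAP = {
    "Integer": "integer",
    "Float": "float",
    "String": "string",
    "Character": "string",
}


def _infer_ftypes(vcf: VCF, configs: list[FieldConfig]) -> list[FieldConfig]:
    out = []
    for cfg in configs:
        try:
            header = vcf.get_header_type(cfg.field)
        except KeyError:
            raise ConfigError(
                f"configured field {cfg.field!r} is not in the VCF header"
            ) from None
        vcf_type = header.get("Type")
        if vcf_type == "Flag":
            raise ConfigError(
                f"field {cfg.field!r} is a Flag; flags have no integer representation"
            )
        ftype = _HEADER_TYPE_MAP.get(vcf_type)
        if ftype is None:
            raise ConfigError(f"field {cfg.field!r} has unsupported Type={vcf_type}")
        out.append(replace(cfg, ftype=ftype))
    return out


def _scalar_info(raw, field: str, chrom: str, pos: int):
    """Unwrap cyvcf2 INFO values; reject multi-valued entries."""
    if isinstance(raw, tuple):
        if len(raw) != 1:
            raise DecompositionError(
                f"{chrom}:{pos} INFO/{field} holds {len(raw)} values; "
                "decompose the input (e.g. bcftools norm -m-) first"
            )
        return raw[0]
    return raw


class _BinAccumulator:
    """Entries of the bin currently being filled, in input order."""

    def __init__(self):
        self.codes: list[int] = []
        self.is_long: list[bool] = []
        self.alleles: list[tuple[str, str] | None] = []
        self.values: list[list[int]] = []

    def __len__(self):
        return len(self.codes)

    def add(self, code: int, long_alleles, values: list[int]) -> None:
        self.codes.append(code)
        self.is_long.append(long_alleles is not None)
        self.alleles.append(long_alleles)
        self.values.append(values)

    def to_bin_data(self, configs: list[FieldConfig]) -> BinData:
        order = sorted(range(len(self.codes)), key=self.codes.__getitem__)
        var32 = [self.codes[i] for i in order]
        columns = {
            cfg.alias: [self.values[i][j] for i in order]
            for j, cfg in enumerate(configs)
        }
        longs = []
        for row, i in enumerate(order):
            if self.is_long[i]:
                ref, alt = self.alleles[i]
                longs.append(
                    LongVariantRecord(self.codes[i] >> 12, ref, alt, field_index=row)
                )
        longs.sort(key=lambda r: r.sort_key)
        return BinData(var32=var32, longs=longs, columns=columns)


def build_archive(vcf_path, configs: list[FieldConfig], out_zip_path) -> BuildSummary:
    """Stream ``vcf_path`` once and write the archive to ``out_zip_path``."""
    vcf = VCF(str(vcf_path))
    configs = _infer_ftypes(vcf, configs)
    dicts = {c.alias: StringDict() for c in configs if c.ftype == "string"}
    summary = BuildSummary()

    writer = ArchiveWriter(out_zip_path, configs)
    acc = _BinAccumulator()
    cur_chrom: str | None = None
    cur_bin = -1
    last_pos = 0
    seen_chroms: set[str] = set()

    def flush():
        if len(acc):
            writer.write_bin(cur_chrom, cur_bin, acc.to_bin_data(configs))
            summary.bins += 1

    try:
        for v in vcf:
            chrom = normalize_chrom(v.CHROM)
            if chrom != cur_chrom:
                if chrom in seen_chroms:
                    raise SortOrderError(
                        f"chromosome {v.CHROM} revisited at POS {v.POS}; "
                        "input must be coordinate-sorted"
                    )
                flush()
                acc = _BinAccumulator()
                if cur_chrom is not None:
                    logger.info("finished chromosome %s", cur_chrom)
                seen_chroms.add(chrom)
                cur_chrom, cur_bin, last_pos = chrom, -1, 0
            elif v.POS < last_pos:
                raise SortOrderError(
                    f"{v.CHROM}:{v.POS} is before the preceding record at "
                    f"{v.CHROM}:{last_pos}; input must be coordinate-sorted"
                )
            last_pos = v.POS

            alts = v.ALT
            if len(alts) != 1:
                raise DecompositionError(
                    f"{v.CHROM}:{v.POS} has {len(alts)} ALT alleles; "
                    "decompose the input (e.g. bcftools norm -m-) first"
                )
            ref = v.REF.upper()
            alt = alts[0].upper()
            if not ref or not alt:
                raise DecompositionError(f"{v.CHROM}:{v.POS} has an empty allele")

            bin_index, offset = bin_of(v.POS)
            if bin_index != cur_bin:
                flush()
                acc = _BinAccumulator()
                cur_bin = bin_index

            values = [
                _extract_value(v, cfg, dicts, chrom) for cfg in configs
            ]
            if is_short(ref, alt):
                acc.add(encode32(offset, ref, alt), None, values)
            else:
                acc.add(placeholder32(offset), (ref, alt), values)
                summary.longs += 1
            summary.variants += 1
        flush()
        for cfg in configs:
            if cfg.ftype == "string":
                writer.write_strings(cfg.alias, dicts[cfg.alias].strings)
    finally:
        writer.close()
        vcf.close()
    summary.chromosomes = len(seen_chroms)
    logger.info(
        "encoded %d variants (%d long) into %d bins across %d chromosomes",
        summary.variants, summary.longs, summary.bins, summary.chromosomes,
    )
    return summary


def _extract_value(v, cfg: FieldConfig, dicts: dict[str, StringDict], chrom: str) -> int:
    raw = _scalar_info(v.INFO.get(cfg.field), cfg.field, chrom, v.POS)
    if cfg.ftype == "string":
        if raw is None:
            return dicts[cfg.alias].encode(cfg.missing_string)
        if isinstance(raw, bytes):
            raw = raw.decode()
        return dicts[cfg.alias].encode(str(raw))
    if raw is None:
        return cfg.missing_value
    if cfg.ftype == "float":
        return quantize(float(raw), cfg.multiplier)
    iv = int(raw)
    if not _I32_MIN <= iv <= _I32_MAX:
        raise FieldOverflowError(
            f"INFO/{cfg.field} value {iv} at {chrom}:{v.POS} exceeds signed 32 bits"
        )
    return iv
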