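"""The ZIP archive format: layout, field configs, bin and string-table I/O.

An archive is a plain ZIP file (DEFLATE entries) with this internal layout::

    vz/config.json                  the field configuration, including the
                                    inferred VCF type of each field, so the
                                    archive is self-describing at annotation
    vz/<chrom>/<bin>/var32.bin      sorted 32-bit variant codes, delta +
                                    Stream VByte   ([u32 count][control][data])
    vz/<chrom>/<bin>/long.bin       supplemental long-variant records
                                    ([u32 count] then per record: varint
                                    offset, varint len(ref), ref bytes,
                                    varint len(alt), alt bytes, varint
                                    field_index; varint = LEB128)
    vz/<chrom>/<bin>/fields/<alias>.bin
                                    one integer per var32 entry, zigzag +
                                    Stream VByte
    vz/strings/<alias>.txt          one unique string per line; the line
                                    number (0-based) is the integer code
                                    stored in the field column

Chromosome directory names are normalized by stripping a leading ``chr``
(case-insensitive) so GRCh37- and GRCh38-style names interoperate.  Entries
are written with a fixed timestamp so identical inputs produce byte-identical
archives.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np

from . import int_codec
from .errors import ArchiveError, ConfigError, CorruptArchiveError
from .variant_codec import LongVariantRecord

PATH_PREFIX = "vz"
_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)
_FTYPES = ("integer", "float", "string")
_CONFIG_KEYS = ("field", "alias", "multiplier", "missing_value", "missing_string", "ftype")


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' (any case) from a chromosome name."""
    return name[3:] if name[:3].lower() == "chr" else name


@dataclass(frozen=True)
class FieldConfig:
    """One INFO field to extract: source key, output alias, and storage rules.

    ``multiplier`` quantizes float fields (stored = round(value * multiplier));
    ``missing_value`` is the integer sentinel stored when the source INFO is
    absent; ``missing_string`` is the string returned for absent string
    fields.  ``ftype`` is inferred from the source VCF header at encode time
    and persisted in the archive.
    """

    field: str
    alias: str = ""
    multiplier: int = 1
    missing_value: int = -1
    missing_string: str = "."
    ftype: str | None = None

    def __post_init__(self):
        if not self.alias:
            object.__setattr__(self, "alias", self.field)


def _validate_alias(alias: str) -> None:
    if not alias or any(c in alias for c in " \t;=\n"):
        raise ConfigError(f"invalid INFO alias: {alias!r}")


def parse_config(config) -> list[FieldConfig]:
    """Parse a JSON configuration (text or already-loaded list) into FieldConfigs."""
    if isinstance(config, (str, bytes)):
        try:
            config = json.loads(config)
        except json.JSONDecodeError as e:
            raise ConfigError(f"configuration is not valid JSON: {e}") from e
    if not isinstance(config, list):
        raise ConfigError("configuration must be a JSON array of objects")
    out: list[FieldConfig] = []
    seen_aliases: set[str] = set()
    for i, entry in enumerate(config):
        if not isinstance(entry, dict) or "field" not in entry:
            raise ConfigError(f"configuration entry {i} lacks a 'field' key")
        unknown = set(entry) - set(_CONFIG_KEYS)
        if unknown:
            raise ConfigError(
                f"configuration entry {i} has unknown keys: {sorted(unknown)}"
            )
        mult = entry.get("multiplier", 1)
        if not isinstance(mult, int) or isinstance(mult, bool) or mult < 1:
            raise ConfigError(
                f"multiplier for field {entry['field']!r} must be a positive integer"
            )
        missing = entry.get("missing_value", -1)
        if not isinstance(missing, int) or isinstance(missing, bool):
            raise ConfigError(
                f"missing_value for field {entry['field']!r} must be an integer"
            )
        ftype = entry.get("ftype")
        if ftype is not None and ftype not in _FTYPES:
            raise ConfigError(f"unknown ftype {ftype!r} for field {entry['field']!r}")
        cfg = FieldConfig(
            field=entry["field"],
            alias=entry.get("alias", entry["field"]),
            multiplier=mult,
            missing_value=missing,
            missing_string=entry.get("missing_string", "."),
            ftype=ftype,
        )
        _validate_alias(cfg.alias)
        if cfg.alias in seen_aliases:
            raise ConfigError(f"duplicate alias {cfg.alias!r} in configuration")
        seen_aliases.add(cfg.alias)
        out.append(cfg)
    if not out:
        raise ConfigError("configuration lists no fields")
    return out


def config_to_json(configs: Iterable[FieldConfig]) -> str:
    """Deterministic JSON rendering of a configuration (stored in the archive)."""
    entries = []
    for c in configs:
        d = {
            "field": c.field,
            "alias": c.alias,
            "multiplier": c.multiplier,
            "missing_value": c.missing_value,
            "missing_string": c.missing_string,
        }
        if c.ftype is not None:
            d["ftype"] = c.ftype
        entries.append(d)
    return json.dumps(entries, indent=2) + "\n"


@dataclass
class BinData:
    """Everything stored for one (chromosome, bin): codes, longs, field columns."""

    var32: list[int] = dc_field(default_factory=list)
    longs: list[LongVariantRecord] = dc_field(default_factory=list)
    columns: dict[str, list[int]] = dc_field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.var32)
        if any(a > b for a, b in zip(self.var32, self.var32[1:])):
            raise CorruptArchiveError("var32 table is not sorted")
        for alias, col in self.columns.items():
            if len(col) != n:
                raise CorruptArchiveError(
                    f"column {alias!r} has {len(col)} values for {n} variants"
                )
        keys = [r.sort_key for r in self.longs]
        if any(a > b for a, b in zip(keys, keys[1:])):
            raise CorruptArchiveError("long-variant table is not sorted")
        for r in self.longs:
            if not r.ref or not r.alt:
                raise CorruptArchiveError("long variant with empty allele")
            if not 0 <= r.field_index < n:
                raise CorruptArchiveError(
                    f"long variant field_index {r.field_index} out of range 0..{n - 1}"
                )

    def is_empty(self) -> bool:
        return not self.var32


# ---------------------------------------------------------------------------
# varint (LEB128) helpers for the long-variant record stream


def write_varint(n: int, out: bytearray) -> None:
    if n < 0:
        raise ValueError("varint is unsigned")
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            out.append(b | 0x80)
        else:
            out.append(b)
            return


def read_varint(buf: bytes, pos: int) -> tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if pos >= len(buf):
            raise CorruptArchiveError("truncated varint")
        b = buf[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7


def _longs_to_bytes(longs: list[LongVariantRecord]) -> bytes:
    out = bytearray(struct.pack("<I", len(longs)))
    for r in longs:
        write_varint(r.offset, out)
        ref = r.ref.encode()
        alt = r.alt.encode()
        write_varint(len(ref), out)
        out += ref
        write_varint(len(alt), out)
        out += alt
        write_varint(r.field_index, out)
    return bytes(out)


def _longs_from_bytes(buf: bytes, entry: str) -> list[LongVariantRecord]:
    if len(buf) < 4:
        raise CorruptArchiveError(f"{entry}: missing record count")
    (n,) = struct.unpack_from("<I", buf)
    pos = 4
    out = []
    try:
        for _ in range(n):
            offset, pos = read_varint(buf, pos)
            ln, pos = read_varint(buf, pos)
            ref = buf[pos : pos + ln].decode()
            pos += ln
            ln, pos = read_varint(buf, pos)
            alt = buf[pos : pos + ln].decode()
            pos += ln
            fi, pos = read_varint(buf, pos)
            out.append(LongVariantRecord(offset, ref, alt, fi))
    except CorruptArchiveError:
        raise CorruptArchiveError(f"{entry}: truncated long-variant stream") from None
    if pos != len(buf):
        raise CorruptArchiveError(f"{entry}: trailing bytes after records")
    return out


# ---------------------------------------------------------------------------


def _bin_dir(chrom: str, bin_index: int) -> str:
    return f"{PATH_PREFIX}/{chrom}/{bin_index}"


class ArchiveWriter:
    """Write a new archive.  Entries get a fixed timestamp for determinism."""

    def __init__(self, path, configs: list[FieldConfig]):
        self.configs = list(configs)
        self._zf = zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED)
        self._writestr(f"{PATH_PREFIX}/config.json", config_to_json(self.configs))

    def _writestr(self, name: str, data) -> None:
        zi = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
        zi.compress_type = zipfile.ZIP_DEFLATED
        zi.external_attr = 0o644 << 16
        self._zf.writestr(zi, data)

    def write_bin(self, chrom: str, bin_index: int, bin_data: BinData) -> None:
        if bin_data.is_empty():
            return
        bin_data.validate()
        base = _bin_dir(normalize_chrom(chrom), bin_index)
        deltas = int_codec.delta_encode(np.asarray(bin_data.var32, dtype=np.uint64))
        self._writestr(f"{base}/var32.bin", int_codec.encode_u32_block(deltas))
        if bin_data.longs:
            self._writestr(f"{base}/long.bin", _longs_to_bytes(bin_data.longs))
        for cfg in self.configs:
            col = bin_data.columns.get(cfg.alias)
            if col is None:
                raise CorruptArchiveError(f"bin lacks column for alias {cfg.alias!r}")
            zz = int_codec.zigzag(np.asarray(col, dtype=np.int64))
            self._writestr(f"{base}/fields/{cfg.alias}.bin", int_codec.encode_u32_block(zz))

    def write_strings(self, alias: str, strings: list[str]) -> None:
        for s in strings:
            if "\n" in s:
                raise ConfigError(f"string value for {alias!r} contains a newline")
        self._writestr(f"{PATH_PREFIX}/strings/{alias}.txt", "\n".join(strings))

    def close(self) -> None:
        self._zf.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class ArchiveReader:
    """Read an archive; self-describing via its stored config.json.

    ``bin_reads`` counts every bin load (including loads of absent bins) so
    the annotator's single-slot cache behaviour is observable.
    """

    def __init__(self, path):
        self.path = path
        try:
            self._zf = zipfile.ZipFile(path, "r")
        except (OSError, zipfile.BadZipFile) as e:
            raise ArchiveError(f"cannot open archive {path}: {e}") from e
        try:
            raw = self._zf.read(f"{PATH_PREFIX}/config.json")
        except KeyError:
            raise ArchiveError(f"{path} is not a varzip archive (no config.json)")
        self.configs = parse_config(raw.decode())
        self._names = set(self._zf.namelist())
        self._strings: dict[str, list[str]] = {}
        self.bin_reads = 0

    def read_strings(self, alias: str) -> list[str]:
        if alias not in self._strings:
            name = f"{PATH_PREFIX}/strings/{alias}.txt"
            if name not in self._names:
                self._strings[alias] = []
            else:
                text = self._zf.read(name).decode()
                self._strings[alias] = text.split("\n") if text else []
        return self._strings[alias]

    def _read_entry(self, name: str) -> bytes | None:
        if name not in self._names:
            return None
        try:
            return self._zf.read(name)
        except (zipfile.BadZipFile, OSError) as e:
            raise CorruptArchiveError(f"{name}: {e}") from e

    def read_bin(self, chrom: str, bin_index: int) -> BinData:
        """Load one bin; an absent (chrom, bin) yields an empty BinData."""
        self.bin_reads += 1
        base = _bin_dir(normalize_chrom(chrom), bin_index)
        raw = self._read_entry(f"{base}/var32.bin")
        if raw is None:
            return BinData()
        try:
            deltas = int_codec.decode_u32_block(raw)
        except CorruptArchiveError as e:
            raise CorruptArchiveError(f"{base}/var32.bin: {e}") from None
        var32 = int_codec.prefix_sum(deltas).tolist()
        longs_raw = self._read_entry(f"{base}/long.bin")
        longs = _longs_from_bytes(longs_raw, f"{base}/long.bin") if longs_raw else []
        columns: dict[str, list[int]] = {}
        for cfg in self.configs:
            entry = f"{base}/fields/{cfg.alias}.bin"
            col_raw = self._read_entry(entry)
            if col_raw is None:
                raise CorruptArchiveError(f"missing field column {entry}")
            try:
                zz = int_codec.decode_u32_block(col_raw)
            except CorruptArchiveError as e:
                raise CorruptArchiveError(f"{entry}: {e}") from None
            columns[cfg.alias] = int_codec.unzigzag(zz).tolist()
        data = BinData(var32=var32, longs=longs, columns=columns)
        data.validate()
        return data

    def bins(self) -> list[tuple[str, int]]:
        """(chrom, bin_index) pairs in archive order."""
        out = []
        for name in self._zf.namelist():
            parts = name.split("/")
            if len(parts) == 4 and parts[0] == PATH_PREFIX and parts[3] == "var32.bin":
                out.append((parts[1], int(parts[2])))
        return out

    def close(self) -> None:
        self._zf.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def validate_archive(path, verbose: bool = False) -> dict:
    """Check every bin's invariants; return per-archive statistics."""
    stats = {"bins": 0, "variants": 0, "longs": 0, "chromosomes": set()}
    lines = []
    with ArchiveReader(path) as reader:
        for chrom, bin_index in reader.bins():
            data = reader.read_bin(chrom, bin_index)  # validates internally
            stats["bins"] += 1
            stats["variants"] += len(data.var32)
            stats["longs"] += len(data.longs)
            stats["chromosomes"].add(chrom)
            if verbose:
                lines.append(
                    f"{chrom}\t{bin_index}\t{len(data.var32)} variants\t"
                    f"{len(data.longs)} long"
                )
    stats["chromosomes"] = sorted(stats["chromosomes"])
    stats["per_bin"] = lines
    return stats


def rewrite_archive(src_path, dst_path) -> None:
    """Re-serialize an archive bin by bin (round-trip / stability checks)."""
    with ArchiveReader(src_path) as reader:
        string_aliases = [
            c.alias for c in reader.configs if c.ftype == "string"
        ]
        with ArchiveWriter(dst_path, reader.configs) as writer:
            for chrom, bin_index in reader.bins():
                writer.write_bin(chrom, bin_index, reader.read_bin(chrom, bin_index))
            for alias in string_aliases:
                writer.write_strings(alias, reader.read_strings(alias))
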