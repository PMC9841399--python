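"""32-bit encoding of small variants and genome binning.

Each chromosome is partitioned into bins of 2^20 bases.  Within a bin, a
variant whose combined REF+ALT length is at most 4 bases (over the plain
nucleotide alphabet A/C/G/T) is packed into one unsigned 32-bit integer:

    bits 31-12   0-based offset of the variant inside its bin (20 bits)
    bits 11-10   REF length, 1-3 (0 is reserved for placeholders)
    bits  9-8    ALT length, 1-3 (0 is reserved for placeholders)
    bits  7-0    the REF then ALT nucleotides, 2 bits each (A=0 C=1 G=2 T=3),
                 first nucleotide in bits 7-6, unused pairs zero

This layout makes unsigned-integer order agree with positional order inside a
bin, and makes a placeholder (all twelve allele bits zero) sort before every
real variant at the same offset.  Variants that do not fit — total allele
length above 4, or any non-ACGT character such as N — are kept verbatim in a
supplemental per-bin table as :class:`LongVariantRecord`, with a placeholder
code holding their slot (and hence their field-column index) in the primary
table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    EncodingDomainError,
    InvalidPositionError,
    PlaceholderDecodeError,
)

BIN_SHIFT = 20
BIN_SIZE = 1 << BIN_SHIFT  # 1 048 576 bases per bin
MAX_SHORT_TOTAL_LEN = 4

NUCLEOTIDE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_NUC_LETTERS = "ACGT"
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class EncodingParams:
    """The fixed constants of the 32-bit code, exposed for introspection."""

    bin_shift: int = BIN_SHIFT
    bin_size: int = BIN_SIZE
    max_short_total_len: int = MAX_SHORT_TOTAL_LEN


def is_short(ref: str, alt: str) -> bool:
    """True iff the REF/ALT pair fits the 32-bit code.

    Requires combined length <= 4 and every character in {A,C,G,T}.
    Alleles must already be uppercased and non-empty.
    """
    if len(ref) + len(alt) > MAX_SHORT_TOTAL_LEN:
        return False
    return _ACGT.issuperset(ref) and _ACGT.issuperset(alt)


def bin_of(pos1: int) -> tuple[int, int]:
    """Map a 1-based VCF POS to (bin_index, 0-based offset within the bin)."""
    if pos1 < 1:
        raise InvalidPositionError(f"VCF POS must be >= 1, got {pos1}")
    pos0 = pos1 - 1
    return pos0 >> BIN_SHIFT, pos0 & (BIN_SIZE - 1)


def encode32(offset: int, ref: str, alt: str) -> int:
    """Pack (offset, ref, alt) into one unsigned 32-bit code."""
    if not 0 <= offset < BIN_SIZE:
        raise InvalidPositionError(f"in-bin offset out of range: {offset}")
    if not (ref and alt and is_short(ref, alt)):
        raise EncodingDomainError(
            f"alleles do not fit a 32-bit code: REF={ref!r} ALT={alt!r}"
        )
    value = (offset << 12) | (len(ref) << 10) | (len(alt) << 8)
    shift = 6
    for ch in ref + alt:
        value |= NUCLEOTIDE_CODES[ch] << shift
        shift -= 2
    return value


def decode32(code: int) -> tuple[int, str, str]:
    """Invert :func:`encode32`.

    Annotation never needs this (archived variants stay as integers); it
    exists for tests, debugging and the archive validator.
    """
    ref_len = (code >> 10) & 0x3
    alt_len = (code >> 8) & 0x3
    if ref_len == 0 or alt_len == 0:
        raise PlaceholderDecodeError(f"code {code} is a placeholder, not a variant")
    if ref_len + alt_len > MAX_SHORT_TOTAL_LEN:
        raise EncodingDomainError(f"code {code} has impossible allele lengths")
    nucs = [_NUC_LETTERS[(code >> (6 - 2 * i)) & 0x3] for i in range(ref_len + alt_len)]
    return code >> 12, "".join(nucs[:ref_len]), "".join(nucs[ref_len:])


def placeholder32(offset: int) -> int:
    """Code marking a long variant's slot in the primary table: offset only."""
    if not 0 <= offset < BIN_SIZE:
        raise InvalidPositionError(f"in-bin offset out of range: {offset}")
    return offset << 12


def is_placeholder(code: int) -> bool:
    return (code & 0xFFF) == 0


@dataclass(frozen=True)
class LongVariantRecord:
    """A variant stored verbatim because it does not fit in 32 bits.

    ``field_index`` points at the slot its placeholder occupies in the bin's
    primary table, which is also its row in every field column.
    """

    offset: int
    ref: str
    alt: str
    field_index: int

    @property
    def sort_key(self) -> tuple[int, str, str]:
        # field_index intentionally excluded: binary search keys on the
        # variant identity only.
        return (self.offset, self.ref, self.alt)
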