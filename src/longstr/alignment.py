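"""SAM alignment model and exact CIGAR coordinate walking.

All internal coordinates are 0-based half-open; the 1-based SAM POS is
converted on parse. Haplotype labels come from integer phasing tags
(``HP`` by convention, as written by longshot/whatshap): value 1 or 2,
anything else (or no tag) is treated as unphased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

UNPHASED = 0  #: haplotype label for reads without a usable phasing tag

# CIGAR op classes (SAM spec): which coordinate each op consumes
_CONSUMES_READ = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")
_VALID_OPS = frozenset("MIDNSHP=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class SamParseError(ValueError):
    """A SAM record that cannot be used, with the offending field named."""


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: a code and a length in bases."""

    code: str
    length: int

    def __post_init__(self) -> None:
        if self.code not in _VALID_OPS:
            raise SamParseError(f"invalid CIGAR op code {self.code!r}")
        if self.length < 1:
            raise SamParseError(f"CIGAR op length must be >= 1, got {self.length}")

    @property
    def consumes_read(self) -> bool:
        return self.code in _CONSUMES_READ

    @property
    def consumes_ref(self) -> bool:
        return self.code in _CONSUMES_REF


@dataclass
class AlignedRead:
    """One mapped long read: reference anchor, CIGAR, sequence, haplotype."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based
    strand: str  # '+' or '-'
    cigar: list[CigarOp]
    sequence: str  # as stored in SAM, i.e. reference orientation
    haplotype: int = UNPHASED  # 1, 2, or UNPHASED
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise SamParseError(f"negative ref_start {self.ref_start}")
        if not self.ref_name:
            raise SamParseError("empty ref_name")
        read_len = sum(op.length for op in self.cigar if op.consumes_read)
        if read_len != len(self.sequence):
            raise SamParseError(
                f"CIGAR consumes {read_len} read bases but SEQ has "
                f"{len(self.sequence)} (read {self.read_id})"
            )

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned span on the reference."""
        return self.ref_start + sum(op.length for op in self.cigar if op.consumes_ref)

    @property
    def read_length(self) -> int:
        return len(self.sequence)


def parse_cigar(text: str) -> list[CigarOp]:
    if text == "*" or not text:
        raise SamParseError("CIGAR is '*' (alignment without CIGAR is unusable)")
    ops = [CigarOp(code, int(length)) for length, code in _CIGAR_RE.findall(text)]
    if sum(op.length for op in ops) != sum(
        int(n) for n in re.findall(r"\d+", text)
    ) or "".join(f"{o.length}{o.code}" for o in ops) != text:
        raise SamParseError(f"malformed CIGAR string {text!r}")
    # internal soft clips are invalid SAM: S may only touch the read ends
    # (possibly through an H)
    inner = [op.code for op in ops]
    while inner and inner[0] in "HS":
        inner.pop(0)
    while inner and inner[-1] in "HS":
        inner.pop()
    if "S" in inner or "H" in inner:
        raise SamParseError(f"internal clip in CIGAR {text!r}")
    return ops


def parse_sam_record(line: str, haplotype_tag_name: str = "HP") -> AlignedRead:
    """Parse one SAM alignment line into an :class:`AlignedRead`.

    The haplotype tag (integer-valued optional tag, default ``HP``) is
    mapped to 1/2; absent or out-of-range values give an unphased read.
    Unmapped records (flag 0x4) are rejected.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(f"SAM record has {len(fields)} fields, expected >= 11")
    qname, flag_s, rname, pos_s, mapq_s, cigar_s = fields[0:6]
    seq = fields[9]
    try:
        flag = int(flag_s)
    except ValueError:
        raise SamParseError(f"non-numeric FLAG {flag_s!r}") from None
    if flag & 0x4:
        raise SamParseError(f"unmapped read {qname}")
    try:
        pos = int(pos_s)
    except ValueError:
        raise SamParseError(f"non-numeric POS {pos_s!r}") from None
    try:
        mapq = int(mapq_s)
    except ValueError:
        raise SamParseError(f"non-numeric MAPQ {mapq_s!r}") from None
    if seq == "*" or not seq:
        raise SamParseError(f"SEQ is '*' for read {qname} (sequence required)")
    cigar = parse_cigar(cigar_s)

    haplotype = UNPHASED
    prefix = f"{haplotype_tag_name}:i:"
    for tag in fields[11:]:
        if tag.startswith(prefix):
            try:
                value = int(tag[len(prefix):])
            except ValueError:
                raise SamParseError(f"non-integer {haplotype_tag_name} tag {tag!r}") from None
            if value in (1, 2):
                haplotype = value
            break

    return AlignedRead(
        read_id=qname,
        ref_name=rname,
        ref_start=pos - 1,
        strand="-" if flag & 0x10 else "+",
        cigar=cigar,
        sequence=seq.upper(),
        haplotype=haplotype,
        mapq=mapq,
    )


def cigar_walk(read: AlignedRead) -> Iterator[tuple[CigarOp, int, int]]:
    """Yield each CIGAR op with the (ref_pos, read_pos) at which it begins.

    M/=/X advance both coordinates, I/S advance the read only, D/N the
    reference only; H and P advance neither.
    """
    ref_pos = read.ref_start
    read_pos = 0
    for op in read.cigar:
        yield op, ref_pos, read_pos
        if op.consumes_ref:
            ref_pos += op.length
        if op.consumes_read:
            read_pos += op.length


def iter_sam_lines(lines: Iterable[str]) -> Iterator[str]:
    """Yield alignment lines from a SAM stream, skipping headers/blanks."""
    for line in lines:
        if line.startswith("@") or not line.strip():
            continue
        yield line


def read_alignments(
    path: str,
    haplotype_tag_name: str = "HP",
    min_mapq: int = 1,
    skip_unusable: bool = True,
) -> Iterator[AlignedRead]:
    """Iterate mapped reads from a SAM text file (or BAM, via pysam).

    Reads below ``min_mapq`` are dropped (ambiguous mappings generate
    spurious clips). When ``skip_unusable`` is set, unmapped/secondary
    records and records without sequence are silently skipped instead of
    raising.
    """
    if path.endswith(".bam"):
        yield from _read_bam(path, haplotype_tag_name, min_mapq)
        return
    with open(path) as fh:
        for line in iter_sam_lines(fh):
            try:
                read = parse_sam_record(line, haplotype_tag_name)
            except SamParseError:
                if skip_unusable:
                    continue
                raise
            if read.mapq >= min_mapq:
                yield read


def _read_bam(path: str, haplotype_tag_name: str, min_mapq: int) -> Iterator[AlignedRead]:
    # adapter over pysam so binary input works; all core logic stays on the
    # text model above
    import pysam

    with pysam.AlignmentFile(path, "rb") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.query_sequence is None:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            hap = UNPHASED
            if rec.has_tag(haplotype_tag_name):
                value = rec.get_tag(haplotype_tag_name)
                if value in (1, 2):
                    hap = int(value)
            cigar = [CigarOp("MIDNSHP=X"[code], length) for code, length in rec.cigartuples]
            yield AlignedRead(
                read_id=rec.query_name,
                ref_name=rec.reference_name,
                ref_start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar,
                sequence=rec.query_sequence.upper(),
                haplotype=hap,
                mapq=rec.mapping_quality,
            )
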