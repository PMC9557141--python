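"""Scan read CIGARs for large insertions and soft-clips.

An expanded STR allele carries sequence absent from the reference; in an
alignment this shows up either as an insertion op in the middle of a read
or as a soft-clipped read end when the aligner gives up anchoring through
the expansion. Any such event longer than a threshold (strictly greater
than ``min_event_len`` bases) becomes a candidate, extracted together with
up to ``flank`` bases of adjacent read sequence on each available side.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import AlignedRead, cigar_walk

INSERTION = "insertion"
LEFT_CLIP = "left_clip"
RIGHT_CLIP = "right_clip"


@dataclass
class CandidateEvent:
    """One insertion or terminal soft-clip that may indicate an expansion."""

    read_id: str
    ref_name: str
    haplotype: int
    anchor: int  # 0-based reference bp: insertion point or clip attachment
    kind: str  # insertion | left_clip | right_clip
    event_seq: str
    flank_left: str  # <= flank bp of read sequence preceding the event
    flank_right: str  # <= flank bp following the event

    @property
    def length(self) -> int:
        return len(self.event_seq)


def detect_candidates(
    read: AlignedRead, min_event_len: int = 15, flank: int = 50
) -> list[CandidateEvent]:
    """Return one event per I op or terminal S op with length > min_event_len.

    The threshold is strict: a 16 bp insertion qualifies at the default, a
    15 bp one does not. Hard clips carry no sequence and are ignored.
    Flanks are truncated at the read boundaries; a left clip has no left
    flank and a right clip no right flank by construction.
    """
    events: list[CandidateEvent] = []
    seq = read.sequence
    ref_end = read.ref_end
    for op, ref_pos, read_pos in cigar_walk(read):
        if op.code == "I" and op.length > min_event_len:
            start, end = read_pos, read_pos + op.length
            events.append(
                CandidateEvent(
                    read_id=read.read_id,
                    ref_name=read.ref_name,
                    haplotype=read.haplotype,
                    anchor=ref_pos,
                    kind=INSERTION,
                    event_seq=seq[start:end],
                    flank_left=seq[max(0, start - flank):start],
                    flank_right=seq[end:end + flank],
                )
            )
        elif op.code == "S" and op.length > min_event_len:
            if read_pos == 0:  # leading clip: attaches at the read's ref start
                end = op.length
                events.append(
                    CandidateEvent(
                        read_id=read.read_id,
                        ref_name=read.ref_name,
                        haplotype=read.haplotype,
                        anchor=read.ref_start,
                        kind=LEFT_CLIP,
                        event_seq=seq[:end],
                        flank_left="",
                        flank_right=seq[end:end + flank],
                    )
                )
            else:  # trailing clip: attaches at the read's ref end
                start = read_pos
                events.append(
                    CandidateEvent(
                        read_id=read.read_id,
                        ref_name=read.ref_name,
                        haplotype=read.haplotype,
                        anchor=ref_end,
                        kind=RIGHT_CLIP,
                        event_seq=seq[start:start + op.length],
                        flank_left=seq[max(0, start - flank):start],
                        flank_right="",
                    )
                )
    return events
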