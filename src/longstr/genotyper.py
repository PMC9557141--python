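"""End-to-end STR genotyping over an alignment file.

Pipeline: parse reads -> detect large insertions/soft-clips -> cluster
per haplotype within 50 bp -> filter by read support -> POA consensus of
each cluster's event sequences (with flanks attached) -> trim flanks ->
tandem-repeat calling on the trimmed consensus -> one per-haplotype
genotype row per surviving cluster, written as a tab-separated table.
Deterministic given inputs and parameters.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .alignment import UNPHASED, AlignedRead, read_alignments
from .candidates import detect_candidates
from .clustering import EventCluster, cluster_events, filter_clusters
from .poa import PoaScores, build_graph, consensus
from .repeats import RepeatCall, find_repeats

NON_REPETITIVE = "non_repetitive"
REPEAT = "repeat"

_TSV_COLUMNS = [
    "ref_name", "position", "haplotype", "motif", "copies",
    "consensus_length", "support", "mismatch_fraction", "status",
]


@dataclass(frozen=True)
class DetectParams:
    """All detector knobs with the documented defaults."""

    haplotype_tag_name: str = "HP"
    min_mapq: int = 1
    min_event_len: int = 15  # strict: events must exceed this length
    flank: int = 50
    max_gap: int = 50
    min_support: int = 3
    period_range: tuple[int, int] = (2, 6)
    resolution: float = 0.1
    min_copies: float = 3.0
    min_span: int = 12
    scores: PoaScores = field(default_factory=PoaScores)
    rescue_unphased: bool = False  # copy unphased events into both haplotypes


@dataclass
class StrGenotype:
    """One per-haplotype STR genotype row."""

    ref_name: str
    position: int  # cluster anchor midpoint, 0-based
    haplotype: int  # 1, 2, or 0 (unphased)
    motif: str  # canonical, or "." when non-repetitive
    copies: Optional[float]
    consensus_length: int
    support: int
    mismatch_fraction: Optional[float]
    status: str  # repeat | non_repetitive


def genotype(
    alignments: str | Iterable[AlignedRead],
    reference: Optional[dict[str, str]] = None,
    regions: Optional[list[tuple[str, int, int]]] = None,
    params: DetectParams = DetectParams(),
) -> list[StrGenotype]:
    """Genotype STR expansions genome-wide or in user-specified regions.

    ``alignments`` is a SAM/BAM path or an iterable of parsed reads;
    ``reference`` (name -> sequence), when given, sharpens flank trimming
    of each cluster consensus; ``regions`` restricts processing to reads
    overlapping the listed 0-based half-open intervals.
    """
    if isinstance(alignments, str):
        reads: Iterable[AlignedRead] = read_alignments(
            alignments,
            haplotype_tag_name=params.haplotype_tag_name,
            min_mapq=params.min_mapq,
        )
    else:
        reads = (r for r in alignments if r.mapq >= params.min_mapq)

    events = []
    for read in reads:
        if regions is not None and not _overlaps_any(read, regions):
            continue
        events.extend(
            detect_candidates(read, params.min_event_len, params.flank)
        )
    if params.rescue_unphased:
        for ev in [e for e in events if e.haplotype == UNPHASED]:
            events.append(replace(ev, haplotype=1))
            events.append(replace(ev, haplotype=2))

    clusters = filter_clusters(
        cluster_events(events, params.max_gap), params.min_support
    )
    genotypes = [genotype_cluster(c, reference, params) for c in clusters]
    if regions is not None:
        # long reads overlapping a target also span far-away loci; report
        # only the calls whose locus lies inside a requested interval
        genotypes = [
            g for g in genotypes
            if any(
                g.ref_name == chrom and start <= g.position < end
                for chrom, start, end in regions
            )
        ]
    return genotypes


def _overlaps_any(read: AlignedRead, regions: list[tuple[str, int, int]]) -> bool:
    return any(
        read.ref_name == chrom and read.ref_start < end and read.ref_end > start
        for chrom, start, end in regions
    )


def genotype_cluster(
    cluster: EventCluster,
    reference: Optional[dict[str, str]],
    params: DetectParams,
) -> StrGenotype:
    """Consensus, flank trimming and repeat calling for one cluster."""
    ordered = sorted(
        cluster.events, key=lambda e: e.read_id
    )  # stable read-id tie-break under build_graph's length sort
    seqs = [e.flank_left + e.event_seq + e.flank_right for e in ordered]
    cons = consensus(build_graph(seqs, params.scores))
    trimmed = trim_flanks(cons.sequence, cluster, reference, params.flank)
    calls = find_repeats(
        trimmed,
        period_range=params.period_range,
        resolution=params.resolution,
        min_copies=params.min_copies,
        min_span=params.min_span,
    )
    best = _best_call(calls)
    if best is None:
        return StrGenotype(
            ref_name=cluster.ref_name,
            position=cluster.position,
            haplotype=cluster.haplotype,
            motif=".",
            copies=None,
            consensus_length=len(trimmed),
            support=cluster.support,
            mismatch_fraction=None,
            status=NON_REPETITIVE,
        )
    return StrGenotype(
        ref_name=cluster.ref_name,
        position=cluster.position,
        haplotype=cluster.haplotype,
        motif=best.motif,
        copies=best.copies,
        consensus_length=len(trimmed),
        support=cluster.support,
        mismatch_fraction=best.mismatch_fraction,
        status=REPEAT,
    )


def _best_call(calls: list[RepeatCall]) -> Optional[RepeatCall]:
    """The reported repeat: widest span, then cleanest, then smallest period."""
    if not calls:
        return None
    return max(
        calls,
        key=lambda c: (c.end - c.start, -c.mismatch_fraction, -c.period, -c.start),
    )


def trim_flanks(
    cons_seq: str,
    cluster: EventCluster,
    reference: Optional[dict[str, str]],
    flank: int,
) -> str:
    """Strip the attached flanks so only the expansion sequence remains.

    The preferred cut is an exact match of the consensus ends against the
    reference flanks around the cluster anchors; when no reference is at
    hand, or residual consensus error breaks the exact match, the median
    per-event flank length is trimmed instead.
    """
    left_lens = [len(e.flank_left) for e in cluster.events]
    right_lens = [len(e.flank_right) for e in cluster.events]
    left_cut = int(statistics.median(left_lens)) if left_lens else 0
    right_cut = int(statistics.median(right_lens)) if right_lens else 0

    if reference is not None and cluster.ref_name in reference:
        ref = reference[cluster.ref_name]
        k_full = min(flank, cluster.anchor_min, len(cons_seq))
        ref_left = ref[cluster.anchor_min - k_full:cluster.anchor_min]
        for k in (k_full, left_cut):
            if 0 < k <= len(cons_seq) and cons_seq[:k] == ref_left[len(ref_left) - k:]:
                left_cut = k
                break
        k_full = min(flank, len(ref) - cluster.anchor_max, len(cons_seq))
        ref_right = ref[cluster.anchor_max:cluster.anchor_max + k_full]
        for k in (k_full, right_cut):
            if 0 < k <= len(cons_seq) and cons_seq[len(cons_seq) - k:] == ref_right[:k]:
                right_cut = k
                break
    left_cut = min(left_cut, len(cons_seq))
    right_cut = min(right_cut, max(0, len(cons_seq) - left_cut))
    return cons_seq[left_cut:len(cons_seq) - right_cut]


# ---------------------------------------------------------------------------
# TSV output


def _format_row(g: StrGenotype) -> str:
    hap = {1: "1", 2: "2"}.get(g.haplotype, "unphased")
    copies = "NA" if g.copies is None else f"{g.copies:.3f}"
    mism = "NA" if g.mismatch_fraction is None else f"{g.mismatch_fraction:.4f}"
    return "\t".join(
        [
            g.ref_name, str(g.position), hap, g.motif, copies,
            str(g.consensus_length), str(g.support), mism, g.status,
        ]
    )


def write_genotypes_tsv(genotypes: list[StrGenotype], path: str) -> None:
    """Header + one row per genotype; '.'/'NA' conventions, LF endings."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for g in genotypes:
            fh.write(_format_row(g) + "\n")


def read_genotypes_tsv(path: str) -> list[StrGenotype]:
    out: list[StrGenotype] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"unexpected genotype TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                StrGenotype(
                    ref_name=f[0],
                    position=int(f[1]),
                    haplotype={"1": 1, "2": 2}.get(f[2], UNPHASED),
                    motif=f[3],
                    copies=None if f[4] == "NA" else float(f[4]),
                    consensus_length=int(f[5]),
                    support=int(f[6]),
                    mismatch_fraction=None if f[7] == "NA" else float(f[7]),
                    status=f[8],
                )
            )
    return out


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Minimal BED reader: chrom, start, end (0-based half-open)."""
    regions: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            regions.append((f[0], int(f[1]), int(f[2])))
    return regions
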