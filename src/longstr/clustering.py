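"""Combine candidate events per haplotype when found close by across reads.

Events on the same reference and haplotype whose anchors chain within
``max_gap`` bases (single linkage: each consecutive gap, not the cluster
diameter) are merged into one cluster; clusters supported by too few
distinct reads are filtered out before consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from .candidates import CandidateEvent


@dataclass
class EventCluster:
    """Co-located candidate events on one reference/haplotype."""

    ref_name: str
    haplotype: int
    anchor_min: int
    anchor_max: int
    events: list[CandidateEvent] = field(default_factory=list)

    @property
    def support(self) -> int:
        """Number of distinct reads contributing events."""
        return len({e.read_id for e in self.events})

    @property
    def position(self) -> int:
        """Reported locus coordinate: midpoint of the anchor range."""
        return (self.anchor_min + self.anchor_max) // 2


def cluster_events(
    events: list[CandidateEvent], max_gap: int = 50
) -> list[EventCluster]:
    """Single-linkage clustering of events by anchor within (ref, haplotype).

    Consecutive anchor gaps <= max_gap join one cluster, so 100 and 149
    co-cluster at the default while 100 and 151 do not. Insertions and
    clips co-cluster freely — both signal the same expansion. The result
    is independent of input order and partitions the input exactly.
    """
    clusters: list[EventCluster] = []
    keyed = sorted(events, key=lambda e: (e.ref_name, e.haplotype, e.anchor, e.read_id))
    for (ref_name, hap), group in groupby(keyed, key=lambda e: (e.ref_name, e.haplotype)):
        current: list[CandidateEvent] = []
        for ev in group:
            if current and ev.anchor - current[-1].anchor > max_gap:
                clusters.append(_make_cluster(ref_name, hap, current))
                current = []
            current.append(ev)
        if current:
            clusters.append(_make_cluster(ref_name, hap, current))
    clusters.sort(key=lambda c: (c.ref_name, c.anchor_min, c.haplotype))
    return clusters


def _make_cluster(ref_name: str, hap: int, events: list[CandidateEvent]) -> EventCluster:
    anchors = [e.anchor for e in events]
    return EventCluster(
        ref_name=ref_name,
        haplotype=hap,
        anchor_min=min(anchors),
        anchor_max=max(anchors),
        events=list(events),
    )


def filter_clusters(
    clusters: list[EventCluster], min_support: int = 3
) -> list[EventCluster]:
    """Keep clusters supported by at least ``min_support`` distinct reads."""
    return [c for c in clusters if c.support >= min_support]
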