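"""Approximate tandem-periodicity detection in consensus sequences.

A window [start, end) of the query is an acceptable repeat of period p
when the minimal number of substitutions that would make it exactly
p-periodic — window length minus the sum over the p alignment columns of
the majority base count — divided by the number of vertically compared
positions (window length − p), is at most ``resolution``. Candidate
windows are maximal (not strictly contained in another acceptable window
of the same period), and must satisfy the span and copy-number floors.
Overlapping calls of different periods are reduced to one call per
overlapping group, preferring the lowest mismatch fraction, then the
smallest period, then the leftmost start.

``brute_force_repeats`` re-derives the same calls by literal enumeration
of every (start, end, period) triple and serves as the testing oracle for
the windowed implementation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

DEFAULT_PERIOD_RANGE = (2, 6)  # STR motifs are 2-6 bp
DEFAULT_RESOLUTION = 0.1
DEFAULT_MIN_COPIES = 3.0
DEFAULT_MIN_SPAN = 12
_ORACLE_MAX_LEN = 64


@dataclass
class RepeatCall:
    """A detected tandem repetition within a query sequence."""

    start: int  # 0-based half-open offsets into the query
    end: int
    period: int
    motif: str  # canonical (smallest rotation of the primitive unit)
    copies: float  # (end - start) / period
    mismatch_fraction: float

    def overlaps(self, other: "RepeatCall") -> bool:
        return self.start < other.end and other.start < self.end


def canonical_motif(unit: str) -> str:
    """Smallest rotation of the primitive (non-self-repeating) unit.

    "CAG" -> "AGC"; "ATAT" collapses to its primitive period first,
    giving "AT".
    """
    if not unit:
        raise ValueError("empty repeat unit")
    # reduce to the smallest primitive period
    for d in range(1, len(unit) + 1):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            unit = unit[:d]
            break
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _window_mismatches(seq: str, start: int, end: int, period: int) -> int:
    """Substitutions needed to make seq[start:end] exactly period-periodic."""
    total = 0
    for col in range(period):
        counts = Counter(seq[i] for i in range(start + col, end, period))
        total += sum(counts.values()) - max(counts.values())
    return total


def _window_motif(seq: str, start: int, end: int, period: int) -> str:
    """Canonical rotation of the most frequent whole p-frame in the window."""
    frames = Counter(
        seq[i:i + period] for i in range(start, end - period + 1, period)
    )
    top = max(frames.values())
    unit = min(f for f, n in frames.items() if n == top)  # deterministic tie
    return canonical_motif(unit)


def _resolve_overlaps(calls: list[RepeatCall]) -> list[RepeatCall]:
    """One winner per group of transitively-overlapping calls."""
    if not calls:
        return []
    calls = sorted(calls, key=lambda c: (c.start, c.end, c.period))
    groups: list[list[RepeatCall]] = [[calls[0]]]
    frontier = calls[0].end
    for call in calls[1:]:
        if call.start < frontier:
            groups[-1].append(call)
        else:
            groups.append([call])
            frontier = call.end
        frontier = max(frontier, call.end)
    winners = [
        min(g, key=lambda c: (c.mismatch_fraction, c.period, c.start, c.end))
        for g in groups
    ]
    winners.sort(key=lambda c: c.start)
    return winners


def find_repeats(
    seq: str,
    period_range: tuple[int, int] = DEFAULT_PERIOD_RANGE,
    resolution: float = DEFAULT_RESOLUTION,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[RepeatCall]:
    """Find maximal approximate tandem repeats of periods in ``period_range``.

    Sequences shorter than ``min_span`` yield no calls. Per period the
    acceptable windows are found with an incremental per-column count
    sweep (O(L^2) per period); maximality and cross-period overlap
    resolution then apply as described in the module docstring.
    """
    lo, hi = period_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid period range {period_range}")
    n = len(seq)
    if n < min_span:
        return []

    calls: list[RepeatCall] = []
    for p in range(lo, min(hi, n - 1) + 1):
        # per start: the largest acceptable end and its mismatch count
        per_start: list[tuple[int, int, int]] = []
        for s in range(0, n - p):
            # incremental column counts while extending the window end
            col_counts = [Counter() for _ in range(p)]
            col_max = [0] * p
            matched = 0  # sum of per-column majority counts
            best_e = -1
            best_mism = 0
            for e in range(s + 1, n + 1):
                pos = e - 1
                col = (pos - s) % p
                c = col_counts[col]
                c[seq[pos]] += 1
                if c[seq[pos]] > col_max[col]:
                    matched += c[seq[pos]] - col_max[col]
                    col_max[col] = c[seq[pos]]
                span = e - s
                if span <= p:
                    continue
                mism = span - matched
                if mism <= resolution * (span - p):
                    best_e, best_mism = e, mism
            if best_e >= 0:
                per_start.append((s, best_e, best_mism))
        # a window is maximal iff its end exceeds every acceptable end
        # starting earlier (any smaller-end window from the same start is
        # contained in the per-start largest one)
        frontier = -1
        for s, e, mism in per_start:
            if e <= frontier:
                continue
            frontier = e
            call = _make_call(seq, s, e, p, mism, min_copies, min_span)
            if call is not None:
                calls.append(call)
    return _resolve_overlaps(calls)


def _make_call(
    seq: str,
    s: int,
    e: int,
    period: int,
    mismatches: int,
    min_copies: float,
    min_span: int,
) -> RepeatCall | None:
    """Apply the span and copy-number floors; build the call record."""
    span = e - s
    if span < min_span or span / period < min_copies:
        return None
    return RepeatCall(
        start=s,
        end=e,
        period=period,
        motif=_window_motif(seq, s, e, period),
        copies=span / period,
        mismatch_fraction=mismatches / (span - period),
    )


def brute_force_repeats(
    seq: str,
    period_range: tuple[int, int] = DEFAULT_PERIOD_RANGE,
    resolution: float = DEFAULT_RESOLUTION,
    min_copies: float = DEFAULT_MIN_COPIES,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[RepeatCall]:
    """Exhaustive oracle: enumerate every (start, end, period) triple.

    Applies acceptance rules identical to :func:`find_repeats` but with no
    sweeping shortcuts; restricted to sequences of at most 64 bp.
    """
    if len(seq) > _ORACLE_MAX_LEN:
        raise ValueError(f"oracle limited to {_ORACLE_MAX_LEN} bp, got {len(seq)}")
    lo, hi = period_range
    n = len(seq)
    if n < min_span:
        return []
    calls: list[RepeatCall] = []
    for p in range(lo, hi + 1):
        accepted = []
        for s in range(n):
            for e in range(s + p + 1, n + 1):
                mism = _window_mismatches(seq, s, e, p)
                if mism <= resolution * (e - s - p):
                    accepted.append((s, e, mism))
        # literal maximality: drop any window strictly contained in
        # another acceptable window of the same period
        for s, e, mism in accepted:
            if any(
                s2 <= s and e <= e2 and (s2, e2) != (s, e) for s2, e2, _ in accepted
            ):
                continue
            call = _make_call(seq, s, e, p, mism, min_copies, min_span)
            if call is not None:
                calls.append(call)
    return _resolve_overlaps(calls)
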