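"""STR-expansion simulator with truth alignments.

The simulator turns a reference FASTA plus a BED of STR loci into two
mutated haplotype sequences (whole motif copies appended to — or removed
from — the 3' end of each tandem array, plus background SNVs at a fixed
per-base rate), draws error-bearing long reads from each haplotype, and
emits *truth alignments*: SAM records whose position and CIGAR are
composed from the known per-read error script and the known
haplotype-to-reference edit map, rather than inferred by a mapper. This
makes the whole detector testable end to end with no external aligner,
and gives an exact truth table to score against.

All randomness flows from one ``numpy`` generator seeded in the config;
draws are ordered deterministically (haplotype 1 then 2, loci in
coordinate order, reads in generation order), so a fixed seed reproduces
every output byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class StrLocusSpec:
    """One tandem-repeat locus on the reference (0-based half-open)."""

    ref_name: str
    start: int
    end: int
    motif: str
    ref_copies: float

    def __post_init__(self) -> None:
        if not (2 <= len(self.motif) <= 6):
            raise ValueError(f"motif length {len(self.motif)} outside 2-6 bp")
        if self.end - self.start != round(self.ref_copies * len(self.motif)):
            raise ValueError(
                f"locus span {self.end - self.start} != "
                f"{self.ref_copies} x {len(self.motif)}"
            )


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base i.i.d. substitution/insertion/deletion probabilities."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


#: error-free reads (truth-alignment debugging, exact-recovery tests)
PERFECT = ErrorProfile(0.0, 0.0, 0.0)
#: Oxford-Nanopore-like raw error, pre-consensus
ONT_LIKE = ErrorProfile(0.05, 0.05, 0.05)
#: PacBio HiFi-like error
HIFI_LIKE = ErrorProfile(0.004, 0.003, 0.003)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the defaults are the tested study conditions."""

    delta_range: tuple[int, int] = (6, 20)  # uniform copy-number change
    snv_rate: float = 0.001  # per-base background SNV probability
    coverage: float = 20.0  # mean reads per haplotype base
    read_length_mean: float = 8000.0  # log-normal mean (bp)
    read_length_sigma: float = 0.25  # log-normal shape
    error_profile: ErrorProfile = PERFECT
    snv_in_loci: bool = False  # keep truth motifs clean by default
    base_quality: int = 30  # constant Phred for FASTQ
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.snv_rate, *vars(self.error_profile).values()):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one (locus, haplotype)."""

    locus_id: str
    ref_name: str
    start: int
    end: int
    haplotype: int  # 1 or 2
    motif: str
    sim_copies: float
    delta_copies: float
    expanded_length: int  # signed bp change

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class EditMap:
    """Haplotype <-> reference liftover as ordered diagonal blocks.

    Blocks are (ref_start, hap_start, length) runs of 1:1 correspondence;
    the gaps between consecutive blocks are insertions (haplotype-only
    bases, i.e. appended motif copies) and/or deletions (reference-only
    bases, i.e. removed copies). Outside edited intervals the mapping is
    bijective.
    """

    def __init__(self, blocks: list[tuple[int, int, int]], hap_length: int):
        self.blocks = blocks
        self.hap_length = hap_length

    def project(self, a: int, b: int) -> tuple[int, list[tuple[str, int]]]:
        """Alignment of haplotype interval [a, b) onto the reference.

        Returns (ref_anchor, ops): ops are (code, length) with code M
        (diagonal), I (haplotype-only) or D (reference-only), in
        haplotype order; ref_anchor is the reference coordinate at which
        the first op begins (for a leading I, the position the insertion
        attaches to).
        """
        if not 0 <= a < b <= self.hap_length:
            raise ValueError(f"interval [{a},{b}) outside haplotype")
        ops: list[tuple[str, int]] = []
        ref_anchor: int | None = None
        for k, (ref_s, hap_s, length) in enumerate(self.blocks):
            hap_e = hap_s + length
            if k > 0:
                # the gap between block k-1 and block k: haplotype-only
                # bases (insertion) and/or reference-only bases (deletion)
                prev_ref_s, prev_hap_s, prev_len = self.blocks[k - 1]
                prev_hap_e = prev_hap_s + prev_len
                prev_ref_e = prev_ref_s + prev_len
                ins_lo, ins_hi = max(prev_hap_e, a), min(hap_s, b)
                if ins_hi > ins_lo:
                    if ref_anchor is None:
                        ref_anchor = ref_s  # insertion attaches before block k
                    ops.append(("I", ins_hi - ins_lo))
                if ref_s > prev_ref_e and a < hap_s and prev_hap_e < b:
                    ops.append(("D", ref_s - prev_ref_e))
            if hap_s >= b:
                break
            if hap_e > a and hap_s < b:
                lo, hi = max(hap_s, a), min(hap_e, b)
                if ref_anchor is None:
                    ref_anchor = ref_s + (lo - hap_s)
                ops.append(("M", hi - lo))
        if ref_anchor is None:
            # interval lies wholly inside one insertion
            ref_anchor = self._ref_pos_of_insertion(a)
            ops = [("I", b - a)]
        return ref_anchor, _merge_ops(ops)

    def _ref_pos_of_insertion(self, a: int) -> int:
        ref = 0
        for ref_s, hap_s, length in self.blocks:
            if hap_s > a:
                return ref_s
            ref = ref_s + length
        return ref


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for code, length in ops:
        if length <= 0:
            continue
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + length)
        else:
            merged.append((code, length))
    return merged


# ---------------------------------------------------------------------------
# reference synthesis


def synthesize_reference(
    length: int,
    n_loci: int,
    rng: np.random.Generator,
    ref_name: str = "chrS",
    motif_len_range: tuple[int, int] = (2, 6),
    ref_copies_range: tuple[int, int] = (8, 12),
) -> tuple[str, list[StrLocusSpec]]:
    """Random mini-chromosome carrying pure tandem arrays at spaced loci.

    Loci are placed on an even grid with jitter so they never overlap and
    stay well separated; motifs are drawn until primitive (not themselves
    a repetition), so the locus period is the motif length.
    """
    if n_loci * 200 > length:
        raise ValueError("too many loci for the requested length")
    seq = rng.choice(list(BASES), size=length)
    loci: list[StrLocusSpec] = []
    slot = length // n_loci
    for k in range(n_loci):
        mlen = int(rng.integers(motif_len_range[0], motif_len_range[1] + 1))
        while True:
            motif = "".join(rng.choice(list(BASES), size=mlen))
            if _is_primitive(motif):
                break
        copies = int(rng.integers(ref_copies_range[0], ref_copies_range[1] + 1))
        span = mlen * copies
        start = k * slot + int(rng.integers(slot // 4, slot // 2))
        array = (motif * copies)
        seq[start:start + span] = list(array)
        loci.append(
            StrLocusSpec(
                ref_name=ref_name,
                start=start,
                end=start + span,
                motif=motif,
                ref_copies=float(copies),
            )
        )
    return "".join(seq), loci


def _is_primitive(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return False
    return True


# ---------------------------------------------------------------------------
# reference mutation


def mutate_reference(
    ref_seqs: dict[str, str],
    loci: list[StrLocusSpec],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[int, dict[str, str]], list[TruthRecord], dict[tuple[int, str], EditMap]]:
    """Apply per-haplotype STR expansions and background SNVs.

    For each haplotype independently, every locus' array is resized by a
    uniform draw from ``delta_range`` (whole motif copies appended to or
    removed from the 3' end); SNVs hit each non-locus base i.i.d. at
    ``snv_rate`` with a uniform choice among the three alternatives.
    Returns haplotype sequences, one truth record per (locus, haplotype),
    and the per-(haplotype, reference) edit maps used by the truth
    aligner.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _check_non_overlapping(loci)
    hap_seqs: dict[int, dict[str, str]] = {1: {}, 2: {}}
    truth: list[TruthRecord] = []
    edit_maps: dict[tuple[int, str], EditMap] = {}
    by_ref: dict[str, list[StrLocusSpec]] = {}
    for locus in loci:
        by_ref.setdefault(locus.ref_name, []).append(locus)
    for hap in (1, 2):
        for ref_name, seq in ref_seqs.items():
            ref_loci = sorted(by_ref.get(ref_name, []), key=lambda l: l.start)
            mutated, records, emap = _mutate_one(seq, ref_name, ref_loci, hap, cfg, rng)
            hap_seqs[hap][ref_name] = mutated
            truth.extend(records)
            edit_maps[(hap, ref_name)] = emap
    return hap_seqs, truth, edit_maps


def _check_non_overlapping(loci: list[StrLocusSpec]) -> None:
    per_ref: dict[str, list[StrLocusSpec]] = {}
    for locus in loci:
        per_ref.setdefault(locus.ref_name, []).append(locus)
    for ref_loci in per_ref.values():
        ref_loci = sorted(ref_loci, key=lambda l: l.start)
        for a, b in zip(ref_loci, ref_loci[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping loci at {a.ref_name}:{a.start}/{b.start}")


def _mutate_one(
    seq: str,
    ref_name: str,
    loci: list[StrLocusSpec],
    hap: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, list[TruthRecord], EditMap]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)

    # background SNVs (substitutions only: coordinates are unchanged)
    if cfg.snv_rate > 0:
        hits = np.flatnonzero(rng.random(n) < cfg.snv_rate)
        if not cfg.snv_in_loci and loci:
            in_locus = np.zeros(n, dtype=bool)
            for locus in loci:
                in_locus[locus.start:locus.end] = True
            hits = hits[~in_locus[hits]]
        if hits.size:
            # uniform among the 3 alternatives of each hit base
            shifts = rng.integers(1, 4, size=hits.size)
            base_idx = np.empty(hits.size, dtype=np.int64)
            for i, b in enumerate(_BASE_ARR):
                base_idx[arr[hits] == b] = i
            arr[hits] = _BASE_ARR[(base_idx + shifts) % 4]
    snv_seq = arr.tobytes().decode()

    # locus resizing, building the edit map left to right
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    truth: list[TruthRecord] = []
    ref_cursor = 0
    hap_cursor = 0
    for j, locus in enumerate(loci):
        mlen = len(locus.motif)
        delta = int(rng.integers(cfg.delta_range[0], cfg.delta_range[1] + 1))
        min_delta = -int(locus.ref_copies)
        if delta < min_delta:
            delta = min_delta  # clipped to an empty array, recorded as such
        if delta >= 0:
            keep_end = locus.end
            inserted = locus.motif * delta
        else:
            keep_end = locus.end + delta * mlen
            inserted = ""
        # diagonal block up to the edit point
        length = keep_end - ref_cursor
        pieces.append(snv_seq[ref_cursor:keep_end])
        blocks.append((ref_cursor, hap_cursor, length))
        hap_cursor += length
        if inserted:
            pieces.append(inserted)
            hap_cursor += len(inserted)
        ref_cursor = locus.end
        truth.append(
            TruthRecord(
                locus_id=f"{ref_name}_L{j}_h{hap}",
                ref_name=ref_name,
                start=locus.start,
                end=locus.end,
                haplotype=hap,
                motif=locus.motif,
                sim_copies=locus.ref_copies + delta,
                delta_copies=float(delta),
                expanded_length=delta * mlen,
            )
        )
    pieces.append(snv_seq[ref_cursor:])
    blocks.append((ref_cursor, hap_cursor, n - ref_cursor))
    hap_seq = "".join(pieces)
    return hap_seq, truth, EditMap(blocks, len(hap_seq))


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimRead:
    """A simulated read with full provenance for truth alignment."""

    read_id: str
    haplotype: int
    ref_name: str
    hap_start: int
    hap_end: int
    sequence: str
    # edit script read -> haplotype, run-length (code, length); codes:
    # M match, X substitution, I read-only insertion, D haplotype-only
    script: list[tuple[str, int]] = field(default_factory=list)


def simulate_reads(
    hap_seqs: dict[int, dict[str, str]],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Draw long reads uniformly over each haplotype with i.i.d. errors.

    Read count per (haplotype, reference) is coverage x length / mean
    read length; lengths are log-normal and truncated at the sequence
    end. The applied edit script is retained per read so the truth
    aligner can compose exact CIGARs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    mu = math.log(cfg.read_length_mean) - cfg.read_length_sigma**2 / 2
    reads: list[SimRead] = []
    for hap in sorted(hap_seqs):
        for ref_name in sorted(hap_seqs[hap]):
            seq = hap_seqs[hap][ref_name]
            n_reads = int(round(cfg.coverage * len(seq) / cfg.read_length_mean))
            for k in range(n_reads):
                start = int(rng.integers(0, max(1, len(seq) - 50)))
                length = int(round(rng.lognormal(mu, cfg.read_length_sigma)))
                end = min(start + max(length, 50), len(seq))
                read_id = f"r_h{hap}_{ref_name}_{k}"
                reads.append(
                    _apply_errors(read_id, hap, ref_name, seq, start, end, cfg, rng)
                )
    return reads


def _apply_errors(
    read_id: str,
    hap: int,
    ref_name: str,
    hap_seq: str,
    start: int,
    end: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> SimRead:
    template = hap_seq[start:end]
    prof = cfg.error_profile
    if prof.total == 0:
        return SimRead(
            read_id, hap, ref_name, start, end, template, [("M", end - start)]
        )
    n = end - start
    dels = rng.random(n) < prof.del_rate
    subs = rng.random(n) < prof.sub_rate
    inss = rng.random(n) < prof.ins_rate  # insertion after each surviving base
    sub_shift = rng.integers(1, 4, size=n)
    ins_base = rng.integers(0, 4, size=n)
    out: list[str] = []
    script: list[tuple[str, int]] = []

    def emit(code: str, length: int = 1) -> None:
        if script and script[-1][0] == code:
            script[-1] = (code, script[-1][1] + length)
        else:
            script.append((code, length))

    for i, base in enumerate(template):
        if dels[i]:
            emit("D")
            continue
        if subs[i]:
            out.append(BASES[(BASES.index(base) + sub_shift[i]) % 4])
            emit("X")
        else:
            out.append(base)
            emit("M")
        if inss[i]:
            out.append(BASES[ins_base[i]])
            emit("I")
    if not out:  # pathological: everything deleted; keep one true base
        out.append(template[0])
        script = [("M", 1), ("D", n - 1)] if n > 1 else [("M", 1)]
    return SimRead(read_id, hap, ref_name, start, end, "".join(out), script)


# ---------------------------------------------------------------------------
# truth alignments


def compose_cigar(
    read: SimRead, edit_map: EditMap
) -> tuple[int, list[tuple[str, int]]] | None:
    """Compose the read's error script with the haplotype->reference map.

    Returns (ref_start, cigar ops) with leading/trailing insertions
    converted to soft clips and boundary deletions dropped; None when the
    read touches no reference base at all (fully inside an insertion).
    """
    ref_anchor, lift = edit_map.project(read.hap_start, read.hap_end)
    lift_ops = [list(op) for op in lift]
    ops: list[tuple[str, int]] = []
    li = 0

    def consume_hap(n: int, to_read: bool) -> None:
        # walk n haplotype bases through the liftover ops
        nonlocal li
        while n > 0:
            code, rem = lift_ops[li]
            if code == "D":  # reference-only bases between blocks
                ops.append(("D", rem))
                li += 1
                continue
            take = min(n, rem)
            if code == "M":
                ops.append(("M" if to_read else "D", take))
            else:  # haplotype insertion bases
                if to_read:
                    ops.append(("I", take))
                # deleted insertion bases vanish from the alignment
            lift_ops[li][1] -= take
            if lift_ops[li][1] == 0:
                li += 1
            n -= take

    for code, length in read.script:
        if code in ("M", "X"):
            consume_hap(length, to_read=True)
        elif code == "D":
            consume_hap(length, to_read=False)
        else:  # read-only insertion (sequencing error)
            ops.append(("I", length))
    # flush a trailing liftover D at the read boundary? no: deletions at the
    # boundary are outside the alignment, so they are dropped below
    ops = _merge_ops(ops)

    # drop boundary deletions, adjusting the anchor for leading ones
    ref_start = ref_anchor
    while ops and ops[0][0] == "D":
        ref_start += ops[0][1]
        ops.pop(0)
    while ops and ops[-1][0] == "D":
        ops.pop()
    if not any(code == "M" for code, _ in ops):
        return None
    # terminal insertions become soft clips
    if ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    return ref_start, ops


def emit_truth_alignments(
    reads: list[SimRead],
    edit_maps: dict[tuple[int, str], EditMap],
    ref_lengths: dict[str, int],
    haplotype_tag_name: str = "HP",
    mapq: int = 60,
) -> list[str]:
    """Render coordinate-sorted SAM text lines (header included).

    Each read gets its true reference interval via the liftover map; the
    CIGAR combines the read's own error edits with any locus expansion it
    crosses (expansion bases become I ops, or terminal S ops when the
    read starts or ends inside the expansion). The HP tag carries the
    true haplotype. Reads lying entirely within an expansion are
    unmappable and skipped.
    """
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name in sorted(ref_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{ref_lengths[name]}")
    body: list[tuple[str, int, str]] = []
    for read in reads:
        placed = compose_cigar(read, edit_maps[(read.haplotype, read.ref_name)])
        if placed is None:
            continue
        ref_start, ops = placed
        cigar = "".join(f"{l}{c}" for c, l in ops)
        line = "\t".join(
            [
                read.read_id,
                "0",
                read.ref_name,
                str(ref_start + 1),
                str(mapq),
                cigar,
                "*",
                "0",
                "0",
                read.sequence,
                "*",
                f"{haplotype_tag_name}:i:{read.haplotype}",
            ]
        )
        body.append((read.ref_name, ref_start, line))
    body.sort(key=lambda t: (t[0], t[1], t[2]))
    lines.extend(line for _, _, line in body)
    return lines


# ---------------------------------------------------------------------------
# file output helpers


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_fastq(reads: list[SimRead], path: str, base_quality: int = 30) -> None:
    q = chr(33 + base_quality)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{q * len(read.sequence)}\n")


def write_truth_tsv(truth: list[TruthRecord], path: str) -> None:
    cols = [
        "locus_id", "ref_name", "start", "end", "haplotype",
        "motif", "sim_copies", "delta_copies", "expanded_length",
    ]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write(
                f"{t.locus_id}\t{t.ref_name}\t{t.start}\t{t.end}\t{t.haplotype}\t"
                f"{t.motif}\t{t.sim_copies:.1f}\t{t.delta_copies:.1f}\t"
                f"{t.expanded_length}\n"
            )


def read_truth_tsv(path: str) -> list[TruthRecord]:
    truth: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truth.append(
                TruthRecord(
                    locus_id=f[idx["locus_id"]],
                    ref_name=f[idx["ref_name"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    haplotype=int(f[idx["haplotype"]]),
                    motif=f[idx["motif"]],
                    sim_copies=float(f[idx["sim_copies"]]),
                    delta_copies=float(f[idx["delta_copies"]]),
                    expanded_length=int(f[idx["expanded_length"]]),
                )
            )
    return truth
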