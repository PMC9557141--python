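"""Score detector genotypes against simulator truth.

Truth records with a non-zero copy-number change are the positive set; a
greedy one-to-one matching (ascending distance, deterministic tie-break)
pairs each with the nearest unmatched call on the same reference and
haplotype within ``pos_tol``. Matched pairs are TPs, leftover truth FNs,
leftover calls FPs — except calls sitting on a zero-delta truth locus,
which are neutral: genotyping a reference-length STR is legitimate, not a
false positive.

Copy-number concordance compares the called copies against the simulated
copy-number change (delta): flank trimming removes the reference copies
from the consensus, so the trimmed sequence carries the inserted copies
only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotyper import StrGenotype
from .repeats import canonical_motif
from .simulate import TruthRecord


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    motif_concordance: float  # over TPs
    copy_concordance: float  # over TPs, |called - delta| <= copy_tol
    n_truth: int
    n_calls: int

    def summary(self) -> str:
        return (
            f"TP={self.tp} FP={self.fp} FN={self.fn} "
            f"precision={self.precision:.4f} recall={self.recall:.4f} "
            f"f1={self.f1:.4f} motif_concordance={self.motif_concordance:.4f} "
            f"copy_concordance={self.copy_concordance:.4f}"
        )


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def compare(
    calls: list[StrGenotype],
    truth: list[TruthRecord],
    pos_tol: int = 100,
    copy_tol: float = 1.0,
) -> EvalReport:
    """Locus-level precision/recall and genotype concordance."""
    positives = [t for t in truth if t.delta_copies != 0]
    neutral = [t for t in truth if t.delta_copies == 0]

    pairs = []
    for ti, t in enumerate(positives):
        for ci, c in enumerate(calls):
            if c.ref_name != t.ref_name or c.haplotype != t.haplotype:
                continue
            dist = abs(c.position - t.midpoint)
            if dist <= pos_tol:
                pairs.append((dist, t.midpoint, c.position, ti, ci))
    pairs.sort()

    matched_t: dict[int, int] = {}
    matched_c: set[int] = set()
    for _, _, _, ti, ci in pairs:
        if ti in matched_t or ci in matched_c:
            continue
        matched_t[ti] = ci
        matched_c.add(ci)

    tp = len(matched_t)
    fn = len(positives) - tp
    fp = 0
    for ci, c in enumerate(calls):
        if ci in matched_c:
            continue
        near_neutral = any(
            c.ref_name == t.ref_name
            and c.haplotype == t.haplotype
            and abs(c.position - t.midpoint) <= pos_tol
            for t in neutral
        )
        if not near_neutral:
            fp += 1

    motif_ok = 0
    copy_ok = 0
    for ti, ci in matched_t.items():
        t, c = positives[ti], calls[ci]
        if c.motif != "." and c.motif == canonical_motif(t.motif):
            motif_ok += 1
        if c.copies is not None and abs(c.copies - t.delta_copies) <= copy_tol:
            copy_ok += 1

    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        motif_concordance=_safe_div(motif_ok, tp),
        copy_concordance=_safe_div(copy_ok, tp),
        n_truth=len(positives),
        n_calls=len(calls),
    )


def write_report_tsv(report: EvalReport, path: str) -> None:
    fields = [
        "tp", "fp", "fn", "precision", "recall", "f1",
        "motif_concordance", "copy_concordance", "n_truth", "n_calls",
    ]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(fields) + "\n")
        values = [getattr(report, f) for f in fields]
        fh.write(
            "\t".join(
                f"{v:.4f}" if isinstance(v, float) else str(v) for v in values
            )
            + "\n"
        )
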