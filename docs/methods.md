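# Methods

`longstr` detects and genotypes short tandem repeat (STR) expansions from
phased long-read alignments, and ships a simulator and evaluation harness
so every stage can be validated end to end on synthetic data. This note
records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Detection model

An STR allele longer than its reference array carries sequence the
aligner cannot place: it shows up either as an insertion (`I`) operation
inside a read's CIGAR or, near read ends or very large expansions, as a
soft-clip (`S`). The detector works directly on these signals:

1. **Candidate events.** Every `I` op and terminal `S` op strictly longer
   than `min_event_len` (default 15 bp, i.e. length ≥ 16 qualifies)
   becomes a candidate. The event sequence is copied verbatim from the
   read together with up to `flank` (50 bp) of adjacent read sequence per
   available side; a left clip has no left flank by construction. Hard
   clips carry no sequence and are ignored. Reads below `min_mapq`
   (default 1) are skipped — ambiguous mappings generate spurious clips.
2. **Clustering.** Events on the same reference and haplotype whose
   anchors chain within `max_gap` (50 bp) merge by single linkage (each
   *consecutive* gap, not the cluster diameter, is bounded; a diameter
   rule would be input-order dependent). Insertions and clips co-cluster
   because both signal the same expansion. Haplotype labels come from an
   integer phasing tag (`HP` by default); unphased reads form their own
   stream and are copied into both haplotypes only when
   `--rescue-unphased` is set. Clusters need `min_support` (3) distinct
   reads — the smallest support at which consensus voting is meaningful.
3. **Consensus.** Each cluster's flanked event sequences are fused into a
   partial-order alignment (POA) graph: the longest sequence seeds a
   linear backbone (so the expansion is covered end to end; equal lengths
   keep read-id order), and each next sequence is globally aligned to the
   DAG by dynamic programming over the topological order and threaded in.
   Scoring is linear-gap, `{match +2, mismatch −4, gap −4}`; `N` matches
   nothing. Same-column branch nodes are tracked so read support
   accumulates per alternative. The consensus is the heaviest-bundle
   source-to-sink path — the path maximizing total traversed *edge*
   weight. Edge weight (reads following each junction) is the graph form
   of per-column majority voting: an error branch or insertion detour
   carries one or two traversals and loses to the direct majority edge.
   (Maximizing summed node weights instead would absorb every one-read
   insertion node that lengthens the path and inflate the consensus under
   indel noise.) Ties prefer the higher-weight incoming edge, then the
   lexicographically smaller base, then the smaller node id — all
   deterministic.
4. **Flank trimming.** The consensus is computed with flanks attached
   (they stabilize the alignment ends) and trimmed afterwards, since
   repeat calling must see only the inserted sequence. The preferred cut
   is an exact match of the consensus ends against the reference flanks
   around the cluster anchors (reference FASTA optional); when the
   reference is absent or residual consensus error breaks the exact
   match, the median per-event flank length is trimmed instead. With
   clean reads both rules give the same cut.
5. **Repeat calling.** A window `[s, e)` of the trimmed consensus is an
   acceptable repeat of period `p` when the minimal number of
   substitutions making it exactly `p`-periodic (window length minus the
   per-column majority counts), divided by the number of vertically
   compared positions (`e − s − p`), is at most `resolution` (0.1 —
   roughly the residual error expected after consensus; raw reads run ~1%
   for HiFi and ~10–15% for ONT). Candidate windows are maximal per
   period; floors `min_span` 12 bp and `min_copies` 3 suppress spurious
   dinucleotide hits; overlapping calls of different periods reduce to
   one per overlapping group (lowest mismatch fraction, then smallest
   period, then leftmost start). Periods span 2–6 bp, the STR motif
   range; the bound is configurable for VNTR exploration. Motifs are
   reported as the lexicographically smallest rotation of the primitive
   unit, so `CAG`/`AGC`/`GCA` and `ATAT`→`AT` collapse to one name. A
   `brute_force_repeats` oracle re-derives calls by literal enumeration
   of all `(start, end, period)` triples on sequences ≤ 64 bp; the
   windowed implementation is tested for exact agreement against it,
   including an exhaustive sweep of all 4^8 8-mers.
6. **Reporting.** One row per surviving cluster: reference, position
   (anchor-range midpoint), haplotype, canonical motif, copy number
   (window span / period), consensus length, read support, mismatch
   fraction, status. Clusters whose consensus shows no qualifying
   periodicity are kept with `status=non_repetitive` rather than silently
   dropped, so large non-STR insertions stay visible. Output is a TSV
   with `.`/`NA` conventions; repeated runs are byte-identical.

A one-sided detection limit follows from the threshold: an expansion must
add **more than 15 bp** of sequence to be seen at all, so dinucleotide
expansions of +6 or +7 copies (12/14 bp) are structurally invisible. The
evaluation reports recall both over all simulated expansions and over the
detectable (>15 bp) subset.

## Simulator

The simulator emulates the pieces of a real benchmark that matter to this
detector, without external mappers:

- **Reference synthesis.** A random mini-chromosome (default 200 kb) with
  pure tandem arrays (primitive motifs, 2–6 bp; 8–12 reference copies) at
  well-separated jittered grid positions.
- **Haplotype mutation.** Per haplotype independently, each locus array
  is resized by a uniform integer draw from `delta_range` (default +6 to
  +20 copies), appending or removing whole motif copies at the 3′ end of
  the array; the truth table records the change so evaluation is
  placement-agnostic. Background SNVs hit each non-locus base i.i.d. at
  `snv_rate` 0.001 (kept out of loci by default so truth motifs stay
  clean; configurable). Coordinate edit maps (haplotype ↔ reference
  liftover, bijective outside edits) are retained.
- **Reads.** Count = coverage × length / mean read length per haplotype;
  log-normal lengths (mean 8 kb), uniform starts, truncated at sequence
  ends. Errors are i.i.d. per base from an `{sub, ins, del}` profile with
  presets: `PERFECT` (0/0/0), `ONT_LIKE` (0.05/0.05/0.05), `HIFI_LIKE`
  (0.004/0.003/0.003). The applied edit script is retained per read.
  Constant base qualities; reads are emitted in reference orientation.
- **Truth alignments.** Each read's SAM record is *composed*, not
  mapped: the read→haplotype error script is pushed through the
  haplotype→reference edit map, so expansion bases become `I` ops (or
  terminal `S` ops when a read starts or ends inside the expansion) at
  exactly the right coordinate, with the `HP` tag set to the true
  haplotype. Reads falling entirely inside an expansion are unmappable
  and skipped.

One seeded `numpy` generator drives all draws in a fixed order
(haplotype 1 then 2, loci by coordinate, reads in generation order), so a
seed fixes every output byte.

What the simulation does **not** emulate: real mapper behaviour around
repeats (alignment ambiguity, split anchors, mismapped clips), phasing
errors, non-uniform coverage, homopolymer-biased ONT errors, somatic
mosaicism, and reference arrays that are themselves impure. Passing the
synthetic suite therefore shows the event→cluster→consensus→repeat
machinery is correct given faithful alignments; it does not bound
performance on real alignments, where mapper artefacts dominate.

## Evaluation

Truth records with a non-zero copy change are positives. Greedy
one-to-one matching by ascending distance pairs each with the nearest
unmatched call on the same reference/haplotype within `pos_tol` (100 bp,
comparing call position against the truth locus midpoint). Unmatched
truth are FNs; unmatched calls are FPs unless they sit on a zero-delta
truth locus (genotyping a reference-length STR is legitimate — neutral,
not false). Precision/recall/F1 use the 0/0 → 0 convention. Over TPs:
motif concordance is canonical-motif equality on the same strand;
copy concordance is `|called_copies − delta_copies| ≤ copy_tol` (1.0) —
the trimmed consensus carries the inserted copies only, so the called
copy number estimates the copy-number *change*, not the total allele
length.

## Problem sizes and measured behaviour

The validation scenarios run a 200 kb chromosome, 50 loci, coverage 20
per haplotype (~1,000 reads of mean 8 kb) — large enough that every locus
is crossed by both event kinds and small enough to iterate on freely.
Under these conditions (recomputed by `scripts/acceptance.py`, not quoted
from elsewhere): error-free recall ≥ 0.94 overall and 1.0 over detectable
expansions, precision 1.0, motif and copy concordance 1.0; under ONT-like
error, recall and motif concordance stay ≥ 0.96 while copy estimates
degrade (indel noise shifts repeat registers during consensus, shrinking
arrays) — the copy-number concordance target is intentionally confined to
the clean-read condition.

## Known limitations

- Expansions adding ≤ 15 bp are invisible by design (threshold fidelity
  is a feature, not a bug; lower `min_event_len` to trade sensitivity for
  clip noise).
- Contractions are not detected (deletion-indicative signals are out of
  scope); the simulator can generate them for future work.
- Copy numbers under high indel error are systematically underestimated;
  consensus polishing (e.g. a second realignment round) would be the
  natural extension.
- One genotype row per cluster: no diploid joint records, no VCF.
- Motifs are reported on the reference strand only; no
  reverse-complement folding of motif classes.
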