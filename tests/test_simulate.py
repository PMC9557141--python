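"""Simulator: reference mutation, read generation, truth alignments."""

import numpy as np
import pytest

import longstr as L
from longstr.simulate import EditMap

from conftest import simulate_scenario


def flat_cfg(**kw):
    defaults = dict(delta_range=(0, 0), snv_rate=0.0, coverage=5.0, seed=1)
    defaults.update(kw)
    return L.SimConfig(**defaults)


def one_locus_ref(motif="CAG", copies=10, pad=300, seed=2):
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), pad))
    right = "".join(rng.choice(list("ACGT"), pad))
    seq = left + motif * copies + right
    locus = L.StrLocusSpec(
        ref_name="c",
        start=pad,
        end=pad + len(motif) * copies,
        motif=motif,
        ref_copies=float(copies),
    )
    return seq, locus


class TestMutateReference:
    def test_identity_when_nothing_is_mutated(self):
        seq, locus = one_locus_ref()
        haps, truth, _ = L.mutate_reference({"c": seq}, [locus], flat_cfg())
        assert haps[1]["c"] == seq and haps[2]["c"] == seq
        assert all(t.delta_copies == 0 for t in truth)

    def test_expansion_length_bookkeeping(self):
        seq, locus = one_locus_ref(motif="CAG")
        haps, truth, _ = L.mutate_reference(
            {"c": seq}, [locus], flat_cfg(delta_range=(3, 3))
        )
        assert len(haps[1]["c"]) == len(seq) + 9
        t = next(t for t in truth if t.haplotype == 1)
        assert (t.delta_copies, t.expanded_length) == (3.0, 9)
        assert t.sim_copies == locus.ref_copies + 3

    def test_expansion_appends_whole_motif_copies(self):
        seq, locus = one_locus_ref(motif="CAG", copies=10)
        haps, _, _ = L.mutate_reference(
            {"c": seq}, [locus], flat_cfg(delta_range=(4, 4))
        )
        hap = haps[1]["c"]
        assert hap[locus.start:locus.end + 12] == "CAG" * 14
        # sequence outside the locus is untouched
        assert hap[:locus.start] == seq[:locus.start]
        assert hap[locus.end + 12:] == seq[locus.end:]

    def test_contraction_clipped_at_empty_array(self):
        seq, locus = one_locus_ref(copies=5)
        haps, truth, _ = L.mutate_reference(
            {"c": seq}, [locus], flat_cfg(delta_range=(-50, -50))
        )
        t = truth[0]
        assert t.sim_copies == 0.0 and t.delta_copies == -5.0
        assert len(haps[1]["c"]) == len(seq) - 15

    def test_overlapping_loci_rejected(self):
        seq, locus = one_locus_ref()
        other = L.StrLocusSpec("c", locus.start + 3, locus.start + 15, "CAG", 4.0)
        with pytest.raises(ValueError, match="overlap"):
            L.mutate_reference({"c": seq}, [locus, other], flat_cfg())

    def test_snv_count_is_binomial(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 1_000_000))
        cfg = flat_cfg(snv_rate=0.001, seed=9)
        haps, _, _ = L.mutate_reference({"c": seq}, [], cfg)
        n_snv = sum(a != b for a, b in zip(seq, haps[1]["c"]))
        sigma = (1_000_000 * 0.001 * 0.999) ** 0.5
        assert abs(n_snv - 1000) <= 3 * sigma


class TestEditMap:
    def test_liftover_bijective_outside_edits(self):
        seq, locus = one_locus_ref()
        _, _, maps = L.mutate_reference(
            {"c": seq}, [locus], flat_cfg(delta_range=(4, 4))
        )
        emap = maps[(1, "c")]
        # before the edit: identity
        anchor, ops = emap.project(0, locus.end)
        assert (anchor, ops) == (0, [("M", locus.end)])
        # after the edit: shifted by the 12 inserted bases
        anchor, ops = emap.project(locus.end + 12, locus.end + 112)
        assert (anchor, ops) == (locus.end, [("M", 100)])

    def test_projection_across_insertion(self):
        emap = EditMap(blocks=[(0, 0, 100), (100, 112, 100)], hap_length=212)
        anchor, ops = emap.project(50, 162)
        assert anchor == 50
        assert ops == [("M", 50), ("I", 12), ("M", 50)]

    def test_projection_starting_inside_insertion(self):
        emap = EditMap(blocks=[(0, 0, 100), (100, 112, 100)], hap_length=212)
        anchor, ops = emap.project(105, 150)
        assert anchor == 100
        assert ops == [("I", 7), ("M", 38)]

    def test_projection_across_deletion(self):
        emap = EditMap(blocks=[(0, 0, 100), (130, 100, 70)], hap_length=170)
        anchor, ops = emap.project(80, 120)
        assert anchor == 80
        assert ops == [("M", 20), ("D", 30), ("M", 20)]


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        seq, locus = one_locus_ref()
        haps, _, _ = L.mutate_reference({"c": seq}, [locus], flat_cfg())
        reads = L.simulate_reads(haps, flat_cfg(read_length_mean=200.0))
        assert len(reads) > 0
        for read in reads:
            hap = haps[read.haplotype][read.ref_name]
            assert read.sequence == hap[read.hap_start:read.hap_end]

    def test_coverage_arithmetic(self):
        rng = np.random.default_rng(4)
        hap = {1: {"c": "".join(rng.choice(list("ACGT"), 100_000))}}
        cfg = L.SimConfig(coverage=20, read_length_mean=10_000, seed=4)
        reads = L.simulate_reads(hap, cfg)
        assert len(reads) == 200

    def test_seeded_runs_are_identical(self, tmp_path):
        for trial in ("a", "b"):
            scenario = simulate_scenario(seed=5, length=20_000, n_loci=4,
                                         error_profile=L.ONT_LIKE)
            L.write_fastq(scenario["reads"], str(tmp_path / f"{trial}.fastq"))
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_error_script_consumes_read_and_haplotype(self):
        scenario = simulate_scenario(seed=6, length=20_000, n_loci=4,
                                     error_profile=L.ONT_LIKE)
        for read in scenario["reads"][:50]:
            read_len = sum(n for c, n in read.script if c in "MXI")
            hap_len = sum(n for c, n in read.script if c in "MXD")
            assert read_len == len(read.sequence)
            assert hap_len == read.hap_end - read.hap_start


class TestTruthAlignments:
    def test_read_in_unedited_region_is_all_match(self):
        seq, locus = one_locus_ref()
        haps, _, maps = L.mutate_reference({"c": seq}, [locus], flat_cfg())
        read = L.SimRead("r", 1, "c", 10, 110, haps[1]["c"][10:110], [("M", 100)])
        ref_start, ops = L.simulate.compose_cigar(read, maps[(1, "c")])
        assert (ref_start, ops) == (10, [("M", 100)])

    def test_read_spanning_expansion_gets_single_insertion_op(self):
        seq, locus = one_locus_ref(motif="CAG")
        haps, _, maps = L.mutate_reference(
            {"c": seq}, [locus], flat_cfg(delta_range=(3, 3))
        )
        hap = haps[1]["c"]
        a, b = locus.start - 60, locus.end + 9 + 60
        read = L.SimRead("r", 1, "c", a, b, hap[a:b], [("M", b - a)])
        ref_start, ops = L.simulate.compose_cigar(read, maps[(1, "c")])
        assert ref_start == a
        assert ops == [("M", locus.end - a), ("I", 9), ("M", 60)]

    def test_read_starting_inside_expansion_is_soft_clipped(self):
        seq, locus = one_locus_ref(motif="CAG")
        haps, _, maps = L.mutate_reference(
            {"c": seq}, [locus], flat_cfg(delta_range=(10, 10))
        )
        hap = haps[1]["c"]
        a = locus.end + 5  # 5 bases into the 30 bp expansion
        b = a + 100
        read = L.SimRead("r", 1, "c", a, b, hap[a:b], [("M", b - a)])
        ref_start, ops = L.simulate.compose_cigar(read, maps[(1, "c")])
        assert ref_start == locus.end
        assert ops[0] == ("S", 25)  # the in-expansion prefix
        assert ops[1] == ("M", 75)

    def test_emitted_sam_parses_with_consistent_lengths(self, small_scenario):
        from longstr.alignment import iter_sam_lines, parse_sam_record

        n = 0
        for line in iter_sam_lines(small_scenario["sam_lines"]):
            read = parse_sam_record(line)  # length invariants checked on init
            assert read.haplotype in (1, 2)
            n += 1
        assert n > 100
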