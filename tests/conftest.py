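import numpy as np
import pytest

import longstr as L


def sam_line(
    qname="r1",
    flag=0,
    rname="chr1",
    pos=101,
    mapq=60,
    cigar="10M",
    seq=None,
    tags=(),
):
    """Build a minimal SAM alignment line with a length-consistent SEQ."""
    if seq is None:
        need = sum(
            int(n)
            for n, c in __import__("re").findall(r"(\d+)([MIDNSHP=X])", cigar)
            if c in "MIS=X"
        )
        seq = "A" * need
    fields = [qname, str(flag), rname, str(pos), str(mapq), cigar,
              "*", "0", "0", seq, "*", *tags]
    return "\t".join(fields)


def simulate_scenario(
    seed,
    length=50_000,
    n_loci=10,
    error_profile=L.PERFECT,
    delta_range=(6, 20),
    snv_rate=0.001,
    coverage=20.0,
):
    """Reference + loci + haplotypes + reads + truth SAM, fully seeded."""
    rng = np.random.default_rng(seed)
    seq, loci = L.synthesize_reference(length, n_loci, rng)
    cfg = L.SimConfig(
        delta_range=delta_range,
        snv_rate=snv_rate,
        coverage=coverage,
        error_profile=error_profile,
        seed=seed,
    )
    hap_seqs, truth, edit_maps = L.mutate_reference({"chrS": seq}, loci, cfg, rng)
    reads = L.simulate_reads(hap_seqs, cfg, rng)
    sam_lines = L.emit_truth_alignments(reads, edit_maps, {"chrS": len(seq)})
    return {
        "reference": {"chrS": seq},
        "loci": loci,
        "cfg": cfg,
        "hap_seqs": hap_seqs,
        "truth": truth,
        "edit_maps": edit_maps,
        "reads": reads,
        "sam_lines": sam_lines,
    }


@pytest.fixture(scope="session")
def small_scenario():
    """Error-free 50 kb / 10 locus scenario shared by end-to-end tests."""
    return simulate_scenario(seed=42)


@pytest.fixture
def sam_path(tmp_path, small_scenario):
    path = tmp_path / "truth.sam"
    path.write_text("\n".join(small_scenario["sam_lines"]) + "\n")
    return str(path)
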