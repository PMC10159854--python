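"""Simulator invariants: planted arrays, reads, contacts and determinism."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from spacerlink import (
    CommunityConfig,
    simulate_community,
    simulate_hic_pairs,
    simulate_reads,
)
from spacerlink._seq import revcomp
from spacerlink.synthetic_community import (
    write_community,
    write_contacts,
    write_reads,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_bacteria": -1},
        {"genome_len_range": (5000, 4000)},
        {"p_shared_repeat": 1.5},
        {"spacer_len_range": (20, 45)},  # must stay above the >25 nt filter
        {"abundance_dirichlet_alpha": 0.0},
        {"repeat_len": 10},
    ],
)
def test_config_rejects_invalid_parameters(kwargs):
    with pytest.raises(ValueError):
        CommunityConfig(**kwargs)


def test_no_viruses_means_no_spacers_or_infections():
    truth = simulate_community(
        dataclasses.replace(CommunityConfig(), n_viruses=0, seed=5)
    )
    assert sum(len(a.spacers) for a in truth.arrays) == 0
    assert truth.infections == []
    assert truth.immunity_pairs() == set()


def test_no_sharing_gives_population_unique_repeats():
    truth = simulate_community(
        dataclasses.replace(CommunityConfig(), p_shared_repeat=0.0, seed=11)
    )
    for mags in truth.shared_repeat_mags().values():
        assert len(mags) == 1


def test_planted_arrays_serialize_and_reparse(default_truth):
    """Re-parsing each genome with the true repeat recovers exactly the
    planted spacers, in order (independent string-level oracle)."""
    for arr in default_truth.arrays:
        contig = default_truth.contig_seqs[arr.contig_id]
        expected = (
            "".join(arr.repeat_seq + sp.seq for sp in arr.spacers) + arr.repeat_seq
        )
        body_start = arr.start + 100  # leader precedes the first repeat
        assert contig[body_start : body_start + len(expected)] == expected
        # oracle: split the array body on the repeat to read spacers back out
        segments = contig[body_start : body_start + len(expected)].split(
            arr.repeat_seq
        )
        assert segments[0] == "" and segments[-1] == ""
        assert segments[1:-1] == [sp.seq for sp in arr.spacers]


def test_planted_spacer_sources_lie_within_viruses(default_truth):
    for arr in default_truth.arrays:
        for sp in arr.spacers:
            vlen = default_truth.genome_length(sp.source_virus)
            assert 0 <= sp.source_start <= vlen - len(sp.seq)
            # mutation count is consistent with the recorded source
            vseq = "".join(
                default_truth.contig_seqs[c]
                for c in default_truth.mag_contigs[sp.source_virus]
            )
            proto = vseq[sp.source_start : sp.source_start + len(sp.seq)]
            if sp.source_strand == "-":
                proto = revcomp(proto)
            diffs = sum(a != b for a, b in zip(proto, sp.seq))
            assert diffs == sp.n_mutations


def test_cross_domain_viruses_span_both_domains(default_truth):
    domain = dict(zip(default_truth.mags["mag_id"], default_truth.mags["domain"]))
    for v in default_truth.cross_domain_viruses:
        doms = {
            domain[arr.mag_id]
            for arr in default_truth.arrays
            for sp in arr.spacers
            if sp.source_virus == v
        }
        assert {"Bacteria", "Archaea"} <= doms


def test_reads_exact_and_depth_calibrated():
    cfg = dataclasses.replace(
        CommunityConfig(), n_bacteria=1, n_archaea=0, n_viruses=0, seed=2
    )
    truth = simulate_community(cfg)
    reads, aln = simulate_reads(truth, mean_depth=10, read_len=150, seed=4)
    glen = truth.genome_length(truth.mag_ids()[0])
    depth = sum(len(s) for _, s in reads) / glen
    assert 9 <= depth <= 11
    for rid, seq in reads:
        row = aln[aln["read_id"] == rid].iloc[0]
        contig = truth.contig_seqs[row["contig"]]
        sub = contig[row["start0"] : row["start0"] + row["length"]]
        assert seq == (sub if row["strand"] == "+" else revcomp(sub))


def test_short_reads_warn():
    truth = simulate_community(
        dataclasses.replace(CommunityConfig(), n_bacteria=1, n_archaea=0, seed=2)
    )
    with pytest.warns(UserWarning):
        simulate_reads(truth, mean_depth=1, read_len=80, seed=1)


def test_hic_labels_conserved_and_within_bounds(default_truth):
    pairs = simulate_hic_pairs(default_truth, 5_000, noise_fraction=0.05, seed=9)
    assert len(pairs) == 5_000
    assert set(pairs["truth_label"]) <= {"intra", "infection", "noise"}
    lengths = {c: len(s) for c, s in default_truth.contig_seqs.items()}
    assert (pairs["pos_a"] < pairs["contig_a"].map(lengths)).all()
    assert (pairs["pos_b"] < pairs["contig_b"].map(lengths)).all()
    assert (pairs["contig_a"] <= pairs["contig_b"]).all()


def test_pure_cellular_pairs_are_intra_genome(default_truth):
    pairs = simulate_hic_pairs(
        default_truth, 2_000, noise_fraction=0.0, seed=9, infection_rate=0.0
    )
    mag_a = pairs["contig_a"].map(default_truth.contig_mag)
    mag_b = pairs["contig_b"].map(default_truth.contig_mag)
    assert (mag_a == mag_b).all()
    assert (pairs["truth_label"] == "intra").all()


def test_pure_noise_intra_fraction_matches_closed_form(default_truth):
    pairs = simulate_hic_pairs(default_truth, 100_000, noise_fraction=1.0, seed=13)
    mag_a = pairs["contig_a"].map(default_truth.contig_mag)
    mag_b = pairs["contig_b"].map(default_truth.contig_mag)
    observed = float((mag_a == mag_b).mean())
    expected = default_truth.expected_intra_mag_fraction()
    assert observed == pytest.approx(expected, rel=0.15)


def test_outputs_byte_identical_for_same_seed(tmp_path, tiny_config):
    digests = []
    for sub in ("a", "b"):
        out = tmp_path / sub
        truth = simulate_community(tiny_config)
        write_community(truth, out)
        reads, aln = simulate_reads(truth, mean_depth=5, seed=21)
        write_reads(reads, aln, out, seed=tiny_config.seed)
        contacts = simulate_hic_pairs(truth, 2_000, 0.02, seed=22)
        write_contacts(contacts, out, seed=tiny_config.seed)
        digests.append(
            {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(Path(out).iterdir())
            }
        )
    assert digests[0] == digests[1]
    assert "genomes.fasta" in digests[0] and "contacts.tsv" in digests[0]
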