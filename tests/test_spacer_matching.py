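"""Protospacer matcher against its brute-force oracle, plus dereplication."""

import numpy as np
import pandas as pd
import pytest

from spacerlink import spacer_matching as sm
from spacerlink._seq import mutate_substitutions, random_dna, revcomp


def _spacers(seqs):
    return pd.DataFrame(
        {"spacer_id": [f"sp{i:03d}" for i in range(len(seqs))], "spacer_seq": seqs}
    )


def _match_set(df):
    return set(
        map(
            tuple,
            df[["spacer_id", "contig", "start0", "strand", "mismatches"]].itertuples(
                index=False
            ),
        )
    )


def random_instance(seed, n_spacers=60, n_contigs=4, contig_len=2_000, planted=20):
    rng = np.random.default_rng(seed)
    contigs = {f"c{i}": random_dna(rng, contig_len) for i in range(n_contigs)}
    keys = list(contigs)
    seqs = []
    for i in range(n_spacers):
        L = int(rng.integers(26, 46))
        if i < planted:
            cid = keys[int(rng.integers(0, n_contigs))]
            s = int(rng.integers(0, contig_len - L))
            seq = mutate_substitutions(
                rng, contigs[cid][s : s + L], int(rng.integers(0, 4))
            )
            if rng.random() < 0.5:
                seq = revcomp(seq)
        else:
            seq = random_dna(rng, L)
        seqs.append(seq)
    return _spacers(seqs), contigs


def test_exact_substring_matches_forward():
    rng = np.random.default_rng(0)
    contig = random_dna(rng, 500)
    spacer = contig[100:135]
    out = sm.find_protospacers(_spacers([spacer]), {"c1": contig})
    assert len(out) == 1
    row = out.iloc[0]
    assert (row["contig"], row["start0"], row["strand"], row["mismatches"]) == (
        "c1",
        100,
        "+",
        0,
    )


def test_reverse_complement_matches_minus_strand():
    rng = np.random.default_rng(1)
    contig = random_dna(rng, 500)
    spacer = revcomp(contig[200:230])
    out = sm.find_protospacers(_spacers([spacer]), {"c1": contig})
    assert len(out) == 1
    assert out.iloc[0]["strand"] == "-"
    assert out.iloc[0]["start0"] == 200


def test_three_substitutions_rejected_at_budget_two():
    rng = np.random.default_rng(2)
    contig = random_dna(rng, 500)
    spacer = mutate_substitutions(rng, contig[50:80], 3)
    assert sm.find_protospacers(_spacers([spacer]), {"c1": contig}).empty
    assert sm.brute_force_match(_spacers([spacer]), {"c1": contig}).empty


def test_matcher_equals_oracle_on_random_instances():
    for seed in range(10):
        spacers, contigs = random_instance(seed)
        a = sm.find_protospacers(spacers, contigs)
        b = sm.brute_force_match(spacers, contigs)
        assert _match_set(a) == _match_set(b)


def test_mismatch_monotonicity():
    for seed in range(5):
        spacers, contigs = random_instance(seed + 100)
        prev = set()
        for budget in (0, 1, 2, 3):
            cur = _match_set(sm.find_protospacers(spacers, contigs, budget))
            cur_keys = {(s, c, p, st) for s, c, p, st, _ in cur}
            assert {(s, c, p, st) for s, c, p, st, _ in prev} <= cur_keys
            prev = cur


def test_strand_symmetry_bijection():
    for seed in range(5):
        spacers, contigs = random_instance(seed + 200)
        fwd = sm.find_protospacers(spacers, contigs)
        rc_contigs = {c: revcomp(s) for c, s in contigs.items()}
        rev = sm.find_protospacers(spacers, rc_contigs)
        lengths = dict(zip(spacers["spacer_id"], spacers["spacer_seq"].str.len()))
        mapped = {
            (
                sid,
                c,
                len(contigs[c]) - p - lengths[sid],
                "-" if st == "+" else "+",
                mm,
            )
            for sid, c, p, st, mm in _match_set(fwd)
        }
        assert mapped == _match_set(rev)


def test_pigeonhole_never_misses_planted_hits():
    """Planted <=2-mismatch copies are always reported (no false negatives
    from chunking, guaranteed when chunks = budget + 1)."""
    rng = np.random.default_rng(42)
    contig = random_dna(rng, 5_000)
    seqs, expected = [], []
    for i in range(50):
        L = int(rng.integers(26, 46))
        s = int(rng.integers(0, 5_000 - L))
        n_mut = int(rng.integers(0, 3))
        seqs.append(mutate_substitutions(rng, contig[s : s + L], n_mut))
        expected.append((f"sp{i:03d}", s, n_mut))
    out = sm.find_protospacers(_spacers(seqs), {"c1": contig})
    found = {(r["spacer_id"], r["start0"]) for _, r in out.iterrows()}
    for sid, s, _ in expected:
        assert (sid, s) in found


def test_spacer_longer_than_contig_is_no_match():
    rng = np.random.default_rng(3)
    out = sm.find_protospacers(_spacers([random_dna(rng, 40)]), {"c1": random_dna(rng, 30)})
    assert out.empty


def test_flag_multi_target():
    matches = pd.DataFrame(
        {
            "spacer_id": ["sp1", "sp1", "sp2"],
            "spacer_seq": ["A" * 30] * 3,
            "contig": ["v1_c1", "v2_c1", "v1_c1"],
            "start0": [0, 5, 9],
            "strand": ["+", "+", "-"],
            "mismatches": [0, 1, 0],
        }
    )
    vmap = {"v1_c1": "v1", "v2_c1": "v2"}
    flags = sm.flag_multi_target(matches, vmap)
    assert list(flags["spacer_id"]) == ["sp1"]
    assert list(flags["n_target_vmags"]) == [2]
    single = sm.flag_multi_target(matches[matches["spacer_id"] == "sp2"], vmap)
    assert single.empty
    with pytest.raises(KeyError):
        sm.flag_multi_target(matches, {"v1_c1": "v1"})


def test_duplicated_viral_region_flags_its_spacers():
    rng = np.random.default_rng(4)
    shared = random_dna(rng, 400)
    v1 = random_dna(rng, 1_000) + shared
    v2 = shared + random_dna(rng, 1_000)
    spacer = shared[100:135]
    matches = sm.find_protospacers(_spacers([spacer]), {"v1_c1": v1, "v2_c1": v2})
    flags = sm.flag_multi_target(matches, {"v1_c1": "v1", "v2_c1": "v2"})
    assert list(flags["n_target_vmags"]) == [2]


def test_dereplication_absorbs_duplicates_and_mutants():
    rng = np.random.default_rng(5)
    base = random_dna(rng, 10_000)
    mutant = mutate_substitutions(rng, base, 100)  # 1% substitutions
    other = random_dna(rng, 10_000)
    res = sm.dereplicate_contigs(
        {"a": base, "dup": base, "mut": mutant, "other": other}
    )
    assert res.membership["dup"] == res.membership["a"]
    assert res.membership["mut"] == res.membership["a"]
    assert res.membership["other"] == "other"
    assert len(res.representatives) == 2


def test_dereplication_keeps_unrelated_contigs():
    rng = np.random.default_rng(6)
    contigs = {f"c{i}": random_dna(rng, 5_000) for i in range(4)}
    res = sm.dereplicate_contigs(contigs)
    assert sorted(res.representatives) == sorted(contigs)
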