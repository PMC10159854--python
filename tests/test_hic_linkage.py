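"""Contact counting, covariate normalization, consolidation and noise ratios."""

import numpy as np
import pandas as pd
import pytest

from spacerlink import hic_linkage as hl


def _meta(contigs, mags=None, length=1000, coverage=10.0, sites=20):
    mags = mags or {c: c.split("_")[0] for c in contigs}
    return pd.DataFrame(
        {
            "contig_id": contigs,
            "mag_id": [mags[c] for c in contigs],
            "length": length,
            "coverage": coverage,
            "sites": sites,
        }
    )


def _pairs(rows, sample="S1"):
    return pd.DataFrame(rows, columns=["contig_a", "pos_a", "contig_b", "pos_b"]).assign(
        sample=sample
    )


def test_contact_counts_canonicalize_pair_order():
    pairs = _pairs(
        [("A", 1, "B", 2), ("A", 3, "B", 4), ("A", 5, "B", 6), ("B", 7, "A", 8)]
    )
    matrix = hl.build_contact_matrix(pairs, _meta(["A", "B"], {"A": "m1", "B": "m1"}))
    assert len(matrix.counts) == 1
    assert matrix.counts.iloc[0]["count"] == 4
    assert matrix.total_pairs() == 4


def test_unknown_contig_raises():
    with pytest.raises(KeyError, match="Z"):
        hl.build_contact_matrix(
            _pairs([("A", 1, "Z", 2)]), _meta(["A"], {"A": "m1"})
        )


def test_empty_pairs_empty_matrix():
    matrix = hl.build_contact_matrix(
        _pairs([]).iloc[0:0], _meta(["A"], {"A": "m1"})
    )
    assert matrix.counts.empty


def _uniform_matrix(n_contigs=12, count=5):
    contigs = [f"m{i}_c1" for i in range(n_contigs)]
    rows = []
    for i in range(n_contigs - 1):
        rows.append(
            {
                "sample": "S1",
                "contig_a": contigs[i],
                "contig_b": contigs[i + 1],
                "count": count,
            }
        )
    counts = pd.DataFrame(rows)
    return hl.ContactMatrix(counts=counts, metadata=_meta(contigs))


def test_identical_covariates_equal_counts_zero_residuals():
    norm = hl.normalize_contacts(_uniform_matrix())
    assert np.all(np.abs(norm["residual"]) < 1e-6)
    assert np.allclose(norm["ratio"], 1.0)


def test_doubled_count_has_unique_largest_residual():
    matrix = _uniform_matrix()
    matrix.counts.loc[4, "count"] = 10
    norm = hl.normalize_contacts(matrix)
    top = norm.sort_values("residual").iloc[-1]
    assert top["raw_count"] == 10
    assert (norm["residual"] < top["residual"]).sum() == len(norm) - 1


def test_too_few_pairs_raises():
    with pytest.raises(ValueError, match="eligible"):
        hl.normalize_contacts(_uniform_matrix(n_contigs=5))


def test_consolidation_arithmetic():
    normalized = pd.DataFrame(
        {
            "sample": ["S1"] * 3,
            "contig_a": ["h1_c1", "h1_c2", "h1_c1"],
            "contig_b": ["v1_c1", "v1_c1", "v1_c2"],
            "raw_count": [4, 5, 6],
            "expected": [2.0, 2.0, 2.0],
            "residual": [1.0, 2.0, 6.0],
            "ratio": [2.0, 2.5, 3.0],
        }
    )
    c2m = {"h1_c1": "h1", "h1_c2": "h1", "v1_c1": "v1", "v1_c2": "v1"}
    roles = {"h1": "microbial", "v1": "viral"}
    out = hl.consolidate_linkages(normalized, c2m, roles)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["n_contig_links"] == 3
    assert row["mean_residual"] == pytest.approx(3.0)
    assert row["max_residual"] == pytest.approx(6.0)


def test_consolidation_without_host_virus_pairs_is_empty():
    normalized = pd.DataFrame(
        {
            "sample": ["S1"],
            "contig_a": ["h1_c1"],
            "contig_b": ["h2_c1"],
            "raw_count": [4],
            "expected": [2.0],
            "residual": [1.0],
            "ratio": [2.0],
        }
    )
    c2m = {"h1_c1": "h1", "h2_c1": "h2"}
    roles = {"h1": "microbial", "h2": "microbial"}
    assert hl.consolidate_linkages(normalized, c2m, roles).empty


def test_consolidation_unbinned_contig_warn_drop_or_error():
    normalized = pd.DataFrame(
        {
            "sample": ["S1"],
            "contig_a": ["h1_c1"],
            "contig_b": ["orphan"],
            "raw_count": [4],
            "expected": [2.0],
            "residual": [1.0],
            "ratio": [2.0],
        }
    )
    c2m = {"h1_c1": "h1"}
    roles = {"h1": "microbial"}
    assert hl.consolidate_linkages(normalized, c2m, roles).empty
    with pytest.raises(KeyError):
        hl.consolidate_linkages(normalized, c2m, roles, on_unassigned="error")


def _noise_inputs(counts_rows):
    counts = pd.DataFrame(
        counts_rows, columns=["sample", "contig_a", "contig_b", "count"]
    )
    contigs = sorted(set(counts["contig_a"]) | set(counts["contig_b"]))
    meta = _meta(contigs, {c: c.split("_")[0] for c in contigs})
    matrix = hl.ContactMatrix(counts=counts, metadata=meta)
    mags = sorted(set(meta["mag_id"]))
    tax = pd.DataFrame(
        {
            "mag_id": mags,
            "role": ["microbial"] * len(mags),
            "domain": ["Bacteria"] * len(mags),
            "phylum": ["p"] * len(mags),
            "class_": ["c"] * len(mags),
            "order": [f"o{i}" for i in range(len(mags))],
        }
    )
    c2m = dict(zip(meta["contig_id"], meta["mag_id"]))
    return matrix, c2m, tax


def test_noise_all_intra_is_zero():
    matrix, c2m, tax = _noise_inputs(
        [("S1", "m1_c1", "m1_c1", 50), ("S1", "m1_c1", "m1_c2", 50)]
    )
    report = hl.noise_ratios(matrix, c2m, tax)
    assert report.raw_noise == 0.0
    assert report.relaxed_noise == 0.0


def test_noise_ratio_arithmetic():
    matrix, c2m, tax = _noise_inputs(
        [
            ("S1", "m1_c1", "m1_c1", 100),
            ("S1", "m1_c1", "m2_c1", 2),
        ]
    )
    report = hl.noise_ratios(matrix, c2m, tax)
    assert report.raw_noise == pytest.approx(0.02)
    assert report.relaxed_noise == pytest.approx(0.02)  # different orders


def test_inter_mag_same_order_relaxes_to_zero():
    matrix, c2m, tax = _noise_inputs(
        [
            ("S1", "m1_c1", "m1_c1", 100),
            ("S1", "m1_c1", "m2_c1", 2),
        ]
    )
    tax["order"] = "o_shared"
    report = hl.noise_ratios(matrix, c2m, tax)
    assert report.raw_noise > 0
    assert report.relaxed_noise == 0.0


def test_zero_denominator_raises():
    matrix, c2m, tax = _noise_inputs([("S1", "m1_c1", "m2_c1", 2)])
    with pytest.raises(ValueError):
        hl.noise_ratios(matrix, c2m, tax)


def test_viral_and_unbinned_contacts_are_dropped():
    matrix, c2m, tax = _noise_inputs(
        [
            ("S1", "m1_c1", "m1_c1", 10),
            ("S1", "m1_c1", "v1_c1", 5),
        ]
    )
    tax.loc[tax["mag_id"] == "v1", "role"] = "viral"
    report = hl.noise_ratios(matrix, c2m, tax)
    assert report.dropped == 5
    assert report.intra_mag == 10


def test_count_conservation(default_run):
    noise = default_run.noise
    matrix_total = default_run.matrix.total_pairs()
    counted = noise.inter_mag + noise.intra_mag + noise.dropped
    assert counted == matrix_total
    assert noise.relaxed_noise <= noise.raw_noise


def test_residual_scale_invariance():
    """Scaling all lengths rescales coefficients but not residual ranking."""
    matrix = _uniform_matrix()
    rng = np.random.default_rng(0)
    matrix.counts["count"] = rng.integers(2, 30, size=len(matrix.counts))
    matrix.metadata["length"] = rng.integers(1_000, 50_000, size=len(matrix.metadata))
    base = hl.normalize_contacts(matrix)
    scaled_meta = matrix.metadata.copy()
    scaled_meta["length"] = scaled_meta["length"] * 10
    scaled = hl.normalize_contacts(
        hl.ContactMatrix(counts=matrix.counts, metadata=scaled_meta)
    )
    assert list(base.sort_values("residual")["contig_a"]) == list(
        scaled.sort_values("residual")["contig_a"]
    )


def test_residual_auc_orders_scores():
    scores = np.array([0.1, 0.2, 0.9, 1.5])
    labels = np.array([False, False, True, True])
    assert hl.residual_auc(scores, labels) == 1.0
    with pytest.raises(ValueError):
        hl.residual_auc(scores, np.array([True] * 4))


def test_contacts_from_sam(tmp_path):
    sam = tmp_path / "pairs.sam"
    sam.write_text(
        "@HD\tVN:1.6\n"
        "@SQ\tSN:ctgA\tLN:1000\n"
        "@SQ\tSN:ctgB\tLN:1000\n"
        "p1\t0\tctgA\t101\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
        "p1\t0\tctgB\t201\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
        "p2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"
    )
    out = hl.contacts_from_sam(str(sam), sample="S9")
    assert len(out) == 1
    row = out.iloc[0]
    assert (row["contig_a"], row["pos_a"], row["contig_b"], row["pos_b"]) == (
        "ctgA",
        100,
        "ctgB",
        200,
    )
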