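"""Full-length protospacer search in viral contigs under a mismatch budget.

A match requires 100% query coverage (no gaps) and at most
``max_mismatches`` substitutions, on either strand. The production
matcher uses pigeonhole acceleration: every spacer is covered by
``max_mismatches + 1`` disjoint equal-length chunks, so any in-budget
occurrence contains at least one exact chunk, which is found through a
k-mer index of the contigs and then verified over the full spacer
length. ``brute_force_match`` is an independent sliding-window Hamming
scan used as a test oracle.

Also provides the multi-target flag (spacers hitting >= 2 vMAGs) and a
k-mer containment dereplicator for near-identical contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._seq import encode, revcomp

MATCH_COLUMNS = ["spacer_id", "spacer_seq", "contig", "start0", "strand", "mismatches"]


def _matches_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    return df.sort_values(
        ["spacer_id", "contig", "start0", "strand"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# indexed matcher
# ---------------------------------------------------------------------------


def _kmer_index(contigs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in contigs.items():
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((cid, pos))
    return index


def _hamming_full(a: str, b: str, budget: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def find_protospacers(
    spacers: pd.DataFrame,
    contigs: dict[str, str],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Report every full-coverage match with <= ``max_mismatches``.

    ``spacers`` needs columns spacer_id and spacer_seq (one row per
    distinct spacer; duplicates are tolerated and deduplicated). Strand
    ``-`` means the reverse complement of the spacer occurs at
    ``start0`` on the forward contig. Output is sorted by
    (spacer_id, contig, start0, strand).
    """
    if spacers.empty or not contigs:
        return _matches_frame([])
    queries = (
        spacers[["spacer_id", "spacer_seq"]]
        .drop_duplicates()
        .sort_values("spacer_id")
        .itertuples(index=False)
    )
    query_list = [(sid, seq) for sid, seq in queries]
    n_chunks = max_mismatches + 1
    min_len = min(len(s) for _, s in query_list)
    k = min_len // n_chunks
    if k < 4:
        raise ValueError("spacers too short for pigeonhole chunking")
    index = _kmer_index(contigs, k)
    rows: list[tuple] = []
    for sid, seq in query_list:
        hits: set[tuple[str, int, str]] = set()
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            L = len(oriented)
            for j in range(n_chunks):
                off = j * k
                for cid, pos in index.get(oriented[off : off + k], ()):
                    start = pos - off
                    if start < 0 or start + L > len(contigs[cid]):
                        continue
                    if (cid, start, strand) in hits:
                        continue
                    mm = _hamming_full(
                        contigs[cid][start : start + L], oriented, max_mismatches
                    )
                    if mm <= max_mismatches:
                        hits.add((cid, start, strand))
                        rows.append((sid, seq, cid, start, strand, mm))
    return _matches_frame(rows)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


@njit(cache=True)
def _scan_all(
    concat: np.ndarray,
    offsets: np.ndarray,
    spacer: np.ndarray,
    max_mm: int,
    out_contig: np.ndarray,
    out_pos: np.ndarray,
    out_mm: np.ndarray,
):  # pragma: no cover - compiled
    L = spacer.size
    c = 0
    # branchless prefilter over the first bases: with a budget of max_mm,
    # any window with > max_mm mismatches among the first `pre` bases is
    # rejected without entering the early-exit loop (predictable branch).
    pre = min(L, 2 * (max_mm + 1))
    for ci in range(offsets.size - 1):
        start = offsets[ci]
        end = offsets[ci + 1]
        for s in range(start, end - L + 1):
            mm = 0
            for j in range(pre):
                mm += concat[s + j] != spacer[j]
            if mm > max_mm:
                continue
            for j in range(pre, L):
                if concat[s + j] != spacer[j]:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                out_contig[c] = ci
                out_pos[c] = s - start
                out_mm[c] = mm
                c += 1
    return c


def brute_force_match(
    spacers: pd.DataFrame,
    contigs: dict[str, str],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Sliding-window Hamming scan at every position, both strands."""
    if spacers.empty or not contigs:
        return _matches_frame([])
    cids = list(contigs)
    concat = np.concatenate([encode(contigs[c]) for c in cids])
    offsets = np.concatenate(
        [[0], np.cumsum([len(contigs[c]) for c in cids])]
    ).astype(np.int64)
    rows: list[tuple] = []
    queries = (
        spacers[["spacer_id", "spacer_seq"]]
        .drop_duplicates()
        .sort_values("spacer_id")
        .itertuples(index=False)
    )
    buf_ci = np.empty(concat.size, dtype=np.int64)
    buf_pos = np.empty(concat.size, dtype=np.int64)
    buf_mm = np.empty(concat.size, dtype=np.int64)
    for sid, seq in queries:
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            n_hit = _scan_all(
                concat, offsets, encode(oriented), max_mismatches,
                buf_ci, buf_pos, buf_mm,
            )
            for i in range(n_hit):
                rows.append(
                    (sid, seq, cids[buf_ci[i]], int(buf_pos[i]), strand, int(buf_mm[i]))
                )
    return _matches_frame(rows)


# ---------------------------------------------------------------------------
# multi-target flag
# ---------------------------------------------------------------------------


def flag_multi_target(
    matches: pd.DataFrame, contig_to_vmag: dict[str, str]
) -> pd.DataFrame:
    """Flag spacers whose matches span >= 2 vMAGs (matches are retained)."""
    if matches.empty:
        return pd.DataFrame(columns=["spacer_id", "n_target_vmags"])
    unmapped = sorted(set(matches["contig"]) - set(contig_to_vmag))
    if unmapped:
        raise KeyError(f"contigs without vMAG assignment: {unmapped}")
    vmags = matches.assign(vmag=matches["contig"].map(contig_to_vmag))
    n_targets = vmags.groupby("spacer_id")["vmag"].nunique()
    flagged = n_targets[n_targets >= 2]
    return pd.DataFrame(
        {"spacer_id": flagged.index, "n_target_vmags": flagged.values}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dereplication (k-mer containment approximation of CD-HIT-EST)
# ---------------------------------------------------------------------------


@dataclass
class DereplicationResult:
    representatives: list[str]
    membership: dict[str, str]  # contig -> representative


def dereplicate_contigs(
    contigs: dict[str, str],
    min_identity: float = 0.95,
    min_cov: float = 0.85,
    k: int = 21,
) -> DereplicationResult:
    """Greedy longest-first dereplication by shared-k-mer containment.

    A contig is absorbed by the first retained representative covering at
    least ``min_cov`` of its length with shared k-mers, with identity
    (estimated as the shared-window fraction over the covered span,
    de-biased by the k-th root) at or above ``min_identity``. This is a
    containment approximation of CD-HIT-EST-style clustering, not a
    reimplementation; thresholds mirror its -aS/-c flags.
    """
    order = sorted(contigs, key=lambda c: (-len(contigs[c]), c))
    reps: list[str] = []
    rep_kmers: dict[str, set[str]] = {}
    membership: dict[str, str] = {}
    for cid in order:
        seq = contigs[cid]
        n_windows = len(seq) - k + 1
        assigned = None
        if n_windows >= 1:
            windows = [seq[i : i + k] for i in range(n_windows)]
            rc = revcomp(seq)
            windows_rc = [rc[i : i + k] for i in range(n_windows)]
            for rep in reps:
                kmers = rep_kmers[rep]
                for wins in (windows, windows_rc):
                    shared = np.fromiter(
                        (w in kmers for w in wins), dtype=bool, count=n_windows
                    )
                    if not shared.any():
                        continue
                    covered = np.zeros(len(seq), dtype=bool)
                    idx = np.flatnonzero(shared)
                    for i in idx:
                        covered[i : i + k] = True
                    cov_frac = covered.mean()
                    # windows overlapping the covered span
                    overlapping = np.fromiter(
                        (covered[i : i + k].any() for i in range(n_windows)),
                        dtype=bool,
                        count=n_windows,
                    )
                    denom = max(1, int(overlapping.sum()))
                    identity = (shared.sum() / denom) ** (1.0 / k)
                    if cov_frac >= min_cov and identity >= min_identity:
                        assigned = rep
                        break
                if assigned:
                    break
        if assigned is None:
            reps.append(cid)
            rep_kmers[cid] = {
                seq[i : i + k] for i in range(max(0, n_windows))
            }
            membership[cid] = cid
        else:
            membership[cid] = assigned
    return DereplicationResult(representatives=reps, membership=membership)
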