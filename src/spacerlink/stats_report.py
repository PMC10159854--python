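"""Abundance profiles, diversity, correlation tests and report assembly.

Detection of a MAG in a sample follows the coverage/breadth rule: mean
genome-wide coverage above 5x and breadth (fraction of positions covered
by at least one read) above 0.7. Microbial relative abundance is the
MAG's share of summed mean coverages; viral abundance is mean coverage
normalized by the sample's read count (reported per million reads).
Correlation p-values use the exact Student-t transform of Pearson's r,
with Benjamini-Hochberg adjustment across a table of tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COVERAGE_DETECT = 5.0
BREADTH_DETECT = 0.7


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    df: int
    p_two_sided: float
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# coverage / abundance
# ---------------------------------------------------------------------------


def coverage_profiles(
    alignments: pd.DataFrame,
    contig_meta: pd.DataFrame,
    detect_coverage: float = COVERAGE_DETECT,
    detect_breadth: float = BREADTH_DETECT,
) -> pd.DataFrame:
    """Per-(MAG, sample) coverage, breadth, abundances and detection flag.

    ``alignments`` holds true or mapped read placements (read_id, contig,
    start0, length, sample); ``contig_meta`` maps contig_id to mag_id and
    length. Depth is accumulated per base and aggregated length-weighted
    over each MAG's contigs.
    """
    multi = contig_meta.groupby("contig_id")["mag_id"].nunique()
    if (multi > 1).any():
        raise ValueError(
            "contigs assigned to more than one MAG: "
            f"{sorted(multi[multi > 1].index)}"
        )
    meta = contig_meta.drop_duplicates("contig_id").set_index("contig_id")
    mag_of = meta["mag_id"]
    clen = meta["length"]
    bad = alignments[
        alignments["start0"] + alignments["length"]
        > alignments["contig"].map(clen).fillna(-1)
    ]
    if not alignments.empty and len(bad):
        unknown = sorted(set(bad["contig"]) - set(clen.index))
        if unknown:
            raise KeyError(f"alignments on unknown contigs: {unknown}")
        raise ValueError("alignment positions exceed contig bounds")

    rows = []
    sample_read_counts = alignments.groupby("sample").size()
    for sample, sub in alignments.groupby("sample"):
        # per-contig depth via difference arrays
        depth_sum: dict[str, float] = {}
        covered: dict[str, int] = {}
        for contig, reads in sub.groupby("contig"):
            n = int(clen[contig])
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, reads["start0"].to_numpy(), 1)
            np.add.at(diff, reads["start0"].to_numpy() + reads["length"].to_numpy(), -1)
            depth = np.cumsum(diff[:-1])
            depth_sum[contig] = float(depth.sum())
            covered[contig] = int(np.count_nonzero(depth))
        for mag in sorted(mag_of.unique()):
            contigs = mag_of[mag_of == mag].index
            total_len = float(clen[contigs].sum())
            total_depth = sum(depth_sum.get(c, 0.0) for c in contigs)
            total_cov = sum(covered.get(c, 0) for c in contigs)
            mean_cov = total_depth / total_len
            breadth = total_cov / total_len
            rows.append(
                {
                    "mag_id": mag,
                    "sample": sample,
                    "mean_coverage": mean_cov,
                    "breadth": breadth,
                    "detected": bool(
                        mean_cov > detect_coverage and breadth > detect_breadth
                    ),
                }
            )
    prof = pd.DataFrame(
        rows, columns=["mag_id", "sample", "mean_coverage", "breadth", "detected"]
    )
    if prof.empty:
        prof["relative_abundance"] = []
        prof["normalized_abundance"] = []
        return prof
    role = (
        contig_meta.drop_duplicates("mag_id")[["mag_id", "role"]]
        .set_index("mag_id")["role"]
        if "role" in contig_meta.columns
        else None
    )
    rel = np.full(len(prof), np.nan)
    norm = np.full(len(prof), np.nan)
    for sample, idx in prof.groupby("sample").groups.items():
        block = prof.loc[idx]
        if role is not None:
            micro = block["mag_id"].map(role) == "microbial"
        else:
            micro = pd.Series(True, index=block.index)
        denom = block.loc[micro, "mean_coverage"].sum()
        if denom > 0:
            rel[block.index[micro]] = block.loc[micro, "mean_coverage"] / denom
        n_reads = float(sample_read_counts.get(sample, 0))
        if n_reads > 0 and role is not None:
            viral = block["mag_id"].map(role) == "viral"
            norm[block.index[viral]] = (
                block.loc[viral, "mean_coverage"] / n_reads * 1e6
            )
    prof["relative_abundance"] = rel
    prof["normalized_abundance"] = norm
    return prof


# ---------------------------------------------------------------------------
# diversity and correlation
# ---------------------------------------------------------------------------


def shannon_diversity(abundances) -> float:
    """Shannon index H = -sum p ln p (nats) over positive entries."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all abundances are zero")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def pearson_test(x, y) -> CorrelationResult:
    """Pearson r with the two-sided Student-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = int(x.size)
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, n=n, t_stat=np.inf, df=n - 2, p_two_sided=0.0)
    return CorrelationResult(r=r, n=n, **_t_from_r(r, n))


def _t_from_r(r: float, n: int) -> dict:
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return {"t_stat": float(t), "df": n - 2, "p_two_sided": float(min(1.0, p))}


def p_from_r(r: float, n: int) -> float:
    """Two-sided p-value implied by a printed Pearson coefficient."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("n must be >= 3")
    return _t_from_r(r, n)["p_two_sided"]


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (Bonferroni via method=)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def assemble_report(bundle: dict, outdir: str | Path) -> Path:
    """Write the report directory from upstream module outputs.

    ``bundle`` maps stage names to tables/objects; required stages are
    checked and a missing one raises, naming the stage. A machine-
    readable manifest records seeds and thresholds; the bundle content
    is deterministic for a fixed config and seed.
    """
    required = [
        "clusters",
        "spacers",
        "matches",
        "immunity_edges",
        "normalized",
        "mag_linkages",
        "noise_report",
        "abundance",
        "manifest",
    ]
    for stage in required:
        if stage not in bundle:
            raise KeyError(f"missing upstream output for stage: {stage}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def tsv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")

    tsv("clusters.tsv", bundle["clusters"])
    tsv("spacers.tsv", bundle["spacers"])
    tsv("matches.tsv", bundle["matches"])
    if "flags" in bundle:
        tsv("flags.tsv", bundle["flags"])
    tsv("immunity_network.tsv", bundle["immunity_edges"])
    if "immunity_pruned" in bundle:
        tsv("immunity_pruned.tsv", bundle["immunity_pruned"])
    if "cross_domain" in bundle:
        tsv("cross_domain.tsv", bundle["cross_domain"])
    tsv("normalized.tsv", bundle["normalized"])
    tsv("mag_linkages.tsv", bundle["mag_linkages"])
    nr = bundle["noise_report"]
    tsv("noise_report.tsv", pd.DataFrame([dataclasses.asdict(nr)]))
    tsv("abundance.tsv", bundle["abundance"])
    if "diversity" in bundle:
        tsv("diversity.tsv", bundle["diversity"])
    if "correlations" in bundle:
        tsv("correlations.tsv", bundle["correlations"])
    if "recovery" in bundle:
        tsv("recovery.tsv", bundle["recovery"])
    for name in ("immunity_graph", "hic_graph"):
        if name in bundle:
            import networkx as nx

            nx.write_graphml(bundle[name], outdir / f"{name}.graphml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
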