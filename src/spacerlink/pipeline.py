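"""End-to-end driver: simulate -> mine -> match -> network -> Hi-C -> report."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import crispr_mining, hic_linkage, immunity_network, spacer_matching, stats_report
from .synthetic_community import (
    CommunityConfig,
    CommunityTruth,
    simulate_community,
    simulate_hic_pairs,
    simulate_reads,
)


@dataclass
class PipelineResult:
    truth: CommunityTruth
    reads: list
    alignments: pd.DataFrame
    contacts: pd.DataFrame
    clusters: list
    spacers: pd.DataFrame
    matches: pd.DataFrame
    flags: pd.DataFrame
    edges: pd.DataFrame
    pruned: pd.DataFrame
    cross_domain: pd.DataFrame
    recovery: immunity_network.RecoveryScore
    matrix: hic_linkage.ContactMatrix
    normalized: pd.DataFrame
    linkages: pd.DataFrame
    noise: hic_linkage.NoiseReport
    profiles: pd.DataFrame


def run_pipeline(
    config: CommunityConfig,
    mean_depth: float = 30.0,
    read_len: int = 150,
    error_rate: float = 0.0,
    n_hic_pairs: int = 200_000,
    noise_fraction: float = 0.02,
    min_distinct: int = 2,
    min_count: int = 2,
    max_mismatches: int = 2,
    outdir: str | Path | None = None,
    sample: str = "S1",
) -> PipelineResult:
    """Run the full analysis on a simulated community.

    Sub-seeds for reads and Hi-C pairs are derived deterministically from
    ``config.seed``, so the whole run (and the written report bundle) is
    reproducible byte-for-byte.
    """
    truth = simulate_community(config)
    seed_reads = (config.seed * 1_000_003 + 1) % (2**31)
    seed_hic = (config.seed * 1_000_003 + 2) % (2**31)
    reads, alignments = simulate_reads(
        truth,
        mean_depth=mean_depth,
        read_len=read_len,
        error_rate=error_rate,
        seed=seed_reads,
        sample=sample,
    )
    contacts = simulate_hic_pairs(
        truth,
        n_pairs=n_hic_pairs,
        noise_fraction=noise_fraction,
        seed=seed_hic,
        sample=sample,
    )

    # CRISPR arm
    repeats = crispr_mining.filter_repeats(truth.repeat_records(), min_evidence=4)
    clusters = crispr_mining.cluster_repeats(repeats)
    spacers = crispr_mining.extract_spacers(reads, clusters, sample=sample)
    spacers = crispr_mining.filter_spacers(spacers)
    spacers = crispr_mining.assign_spacer_ids(spacers)
    contig_to_mag = dict(truth.contig_mag)
    viral = truth.viral_contig_seqs()
    matches = spacer_matching.find_protospacers(
        spacers, viral, max_mismatches=max_mismatches
    )
    vmag_map = {c: contig_to_mag[c] for c in viral}
    flags = spacer_matching.flag_multi_target(matches, vmag_map)
    taxonomy = truth.taxonomy_table()
    edges = immunity_network.build_immunity_network(
        matches, spacers, clusters, vmag_map, taxonomy
    )
    pruned = immunity_network.prune_network(edges, min_distinct=min_distinct)
    cross = immunity_network.detect_cross_domain_viruses(edges, taxonomy)
    recovery = immunity_network.score_recovery(
        edges, truth.immunity_pairs(max_mutations=max_mismatches)
    )

    # Hi-C arm
    profiles = stats_report.coverage_profiles(
        alignments,
        truth.contig_table().merge(
            taxonomy[["mag_id", "role"]], on="mag_id", how="left"
        ),
    )
    cov_by_mag = profiles.set_index(["mag_id", "sample"])["mean_coverage"]
    contig_tbl = truth.contig_table()
    meta = pd.DataFrame(
        {
            "contig_id": contig_tbl["contig_id"],
            "mag_id": contig_tbl["mag_id"],
            "length": contig_tbl["length"],
            "coverage": [
                float(cov_by_mag.get((m, sample), 0.0))
                for m in contig_tbl["mag_id"]
            ],
            "sites": contig_tbl["gatc_sites"] + contig_tbl["aatt_sites"],
        }
    )
    matrix = hic_linkage.build_contact_matrix(contacts, meta)
    normalized = hic_linkage.normalize_contacts(matrix, min_count=min_count)
    roles = dict(zip(taxonomy["mag_id"], taxonomy["role"]))
    linkages = hic_linkage.consolidate_linkages(normalized, contig_to_mag, roles)
    noise = hic_linkage.noise_ratios(matrix, contig_to_mag, taxonomy)

    result = PipelineResult(
        truth=truth,
        reads=reads,
        alignments=alignments,
        contacts=contacts,
        clusters=clusters,
        spacers=spacers,
        matches=matches,
        flags=flags,
        edges=edges,
        pruned=pruned,
        cross_domain=cross,
        recovery=recovery,
        matrix=matrix,
        normalized=normalized,
        linkages=linkages,
        noise=noise,
        profiles=profiles,
    )
    if outdir is not None:
        write_report(result, outdir, config, locals_snapshot={
            "mean_depth": mean_depth,
            "read_len": read_len,
            "error_rate": error_rate,
            "n_hic_pairs": n_hic_pairs,
            "noise_fraction": noise_fraction,
            "min_distinct": min_distinct,
            "min_count": min_count,
            "max_mismatches": max_mismatches,
        })
    return result


def _correlation_table(result: PipelineResult) -> pd.DataFrame:
    """vMAG size vs CRISPR host count, BH-adjusted."""
    rows = []
    if not result.edges.empty:
        hosts_per_vmag = result.edges.groupby("vmag_id")["mag_id"].nunique()
        sizes = {
            v: result.truth.genome_length(v)
            for v in result.truth.mag_ids("viral")
        }
        x = [sizes[v] for v in hosts_per_vmag.index]
        y = hosts_per_vmag.to_list()
        if len(x) >= 3 and pd.Series(x).std() > 0 and pd.Series(y).std() > 0:
            res = stats_report.pearson_test(x, y)
            rows.append(
                {
                    "test": "vmag_size_vs_host_count",
                    "r": res.r,
                    "n": res.n,
                    "t_stat": res.t_stat,
                    "df": res.df,
                    "p_two_sided": res.p_two_sided,
                }
            )
    df = pd.DataFrame(
        rows, columns=["test", "r", "n", "t_stat", "df", "p_two_sided"]
    )
    if not df.empty:
        df["p_adjusted"] = stats_report.bh_adjust(df["p_two_sided"].to_numpy())
    else:
        df["p_adjusted"] = []
    return df


def write_report(
    result: PipelineResult,
    outdir: str | Path,
    config: CommunityConfig,
    locals_snapshot: dict | None = None,
) -> Path:
    taxonomy = result.truth.taxonomy_table()
    vmag_lengths = {
        v: result.truth.genome_length(v) for v in result.truth.mag_ids("viral")
    }
    diversity_rows = []
    for sample, sub in result.profiles.groupby("sample"):
        roles = taxonomy.set_index("mag_id")["role"]
        for role_name in ("microbial", "viral"):
            vals = sub[sub["mag_id"].map(roles) == role_name]["mean_coverage"]
            vals = vals[vals > 0]
            if len(vals):
                diversity_rows.append(
                    {
                        "sample": sample,
                        "role": role_name,
                        "shannon_nats": stats_report.shannon_diversity(vals),
                    }
                )
    diversity = pd.DataFrame(diversity_rows, columns=["sample", "role", "shannon_nats"])
    manifest = {
        "package": "spacerlink",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "parameters": locals_snapshot or {},
        "thresholds": {
            "min_evidence": 4,
            "repeat_min_identity": 0.95,
            "spacer_min_len": 26,
            "max_mismatches": (locals_snapshot or {}).get("max_mismatches", 2),
            "min_distinct": (locals_snapshot or {}).get("min_distinct", 2),
            "min_count": (locals_snapshot or {}).get("min_count", 2),
            "detect_coverage": stats_report.COVERAGE_DETECT,
            "detect_breadth": stats_report.BREADTH_DETECT,
        },
    }
    bundle = {
        "clusters": crispr_mining.clusters_table(result.clusters),
        "spacers": result.spacers,
        "matches": result.matches,
        "flags": result.flags,
        "immunity_edges": result.edges,
        "immunity_pruned": result.pruned,
        "cross_domain": result.cross_domain,
        "normalized": result.normalized,
        "mag_linkages": result.linkages,
        "noise_report": result.noise,
        "abundance": result.profiles,
        "diversity": diversity,
        "correlations": _correlation_table(result),
        "recovery": pd.DataFrame([dataclasses.asdict(result.recovery)]),
        "immunity_graph": immunity_network.to_graphml(
            result.edges, taxonomy, vmag_lengths
        ),
        "hic_graph": hic_linkage.to_graphml(
            result.linkages, taxonomy, crispr_edges=result.edges
        ),
        "manifest": manifest,
    }
    return stats_report.assemble_report(bundle, outdir)
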