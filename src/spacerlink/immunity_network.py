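"""CRISPR immunity network construction, pruning and cross-domain calls.

Edges are MAG-level: a host MAG and a viral MAG are connected when at
least one spacer from a population-specific repeat cluster of that host
matches the virus with full coverage within the mismatch budget. Spacers
from repeat clusters shared across MAGs cannot be assigned to a taxon
and are excluded. Edge weight is the number of distinct matching spacer
sequences (multiple spacers = multiple acquisition events).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .crispr_mining import RepeatCluster

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["mag_id", "vmag_id", "n_distinct_matches", "spacer_ids", "samples"]


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    true_edges: int
    predicted_edges: int
    intersection: int


def build_immunity_network(
    matches: pd.DataFrame,
    spacers: pd.DataFrame,
    clusters: list[RepeatCluster],
    contig_to_vmag: dict[str, str],
    taxonomy: pd.DataFrame,
    count_mode: str = "spacer",
) -> pd.DataFrame:
    """Aggregate protospacer matches into MAG-level immunity edges.

    ``count_mode='spacer'`` counts distinct spacer sequences per edge
    (default); ``'locus'`` counts distinct protospacer loci instead.
    Matches whose spacer traces to a repeat cluster spanning more than
    one MAG are dropped (logged), mirroring the shared-repeat exclusion.
    """
    if count_mode not in ("spacer", "locus"):
        raise ValueError("count_mode must be 'spacer' or 'locus'")
    if matches.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    cluster_by_id = {cl.cluster_id: cl for cl in clusters}
    spacer_info = spacers.drop_duplicates("spacer_id").set_index("spacer_id")
    dangling = sorted(set(spacer_info["cluster_id"]) - set(cluster_by_id))
    if dangling:
        raise KeyError(f"spacers reference unknown clusters: {dangling}")
    unmapped = sorted(set(matches["contig"]) - set(contig_to_vmag))
    if unmapped:
        raise KeyError(f"matched contigs without vMAG assignment: {unmapped}")

    sample_by_spacer = spacers.groupby("spacer_id")["sample"].apply(set)
    agg: dict[tuple[str, str], dict] = {}
    n_dropped = 0
    for row in matches.itertuples(index=False):
        cl = cluster_by_id[spacer_info.loc[row.spacer_id, "cluster_id"]]
        if not cl.population_specific:
            n_dropped += 1
            continue
        mag = next(iter(cl.mag_set))
        vmag = contig_to_vmag[row.contig]
        entry = agg.setdefault(
            (mag, vmag),
            {"spacer_ids": set(), "seqs": set(), "loci": set(), "samples": set()},
        )
        entry["spacer_ids"].add(row.spacer_id)
        entry["seqs"].add(row.spacer_seq)
        entry["loci"].add((row.contig, row.start0, row.strand))
        entry["samples"].update(sample_by_spacer.get(row.spacer_id, set()))
    if n_dropped:
        logger.info(
            "dropped %d matches via repeat clusters shared across MAGs", n_dropped
        )
    rows = []
    for (mag, vmag) in sorted(agg):
        entry = agg[(mag, vmag)]
        n = len(entry["seqs"]) if count_mode == "spacer" else len(entry["loci"])
        rows.append(
            {
                "mag_id": mag,
                "vmag_id": vmag,
                "n_distinct_matches": n,
                "spacer_ids": ",".join(sorted(entry["spacer_ids"])),
                "samples": ",".join(sorted(entry["samples"])),
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def prune_network(edges: pd.DataFrame, min_distinct: int = 2) -> pd.DataFrame:
    """Keep edges supported by at least ``min_distinct`` distinct matches."""
    if edges.empty:
        return edges
    return edges[edges["n_distinct_matches"] >= min_distinct].reset_index(drop=True)


def detect_cross_domain_viruses(
    edges: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Viruses whose host set spans both bacteria and archaea."""
    if edges.empty:
        return pd.DataFrame(columns=["vmag_id", "bacterial_hosts", "archaeal_hosts"])
    domain = taxonomy.set_index("mag_id")["domain"]
    missing = sorted(set(edges["mag_id"]) - set(domain.index))
    if missing:
        raise KeyError(f"MAGs lacking a domain assignment: {missing}")
    rows = []
    for vmag, group in edges.groupby("vmag_id"):
        doms = group["mag_id"].map(domain)
        bact = sorted(group.loc[doms == "Bacteria", "mag_id"])
        arch = sorted(group.loc[doms == "Archaea", "mag_id"])
        if bact and arch:
            rows.append(
                {
                    "vmag_id": vmag,
                    "bacterial_hosts": ",".join(bact),
                    "archaeal_hosts": ",".join(arch),
                }
            )
    return pd.DataFrame(
        rows, columns=["vmag_id", "bacterial_hosts", "archaeal_hosts"]
    ).sort_values("vmag_id").reset_index(drop=True)


def score_recovery(
    predicted: set[tuple[str, str]] | pd.DataFrame,
    truth: set[tuple[str, str]],
) -> RecoveryScore:
    """Precision/recall of predicted (MAG, vMAG) pairs against truth.

    An empty prediction has undefined precision; by convention it is
    reported as 1.0 with zero support (warned).
    """
    if isinstance(predicted, pd.DataFrame):
        predicted = set(zip(predicted["mag_id"], predicted["vmag_id"]))
    inter = predicted & truth
    if not predicted:
        if truth:
            logger.warning("empty prediction against non-empty truth")
        precision = 1.0
    else:
        precision = len(inter) / len(predicted)
    recall = 1.0 if not truth else len(inter) / len(truth)
    return RecoveryScore(
        precision=precision,
        recall=recall,
        true_edges=len(truth),
        predicted_edges=len(predicted),
        intersection=len(inter),
    )


def to_graphml(
    edges: pd.DataFrame,
    taxonomy: pd.DataFrame,
    vmag_lengths: dict[str, int] | None = None,
    path=None,
) -> nx.Graph:
    """Bipartite immunity graph with node role/taxonomy attributes."""
    g = nx.Graph()
    tax = taxonomy.set_index("mag_id")
    for row in edges.itertuples(index=False):
        for node in (row.mag_id, row.vmag_id):
            if node not in g:
                attrs = {}
                if node in tax.index:
                    attrs = {
                        "role": tax.loc[node, "role"],
                        "domain": tax.loc[node, "domain"],
                        "phylum": tax.loc[node, "phylum"],
                    }
                if vmag_lengths and node in vmag_lengths:
                    attrs["length"] = int(vmag_lengths[node])
                g.add_node(node, **attrs)
        g.add_edge(
            row.mag_id, row.vmag_id, n_distinct_matches=int(row.n_distinct_matches)
        )
    if path is not None:
        nx.write_graphml(g, path)
    return g
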