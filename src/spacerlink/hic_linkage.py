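"""Hi-C contact matrices, covariate normalization and MAG-level linkage.

Contig-level contact counts are normalized against the known biases of
proximity-ligation signal -- contig length, shotgun coverage and
restriction-site content -- with a log-link Poisson regression over
inter-contig pairs (a simplified, zero-inflation-free variant of
HiCZin-style normalization; pairs below a minimum raw count are excluded
instead). The "strength" of a linkage is the Pearson residual of the
observed count under that model, with dispersion estimated by the method
of moments. Host-virus contig links are consolidated to MAG-vMAG level,
and inter/intra contact ratios quantify the inter-cell noise floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    """Per-sample symmetric contig-pair counts plus contig metadata."""

    counts: pd.DataFrame  # sample, contig_a, contig_b, count (canonical pairs)
    metadata: pd.DataFrame  # contig_id, mag_id, length, coverage, sites

    def total_pairs(self) -> int:
        return int(self.counts["count"].sum())


@dataclass
class NoiseReport:
    raw_noise: float
    relaxed_noise: float
    inter_mag: int
    intra_mag: int
    inter_order: int
    intra_order: int
    dropped: int


def build_contact_matrix(
    pairs: pd.DataFrame, metadata: pd.DataFrame
) -> ContactMatrix:
    """Count canonicalized contig pairs per sample.

    ``pairs`` needs columns contig_a, contig_b, sample; ``metadata``
    needs contig_id, mag_id, length, coverage, sites. Self-pairs are
    retained (they count as intra-cell signal for noise statistics).
    """
    known = set(metadata["contig_id"])
    offenders = sorted(
        (set(pairs["contig_a"]) | set(pairs["contig_b"])) - known
    )
    if offenders:
        raise KeyError(f"contact pairs reference unknown contigs: {offenders}")
    if pairs.empty:
        counts = pd.DataFrame(columns=["sample", "contig_a", "contig_b", "count"])
        return ContactMatrix(counts=counts, metadata=metadata.copy())
    a = pairs["contig_a"].where(pairs["contig_a"] <= pairs["contig_b"], pairs["contig_b"])
    b = pairs["contig_b"].where(pairs["contig_a"] <= pairs["contig_b"], pairs["contig_a"])
    canon = pd.DataFrame({"sample": pairs["sample"], "contig_a": a, "contig_b": b})
    counts = (
        canon.groupby(["sample", "contig_a", "contig_b"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["sample", "contig_a", "contig_b"])
        .reset_index(drop=True)
    )
    return ContactMatrix(counts=counts, metadata=metadata.copy())


def normalize_contacts(matrix: ContactMatrix, min_count: int = 2) -> pd.DataFrame:
    """Fit the covariate model and return normalized inter-contig linkages.

    Per sample, over inter-contig pairs with raw count >= ``min_count``:
    log mu = b0 + b1 log(len_a len_b) + b2 log(cov_a cov_b)
           + b3 log(sites_a sites_b), Poisson fit; variance inflated by a
    method-of-moments dispersion (Poisson fallback when underdispersed).
    Residual = (raw - mu) / sqrt(var(mu)); ratio = raw / mu. Constant or
    collinear covariates are dropped with a warning.
    """
    meta = matrix.metadata.set_index("contig_id")
    length = meta["length"].astype(float)
    coverage = meta["coverage"].astype(float).clip(lower=0.05)
    sites = meta["sites"].astype(float).clip(lower=1.0)
    out = []
    for sample, sub in matrix.counts.groupby("sample"):
        inter = sub[sub["contig_a"] != sub["contig_b"]]
        inter = inter[inter["count"] >= min_count]
        if len(inter) < 10:
            raise ValueError(
                f"sample {sample}: only {len(inter)} eligible inter-contig pairs "
                "(>= 10 required); provide more contact data or lower min_count"
            )
        y = inter["count"].to_numpy(dtype=float)
        la = inter["contig_a"].map(length).to_numpy()
        lb = inter["contig_b"].map(length).to_numpy()
        ca = inter["contig_a"].map(coverage).to_numpy()
        cb = inter["contig_b"].map(coverage).to_numpy()
        sa = inter["contig_a"].map(sites).to_numpy()
        sb = inter["contig_b"].map(sites).to_numpy()
        cols = {
            "log_len": np.log(la * lb),
            "log_cov": np.log(ca * cb),
            "log_sites": np.log(sa * sb),
        }
        keep = {}
        for name, col in cols.items():
            if np.ptp(col) < 1e-12:
                logger.warning("sample %s: covariate %s constant, dropped", sample, name)
            else:
                keep[name] = col
        X = np.column_stack([np.ones(len(y))] + list(keep.values()))
        if keep and np.linalg.matrix_rank(X) < X.shape[1] and "log_sites" in keep:
            logger.warning("sample %s: collinear covariates, dropping site term", sample)
            del keep["log_sites"]
            X = np.column_stack([np.ones(len(y))] + list(keep.values()))
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mu = np.asarray(fit.mu)
        alpha = max(0.0, float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)))
        var = mu + alpha * mu**2
        resid = (y - mu) / np.sqrt(var)
        out.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "contig_a": inter["contig_a"].to_numpy(),
                    "contig_b": inter["contig_b"].to_numpy(),
                    "raw_count": inter["count"].to_numpy(),
                    "expected": mu,
                    "residual": resid,
                    "ratio": y / mu,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def consolidate_linkages(
    normalized: pd.DataFrame,
    contig_to_mag: dict[str, str],
    roles: dict[str, str],
    on_unassigned: str = "warn",
) -> pd.DataFrame:
    """Consolidate host-virus contig links to (MAG, vMAG) level.

    Keeps only (microbial contig, viral contig) pairs and reports, per
    (mag, vmag): the number of distinct contig pairs, mean and max
    residual, and the set of supporting samples. Contigs without a MAG
    are dropped with a warning (``on_unassigned='error'`` raises).
    """
    if normalized.empty:
        return pd.DataFrame(
            columns=[
                "mag_id",
                "vmag_id",
                "n_contig_links",
                "mean_residual",
                "max_residual",
                "samples",
            ]
        )
    df = normalized.copy()
    unassigned = sorted(
        (set(df["contig_a"]) | set(df["contig_b"])) - set(contig_to_mag)
    )
    if unassigned:
        if on_unassigned == "error":
            raise KeyError(f"contigs without MAG assignment: {unassigned}")
        logger.warning("dropping links to %d unbinned contigs", len(unassigned))
        df = df[
            df["contig_a"].isin(contig_to_mag) & df["contig_b"].isin(contig_to_mag)
        ]
    df = df.assign(
        mag_a=df["contig_a"].map(contig_to_mag), mag_b=df["contig_b"].map(contig_to_mag)
    )
    role_a = df["mag_a"].map(roles)
    role_b = df["mag_b"].map(roles)
    hv = df[(role_a == "microbial") & (role_b == "viral")].assign(
        mag_id=lambda d: d["mag_a"], vmag_id=lambda d: d["mag_b"]
    )
    vh = df[(role_a == "viral") & (role_b == "microbial")].assign(
        mag_id=lambda d: d["mag_b"], vmag_id=lambda d: d["mag_a"]
    )
    links = pd.concat([hv, vh], ignore_index=True)
    if links.empty:
        return pd.DataFrame(
            columns=[
                "mag_id",
                "vmag_id",
                "n_contig_links",
                "mean_residual",
                "max_residual",
                "samples",
            ]
        )
    rows = []
    for (mag, vmag), grp in links.groupby(["mag_id", "vmag_id"]):
        rows.append(
            {
                "mag_id": mag,
                "vmag_id": vmag,
                "n_contig_links": int(
                    grp[["contig_a", "contig_b"]].drop_duplicates().shape[0]
                ),
                "mean_residual": float(grp["residual"].mean()),
                "max_residual": float(grp["residual"].max()),
                "samples": ",".join(sorted(set(grp["sample"]))),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["mag_id", "vmag_id"])
        .reset_index(drop=True)
    )


def noise_ratios(
    matrix: ContactMatrix,
    contig_to_mag: dict[str, str],
    taxonomy: pd.DataFrame,
) -> NoiseReport:
    """Inter/intra contact ratios over microbial contigs.

    raw = (# inter-MAG pairs) / (# pairs on the same MAG or contig);
    relaxed = (# pairs across different taxonomic orders) / (# pairs on
    the same contig or within the same order). Viral contigs are
    excluded entirely; pairs touching unbinned contigs are dropped from
    both numerator and denominator.
    """
    role = taxonomy.set_index("mag_id")["role"]
    order = taxonomy.set_index("mag_id")["order"]
    inter_mag = intra_mag = inter_order = intra_order = dropped = 0
    triples = zip(
        matrix.counts["contig_a"], matrix.counts["contig_b"], matrix.counts["count"]
    )
    for ca, cb, n in triples:
        n = int(n)
        mag_a = contig_to_mag.get(ca)
        mag_b = contig_to_mag.get(cb)
        if mag_a is None or mag_b is None:
            dropped += n
            continue
        if role.get(mag_a) != "microbial" or role.get(mag_b) != "microbial":
            dropped += n
            continue
        same_contig = ca == cb
        if same_contig or mag_a == mag_b:
            intra_mag += n
        else:
            inter_mag += n
        if same_contig or order[mag_a] == order[mag_b]:
            intra_order += n
        else:
            inter_order += n
    if intra_mag == 0 or intra_order == 0:
        raise ValueError("zero intra-contact denominator; cannot form noise ratios")
    return NoiseReport(
        raw_noise=inter_mag / intra_mag,
        relaxed_noise=inter_order / intra_order,
        inter_mag=inter_mag,
        intra_mag=intra_mag,
        inter_order=inter_order,
        intra_order=intra_order,
        dropped=dropped,
    )


def residual_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank AUC of positive-labelled scores over negative-labelled ones."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def contacts_from_sam(path: str, sample: str = "S1") -> pd.DataFrame:
    """Convert name-paired SAM alignments into a contact-pair table."""
    import pysam

    ends: dict[str, list[tuple[str, int]]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            ends.setdefault(rec.query_name, []).append(
                (rec.reference_name, int(rec.reference_start))
            )
    rows = []
    for name in sorted(ends):
        hits = ends[name]
        if len(hits) != 2:
            continue
        (ca, pa), (cb, pb) = hits
        if (ca, pa) > (cb, pb):
            (ca, pa), (cb, pb) = (cb, pb), (ca, pa)
        rows.append(
            {
                "contig_a": ca,
                "pos_a": pa,
                "contig_b": cb,
                "pos_b": pb,
                "sample": sample,
            }
        )
    return pd.DataFrame(
        rows, columns=["contig_a", "pos_a", "contig_b", "pos_b", "sample"]
    )


def to_graphml(
    linkages: pd.DataFrame,
    taxonomy: pd.DataFrame,
    crispr_edges: pd.DataFrame | None = None,
    path=None,
) -> nx.Graph:
    """Hi-C linkage graph; edge width field = n_contig_links, darkness
    field = max_residual, with a flag for overlap with CRISPR edges."""
    overlap: set[tuple[str, str]] = set()
    if crispr_edges is not None and not crispr_edges.empty:
        overlap = set(zip(crispr_edges["mag_id"], crispr_edges["vmag_id"]))
    tax = taxonomy.set_index("mag_id")
    g = nx.Graph()
    for row in linkages.itertuples(index=False):
        for node in (row.mag_id, row.vmag_id):
            if node not in g:
                attrs = {}
                if node in tax.index:
                    attrs = {
                        "role": tax.loc[node, "role"],
                        "domain": tax.loc[node, "domain"],
                    }
                g.add_node(node, **attrs)
        g.add_edge(
            row.mag_id,
            row.vmag_id,
            width=int(row.n_contig_links),
            darkness=float(row.max_residual),
            crispr_overlap=(row.mag_id, row.vmag_id) in overlap,
        )
    if path is not None:
        nx.write_graphml(g, path)
    return g
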