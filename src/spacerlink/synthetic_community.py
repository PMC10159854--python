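"""Synthetic host-virus community generator with planted ground truth.

Emulates the statistical structure that downstream CRISPR and Hi-C
host-virus inference assumes: microbial genomes (bacteria + archaea)
carrying CRISPR arrays whose spacers are mutated copies of viral
subsequences, free viral genomes, shotgun reads covering the arrays, and
proximity-ligation contact pairs mixing intra-cell contacts, planted
host-virus infection contacts and random inter-cell noise.

Everything is deterministic for a fixed config/seed, and the generator
emits enough truth (arrays, infections, labels) to score recovery of the
planted interactions.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import count_motif, mutate_substitutions, random_dna, revcomp

_LEADER_LEN = 100
_MIN_CONTIG_LEN = 1500


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of a simulated mat community.

    Counts are numbers of genomes; length ranges are inclusive nucleotide
    intervals; ``abundance_dirichlet_alpha`` controls evenness of the
    relative-abundance draw (larger = more even). ``p_cross_domain_virus``
    is the fraction of viruses designated cross-domain (spacers planted in
    at least one bacterial and one archaeal MAG); ``p_shared_repeat`` is
    the per-array probability that its repeat is a verbatim copy of
    another MAG's repeat. ``infection_rate`` is the fraction of an
    infected host's cellular Hi-C pairs that link to an infecting virus.
    """

    n_bacteria: int = 12
    n_archaea: int = 4
    n_viruses: int = 8
    genome_len_range: tuple[int, int] = (12_000, 20_000)
    virus_len_range: tuple[int, int] = (6_000, 12_000)
    abundance_dirichlet_alpha: float = 10.0
    arrays_per_host: tuple[int, int] = (1, 2)
    spacers_per_array: tuple[int, int] = (4, 8)
    repeat_len: int = 30
    spacer_len_range: tuple[int, int] = (26, 45)
    spacer_mutations_range: tuple[int, int] = (0, 2)
    p_cross_domain_virus: float = 0.25
    p_shared_repeat: float = 0.1
    contigs_per_microbe: tuple[int, int] = (2, 4)
    contigs_per_virus: tuple[int, int] = (1, 2)
    infection_rate: float = 0.2
    infections_per_virus: tuple[int, int] = (1, 2)
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_bacteria", "n_archaea", "n_viruses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "genome_len_range",
            "virus_len_range",
            "arrays_per_host",
            "spacers_per_array",
            "spacer_len_range",
            "spacer_mutations_range",
            "contigs_per_microbe",
            "contigs_per_virus",
            "infections_per_virus",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval is empty: {lo} > {hi}")
        for name in ("p_cross_domain_virus", "p_shared_repeat", "infection_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.abundance_dirichlet_alpha <= 0:
            raise ValueError("abundance_dirichlet_alpha must be positive")
        if self.spacer_len_range[0] <= 25:
            # planted spacers must survive the >25 nt length filter
            raise ValueError("spacer_len_range minimum must be > 25")
        if self.repeat_len < 18:
            raise ValueError("repeat_len must be >= 18")
        if self.n_viruses > 0 and self.spacer_len_range[1] > self.virus_len_range[0]:
            raise ValueError("longest spacer exceeds shortest virus genome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunityConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


@dataclass
class PlantedSpacer:
    seq: str
    source_virus: str
    source_start: int
    source_strand: str
    n_mutations: int


@dataclass
class PlantedArray:
    array_id: str
    mag_id: str
    repeat_seq: str
    contig_id: str
    start: int  # 0-based position of the leader in the final contig
    spacers: list[PlantedSpacer]
    evidence_level: int = 4
    is_anchor: bool = False


@dataclass
class Infection:
    mag_id: str
    virus_id: str
    intensity: float


@dataclass
class CommunityTruth:
    """Planted community: genomes, arrays, infections and taxonomy."""

    config: CommunityConfig
    contig_seqs: dict[str, str]  # contig_id -> sequence
    contig_order: list[str]
    contig_mag: dict[str, str]
    mag_contigs: dict[str, list[str]]  # in genome order
    mags: pd.DataFrame  # mag_id, role, domain, phylum, class_, order
    arrays: list[PlantedArray]
    infections: list[Infection]
    abundances: dict[str, float]
    cross_domain_viruses: list[str]

    # ------------------------------------------------------------------ views

    def mag_ids(self, role: str | None = None) -> list[str]:
        df = self.mags
        if role is not None:
            df = df[df["role"] == role]
        return list(df["mag_id"])

    def genome_length(self, mag_id: str) -> int:
        return sum(len(self.contig_seqs[c]) for c in self.mag_contigs[mag_id])

    def contig_table(self) -> pd.DataFrame:
        rows = []
        for cid in self.contig_order:
            seq = self.contig_seqs[cid]
            rows.append(
                {
                    "contig_id": cid,
                    "mag_id": self.contig_mag[cid],
                    "length": len(seq),
                    "gatc_sites": count_motif(seq, "GATC"),
                    "aatt_sites": count_motif(seq, "AATT"),
                }
            )
        return pd.DataFrame(
            rows, columns=["contig_id", "mag_id", "length", "gatc_sites", "aatt_sites"]
        )

    def arrays_table(self) -> pd.DataFrame:
        rows = []
        for arr in self.arrays:
            for i, sp in enumerate(arr.spacers):
                rows.append(
                    {
                        "array_id": arr.array_id,
                        "mag_id": arr.mag_id,
                        "contig_id": arr.contig_id,
                        "repeat_seq": arr.repeat_seq,
                        "evidence_level": arr.evidence_level,
                        "spacer_index": i,
                        "spacer_seq": sp.seq,
                        "source_virus": sp.source_virus,
                        "source_start": sp.source_start,
                        "source_strand": sp.source_strand,
                        "n_mutations": sp.n_mutations,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "array_id",
                "mag_id",
                "contig_id",
                "repeat_seq",
                "evidence_level",
                "spacer_index",
                "spacer_seq",
                "source_virus",
                "source_start",
                "source_strand",
                "n_mutations",
            ],
        )

    def infections_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(i) for i in self.infections],
            columns=["mag_id", "virus_id", "intensity"],
        )

    def repeat_records(self) -> pd.DataFrame:
        """One repeat record per planted array (crispr_mining input)."""
        return pd.DataFrame(
            [
                {
                    "mag_id": a.mag_id,
                    "repeat_seq": a.repeat_seq,
                    "evidence_level": a.evidence_level,
                }
                for a in self.arrays
            ],
            columns=["mag_id", "repeat_seq", "evidence_level"],
        )

    def viral_contig_seqs(self) -> dict[str, str]:
        return {
            c: self.contig_seqs[c]
            for c in self.contig_order
            if self.contig_mag[c] in set(self.mag_ids("viral"))
        }

    def shared_repeat_mags(self) -> dict[str, set[str]]:
        by_repeat: dict[str, set[str]] = {}
        for arr in self.arrays:
            by_repeat.setdefault(arr.repeat_seq, set()).add(arr.mag_id)
        return by_repeat

    def immunity_pairs(
        self, max_mutations: int = 2, specific_only: bool = True
    ) -> set[tuple[str, str]]:
        """Planted (host MAG, virus) pairs recoverable by the method.

        ``specific_only`` drops pairs whose only evidence sits in arrays
        with a repeat shared across MAGs (the method excludes those);
        ``max_mutations`` drops spacers mutated beyond the matcher budget.
        """
        shared = {r for r, mags in self.shared_repeat_mags().items() if len(mags) > 1}
        pairs: set[tuple[str, str]] = set()
        for arr in self.arrays:
            if specific_only and arr.repeat_seq in shared:
                continue
            for sp in arr.spacers:
                if sp.n_mutations <= max_mutations:
                    pairs.add((arr.mag_id, sp.source_virus))
        return pairs

    def taxonomy_table(self) -> pd.DataFrame:
        return self.mags.copy()

    # ------------------------------------------------------ closed-form noise

    def expected_noise_ratios(
        self, noise_fraction: float, infection_rate: float | None = None
    ) -> tuple[float, float]:
        """Closed-form expectation of the (raw, relaxed) noise ratios.

        Under uniform end placement, a noise pair lands in microbial MAG M
        with probability proportional to M's total contig length; cellular
        pairs contribute to the intra terms through host abundances, net of
        the fraction redirected to infecting viruses (those pairs have a
        viral end and are excluded from the microbial-only ratios).
        """
        if infection_rate is None:
            infection_rate = self.config.infection_rate
        f = noise_fraction
        total_len = sum(len(s) for s in self.contig_seqs.values())
        micro = [m for m in self.mag_ids() if m in set(self.mag_ids("microbial"))]
        mag_len = {m: self.genome_length(m) for m in micro}
        order_of = dict(zip(self.mags["mag_id"], self.mags["order"]))
        order_len: dict[str, float] = {}
        for m in micro:
            order_len[order_of[m]] = order_len.get(order_of[m], 0.0) + mag_len[m]
        lm = sum(mag_len.values())
        q_mm_total = (lm / total_len) ** 2
        q_mag_intra = sum((v / total_len) ** 2 for v in mag_len.values())
        q_order_intra = sum((v / total_len) ** 2 for v in order_len.values())
        infected = {i.mag_id for i in self.infections}
        cellular_intra = sum(
            self.abundances[m] * (1.0 - (infection_rate if m in infected else 0.0))
            for m in micro
        )
        raw_num = f * (q_mm_total - q_mag_intra)
        raw_den = (1 - f) * cellular_intra + f * q_mag_intra
        rel_num = f * (q_mm_total - q_order_intra)
        rel_den = (1 - f) * cellular_intra + f * q_order_intra
        return raw_num / raw_den, rel_num / rel_den

    def expected_intra_mag_fraction(self) -> float:
        """P(both uniform ends fall in the same MAG); all contigs, all roles."""
        total = sum(len(s) for s in self.contig_seqs.values())
        return sum(
            (self.genome_length(m) / total) ** 2 for m in self.mag_contigs
        )


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------


def _split_lengths(rng: np.random.Generator, total: int, n_parts: int) -> list[int]:
    """Random partition of ``total`` into parts of >= _MIN_CONTIG_LEN."""
    if n_parts == 1 or total < 2 * _MIN_CONTIG_LEN * n_parts:
        return [total]
    for _ in range(20):
        props = rng.dirichlet(np.ones(n_parts))
        parts = np.maximum(1, np.round(props * total).astype(int))
        parts[-1] = total - int(parts[:-1].sum())
        if (parts >= _MIN_CONTIG_LEN).all():
            return [int(x) for x in parts]
    base = total // n_parts
    parts = [base] * (n_parts - 1) + [total - base * (n_parts - 1)]
    return parts


def _assign_lineages(
    rng: np.random.Generator, mag_ids: list[str], domain: str
) -> dict[str, tuple[str, str, str]]:
    """Random phylum/class/order lineages with deliberate order sharing."""
    n = len(mag_ids)
    n_lineages = max(1, int(round(n * 0.6)))
    tag = domain[0].lower()
    lineages = [
        (
            f"{tag}_phy{1 + i // 4}",
            f"{tag}_cls{1 + i // 2}",
            f"{tag}_ord{1 + i}",
        )
        for i in range(n_lineages)
    ]
    picks = rng.integers(0, n_lineages, size=n)
    return {m: lineages[picks[i]] for i, m in enumerate(mag_ids)}


def simulate_community(config: CommunityConfig) -> CommunityTruth:
    """Generate genomes, CRISPR arrays, taxonomy, abundances and infections."""
    rng = np.random.default_rng(config.seed)
    bact = [f"bMAG_{i + 1:02d}" for i in range(config.n_bacteria)]
    arch = [f"aMAG_{i + 1:02d}" for i in range(config.n_archaea)]
    viruses = [f"vMAG_{i + 1:02d}" for i in range(config.n_viruses)]
    hosts = bact + arch
    if not hosts and not viruses:
        raise ValueError("empty community: no genomes requested")

    # --- viral genomes ------------------------------------------------------
    virus_len = {
        v: int(rng.integers(config.virus_len_range[0], config.virus_len_range[1] + 1))
        for v in viruses
    }
    virus_seq = {v: random_dna(rng, virus_len[v]) for v in viruses}

    # --- cross-domain designation and per-domain virus pools ----------------
    n_cross = int(round(config.p_cross_domain_virus * config.n_viruses))
    n_cross = min(n_cross, config.n_viruses)
    cross: list[str] = []
    if n_cross and bact and arch:
        cross = sorted(rng.choice(viruses, size=n_cross, replace=False).tolist())
    home_domain: dict[str, str] = {}
    for v in viruses:
        if v in cross:
            continue
        p_b = len(bact) / max(1, len(hosts))
        home_domain[v] = "Bacteria" if rng.random() < p_b else "Archaea"
    pool = {
        "Bacteria": cross + [v for v in viruses if home_domain.get(v) == "Bacteria"],
        "Archaea": cross + [v for v in viruses if home_domain.get(v) == "Archaea"],
    }

    # --- plan arrays --------------------------------------------------------
    domain_of = {m: "Bacteria" for m in bact} | {m: "Archaea" for m in arch}
    planned: list[PlantedArray] = []
    arrays_by_host: dict[str, list[PlantedArray]] = {}
    array_counter = 0
    for m in hosts:
        n_arrays = int(
            rng.integers(config.arrays_per_host[0], config.arrays_per_host[1] + 1)
        )
        arrays_by_host[m] = []
        for _ in range(n_arrays):
            array_counter += 1
            arr = PlantedArray(
                array_id=f"arr_{array_counter:03d}",
                mag_id=m,
                repeat_seq="",
                contig_id="",
                start=-1,
                spacers=[],
            )
            n_sp = int(
                rng.integers(
                    config.spacers_per_array[0], config.spacers_per_array[1] + 1
                )
            )
            arr.spacers = [None] * n_sp  # slots, filled below
            planned.append(arr)
            arrays_by_host[m].append(arr)

    def draw_spacer(source: str) -> PlantedSpacer:
        vlen = virus_len[source]
        length = int(
            rng.integers(config.spacer_len_range[0], config.spacer_len_range[1] + 1)
        )
        if length > vlen:
            raise ValueError(f"spacer length {length} exceeds virus {source} length")
        start = int(rng.integers(0, vlen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        proto = virus_seq[source][start : start + length]
        if strand == "-":
            proto = revcomp(proto)
        n_mut = int(
            rng.integers(
                config.spacer_mutations_range[0], config.spacer_mutations_range[1] + 1
            )
        )
        return PlantedSpacer(
            seq=mutate_substitutions(rng, proto, n_mut),
            source_virus=source,
            source_start=start,
            source_strand=strand,
            n_mutations=n_mut,
        )

    if viruses:
        # anchor spacers guaranteeing each cross-domain virus hits both domains
        for v in cross:
            for dom_hosts in (bact, arch):
                host = dom_hosts[int(rng.integers(0, len(dom_hosts)))]
                arr = arrays_by_host[host][
                    int(rng.integers(0, len(arrays_by_host[host])))
                ]
                arr.is_anchor = True
                n_anchor = min(2, len(arr.spacers))
                for slot in range(n_anchor):
                    if arr.spacers[slot] is None:
                        arr.spacers[slot] = draw_spacer(v)
        # fill the remaining slots from the host domain's virus pool
        for arr in planned:
            allowed = pool[domain_of[arr.mag_id]]
            for slot in range(len(arr.spacers)):
                if arr.spacers[slot] is None:
                    if not allowed:
                        continue
                    source = allowed[int(rng.integers(0, len(allowed)))]
                    arr.spacers[slot] = draw_spacer(source)
        for arr in planned:
            arr.spacers = [s for s in arr.spacers if s is not None]
    else:
        for arr in planned:
            arr.spacers = []
    planned = [a for a in planned if a.spacers]

    # --- repeats (unique, then optional verbatim sharing) -------------------
    seen_repeats: set[str] = set()
    for arr in planned:
        rep = random_dna(rng, config.repeat_len)
        while rep in seen_repeats:
            rep = random_dna(rng, config.repeat_len)
        seen_repeats.add(rep)
        arr.repeat_seq = rep
    non_anchor = [a for a in planned if not a.is_anchor]
    for arr in non_anchor:
        if rng.random() < config.p_shared_repeat:
            donors = [a for a in non_anchor if a.mag_id != arr.mag_id and a is not arr]
            if donors:
                donor = donors[int(rng.integers(0, len(donors)))]
                arr.repeat_seq = donor.repeat_seq

    # --- microbial contigs with arrays spliced in ---------------------------
    contig_seqs: dict[str, str] = {}
    contig_order: list[str] = []
    contig_mag: dict[str, str] = {}
    mag_contigs: dict[str, list[str]] = {}
    for m in hosts:
        glen = int(
            rng.integers(config.genome_len_range[0], config.genome_len_range[1] + 1)
        )
        n_c = int(
            rng.integers(config.contigs_per_microbe[0], config.contigs_per_microbe[1] + 1)
        )
        parts = _split_lengths(rng, glen, n_c)
        cids = [f"{m}_c{j + 1}" for j in range(len(parts))]
        mag_contigs[m] = cids
        base = {cid: random_dna(rng, plen) for cid, plen in zip(cids, parts)}
        # assign this host's arrays to contigs, length-weighted
        host_arrays = [a for a in planned if a.mag_id == m]
        weights = np.array(parts, dtype=float)
        weights /= weights.sum()
        per_contig: dict[str, list[PlantedArray]] = {cid: [] for cid in cids}
        for arr in host_arrays:
            cid = cids[int(rng.choice(len(cids), p=weights))]
            per_contig[cid].append(arr)
        for cid in cids:
            seq = base[cid]
            todo = per_contig[cid]
            if todo:
                margin = 50
                offsets = sorted(
                    int(rng.integers(margin, len(seq) - margin + 1))
                    for _ in range(len(todo))
                )
                shift = 0
                pieces = []
                prev = 0
                for arr, off in zip(todo, offsets):
                    arr_seq = (
                        random_dna(rng, _LEADER_LEN)
                        + "".join(arr.repeat_seq + sp.seq for sp in arr.spacers)
                        + arr.repeat_seq
                    )
                    pieces.append(seq[prev:off])
                    arr.contig_id = cid
                    arr.start = off + shift
                    pieces.append(arr_seq)
                    shift += len(arr_seq)
                    prev = off
                pieces.append(seq[prev:])
                seq = "".join(pieces)
            contig_seqs[cid] = seq
            contig_order.append(cid)
            contig_mag[cid] = m

    # --- viral contigs: split avoiding planted protospacer intervals --------
    source_intervals: dict[str, list[tuple[int, int]]] = {v: [] for v in viruses}
    for arr in planned:
        for sp in arr.spacers:
            source_intervals[sp.source_virus].append(
                (sp.source_start, sp.source_start + len(sp.seq))
            )
    for v in viruses:
        n_c = int(
            rng.integers(config.contigs_per_virus[0], config.contigs_per_virus[1] + 1)
        )
        vlen = virus_len[v]
        cuts: list[int] = []
        if n_c > 1 and vlen >= 2 * _MIN_CONTIG_LEN * n_c:
            forbidden = source_intervals[v]
            for _ in range(50):
                cand = sorted(
                    int(rng.integers(_MIN_CONTIG_LEN, vlen - _MIN_CONTIG_LEN + 1))
                    for _ in range(n_c - 1)
                )
                bounds = [0] + cand + [vlen]
                seg_ok = all(
                    bounds[i + 1] - bounds[i] >= _MIN_CONTIG_LEN
                    for i in range(len(bounds) - 1)
                )
                cut_ok = all(
                    not (s < c < e) for c in cand for (s, e) in forbidden
                )
                if seg_ok and cut_ok:
                    cuts = cand
                    break
        bounds = [0] + cuts + [vlen]
        cids = [f"{v}_c{j + 1}" for j in range(len(bounds) - 1)]
        mag_contigs[v] = cids
        for j, cid in enumerate(cids):
            contig_seqs[cid] = virus_seq[v][bounds[j] : bounds[j + 1]]
            contig_order.append(cid)
            contig_mag[cid] = v

    # --- taxonomy -----------------------------------------------------------
    lineage = _assign_lineages(rng, bact, "Bacteria") | _assign_lineages(
        rng, arch, "Archaea"
    )
    rows = []
    for m in hosts:
        phy, cls, order = lineage[m]
        rows.append(
            {
                "mag_id": m,
                "role": "microbial",
                "domain": domain_of[m],
                "phylum": phy,
                "class_": cls,
                "order": order,
            }
        )
    for v in viruses:
        rows.append(
            {
                "mag_id": v,
                "role": "viral",
                "domain": "Viruses",
                "phylum": "NA",
                "class_": "NA",
                "order": "NA",
            }
        )
    mags = pd.DataFrame(
        rows, columns=["mag_id", "role", "domain", "phylum", "class_", "order"]
    )

    # --- abundances and infections ------------------------------------------
    all_mags = hosts + viruses
    abund = rng.dirichlet(
        np.full(len(all_mags), config.abundance_dirichlet_alpha)
    )
    abundances = dict(zip(all_mags, abund.tolist()))
    infections: list[Infection] = []
    if hosts:
        for v in viruses:
            k = int(
                rng.integers(
                    config.infections_per_virus[0], config.infections_per_virus[1] + 1
                )
            )
            k = min(k, len(hosts))
            chosen = rng.choice(hosts, size=k, replace=False)
            for h in sorted(chosen.tolist()):
                infections.append(
                    Infection(
                        mag_id=h,
                        virus_id=v,
                        intensity=float(rng.lognormal(0.0, 0.5)),
                    )
                )

    return CommunityTruth(
        config=config,
        contig_seqs=contig_seqs,
        contig_order=contig_order,
        contig_mag=contig_mag,
        mag_contigs=mag_contigs,
        mags=mags,
        arrays=planned,
        infections=infections,
        abundances=abundances,
        cross_domain_viruses=cross,
    )


# ---------------------------------------------------------------------------
# shotgun reads
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: CommunityTruth,
    mean_depth: float = 30.0,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    sample: str = "S1",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads uniformly per contig at abundance-weighted depth.

    Returns ``(reads, alignments)`` where reads are ``(read_id, seq)`` and
    the alignment table gives the true origin of every read (contig,
    0-based start, strand), so coverage can be computed without a mapper.
    """
    cfg = truth.config
    max_spacer = cfg.spacer_len_range[1]
    if read_len < 2 * cfg.repeat_len + max_spacer:
        warnings.warn(
            "read_len below 2*repeat_len + max spacer length; "
            "repeat-anchored spacer mining will miss long spacers",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_genomes = len(truth.mag_contigs)
    reads: list[tuple[str, str]] = []
    aln_rows = []
    k = 0
    for m in truth.mag_contigs:
        depth = mean_depth * truth.abundances[m] * n_genomes
        for cid in truth.mag_contigs[m]:
            seq = truth.contig_seqs[cid]
            if len(seq) < read_len:
                continue
            n_reads = int(round(depth * len(seq) / read_len))
            starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            for s, minus in zip(starts, strands):
                r = seq[s : s + read_len]
                strand = "-" if minus else "+"
                if minus:
                    r = revcomp(r)
                if error_rate > 0:
                    n_err = rng.binomial(read_len, error_rate)
                    if n_err:
                        r = mutate_substitutions(rng, r, n_err)
                rid = f"{sample}:r{k:07d}"
                k += 1
                reads.append((rid, r))
                aln_rows.append(
                    {
                        "read_id": rid,
                        "contig": cid,
                        "start0": int(s),
                        "strand": strand,
                        "length": read_len,
                        "sample": sample,
                    }
                )
    alignments = pd.DataFrame(
        aln_rows, columns=["read_id", "contig", "start0", "strand", "length", "sample"]
    )
    return reads, alignments


# ---------------------------------------------------------------------------
# Hi-C contact pairs
# ---------------------------------------------------------------------------


def simulate_hic_pairs(
    truth: CommunityTruth,
    n_pairs: int,
    noise_fraction: float = 0.02,
    seed: int = 0,
    infection_rate: float | None = None,
    sample: str = "S1",
) -> pd.DataFrame:
    """Simulate labelled proximity-ligation contact pairs.

    With probability ``noise_fraction`` both ends are uniform over all
    contig positions (label ``noise``); otherwise a genome is chosen
    abundance-weighted and both ends placed uniformly within it (label
    ``intra``), except that an infected host redirects a fraction
    ``infection_rate`` of its cellular pairs so one end falls on an
    infecting virus, weighted by infection intensity (label ``infection``).
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not truth.mag_contigs:
        raise ValueError("empty community")
    if infection_rate is None:
        infection_rate = truth.config.infection_rate
    rng = np.random.default_rng(seed)

    contigs = truth.contig_order
    lengths = np.array([len(truth.contig_seqs[c]) for c in contigs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cum[-1])
    mag_list = list(truth.mag_contigs)
    mag_index = {m: i for i, m in enumerate(mag_list)}
    # per-genome contig spans for mapping genome positions to contigs
    g_contigs = {m: truth.mag_contigs[m] for m in mag_list}
    g_cum = {
        m: np.concatenate(
            [[0], np.cumsum([len(truth.contig_seqs[c]) for c in g_contigs[m]])]
        )
        for m in mag_list
    }
    abund = np.array([truth.abundances[m] for m in mag_list])
    abund = abund / abund.sum()
    infections_by_host: dict[str, list[Infection]] = {}
    for inf in truth.infections:
        infections_by_host.setdefault(inf.mag_id, []).append(inf)

    def global_to_contig(gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(cum, gpos, side="right") - 1
        return idx, gpos - cum[idx]

    def genome_pos_to_contig(m: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cc = g_cum[m]
        idx = np.searchsorted(cc, pos, side="right") - 1
        return idx, pos - cc[idx]

    u = rng.random(n_pairs)
    is_noise = u < noise_fraction
    n_noise = int(is_noise.sum())
    n_cell = n_pairs - n_noise

    rows_a_contig: list[str] = []
    rows_a_pos: list[int] = []
    rows_b_contig: list[str] = []
    rows_b_pos: list[int] = []
    rows_label: list[str] = []

    # noise pairs
    if n_noise:
        ga = rng.integers(0, total, size=n_noise)
        gb = rng.integers(0, total, size=n_noise)
        ia, oa = global_to_contig(ga)
        ib, ob = global_to_contig(gb)
        for j in range(n_noise):
            rows_a_contig.append(contigs[ia[j]])
            rows_a_pos.append(int(oa[j]))
            rows_b_contig.append(contigs[ib[j]])
            rows_b_pos.append(int(ob[j]))
            rows_label.append("noise")

    # cellular pairs
    if n_cell:
        genome_pick = rng.choice(len(mag_list), size=n_cell, p=abund)
        inf_draw = rng.random(n_cell)
        for j in range(n_cell):
            m = mag_list[genome_pick[j]]
            glen = truth.genome_length(m)
            infs = infections_by_host.get(m)
            if infs and inf_draw[j] < infection_rate:
                weights = np.array([i.intensity for i in infs])
                weights = weights / weights.sum()
                virus = infs[int(rng.choice(len(infs), p=weights))].virus_id
                vlen = truth.genome_length(virus)
                pa = np.array([rng.integers(0, glen)])
                pb = np.array([rng.integers(0, vlen)])
                ia, oa = genome_pos_to_contig(m, pa)
                ib, ob = genome_pos_to_contig(virus, pb)
                rows_a_contig.append(g_contigs[m][int(ia[0])])
                rows_a_pos.append(int(oa[0]))
                rows_b_contig.append(g_contigs[virus][int(ib[0])])
                rows_b_pos.append(int(ob[0]))
                rows_label.append("infection")
            else:
                pa = np.array([rng.integers(0, glen)])
                pb = np.array([rng.integers(0, glen)])
                ia, oa = genome_pos_to_contig(m, pa)
                ib, ob = genome_pos_to_contig(m, pb)
                rows_a_contig.append(g_contigs[m][int(ia[0])])
                rows_a_pos.append(int(oa[0]))
                rows_b_contig.append(g_contigs[m][int(ib[0])])
                rows_b_pos.append(int(ob[0]))
                rows_label.append("intra")

    df = pd.DataFrame(
        {
            "contig_a": rows_a_contig,
            "pos_a": rows_a_pos,
            "contig_b": rows_b_contig,
            "pos_b": rows_b_pos,
            "sample": sample,
            "truth_label": rows_label,
        }
    )
    # canonical unordered pair: lexicographically smaller contig id first
    swap = (df["contig_a"] > df["contig_b"]) | (
        (df["contig_a"] == df["contig_b"]) & (df["pos_a"] > df["pos_b"])
    )
    for col_a, col_b in (("contig_a", "contig_b"), ("pos_a", "pos_b")):
        a = df[col_a].where(~swap, df[col_b])
        b = df[col_b].where(~swap, df[col_a])
        df[col_a], df[col_b] = a, b
    return df


def label_host_virus_contig_pairs(
    contacts: pd.DataFrame, truth: CommunityTruth
) -> pd.DataFrame:
    """Majority truth label for each (host contig, viral contig) pair.

    Returns one row per canonical host-virus contig pair with
    ``is_infection`` true when at least half of its contacts carry the
    ``infection`` label (the rest being stray inter-cell noise).
    """
    roles = dict(zip(truth.mags["mag_id"], truth.mags["role"]))
    df = contacts.copy()
    ra = df["contig_a"].map(truth.contig_mag).map(roles)
    rb = df["contig_b"].map(truth.contig_mag).map(roles)
    hv = df[((ra == "microbial") & (rb == "viral")) | ((ra == "viral") & (rb == "microbial"))]
    lab = (
        hv.groupby(["contig_a", "contig_b"])["truth_label"]
        .agg(lambda s: (s == "infection").mean() >= 0.5)
        .rename("is_infection")
        .reset_index()
    )
    return lab


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, seed: int | None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_community(truth: CommunityTruth, outdir: str | Path) -> None:
    """Write genomes.fasta, truth tables, taxonomy and MAG membership."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = truth.config.seed
    with open(outdir / "genomes.fasta", "w") as fh:
        for cid in truth.contig_order:
            fh.write(f">{truth.contig_mag[cid]}|{cid} seed={seed}\n")
            seq = truth.contig_seqs[cid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    _write_tsv(truth.arrays_table(), outdir / "truth_arrays.tsv", seed)
    _write_tsv(truth.infections_table(), outdir / "truth_infections.tsv", seed)
    _write_tsv(truth.taxonomy_table(), outdir / "taxonomy.tsv", seed)
    _write_tsv(truth.repeat_records(), outdir / "repeats.tsv", seed)
    contig_df = truth.contig_table()
    _write_tsv(contig_df, outdir / "contigs.tsv", seed)
    _write_tsv(
        contig_df[["contig_id", "mag_id"]], outdir / "mags.tsv", seed
    )
    abund = pd.DataFrame(
        {"mag_id": list(truth.abundances), "abundance": list(truth.abundances.values())}
    )
    _write_tsv(abund, outdir / "abundances.tsv", seed)


def write_reads(
    reads: list[tuple[str, str]],
    alignments: pd.DataFrame,
    outdir: str | Path,
    seed: int | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "reads.fastq", "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    _write_tsv(alignments, outdir / "truth_alignments.tsv", seed)


def write_contacts(
    contacts: pd.DataFrame, outdir: str | Path, seed: int | None = None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(contacts, outdir / "contacts.tsv", seed)
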