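# Methods

## Problem setting

In dense microbial mats and biofilms, viruses interact with
phylogenetically diverse hosts, up to the domain level. Two observable
footprints of those interactions survive in metagenomes: CRISPR spacers
(a sequence record of past encounters, attributable to a host via the
repeat flanking them) and Hi-C proximity-ligation contacts (a snapshot
of physical co-location, including intracellular viral DNA). spacerlink
implements both inference arms and a simulator that plants known
interactions so the arms can be scored.

## CRISPR arm

**Repeat evidence and clustering.** Only repeats from arrays at
evidence level 4 (the detection tools' highest-confidence call) enter
the analysis. Distinct repeat sequences are clustered greedily:
sequences sorted by (descending occurrence count, lexicographic) join
the first centroid whose identity, `1 − editDistance/max(len)` taken
over both strands, exceeds 0.95, else found a new cluster. Edit (not
Hamming) distance is used because repeat boundary calls differ by ±1 nt
between detection tools. The deterministic sort key makes clustering
invariant to input order. A cluster whose members span more than one
MAG is retained through mining but flagged non-population-specific;
its spacers are excluded at network construction, since they cannot be
assigned to a taxon.

**Spacer mining from reads.** Spacers are extracted directly from
shotgun reads, not from assemblies (arrays assemble poorly). For each
read and its reverse complement, occurrences of each cluster centroid
with Hamming distance ≤ 2 are located by pigeonhole search (the
centroid is covered by three disjoint equal chunks; any in-budget
occurrence contains one exact chunk, found via a k-mer lookup, then
verified). When two non-overlapping occurrences of the same centroid
flank an interval of 20–60 nt, the interval is emitted as a spacer;
trailing partials at read ends are not. Spacers shorter than 26 nt are
then filtered out (the strictly-greater-than-25 rule). The spacer is
reported on the strand where the centroid matched forward; protospacer
search is strand-symmetric, so the choice is a convention.

**Protospacer matching.** A high-confidence match is 100% query
coverage with at most 2 substitutions, on either strand. Because full
coverage excludes gaps, matching is Hamming-based; indel-containing
hits that a gapped local aligner could report are deliberately out of
scope. The production matcher uses pigeonhole chunking against a k-mer
index of the viral contigs (chunk length `min_spacer_len // 3`, which
preserves the pigeonhole guarantee since three disjoint chunks cannot
all contain one of ≤2 mismatches); a brute-force sliding Hamming scan
with early exit serves as an independent oracle in the tests, and the
two are asserted set-equal on randomized instances. Spacers matching
≥2 viral MAGs are flagged (non-unique target regions) but retained.

**Network rules.** An immunity edge connects a host MAG and a viral MAG
when at least one spacer from one of the host's population-specific
clusters matches the virus. Edge weight is the number of *distinct
spacer sequences* (each spacer is an independent acquisition event);
counting distinct protospacer loci instead is available via
`count_mode="locus"`. The pruned view keeps edges with ≥2 distinct
matches. Cross-domain viruses are those whose host set spans Bacteria
and Archaea, evaluated on the unpruned network by default (single
strong spacer matches still witness an encounter).

## Hi-C arm

**Counting.** Mapped contact pairs are canonicalized (lexicographically
smaller contig first) and counted per sample. Self-pairs count as
intra-cell signal for noise statistics but are excluded from
normalization, which needs covariate contrast.

**Normalization.** Hi-C counts scale with contig length, shotgun
coverage (copy number) and restriction-site density. Over inter-contig
pairs with raw count ≥ 2, a Poisson GLM with log link fits
`log μ = β₀ + β₁ log(ℓ_aℓ_b) + β₂ log(c_ac_b) + β₃ log(s_as_b)`;
dispersion α is then estimated by method of moments
(`α = max(0, Σ[(y−μ)² − μ]/Σμ²)`, Poisson fallback when
underdispersed) and the linkage strength is the Pearson residual
`(y − μ)/√(μ + αμ²)`. The ratio `y/μ` is also emitted for users who
prefer normalized counts. This is a simplified stand-in for
zero-inflated count normalization: instead of modelling unobserved
pairs, pairs below the minimum count are excluded — equivalent in
effect at these scales and far simpler to fit deterministically.
Constant covariates (e.g. equal coverage everywhere in a simulation)
are dropped with a warning; a collinear site term is dropped likewise.
Fits are per sample; consolidation unions samples with provenance.

**Consolidation and noise.** Host–virus contig links aggregate to
(MAG, vMAG) with the number of distinct contig pairs, mean residual and
max residual (mean is over signed residuals and may exceed neither
bound; max is exact). The noise floor uses microbial contigs only:
`raw = inter-MAG / intra-MAG` and `relaxed = inter-order / intra-order`
contact ratios, where intra includes same-contig pairs and pairs
touching viral or unbinned contigs are excluded from both numerator and
denominator. Relaxed ≤ raw by construction (the numerator shrinks and
the denominator grows when MAG boundaries widen to order boundaries).
No residual threshold is asserted for calling a "linkage"; thresholds
are exposed, not baked in.

## Synthetic community generator

The generator emulates the statistical structure the analysis assumes,
not sequencing realism. Defaults define the study conditions used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_bacteria / n_archaea / n_viruses | 12 / 4 / 8 | community size |
| genome_len_range | 12–20 kb | microbial genome length (desk-scale) |
| virus_len_range | 6–12 kb | viral genome length |
| contigs per microbe / virus | 2–4 / 1–2 | genomes split into contigs |
| abundance_dirichlet_alpha | 10 | evenness of relative abundances |
| arrays_per_host / spacers_per_array | 1–2 / 4–8 | CRISPR array sizes |
| repeat_len | 30 nt | direct repeat length |
| spacer_len_range | 26–45 nt | survives the >25 nt filter by construction |
| spacer_mutations_range | 0–2 | substitutions between spacer and protospacer |
| p_cross_domain_virus | 0.25 | fraction of viruses designated cross-domain |
| p_shared_repeat | 0.1 | arrays given another MAG's repeat verbatim |
| infection_rate | 0.2 | infected host's cellular pairs linking to a virus |
| seed | 7 | the pinned default fixture |

Genomes are i.i.d. uniform nucleotides (no GC skew): matching and
contact statistics are composition-agnostic at spacer lengths >25 nt
(a random 26-mer collision has probability 4⁻²⁶ per window), so
realistic composition would add nothing the method is sensitive to.
Arrays are serialized as leader + (repeat, spacer)×n + terminal repeat
and spliced into host contigs; spacer mutations are substitutions only,
matching the gap-free matcher. The number of cross-domain viruses is
the deterministic count `round(p · n_viruses)` rather than a Bernoulli
draw, so the planted truth is well-defined for exact recovery scoring;
each designated virus gets ≥2 anchor spacers in at least one bacterial
and one archaeal MAG. Shared-repeat planting skips those anchor arrays:
the method itself excludes shared repeats, so sharing an anchor would
silently erase the planted cross-domain signal the fixture exists to
test. Restriction-site counts (GATC for Sau3AI, AATT for MluCI) are
exported per contig as normalization covariates.

Reads are drawn uniformly per contig at abundance-weighted depth with
flat quality and optional uniform substitution errors; a truth
alignment table allows coverage computation without a mapper. Hi-C
pairs are labelled at generation: noise pairs place both ends uniformly
over all contig positions; cellular pairs pick a genome
abundance-weighted and place both ends uniformly within it (no distance
decay — downstream statistics only use contig-level counts), except
that infected hosts redirect a fraction `infection_rate` of their
cellular pairs to an infecting virus, intensity-weighted. Per-cell
virus copy number during infection is not an observable we can anchor,
so infection intensity is a free parameter (log-normal, σ=0.5).

The generator also provides the closed-form expectation of the noise
ratios under these rules (length-share arithmetic over MAGs and orders,
with the infection-redirected fraction removed from the intra terms),
which the tests use as the calibration target.

**What passing tests do and do not show.** Recovery at precision 1.0 /
recall ~1.0 on this simulator demonstrates the pipeline's logic is
sound under its own assumptions: substitution-only divergence within
the mismatch budget, error-free or low-error reads at ≥30× depth,
unique repeats per population except where planted otherwise. It does
not demonstrate robustness to assembly artefacts, strain microdiversity,
proviruses, chimeric bins or mapping error — real-data failure modes
the out-of-scope upstream tools are responsible for.

## Numerical choices and determinism

- All randomness flows through seeded numpy generators; one seed per
  operation, recorded in output headers and the manifest. Pipeline
  sub-seeds derive arithmetically from the config seed; reruns are
  byte-identical, which the tests assert on file hashes.
- Greedy clustering and dereplication iterate in deterministic sorted
  orders; GLM fitting is IRLS and deterministic.
- Dereplication is a k-mer (k=21) containment approximation of
  CD-HIT-EST-style clustering (−aS 0.85 −c 0.95): identity is estimated
  as the shared-window fraction over the covered span, de-biased by the
  k-th root (a 1% substitution rate leaves ≈0.99²¹ ≈ 0.81 of windows
  shared, estimating identity 0.81^(1/21) ≈ 0.99). Thresholds are
  configurable; this is an approximation, not a reimplementation.
- Degenerate inputs: empty repeat sets cluster to nothing; all-short
  spacer sets filter to empty with a warning; an empty prediction
  against non-empty truth reports precision 1.0 with zero support (and
  a warning); zero-coverage or zero-site contigs are floored at a
  pseudocount before taking logs; fewer than 10 eligible contact pairs
  is an error rather than an unstable fit.
- Problem sizes in the default validation fixture (desk-scale genomes,
  2×10⁵ contact pairs, 50 matcher-oracle instances of 1,000 spacers vs
  100 kb) were chosen so the full suite and the acceptance sweep run
  comfortably on a single CPU while keeping every statistical check
  well-powered.

## Known limitations

- Gapped protospacer hits are excluded by design; a real BLAST-based
  workflow could count an indel as a "mismatch".
- The Hi-C model has no distance decay and no zero-inflation; it is
  calibrated for contig-level linkage calling, not contact-map
  reconstruction.
- Multi-sample support is structural (per-sample fits, sample
  provenance on edges) but the default fixture is single-sample.
- Shannon diversity uses natural log (configurable upstream of the
  report only by transforming the output; the base is a convention).
- Benjamini–Hochberg is the default multiplicity adjustment; Bonferroni
  is available via the `method` argument.
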