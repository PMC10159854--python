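# spacerlink

Host–virus interaction inference for dense microbial communities, from
two independent lines of evidence:

1. **CRISPR immunity networks.** Bacteria and archaea record past viral
   encounters as spacers in their CRISPR arrays. spacerlink clusters
   high-evidence direct repeats (>95% identity, both strands), mines
   spacers straight from shotgun reads by repeat-anchored extraction,
   and matches them against viral contigs under the strict protospacer
   criterion — 100% query coverage with at most 2 mismatches on either
   strand. MAG-level bipartite edges count distinct matching spacer
   sequences; repeats found in more than one MAG are excluded because
   their spacers cannot be assigned to a taxon. Viruses whose host set
   spans both bacteria and archaea are reported as cross-domain.
2. **Hi-C proximity-ligation linkage.** Chimeric Hi-C read pairs link
   co-located genomes, including viruses replicating inside host cells.
   spacerlink counts contig-level contacts, fits a log-link count
   regression `log μ = β₀ + β₁log(ℓ_aℓ_b) + β₂log(c_ac_b) + β₃log(s_as_b)`
   (length, coverage, restriction-site covariates) over inter-contig
   pairs, scores each pair by its Pearson residual `(y−μ)/√(μ+αμ²)`,
   consolidates host–virus contig links to MAG level (count / mean /
   max residual), and reports the inter-cell noise floor as
   raw = inter-MAG/intra-MAG and relaxed = inter-order/intra-order
   contact ratios.

Because real mat metagenomes are far beyond desk scale, the package
ships a first-class synthetic community generator that plants the exact
structures the method assumes — CRISPR arrays whose spacers are mutated
viral subsequences, abundance-weighted reads, and labelled Hi-C pairs
(intra-cell / infection / inter-cell noise) — so precision, recall and
noise calibration can be scored against known truth.

Audience: microbiome and viral-ecology researchers who want a tested,
reproducible reference implementation of spacer-based and Hi-C-based
host assignment, or a planted-truth harness to validate their own.

## Worked example

```python
from spacerlink import CommunityConfig, run_pipeline

result = run_pipeline(CommunityConfig(), mean_depth=30.0,
                      n_hic_pairs=200_000, noise_fraction=0.02)
print(f"immunity edges: {len(result.edges)}")
print(f"precision {result.recovery.precision:.2f}, recall {result.recovery.recall:.2f}")
print(f"cross-domain viruses: {sorted(result.cross_domain['vmag_id'])}")
print(f"raw noise {result.noise.raw_noise:.4f}, relaxed {result.noise.relaxed_noise:.4f}")
```

prints (seed 7, the default):

```
immunity edges: 60
precision 1.00, recall 1.00
cross-domain viruses: ['vMAG_04', 'vMAG_07']
raw noise 0.0201, relaxed 0.0168
```

All 60 planted host–virus immunity pairs are recovered with no false
edges; the two viruses planted with spacers in both bacterial and
archaeal MAGs are the two detected; the measured Hi-C noise ratios sit
on the simulator's closed-form expectation for a 2% inter-cell noise
fraction (raw 0.0202, relaxed 0.0169), with relaxed ≤ raw as the
order-level definition implies.

The same run is available from the shell:

```bash
spacerlink run --outdir out/          # simulate → mine → match → network → hic → report
spacerlink simulate --outdir sim/     # just the synthetic community + reads + contacts
spacerlink mine-spacers --repeats sim/repeats.tsv --reads sim/reads.fastq --out spacers.tsv
```

`out/` contains the immunity and Hi-C networks (TSV + GraphML),
normalized linkages, the noise report, abundance/diversity tables and a
`manifest.json` recording every seed and threshold. Reruns with the
same config are byte-identical.

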