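# pcpg-somatics

Pipeline primitives for multi-sample somatic tumour cohorts:

- **snv_consensus** — 2-of-3 multi-caller consensus acceptance, a
  panel-of-normals blacklist (≥3 supporting reads in more than two normal
  controls), a pooled reject:pass-ratio blacklist (ratio strictly > 1), and
  tumour mutation burden (mut/Mb).
- **sv_filter** — structural-variant recurrence blacklist (exact breakpoint
  pair observed in more than two unrelated patients, pass or reject) and the
  read-support filter (≥3 split reads, or ≥3 paired reads, or ≥1 of each).
- **signatures** — SBS-96 / DBS-78 context classification, catalog
  construction, non-negative least-squares refitting onto a signature
  matrix, and cohort-level reporting thresholds (≥15% of a sample's fitted
  total and ≥500/50/10 mutations for SBS/ID/DBS).
- **telomere** — telomere content (intratelomeric reads per GC-matched
  million), tumour:blood log2 enrichment classification (strictly > 0.5),
  per-TVR differential usage between C-circle groups (Welch t-test,
  Benjamini–Hochberg), canonical-TVR proportion.
- **cn_msi** — GISTIC input transform log2(CN + 0.01) − 1, small-segment
  joining (< 50 markers, marker-weighted merge into the nearer-CN
  neighbour), percent genome altered relative to sample ploidy, and MSI
  scoring (> 4 microsatellite indels/Mb).
- **clonal** — per-patient variant unification with the 1–3-read exclusion
  band, the copy-number-aware variant-read-probability (VRP) rule table,
  a binomial-mixture EM subclone-frequency estimator (simplified stand-in,
  validated by parameter recovery), and shared/private partitioning for
  sample pairs.
- **synthetic** — seeded generator of every fixture above with recorded
  ground truth (caller calls with planted panel artifacts, clone-tree read
  counts, CN segments, telomere/TVR tables, signature-mixture catalogs,
  SV calls, MSI burdens). Identical seed + config ⇒ byte-identical output.

All exchange formats are plain text (minimal VCF 4.2, SEG-style TSV, TSV
count tables, JSON sidecars).

## CLI

```bash
# full seeded demo pipeline (simulate → filter → signatures → telomere →
# cn/msi → clonal), writes a manifest with content digests
pcpg-somatics run --seed 11 --outdir out/

# individual stages
pcpg-somatics simulate --seed 3 --outdir fixtures/
pcpg-somatics filter-snv --calls fixtures/calls.vcf --out filtered.vcf \
    --blacklist-out blacklist.tsv
pcpg-somatics filter-sv --calls fixtures/sv_calls.tsv --out kept.tsv
pcpg-somatics fit-signatures --catalog catalog.tsv --signatures sigs.tsv \
    --scheme SBS96 --out exposures.tsv
pcpg-somatics telomere --counts fixtures/telomere_counts.tsv --out stats.tsv
pcpg-somatics gistic-prep --seg fixtures/segments.seg --out gistic.seg
pcpg-somatics msi --counts fixtures/msi_inputs.tsv
pcpg-somatics pga --seg fixtures/segments.seg
pcpg-somatics vrp --grid recall_grid.tsv --seg segments.seg --out vrp.tsv
pcpg-somatics cluster --grid recall_grid.tsv --seg segments.seg --k 2 \
    --seed 0 --out clones.json
```

Re-running `run` with the same seed reproduces byte-identical outputs
(checked via the manifest's SHA-256 digests).

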