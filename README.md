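# venomont

Venom-gland transcriptomic ontogeny analysis for snakes, built around the
study design of paired adult/juvenile individuals sampled across
populations. The package identifies which toxin loci drive an ontogenetic
(age-related) shift in venom composition, and provides the surrounding
pipeline stages needed to get there from raw merged RNA-seq reads:

* **Greedy seed-extension assembly** (`venomont.assembler`) — extends read
  seeds through highly paralogous toxin families using an exact 120-nt
  overlap rule, with per-contig read support and coverage profiles.
* **Consensus transcriptome construction** (`venomont.consensus`) —
  clusters assembled transcripts at ≤1% nucleotide divergence within
  individuals and ≤1.5% across individuals (single linkage over
  global-alignment p-distance), takes column-majority consensus
  sequences, and screens chimeric assemblies by coverage steps.
* **Presence/absence calling** (`venomont.presence_absence`) — maps reads
  end-to-end (≤2 mismatches) and declares a transcript absent from a
  transcriptome when >10% of its coding sequence has <5× coverage.
* **Compositional outlier test** (`venomont.ontogeny`) — the core
  statistic. TPM expression is a composition, so analysis happens on
  centered log-ratios, clr\_i = ln x\_i − (1/D) Σ\_j ln x\_j, after
  flooring zeros at 1 TPM. For each adult/juvenile population pair the
  per-transcript difference Δ = clr(adult) − clr(juvenile) is compared
  with an empirical null: the 99th percentile of |Δ| over the (large)
  nontoxin background. A toxin is called ontogenetically variable only
  when it is an outlier in ≥3 of 5 population pairs with a consistent
  direction in ≥3 — a majority-consensus rule that absorbs geographic
  expression variation. Calls can be cross-checked against external
  DESeq/DESeq2 detections at FDR 0.1.
* **Median lethal dose** (`venomont.toxicity`) — Spearman-Karber LD50 on
  a two-fold serial-dilution design, with binomial standard errors,
  optional trimming, and isotonic smoothing of non-monotone mortality.
* **Synthetic data** (`venomont.synthetic`) — generators for paired
  expression matrices with planted log-fold-changes and a truth table,
  paralog families at controlled divergence, uniform-coverage merged
  reads with dropout, chimeric transcripts, and binomial dose-mortality
  tables; every downstream stage is testable without any downloads.

Transcriptions of the published summary tables (toxin TPM matrix,
presence/absence matrices at two read depths, per-population outlier
flags, and DESeq/DESeq2 adjusted p-values for 59 toxin transcripts of
*Crotalus adamanteus*) ship as packaged fixtures, loadable with
`venomont.load_fixture(...)`.

## Worked example

Reproduce the consensus ontogeny calls from the packaged fixtures:

```
$ venomont --out-dir out repro-table5
13 toxins upregulated in adults, 4 downregulated, 12 confirmed by DESeq/DESeq2 -> out/consensus_calls.tsv
```

Of 59 toxin transcripts, 13 are upregulated and 4 downregulated in adults
under the majority-consensus rule; 12 of those 17 are independently
confirmed by DESeq or DESeq2 and constitute the conservative estimate of
the loci behind the ontogenetic venom shift. The per-transcript detail is
in `out/consensus_calls.tsv` (outlier counts, direction counts, call,
confirmation).

The presence/absence summary:

```
$ venomont --out-dir out repro-table4
full reads: 17 variable transcripts, mean missing 4.5 (adults 3.2, juveniles 5.8, max 13)
9.5M reads: 20 variable transcripts, mean missing 5.4
```

17 of 59 toxins (29%) are missing from at least one of the ten
transcriptomes, 4.5 on average per transcriptome; equalizing read counts
at 9.5M reads per sample raises this to 20 and 5.4. The adult/juvenile
means (3.2 vs 5.8) are not significantly different (Welch t-test,
p ≈ 0.31).

The same stages run on synthetic data end to end:

```
$ venomont --seed 7 --out-dir sim simulate --n-nontoxins 2000
$ venomont --out-dir sim ontogeny --expression sim/expression.tsv --catalog sim/catalog.tsv
0 up, 0 down -> sim/consensus_calls.tsv
```

(no effects planted, none called). An LD50 from a dose-mortality CSV:

```
$ venomont ld50 --input doses.csv
{"ld50": 3.999999999999999, "log10_se": 0.05688932183555331, "warnings": []}
```

(a symmetric mortality step at the middle dose of a two-fold series: the
estimator returns that dose exactly, up to floating point).

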