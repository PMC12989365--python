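# micapop

Population-genetic analysis of MICA genotyping data, built around the
reporting quirks of high-throughput immunogenetics workflows:

- **Nomenclature** (`micapop.alleles`) — parsing of `LOCUS*F1:F2…[SUFFIX][#]`
  allele names, first-field (protein-resolution) reduction, hash-marked
  ambiguity groups with a packaged group fixture, and submission-ledger
  arithmetic.
- **Synthetic cohorts** (`micapop.cohort`) — diploid Hardy–Weinberg sampling
  per population with hash-group masking, deletion (reported homozygous) and
  duplication (three reported alleles) artifacts, phasing-ambiguity candidate
  sets, and deterministic MICA→HLA-B haplotype linkage. Calls keep their
  pre-masking haplotypes so parameter recovery can be verified.
- **Frequency estimation** (`micapop.frequencies`) — two-pass estimator:
  direct counting of unambiguous calls, then Hardy–Weinberg-weighted
  allocation of ambiguous calls over their candidate sets; optional smoothing
  and EM refinement; cumulative NEW (unnamed-allele) frequency; deletion-bias
  experiment.
- **Population comparison** (`micapop.compare`) — per-allele frequency-ratio
  tables against a reference population with strict over-twofold / under-half
  flagging, plus population-specific allele reports.
- **Linkage** (`micapop.linkage`) — MICA↔HLA-B association by the
  co-occurrence rule (≥ 10 unambiguous carriers, all positive for one HLA-B
  allele).
- **Protein variation** (`micapop.proteins`) — reference-anchored star
  alignment in mature-protein coordinates, per-allele difference calls,
  Met/Val classification at position 129, frameshift / premature-stop null
  detection on coding sequences, nearest-frequent-allele grouping.
- **Phylogeny** (`micapop.phylo`) — hamming distance matrices, deterministic
  neighbor joining (additive-exact), midpoint rooting, square-root branch
  display transform, byte-stable Newick round-trip.

## CLI

All stages are exposed through one entry point; every run writes a JSON run
report (`<out>.report.json`) with inputs, seed and warnings.

```bash
micapop simulate --config cfg.json --out cohort.tsv --seed 1
micapop freq     --cohort cohort.tsv --population DE_Germany --out de.csv
micapop compare  --ref de.csv --pop pl.csv --pop tr.csv --out ratios.csv
micapop linkage  --cohort cohort.tsv --min-count 10 --out linkage.csv
micapop align    --fasta proteins.fasta --reference 'MICA*002' --out aln.fasta
micapop variants --fasta proteins.fasta --reference 'MICA*002' --out variants.csv
micapop tree     --alignment proteins.fasta --reference 'MICA*002' \
                 --exclude-nulls --sqrt-display --out tree.nwk
micapop ledger   --csv ledger.csv
```

Cohort tables are TSV with columns `sample_id`, `population`, `candidates`
(semicolon-separated candidate pairs, alleles `+`-joined) and `hla_b`.
Frequency tables are CSV (`allele,count,frequency`) with `#`-prefixed
metadata lines.

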