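# snpforge

A toolkit for building a genotyping-array SNP resource from discovery
variant calls and analysing the resulting population data:

* **synthetic_data** — simulators for every input the pipeline consumes:
  two-level (regions ⊃ populations) Balding–Nichols genotypes with
  per-population inbreeding, discovery VCFs with planted artifacts (indels,
  SNP clusters, low-complexity regions, heterozygous-haploid calls,
  low-confidence genotypes), array call matrices with missingness and
  duplicated samples, and STRUCTURE-style log-likelihood tables.  Every
  simulator emits a truth ledger for recovery testing.
* **ascertainment** — simultaneous SNP-exclusion tagging
  (`LowConfidenceNulled`, `TypeIndel`, `SnpGap`, `snpCluster`,
  `LowComplexityRegion`, `Homopolymer`, `FailureOnGatkHardFilter`,
  `FailHaploidTest`, `FlankTooShort`, `NonSingleProbeType`,
  `ExcludedContig`), DUST-style low-complexity detection, per-tag count
  summaries and selection of the tag-free assayable-SNP catalog.
* **probe_design** — 71-base probe context extraction (35 bp flanks, both
  strands), canonical 16-mer indexing of the reference and the
  >100-matches screening rule, plus capped per-contig random array-content
  sampling.
* **array_qc** — sample QC (DQC > 0.82, CR > 0.97), per-SNP call metrics,
  Axiom-style classification (PHR/MHR/NMH/CRBT), conventional success
  (CR ≥ 90%) and conversion (+ MAF ≥ 0.005) flags, duplicate-pair
  reproducibility and a per-source performance summary table.
* **popgen** — observed/unbiased expected heterozygosity, Weir–Cockerham
  f and θ (multilocus ratio of sums, bootstrap CIs), three-level AMOVA
  with permutation tests, pairwise Fst, squared-increment genetic
  distances with PCoA, locus subset resampling, the site frequency
  spectrum and the Evanno ΔK diagnostic.  Multiallelic (microsatellite)
  data is supported through a shared allele-dosage representation.
* **io / cli** — VCF v4.2 (FORMAT `GT:GQ:GC`), FASTA, BED, CSV readers and
  writers plus an umbrella `snpforge` command.

## Command line

```bash
snpforge run --config config.yaml --out results/      # full simulated pipeline
snpforge simulate --kind discovery --seed 1 --out sim/
snpforge ascertain --vcf sim/discovery.vcf --ref sim/reference.fasta \
    --source rad --out asc/
snpforge design-probes --catalog asc/catalog.csv --ref sim/reference.fasta \
    --n-target 100 --out probes/
snpforge array-qc --calls calls.csv --samples samples.csv --out qc/
snpforge popgen --calls calls.csv --samples samples.csv --boot 1000 \
    --perm 999 --seed 1 --out popgen/
snpforge evanno --lnp likelihoods.csv --out evanno.csv
```

A pipeline config is a YAML file with optional sections `discovery`,
`ascertainment`, `probes`, `population`, `array`, `array_qc`, `popgen`,
`structure` and a global `seed`; unknown keys are rejected and the
resolved config is copied next to the outputs, which makes any run
reproducible byte-for-byte.

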