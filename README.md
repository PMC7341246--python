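# herdgen

Genomic management toolkit for small, fragmented livestock populations
genotyped on medium-density SNP arrays — the typical situation of local
endangered cattle breeds, where a few dozen related sires carry the breed
and inbreeding control is the central concern.

It implements, as one tested pipeline:

- **Quality control** of PLINK genotypes (call rate, MAF, exact
  Hardy–Weinberg test) and pairwise-r² LD pruning;
- **Runs of homozygosity** by sliding window and the genomic inbreeding
  coefficient *F*<sub>ROH</sub> = Σ len(ROH ≥ L) / covered autosome length,
  at L = 4 Mb and 8 Mb;
- **LD decay and ancestral Ne**: binned mean r² inverted through
  E[r²] ≈ 1/(α + 4·Ne·c) + 1/(βn), giving Ne at t ≈ 1/(2c) generations ago;
- **Animal-model BLUP** (Henderson's MME with A⁻¹ from the Meuwissen–Luo
  recursion; optional maternal and permanent-environment terms), EM-REML
  variance components, and **Garrick-style deregression** of EBVs
  (DEBV = EBV/r², w = (1−c)/[c + (1−r²)/r²]);
- **Single-SNP GWAS** of deregressed EBVs with principal-component
  stratification correction (χ²₁ = (n−k−1)·r² score test), genomic-control
  λ adjustment, dual significance thresholds (5×10⁻⁶ genome-wide,
  5×10⁻⁵ suggestive), per-SNP variance explained, and GFF3 feature labels;
- **Synthetic cohorts** with exact ground truth: pedigree simulation with
  controllable close-kin mating, gene drop with founder-allele tracking
  (true IBD segments), Wright–Fisher drift with recombination, and
  animal-model phenotype/EBV generation.

See `docs/methods.md` for model details and assumptions.

## Worked example

Simulate an inbred island herd (44 founders, three generations with
full-sib-mating probability 0.25, 29 autosomes of 90 Mb at 50K-chip
density), then run the ROH branch of the pipeline:

```python
from herdgen import *
from herdgen.genio import apply_snp_selection
from herdgen.roh import covered_genome
from herdgen.simulate import ChromosomeSpec

cfg = SimConfig(seed=11, n_founders=44, n_generations=3, mating="close_kin",
                close_kin_prob=0.25,
                chrom=ChromosomeSpec(n_chrom=29, length_bp=90_000_000))
ped = sim_pedigree(cfg)
genos, truth = gene_drop_genotypes(ped, cfg)
cohort = list(ped.df[ped.df["generation"] == 3]["animal"])[:42]
genos = genos.subset(sample_idx=[genos.samples.index(a) for a in cohort])

qc_ds, report = qc_filter(genos, QCParams())
pruned = apply_snp_selection(qc_ds, ld_prune(qc_ds))
segments = detect_roh(pruned, ROHParams())
froh = compute_froh(segments, covered_genome(pruned), samples=pruned.samples)
table = length_class_table(segments)

print(f"retained {report.n_snps_retained} SNPs in {report.n_samples_retained} animals; "
      f"{pruned.n_snps} after pruning")
print(f"{len(segments)} ROH; mean F_ROH = {froh.mean():.3f} "
      f"(true autozygosity {truth.autozygosity[cohort].mean():.3f})")
print(table.to_string(index=False))
```

prints

```
retained 50568 SNPs in 42 animals; 40961 after pruning
527 ROH; mean F_ROH = 0.100 (true autozygosity 0.099)
length_class_mb  n_roh  frequency_pct
            4–8    109           20.7
           8–16    154           29.2
            >16    264           50.1
```

The detector's mean *F*<sub>ROH</sub> (0.100) matches the gene-drop truth
(0.099) to three decimals, and half the segments exceed 16 Mb — the long-ROH
signature of the recent close-kin matings the simulation planted.

## Command line

Every stage is also a subcommand over a YAML config:

```sh
herdgen simulate --scale full --seed 1 --out cohort/
herdgen all --config pipeline.yaml          # qc → roh | ld → ne | deregress → gwas
herdgen qc|roh|ldne|deregress|gwas ...      # individual stages
```

The run report (`run_report.json`) echoes the full configuration, so a rerun
with the same config and seed reproduces it byte for byte.

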